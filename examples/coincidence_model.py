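"""The Poisson-coincidence search model: closed forms vs simulation.

Recognition of a degraded image is modelled as the first window in which
all nu missing components of the object's representation are active at
once; search times are exponential with rate p**nu/tau, and their log10
has a rate-independent SD of pi/(sqrt(6) ln 10) ~ 0.557.
"""

import numpy as np

from emrec.coincidence import (
    SD_LOG10_EXPONENTIAL,
    CoincidenceParams,
    coincidence_rate,
    log_time_moments,
    sample_search_times,
    simulate_mechanistic_batch,
)

params = CoincidenceParams(nu=2, p=0.1, tau=1.0)
rate = coincidence_rate(params)
mom = log_time_moments(rate)
print(f"rate for nu={params.nu}, p={params.p}, tau={params.tau}: {rate:.4f} /s")
print(f"analytic mean log10 t = {mom.mean_log10:.3f}, SD = {mom.sd_log10:.4f}")

t_exact = sample_search_times(rate, 200_000, rng_seed=0)
t_step = sample_search_times(rate, 200_000, method="stepwise", step=0.1, rng_seed=0)
t_mech = simulate_mechanistic_batch(params, 200_000, rng_seed=0)
for name, t in [("exact", t_exact), ("stepwise", t_step), ("mechanistic", t_mech)]:
    lg = np.log10(t[np.isfinite(t)])
    print(f"{name:>11}: mean log10 t = {lg.mean():+.3f}, SD = {lg.std(ddof=1):.3f}")

print(
    f"\nThe exact sampler reproduces the Gumbel constant "
    f"{SD_LOG10_EXPONENTIAL:.4f}; the discrete-window samplers sit slightly "
    "below it (their grid clips the fast tail) and converge to it as the "
    "window shrinks. The spread of log search times does not depend on how "
    "hard the image is, only the mean does."
)
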