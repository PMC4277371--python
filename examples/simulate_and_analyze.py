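"""Generate a synthetic recognition study and recover its parameters.

Simulates 91 subjects x 90 degraded images at the default operating point
(kappa = 1.17, capability gain A = 0.40, time constant C = 0.05 s, 30 s
censoring, 30 ms timer), runs the corrected analysis pipeline, and compares
what comes out against the generator's ground truth.
"""

import numpy as np
from scipy.stats import spearmanr

from emrec import analyze_er_study, simulate_er_study
from emrec.synthetic import PopulationParams, StudyDesign

pop = PopulationParams()
design = StudyDesign()
trials = simulate_er_study(pop, design, rng_seed=42)
print(f"trials: {len(trials)}, censored fraction {trials['censored'].mean():.2f}")

res = analyze_er_study(trials, corrected=True, delta=0.30)
print(f"\nrecovered period kappa = {res.kappa:.2f}  (generator used {pop.kappa})")
print(f"mean-SD regression: A = {res.fit.A:.3f}, B = {res.fit.B:.3f} (r2 = {res.fit.r2:.2f})")
print(f"time constant C = {res.fit.C:.3f} s, coincidence window tau = {res.fit.tau:.3f} s")
print(f"p0 = 10^-kappa = {res.p0:.3f}")

truth_nu = trials.drop_duplicates("image_id").set_index("image_id")["nu"]
ist = res.image_stats.set_index("image_id")
match = (ist["nu"] == truth_nu.loc[ist.index]).mean()
print(f"\nimages fitted: {len(ist)} of {design.n_images}; "
      f"missing-component count exact for {match:.0%} of them")

truth_z = trials.drop_duplicates("subject_id").set_index("subject_id")["true_Z"]
sc = res.subject_scores.set_index("subject_id")
rho = spearmanr(sc["mean_z"], truth_z.loc[sc.index]).statistic
print(f"subject capability vs generating Z: Spearman rho = {rho:.3f}")
print(
    "\nUnder 30 s censoring the period and regression constants carry "
    "substantial sampling noise (hard images are fitted from their fastest "
    "responders only); the subject ranking is robust regardless."
)
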