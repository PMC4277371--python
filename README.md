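# emrec

Stochastic modelling and analysis of **emergent recognition** — the sudden,
uncued recognition of an object hidden in a severely degraded image after
seconds to tens of seconds of viewing.

The package is aimed at researchers modelling long-tailed recognition
times. It implements, end to end:

* **A Poisson-coincidence search model.** A degraded image silences ν
  "missing components" of the object's stored representation; each
  activates spontaneously with probability *p* within a coincidence window
  τ, so full coincidences occur at rate λ = *p*^ν/τ and the search time is
  exponential. The log₁₀ of an exponential time has mean
  (−ln λ − γ)/ln 10 (γ Euler's constant) and the rate-independent SD
  π/(√6·ln 10) ≈ **0.557** — the within-subject floor of any observed
  spread of log search times.
* **The analysis pipeline.** Per-image log-normal fits of log₁₀ search
  times on censoring-aware normal probability plots; reversed z-scores and
  subject capabilities Z̄; the regression σ = A·m + B across images, giving
  the time constant C = 10^(−B/A) and window τ = e^γ·C; image difficulty
  M = m + B/A and a grid scan for its period κ (so that M/κ ≈ ν ∈ ℕ);
  model-based corrections (300 ms interval correction, SD correction
  σ_between = √(σ² − 0.557²)) and the selection rule for the correction
  interval; Monte Carlo replication of the whole experiment.
* **A synthetic-study generator** with the full statistical structure the
  analysis assumes (standard-normal capabilities, log₁₀ p = −κ(1 − A·Z),
  common reaction-time components, 30 s censoring, 30 ms quantization), so
  every stage is testable against ground truth without any data download.
* **A drift-diffusion comparison.** A two-boundary DDM simulator with
  closed-form cross-checks, latency–probability functions, and the mirror
  analysis of decision times showing the structural contrast: diffusion
  decisions slow *linearly* with difficulty (flat SD of log decision
  times), coincidence search slows *exponentially* (SD grows with the
  mean).
* **Stimulus synthesis**: monochromatic binarization and weighted-mean-phase
  (WMP) Fourier degradation with magnitude averaging and luminance/contrast
  normalization.

## Worked example

```bash
python examples/simulate_and_analyze.py
```

prints, for one simulated 91 × 90 study at the default operating point:

```
trials: 8190, censored fraction 0.56

recovered period kappa = 1.28  (generator used 1.17)
mean-SD regression: A = 0.509, B = 0.160 (r2 = 0.91)
time constant C = 0.485 s, coincidence window tau = 0.864 s
p0 = 10^-kappa = 0.052

images fitted: 72 of 90; missing-component count exact for 28% of them
subject capability vs generating Z: Spearman rho = 0.937
```

The censored operating point is deliberately hard: hard images are fitted
from their fastest responders only, so κ, A and C carry visible sampling
noise, while the subject ranking (ρ ≈ 0.94) is robust. On an uncensored
validation design the same pipeline recovers ν exactly for 100% of images
and κ within a few hundredths (see `tests/test_acceptance.py`).

Other examples: `examples/coincidence_model.py` (closed forms vs three
samplers), `examples/interval_correction.py` (the 7.4-image expectation and
the 300 ms selection), `examples/pdm_comparison.py` (the DDM contrast),
`examples/wmp_stimuli.py` (stimulus degradation).

## Layout

```
src/emrec/coincidence.py   closed forms and samplers of the search model
src/emrec/synthetic.py     synthetic-study generator + trial-table I/O
src/emrec/pipeline.py      the analysis pipeline and corrections
src/emrec/ddm.py           drift-diffusion simulation and PDM comparison
src/emrec/stimuli.py       binarization and WMP degradation
docs/methods.md            model, calibration and design notes
```
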