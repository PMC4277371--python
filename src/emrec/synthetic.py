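"""Synthetic emergent-recognition (ER) studies with known ground truth.

The generator emulates the statistical structure the ER analysis assumes:

* ``n_subjects`` latent capabilities Z drawn standard normal; a subject's
  per-window activation probability follows ``log10 p = -kappa*(1 - A*Z)``,
  so the population log10 p has mean ``-kappa`` (defining ``p0 = 10**-kappa``)
  and SD ``kappa*A``.

Default population parameters (kappa = 1.17, A = 0.40, C = 0.05 s) and the
default missing-component composition (peaks of 16 and 25 images at nu = 1
and 2, tail out to nu = 7 over 90 images) are calibrated so the simulated
study reproduces the observable profile of the experiment the analysis was
designed for: nearly every subject answers the easiest images (geometric
mean search time ~0.7 s), the hardest images are answered by only ~5 of 91
subjects within the 30 s limit, and a small percentage of search-time
estimates come out negative on the easiest images.
* each image carries a number of missing components ``nu``; the search time
  for subject x image is exponential with rate ``p**nu / tau`` where
  ``tau = e^gamma * C`` seconds.
* the observed reaction time for a degraded image adds a common (non-search)
  component, log-normal with mean 0.77 s and SD 0.42 s across subject x
  image cells, plus a fixed decision surplus of 300 ms specific to degraded
  stimuli; the color-image reaction time is a common draw alone.  The
  degraded and color presentations of one subject x image cell share the
  same common draw — the premise of the subtraction that defines the search
  time — and differ only by independent per-presentation motor jitter
  (default SD 0.12 s); ``common_mode`` switches to fully independent draws
  (a deliberately adversarial condition) or to exactly paired ones.
* degraded trials are censored at the 30 s presentation limit and all
  recorded times are quantized to the 30 ms timer resolution.

Defaults (91 subjects, 90 images, kappa = 1.17, nu weighted 16:25 over
{1, 2}) reproduce the scale of the study the analysis was designed for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .coincidence import EULER_GAMMA, ParameterError

__all__ = [
    "PopulationParams",
    "StudyDesign",
    "SubjectProfile",
    "draw_subjects",
    "draw_images",
    "simulate_er_study",
    "trials_to_long",
    "write_trials",
    "read_trials",
    "write_config",
    "read_config",
]


@dataclass(frozen=True)
class PopulationParams:
    """Population-level parameters linking capability to activation probability.

    Parameters
    ----------
    n_subjects : int
        Number of subjects (default 91).
    kappa : float
        Period of image difficulty in log10 units; ``p0 = 10**-kappa`` is
        the activation probability of the mean-capability subject.
    slope_a : float
        Capability gain A (dimensionless): ``log10 p = -kappa*(1 - A*Z)``.
    const_c : float
        Time constant C in seconds; the coincidence window is
        ``tau = e^gamma * C``.
    """

    n_subjects: int = 91
    kappa: float = 1.17
    slope_a: float = 0.40
    const_c: float = 0.05

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if not self.kappa > 0:
            raise ParameterError("kappa must be positive")
        if self.slope_a < 0:
            raise ParameterError("slope_a must be nonnegative")
        if not self.const_c > 0:
            raise ParameterError("const_c must be positive")

    @property
    def p0(self) -> float:
        """Activation probability of the mean-capability subject (Z = 0)."""
        return 10.0 ** (-self.kappa)

    @property
    def tau(self) -> float:
        """Coincidence window length in seconds, e^gamma * C."""
        return math.exp(EULER_GAMMA) * self.const_c

    def p_of_z(self, z: float | np.ndarray) -> np.ndarray:
        """Map capability Z to activation probability p."""
        return 10.0 ** (-self.kappa * (1.0 - self.slope_a * np.asarray(z, dtype=float)))

    def z_max_valid(self) -> float:
        """Largest Z for which the mapping stays inside p <= 1 (inf if A = 0)."""
        if self.slope_a == 0:
            return math.inf
        return 1.0 / self.slope_a


def _default_nu_weights() -> dict[int, float]:
    # peaks of 16 and 25 at nu = 1 and 2 as observed, with a tail to nu = 7
    return {1: 16.0, 2: 25.0, 3: 18.0, 4: 12.0, 5: 9.0, 6: 6.0, 7: 4.0}


@dataclass(frozen=True)
class StudyDesign:
    """Design of one synthetic ER session."""

    n_images: int = 90
    nu_weights: dict[int, float] = field(default_factory=_default_nu_weights)
    time_limit: float = 30.0
    rt_common_mean: float = 0.77
    rt_common_sd: float = 0.42
    rt_trial_jitter_sd: float = 0.12
    decision_surplus: float = 0.30
    quantization: float = 0.03

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ParameterError("n_images must be >= 1")
        if not self.time_limit > 0:
            raise ParameterError("time_limit must be positive")
        if self.rt_common_mean < 0 or self.rt_common_sd < 0:
            raise ParameterError("common reaction-time moments must be nonnegative")
        if self.rt_trial_jitter_sd < 0:
            raise ParameterError("rt_trial_jitter_sd must be nonnegative")
        if self.decision_surplus < 0 or self.quantization < 0:
            raise ParameterError("decision_surplus and quantization must be nonnegative")


@dataclass(frozen=True)
class SubjectProfile:
    """One subject's latent capability Z and activation probability p."""

    subject_id: int
    Z: float
    p: float


def draw_subjects(
    pop: PopulationParams,
    rng_seed: int | np.random.Generator | None = None,
    saturate_p: bool = False,
) -> list[SubjectProfile]:
    """Draw subject capabilities Z ~ N(0,1) and map them to probabilities.

    With ``saturate_p=True`` a Z beyond ``1/slope_a`` gets p clipped to 1
    (capability saturation: that subject needs a single coincidence window).

    Raises
    ------
    ParameterError
        If ``saturate_p`` is False and a sampled Z maps to p > 1 (the error
        names the offending Z).
    """
    rng = np.random.default_rng(rng_seed)
    z = rng.standard_normal(pop.n_subjects)
    p = pop.p_of_z(z)
    bad = np.nonzero(p > 1.0)[0]
    if bad.size:
        if not saturate_p:
            raise ParameterError(
                f"sampled Z = {z[bad[0]]:.4f} maps to p = {p[bad[0]]:.4f} > 1 "
                f"(requires Z <= {pop.z_max_valid():.4f} at these parameters)"
            )
        p = np.minimum(p, 1.0)
    return [SubjectProfile(subject_id=i, Z=float(z[i]), p=float(p[i])) for i in range(pop.n_subjects)]


def draw_images(
    design: StudyDesign,
    nu_weights: dict[int, float] | None = None,
    rng_seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Sample per-image missing-component counts nu by weight."""
    weights = design.nu_weights if nu_weights is None else nu_weights
    if not weights:
        raise ParameterError("nu_weights must be non-empty")
    nus = np.array(sorted(weights), dtype=int)
    w = np.array([weights[int(v)] for v in nus], dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ParameterError("nu weights must be nonnegative and not all zero")
    if np.any(nus < 1):
        raise ParameterError("all nu values must be >= 1")
    rng = np.random.default_rng(rng_seed)
    return rng.choice(nus, size=design.n_images, p=w / w.sum())


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal for a log-normal with given mean/SD."""
    if mean <= 0:
        raise ParameterError("log-normal mean must be positive")
    s2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


def _quantize(x: np.ndarray, q: float) -> np.ndarray:
    if q <= 0:
        return x
    return np.round(x / q) * q


def simulate_er_study(
    pop: PopulationParams,
    design: StudyDesign,
    rng_seed: int | np.random.Generator | None = None,
    nu_per_image: np.ndarray | None = None,
    common_mode: str = "shared",
) -> pd.DataFrame:
    """Simulate a full subject x image trial table.

    Returns a wide DataFrame with one row per subject x image and columns
    ``subject_id, image_id, nu, rt_degraded, rt_color, censored,
    true_search_time, true_Z``.  ``rt_degraded`` is NaN on censored trials
    (accumulated degraded presentation exceeded ``time_limit``).

    ``common_mode`` controls the non-search component of the two
    presentations of a subject x image cell:

    * ``"shared"`` (default): one common draw per cell shared by the
      degraded and color presentations — the premise under which the
      subtraction isolates the search time — plus independent Gaussian
      per-presentation jitter (``rt_trial_jitter_sd``, truncated at zero).
    * ``"independent"``: fully independent common draws, a deliberately
      adversarial condition that injects sqrt(2)*rt_common_sd of noise
      into every search-time estimate.
    * ``"paired"``: shared draw and no jitter, so
      ``rt_degraded - rt_color`` recovers the search time exactly up to
      surplus and quantization (for exact-recovery tests).
    """
    if common_mode not in ("shared", "independent", "paired"):
        raise ParameterError(f"unknown common_mode {common_mode!r}")
    rng = np.random.default_rng(rng_seed)
    subjects = draw_subjects(pop, rng, saturate_p=True)
    if nu_per_image is None:
        nu_per_image = draw_images(design, rng_seed=rng)
    nu_per_image = np.asarray(nu_per_image, dtype=int)
    if nu_per_image.shape != (design.n_images,):
        raise ParameterError("nu_per_image must have length n_images")

    n_s, n_i = pop.n_subjects, design.n_images
    p = np.array([s.p for s in subjects])[:, None]  # (n_s, 1)
    rate = p ** nu_per_image[None, :] / pop.tau  # (n_s, n_i)
    t = rng.exponential(scale=1.0 / rate)

    if design.rt_common_mean > 0:
        mu, sig = _lognormal_params(design.rt_common_mean, design.rt_common_sd)
        base = rng.lognormal(mu, sig, size=(n_s, n_i))
    else:
        base = np.zeros((n_s, n_i))
    if common_mode == "independent":
        common_deg = base
        common_col = rng.lognormal(mu, sig, size=(n_s, n_i)) if design.rt_common_mean > 0 else base
    else:
        common_deg = base
        common_col = base
        if common_mode == "shared" and design.rt_trial_jitter_sd > 0:
            j = design.rt_trial_jitter_sd
            common_deg = np.clip(base + rng.normal(0.0, j, size=(n_s, n_i)), 0.0, None)
            common_col = np.clip(base + rng.normal(0.0, j, size=(n_s, n_i)), 0.0, None)

    rt_deg = t + common_deg + design.decision_surplus
    rt_col = common_col
    censored = rt_deg > design.time_limit
    rt_deg = _quantize(rt_deg, design.quantization)
    rt_col = _quantize(rt_col, design.quantization)
    rt_deg = np.where(censored, np.nan, rt_deg)

    sid = np.repeat(np.arange(n_s), n_i)
    iid = np.tile(np.arange(n_i), n_s)
    return pd.DataFrame(
        {
            "subject_id": sid,
            "image_id": iid,
            "nu": nu_per_image[iid],
            "rt_degraded": rt_deg.ravel(),
            "rt_color": rt_col.ravel(),
            "censored": censored.ravel(),
            "true_search_time": t.ravel(),
            "true_Z": np.array([s.Z for s in subjects])[sid],
        }
    )


def trials_to_long(trials: pd.DataFrame) -> pd.DataFrame:
    """Convert the wide trial table to the long delimited-text layout.

    Columns: subject_id, image_id, condition in {degraded, color}, rt_s
    (empty on censored degraded trials), censored flag.
    """
    deg = trials[["subject_id", "image_id", "rt_degraded", "censored"]].rename(
        columns={"rt_degraded": "rt_s"}
    )
    deg["condition"] = "degraded"
    col = trials[["subject_id", "image_id", "rt_color"]].rename(columns={"rt_color": "rt_s"})
    col["condition"] = "color"
    col["censored"] = False
    out = pd.concat([deg, col], ignore_index=True)
    return out[["subject_id", "image_id", "condition", "rt_s", "censored"]]


def write_trials(trials: pd.DataFrame, path, ground_truth_path=None) -> None:
    """Write the long trial table (TSV); optionally a ground-truth sidecar."""
    trials_to_long(trials).to_csv(path, sep="\t", index=False)
    if ground_truth_path is not None:
        trials[["subject_id", "image_id", "nu", "true_search_time", "true_Z"]].to_csv(
            ground_truth_path, sep="\t", index=False
        )


def read_trials(path) -> pd.DataFrame:
    """Read a long trial table (TSV) back into the wide layout."""
    long = pd.read_csv(path, sep="\t")
    deg = long[long["condition"] == "degraded"].set_index(["subject_id", "image_id"])
    col = long[long["condition"] == "color"].set_index(["subject_id", "image_id"])
    wide = pd.DataFrame(
        {
            "rt_degraded": deg["rt_s"],
            "rt_color": col["rt_s"],
            "censored": deg["censored"].astype(bool),
        }
    ).reset_index()
    return wide


def write_config(pop: PopulationParams, design: StudyDesign, path) -> None:
    """Serialize generator parameters to YAML."""
    cfg = {
        "population": {
            "n_subjects": pop.n_subjects,
            "kappa": pop.kappa,
            "slope_a": pop.slope_a,
            "const_c": pop.const_c,
        },
        "design": {
            "n_images": design.n_images,
            "nu_weights": {int(k): float(v) for k, v in design.nu_weights.items()},
            "time_limit": design.time_limit,
            "rt_common_mean": design.rt_common_mean,
            "rt_common_sd": design.rt_common_sd,
            "decision_surplus": design.decision_surplus,
            "quantization": design.quantization,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def read_config(path) -> tuple[PopulationParams, StudyDesign]:
    """Load generator parameters from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    d = dict(cfg["design"])
    d["nu_weights"] = {int(k): float(v) for k, v in d["nu_weights"].items()}
    return PopulationParams(**cfg["population"]), StudyDesign(**d)
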