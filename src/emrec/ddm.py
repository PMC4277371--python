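"""Drift-diffusion simulation and the perceptual-decision-making comparison.

Two-choice perceptual decision making (PDM) is modelled by the Ratcliff
drift-diffusion model (DDM): noisy evidence accumulates from a starting
point ``z`` between absorbing boundaries 0 (house) and ``a`` (face) with
drift ``u`` and intratrial noise scale ``s`` (fixed at 1), plus
trial-to-trial variability in drift (normal, SD ``s_u``), starting point
(uniform, range ``s_z``) and nondecision time (uniform, range ``s_t0``).

The comparison analysis mirrors the emergent-recognition pipeline on
decision times (``rt - t0``): per-stimulus across-subject log-normal fits,
reversed z-scores, subject capability, and the regression of the
distribution SD on the mean.  Under the near-linear map from difficulty d
(mean log10 decision time) to drift, ``u = k*(d0 - d)``, the mean decision
time is approximately ``a/(2u)``, so log decision time is
``log(a*k/2) - log(d0 - d)`` and its across-subject spread does not grow
with difficulty — the opposite of the exponential coincidence process,
where the spread grows linearly with the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coincidence import ParameterError
from .pipeline import (
    DegenerateFitError,
    InsufficientDataError,
    fit_log_normal,
    regress_sigma_on_m,
)

__all__ = [
    "DDMParams",
    "DriftDifficultyFit",
    "simulate_ddm",
    "ddm_closed_forms",
    "build_latency_probability",
    "analyze_decision_times",
    "regress_drift_on_difficulty",
    "PDMPopulation",
    "simulate_pdm_study",
]


@dataclass(frozen=True)
class DDMParams:
    """Parameters of one subject's drift-diffusion process.

    ``u_by_class`` maps stimulus class (1-10) to the face drift rate in
    evidence units per second; house stimuli use the sign-reversed drift
    internally (face = upper boundary ``a``, house = lower boundary 0).
    """

    a: float
    z_start: float
    u_by_class: dict[int, float]
    t0: float = 0.3
    s_u: float = 0.0
    s_z: float = 0.0
    s_t0: float = 0.0
    s: float = 1.0
    dt: float = 0.001

    def __post_init__(self) -> None:
        if not (0.0 < self.z_start < self.a):
            raise ParameterError("starting point must lie strictly between 0 and a")
        if self.z_start - self.s_z / 2 <= 0 or self.z_start + self.s_z / 2 >= self.a:
            raise ParameterError("starting-point range escapes (0, a)")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.s <= 0:
            raise ParameterError("noise scale s must be positive")


def _first_passage(
    drifts: np.ndarray,
    starts: np.ndarray,
    a: float,
    s: float,
    dt: float,
    rng: np.random.Generator,
    max_time: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler simulation of first passage through 0 or a for many trials.

    Returns (decision_time, hit_upper).  Trials not absorbed within
    ``max_time`` get the boundary nearer their final state and the cap as
    their time (rare for sane parameters; keeps output total).
    """
    n = drifts.size
    x = starts.copy()
    t = np.zeros(n)
    upper = np.zeros(n, dtype=bool)
    active = np.arange(n)
    sq = s * math.sqrt(dt)
    n_steps = int(round(max_time / dt))
    for _ in range(n_steps):
        if active.size == 0:
            break
        x[active] += drifts[active] * dt + rng.normal(0.0, sq, size=active.size)
        t[active] += dt
        hit_up = x[active] >= a
        hit_lo = x[active] <= 0.0
        upper[active[hit_up]] = True
        active = active[~(hit_up | hit_lo)]
    if active.size:
        upper[active] = x[active] >= a / 2.0
    return t, upper


def simulate_ddm(
    params: DDMParams,
    n_trials: int,
    rng_seed: int | np.random.Generator | None = None,
    subject_id: int = 0,
    n_images_per_cell: int | None = None,
    max_time: float = 10.0,
) -> pd.DataFrame:
    """Simulate ``n_trials`` per class and category for one subject.

    Per trial the drift is drawn Normal(u, s_u), the start
    Uniform(z +/- s_z/2) and the nondecision time Uniform(t0 +/- s_t0/2);
    the accumulator then takes Euler steps ``drift*dt + Normal(0, s*sqrt(dt))``
    until absorption.  Face trials use drift +u, house trials -u; the
    response is read from the absorbing boundary.

    Returns a trial table with columns ``subject_id, image_id, class,
    true_category, choice, correct, rt``.  When ``n_images_per_cell`` is
    given, trials within a class/category cell cycle over that many image
    labels (one trial per subject per image, as in the experiment).
    """
    if n_trials <= 0:
        raise ParameterError("n_trials must be positive")
    rng = np.random.default_rng(rng_seed)
    cells = [
        (cls, u, category, sign)
        for cls, u in sorted(params.u_by_class.items())
        for category, sign in (("face", 1.0), ("house", -1.0))
    ]
    n_total = n_trials * len(cells)
    mean_drift = np.repeat([sign * u for _, u, _, sign in cells], n_trials)
    drifts = rng.normal(mean_drift, params.s_u)
    starts = params.z_start + rng.uniform(-0.5, 0.5, size=n_total) * params.s_z
    nondec = params.t0 + rng.uniform(-0.5, 0.5, size=n_total) * params.s_t0
    dtimes, hit_upper = _first_passage(drifts, starts, params.a, params.s, params.dt, rng,
                                       max_time=max_time)
    choice = np.where(hit_upper, "face", "house")
    n_img = n_images_per_cell or n_trials
    category_col = np.repeat([c for _, _, c, _ in cells], n_trials)
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "image_id": [
                f"{cat}_{cls}_{i % n_img}"
                for (cls, _, cat, _) in cells
                for i in range(n_trials)
            ],
            "class": np.repeat([cls for cls, _, _, _ in cells], n_trials),
            "true_category": category_col,
            "choice": choice,
            "correct": choice == category_col,
            "rt": dtimes + nondec,
            "decision_time": dtimes,
        }
    )


def ddm_closed_forms(a: float, z_start: float, u: float, s: float = 1.0) -> tuple[float, float]:
    """Exact absorption probability and mean first-passage time.

    For a Wiener process with drift u and noise scale s between absorbing
    boundaries 0 and a started at z: the upper-boundary probability is
    ``(1 - exp(-2*u*z/s^2)) / (1 - exp(-2*u*a/s^2))`` (-> z/a as u -> 0)
    and the unconditional mean decision time is ``(a/u)*p_upper - z/u``
    (-> z*(a - z)/s^2 as u -> 0).  With z = a/2 these reduce to the
    logistic form ``1/(1 + exp(-u*a/s^2))`` and
    ``(a/(2u))*tanh(u*a/(2 s^2))``.
    """
    if not a > 0 or not (0.0 < z_start < a):
        raise ParameterError("require a > 0 and 0 < z_start < a")
    x = 2.0 * u / s**2
    if abs(u) < 1e-9 * s**2 / a:
        return z_start / a, z_start * (a - z_start) / s**2
    p_upper = math.expm1(-x * z_start) / math.expm1(-x * a)
    mean_dt = (a / u) * p_upper - z_start / u
    return p_upper, mean_dt


def build_latency_probability(
    trials: pd.DataFrame,
    class_pairs: tuple[tuple[int, int], ...] = ((1, 2), (3, 4), (5, 6), (7, 8), (9, 10)),
) -> pd.DataFrame:
    """Latency-probability points per class pair and stimulus category.

    For each pair and category the correct branch is (response probability
    p, mean correct RT) and the error branch is (1 - p, mean error RT).
    Cells with no trials are omitted.
    """
    rows = []
    for pair in class_pairs:
        sub = trials[trials["class"].isin(pair)]
        for category, grp in sub.groupby("true_category"):
            if grp.empty:
                continue
            p = grp["correct"].mean()
            for branch, sel in (("correct", grp["correct"]), ("error", ~grp["correct"])):
                cell = grp[sel]
                if cell.empty:
                    continue
                rows.append(
                    {
                        "class_pair": pair,
                        "category": category,
                        "branch": branch,
                        "probability": p if branch == "correct" else 1.0 - p,
                        "mean_rt": cell["rt"].mean(),
                        "n": len(cell),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class PDMAnalysis:
    image_stats: pd.DataFrame
    z_scores: pd.DataFrame
    capabilities: pd.DataFrame
    sd_on_mean: object  # RegressionFit, image level (single-trial noise included)
    class_stats: pd.DataFrame | None = None
    sd_on_mean_class: object | None = None  # between-subject construct


def analyze_decision_times(
    trials: pd.DataFrame,
    t0_by_subject: dict[int, float],
    min_per_image: int = 5,
) -> PDMAnalysis:
    """Mirror the emergent-recognition analysis on PDM decision times.

    Correct trials only; decision time = rt - t0 (t0 known, oracle mode).
    Per image the across-subject distribution of log10 decision times is
    fitted on a probability plot; reversed-sign z-scores give a subject's
    PDM capability as the within-subject mean z, and the distribution SD is
    regressed on the mean across images.
    """
    ok = trials[trials["correct"]].copy()
    ok["t0"] = ok["subject_id"].map(t0_by_subject)
    ok["decision_time"] = ok["rt"] - ok["t0"]
    ok = ok[ok["decision_time"] > 0]
    n_subjects = ok["subject_id"].nunique()
    rows, zrows = [], []
    for image_id, grp in ok.groupby("image_id"):
        t = grp["decision_time"].to_numpy()
        try:
            m, sigma, r2 = fit_log_normal(t, n_subjects, min_loggable=min_per_image)
        except (InsufficientDataError, DegenerateFitError):
            continue
        rows.append(
            {
                "image_id": image_id,
                "class": grp["class"].iloc[0],
                "true_category": grp["true_category"].iloc[0],
                "m": m,
                "sigma": sigma,
                "r2_fit": r2,
                "n_observed": len(grp),
            }
        )
        z = -(np.log10(t) - m) / sigma
        zrows.append(
            pd.DataFrame(
                {"subject_id": grp["subject_id"].to_numpy(), "image_id": image_id, "z": z}
            )
        )
    if not rows:
        raise InsufficientDataError("no PDM image could be fitted")
    image_stats = pd.DataFrame(rows)
    z_scores = pd.concat(zrows, ignore_index=True)
    capabilities = (
        z_scores.groupby("subject_id")["z"].mean().rename("mean_z").reset_index()
    )
    sd_on_mean = regress_sigma_on_m(image_stats, corrected=False)
    # between-subject construct: average log10 decision time per subject over
    # the images of a class/category cell, then spread of those means across
    # subjects -- this is where the flat SD-vs-mean relation is predicted
    ok["log10_dt"] = np.log10(ok["decision_time"])
    per_subj = (
        ok.groupby(["class", "true_category", "subject_id"])["log10_dt"].mean().reset_index()
    )
    class_stats = (
        per_subj.groupby(["class", "true_category"])["log10_dt"]
        .agg(m="mean", sigma=lambda v: v.std(ddof=1))
        .reset_index()
    )
    sd_on_mean_class = regress_sigma_on_m(class_stats, corrected=False)
    return PDMAnalysis(
        image_stats=image_stats,
        z_scores=z_scores,
        capabilities=capabilities,
        sd_on_mean=sd_on_mean,
        class_stats=class_stats,
        sd_on_mean_class=sd_on_mean_class,
    )


@dataclass(frozen=True)
class DriftDifficultyFit:
    """Linear map from image difficulty d to drift: ``u = k*(d0 - d)``."""

    k: float
    d0: float
    r2: float
    consistent: bool = True


def regress_drift_on_difficulty(u_by_class, d_by_class) -> DriftDifficultyFit:
    """Least squares of drift on difficulty; k = -slope, d0 = d-axis intercept."""
    u = np.asarray(u_by_class, dtype=float)
    d = np.asarray(d_by_class, dtype=float)
    if u.size != d.size or u.size < 3:
        raise ParameterError("need >= 3 matched (u, d) points")
    res = stats.linregress(d, u)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope >= 0:
        return DriftDifficultyFit(k=-slope, d0=float("nan"), r2=float(res.rvalue**2),
                                  consistent=False)
    k = -slope
    d0 = intercept / k
    return DriftDifficultyFit(k=k, d0=d0, r2=float(res.rvalue**2))


def _default_class_difficulty() -> dict[int, float]:
    # class 1 hardest; difficulties (log10 s) spaced below the d-axis
    # intercept, far enough that drifts stay in the tanh-saturated regime
    # where mean decision time is ~ a/(2u)
    return {c: -0.50 - (0.30 / 9) * (c - 1) for c in range(1, 11)}


@dataclass(frozen=True)
class PDMPopulation:
    """Synthetic PDM subject population (oracle-mode generator).

    Boundary separation, nondecision time and drift sensitivity k vary
    across subjects; drifts follow ``u = k*(d0 - d)`` with per-class
    difficulties d.  Defaults track the scale of typical fitted values:
    k = 10.5 +/- 2.7 and d0 = -0.364 across subjects, a about 1.3.
    """

    n_subjects: int = 24
    a_mean: float = 1.3
    a_sd: float = 0.25
    t0_mean: float = 0.35
    t0_sd: float = 0.05
    k_mean: float = 10.5
    k_sd: float = 2.66
    d0: float = -0.364
    s_u: float = 0.4
    s_z_frac: float = 0.5
    s_t0: float = 0.1
    d_by_class: dict[int, float] = field(default_factory=_default_class_difficulty)


def simulate_pdm_study(
    popn: PDMPopulation,
    n_trials_per_cell: int = 20,
    rng_seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[int, float], pd.DataFrame]:
    """Simulate a full PDM study across subjects.

    Returns (trial table, t0 per subject, subject parameter table with the
    generator's ground-truth a, t0, k).
    """
    rng = np.random.default_rng(rng_seed)
    frames, t0s, subj_rows = [], {}, []
    for sid in range(popn.n_subjects):
        a = max(0.4, rng.normal(popn.a_mean, popn.a_sd))
        t0 = max(0.1, rng.normal(popn.t0_mean, popn.t0_sd))
        k = max(2.0, rng.normal(popn.k_mean, popn.k_sd))
        u_by_class = {c: k * (popn.d0 - d) for c, d in popn.d_by_class.items()}
        params = DDMParams(
            a=a,
            z_start=a / 2.0,
            u_by_class=u_by_class,
            t0=t0,
            s_u=popn.s_u,
            s_z=popn.s_z_frac * a / 2.0,
            s_t0=popn.s_t0,
        )
        frames.append(
            simulate_ddm(params, n_trials_per_cell, rng, subject_id=sid,
                         n_images_per_cell=n_trials_per_cell, max_time=5.0)
        )
        t0s[sid] = t0
        subj_rows.append({"subject_id": sid, "a": a, "t0": t0, "k": k})
    return pd.concat(frames, ignore_index=True), t0s, pd.DataFrame(subj_rows)
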