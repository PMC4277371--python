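"""Analysis pipeline for emergent-recognition search times.

The pipeline turns a subject x image trial table into:

* per-image log-normal fits of the across-subject distribution of log10
  search times (probability-plot least squares, censoring-aware ranks),
* reversed-sign z-scores and per-subject capabilities,
* the linear regression of the distribution SD on the mean, whose slope A
  and intercept B define the time constant ``C = 10**(-B/A)`` and the
  coincidence window ``tau = e^gamma * C``,
* image difficulty ``M = m + B/A`` and its periodicity: a grid scan for the
  period kappa such that ``M/kappa`` clusters on natural numbers, and the
  per-image missing-component count ``nu = round(M/kappa)``,
* the model-based corrections: subtracting a fixed decision surplus from
  every search time (interval correction) and removing the within-subject
  Gumbel variance floor 0.557 in quadrature from each fitted SD
  (SD correction), plus the procedure selecting the interval from
  sub-threshold SD counts,
* Monte Carlo replication of the whole experiment from fitted parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coincidence import EULER_GAMMA, SD_LOG10_EXPONENTIAL, ParameterError
from .synthetic import PopulationParams

__all__ = [
    "InsufficientDataError",
    "DegenerateFitError",
    "SearchTimes",
    "RegressionFit",
    "PeriodScan",
    "ERResults",
    "compute_search_times",
    "apply_interval_correction",
    "fit_log_normal",
    "fit_images",
    "sd_correction",
    "compute_z_scores",
    "estimate_capability",
    "regress_sigma_on_m",
    "compute_image_difficulty",
    "scan_period",
    "test_quarter_proportions",
    "assign_nu",
    "select_interval_correction",
    "replicate_model_experiment",
    "prediction_interval_coverage",
    "analyze_er_study",
]

log = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few usable observations to fit an image."""


class DegenerateFitError(ValueError):
    """The observations carry no spread; a log-normal cannot be fitted."""


@dataclass
class SearchTimes:
    """Per-trial search times with censoring/rank-only bookkeeping.

    ``table`` has columns ``subject_id, image_id, search_time, loggable``.
    Rank-only records (nonpositive differences) keep a row with
    ``loggable=False``: they occupy the lowest ranks of an image's
    cumulative distribution but contribute no log value.  Censored trials
    are excluded entirely and counted in ``n_censored``.
    """

    table: pd.DataFrame
    n_subjects: int
    n_censored: int = 0


def compute_search_times(trials: pd.DataFrame, n_subjects: int | None = None) -> SearchTimes:
    """Subtract the color-image RT from the degraded-image RT per trial.

    Parameters
    ----------
    trials : DataFrame
        Wide trial table with columns ``subject_id, image_id, rt_degraded,
        rt_color, censored`` (as produced by
        :func:`emrec.synthetic.simulate_er_study` or
        :func:`emrec.synthetic.read_trials`).
    n_subjects : int, optional
        Total number of subjects N used for probability-plot positions;
        defaults to the number of distinct subject ids in the table.

    Rows with a missing color RT are skipped with a warning.  Censored
    degraded trials are excluded.  Nonpositive differences become
    rank-only records.
    """
    if n_subjects is None:
        n_subjects = trials["subject_id"].nunique()
    missing = trials["rt_color"].isna()
    if missing.any():
        log.warning("skipping %d trials with missing color RT", int(missing.sum()))
        trials = trials[~missing]
    censored = trials["censored"].astype(bool) | trials["rt_degraded"].isna()
    usable = trials[~censored]
    st = usable["rt_degraded"].to_numpy() - usable["rt_color"].to_numpy()
    table = pd.DataFrame(
        {
            "subject_id": usable["subject_id"].to_numpy(),
            "image_id": usable["image_id"].to_numpy(),
            "search_time": st,
            "loggable": st > 0,
        }
    )
    return SearchTimes(table=table, n_subjects=int(n_subjects), n_censored=int(censored.sum()))


def apply_interval_correction(search: SearchTimes, delta: float) -> SearchTimes:
    """Reduce every search time by ``delta`` seconds (the interval correction).

    Times that become nonpositive turn into rank-only records.
    """
    if delta < 0:
        raise ParameterError("delta must be nonnegative")
    table = search.table.copy()
    table["search_time"] = table["search_time"] - delta
    table["loggable"] = table["search_time"] > 0
    return SearchTimes(table=table, n_subjects=search.n_subjects, n_censored=search.n_censored)


def fit_log_normal(
    times: np.ndarray,
    n_total_subjects: int,
    n_rank_only: int = 0,
    min_loggable: int = 5,
) -> tuple[float, float, float]:
    """Fit a normal distribution to log10 search times on a probability plot.

    Ascending ranks ``i`` run over all answered records (rank-only records
    occupy the lowest ranks); plotting positions are ``(i - 0.5)/N`` with N
    the total subject count, so censored subjects compress the observed
    records into the lower part of the plot and the fitted line
    extrapolates the full distribution.  Far-out outliers (log10 time above
    Q3 + 3*IQR of the loggable log10 times) are excluded from the least
    squares fit but keep their ranks.

    Returns ``(m, sigma, r2)``: fitted mean, SD (log10 units) and goodness
    of fit of the regression of log10 time on normal score.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ParameterError("times must be 1-D")
    if np.any(times <= 0):
        raise ParameterError("times must be positive; pass nonpositive records via n_rank_only")
    n_log = times.size
    if n_log < min_loggable:
        raise InsufficientDataError(
            f"need >= {min_loggable} loggable times, got {n_log}"
        )
    y = np.sort(np.log10(times))
    if np.ptp(y) == 0.0:
        raise DegenerateFitError("zero spread in log10 times")
    ranks = n_rank_only + np.arange(1, n_log + 1)
    x = stats.norm.ppf((ranks - 0.5) / n_total_subjects)
    q1, q3 = np.percentile(y, [25, 75])
    keep = y <= q3 + 3.0 * (q3 - q1)
    if keep.sum() < 2 or np.ptp(y[keep]) == 0.0:
        raise DegenerateFitError("degenerate fit after outlier exclusion")
    res = stats.linregress(x[keep], y[keep])
    return float(res.intercept), float(res.slope), float(res.rvalue**2)


def fit_images(search: SearchTimes, corrected: bool = False) -> pd.DataFrame:
    """Fit every image; returns the per-image statistics table.

    Columns: ``image_id, m, sigma, r2_fit, n_observed, answered_fraction``
    plus, when ``corrected``, ``sigma_between`` and ``below_floor``.
    Images with fewer than five loggable times are dropped (logged).
    """
    rows = []
    for image_id, grp in search.table.groupby("image_id"):
        t = grp.loc[grp["loggable"], "search_time"].to_numpy()
        n_rank_only = int((~grp["loggable"]).sum())
        try:
            m, sigma, r2 = fit_log_normal(t, search.n_subjects, n_rank_only)
        except (InsufficientDataError, DegenerateFitError) as err:
            log.info("image %s not fitted: %s", image_id, err)
            continue
        rows.append(
            {
                "image_id": image_id,
                "m": m,
                "sigma": sigma,
                "r2_fit": r2,
                "n_observed": len(grp),
                "answered_fraction": len(grp) / search.n_subjects,
            }
        )
    if not rows:
        raise InsufficientDataError("no image could be fitted")
    out = pd.DataFrame(rows)
    if corrected:
        sb, flag = sd_correction(out["sigma"].to_numpy())
        out["sigma_between"] = sb
        out["below_floor"] = flag
    return out


def sd_correction(sigma):
    """Remove the within-subject variance floor in quadrature.

    ``sigma_between = sqrt(sigma**2 - 0.557**2)`` where sigma exceeds the
    floor, else 0 with a below-floor flag.  Accepts scalars or arrays.
    """
    sigma_arr = np.asarray(sigma, dtype=float)
    if np.any(sigma_arr < 0):
        raise ParameterError("sigma must be nonnegative")
    floor = SD_LOG10_EXPONENTIAL
    below = sigma_arr <= floor
    sb = np.sqrt(np.clip(sigma_arr**2 - floor**2, 0.0, None))
    sb = np.where(below, 0.0, sb)
    if np.isscalar(sigma) or getattr(sigma, "ndim", 1) == 0:
        return float(sb), bool(below)
    return sb, below


def compute_z_scores(
    search: SearchTimes, image_stats: pd.DataFrame, corrected: bool = False
) -> pd.DataFrame:
    """Reversed-sign z-score per (subject, image): ``z = -(log10 t - m)/s``.

    ``s`` is the fitted sigma, or sigma_between in corrected mode (images
    with sigma_between = 0 are excluded there, flagged in the log).
    """
    stats_idx = image_stats.set_index("image_id")
    scale_col = "sigma_between" if corrected else "sigma"
    if corrected and scale_col not in stats_idx:
        raise ParameterError("corrected z-scores require sigma_between (run fit_images(corrected=True))")
    tab = search.table[search.table["loggable"]]
    tab = tab[tab["image_id"].isin(stats_idx.index)]
    m = stats_idx.loc[tab["image_id"], "m"].to_numpy()
    s = stats_idx.loc[tab["image_id"], scale_col].to_numpy()
    ok = s > 0
    if corrected and not ok.all():
        excluded = np.unique(tab["image_id"].to_numpy()[~ok])
        log.info("corrected z-scores: %d images excluded (sigma_between = 0)", excluded.size)
    z = -(np.log10(tab["search_time"].to_numpy()[ok]) - m[ok]) / s[ok]
    return pd.DataFrame(
        {
            "subject_id": tab["subject_id"].to_numpy()[ok],
            "image_id": tab["image_id"].to_numpy()[ok],
            "z": z,
        }
    )


def estimate_capability(
    z_scores: pd.DataFrame,
    image_stats: pd.DataFrame,
    mode: str = "uncorrected",
    answered_threshold: float = 0.85,
    n_easiest: int = 50,
    n_drop: int = 5,
) -> pd.DataFrame:
    """Per-subject mean z-score over a bias-controlled image subset.

    Difficult images yield z-scores only for the fastest subjects, biasing
    a naive average upward, so the mean is restricted to easy images:

    * ``uncorrected``: images whose answered-within-limit fraction is at
      least ``answered_threshold`` (85%); if fewer images qualify than the
      paper-scale 43, all qualifying ones are used (logged).
    * ``corrected``: the ``n_easiest`` (50) lowest-m images minus the
      ``n_drop`` (5) very easiest, whose tiny sigma_between makes corrected
      z-scores explode; the remaining 45 are averaged.

    Returns a DataFrame ``subject_id, mean_z, n_images``.
    """
    if mode == "uncorrected":
        chosen = image_stats.loc[
            image_stats["answered_fraction"] >= answered_threshold, "image_id"
        ]
        if chosen.empty:
            raise InsufficientDataError(
                "no image reaches the answered-fraction threshold "
                f"{answered_threshold}; capability undefined in uncorrected mode"
            )
        if len(chosen) < 43:
            log.info("only %d images reach the answered threshold; using all of them", len(chosen))
    elif mode == "corrected":
        usable = image_stats
        if "sigma_between" in image_stats:
            usable = image_stats[image_stats["sigma_between"] > 0]
        ranked = usable.sort_values("m")["image_id"]
        take = min(n_easiest, len(ranked))
        drop = min(n_drop, max(take - 1, 0))
        chosen = ranked.iloc[drop:take]
        if take < n_easiest:
            log.info("only %d usable images for corrected capability", take)
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    sub = z_scores[z_scores["image_id"].isin(set(chosen))]
    out = sub.groupby("subject_id")["z"].agg(["mean", "size"]).reset_index()
    out.columns = ["subject_id", "mean_z", "n_images"]
    return out


@dataclass(frozen=True)
class RegressionFit:
    """Least-squares fit of the distribution SD on the mean.

    ``sigma = A*m + B``; A and B define the time constant
    ``C = 10**(-B/A)`` seconds and the coincidence window
    ``tau = e^gamma * C``.  When the slope is not positive, C and tau are
    NaN and ``defined`` is False.
    """

    A: float
    B: float
    r2: float
    C: float
    tau: float
    defined: bool = True
    corrected: bool = False


def regress_sigma_on_m(image_stats: pd.DataFrame, corrected: bool = False) -> RegressionFit:
    """Regress sigma (or sigma_between, zeros included) on m across images."""
    if len(image_stats) < 3:
        raise InsufficientDataError("need >= 3 images for the mean-SD regression")
    y_col = "sigma_between" if corrected else "sigma"
    if corrected and y_col not in image_stats:
        raise ParameterError("corrected regression requires sigma_between")
    res = stats.linregress(image_stats["m"].to_numpy(), image_stats[y_col].to_numpy())
    A, B = float(res.slope), float(res.intercept)
    if A > 0:
        C = 10.0 ** (-B / A)
        tau = math.exp(EULER_GAMMA) * C
        defined = True
    else:
        C = tau = float("nan")
        defined = False
    return RegressionFit(A=A, B=B, r2=float(res.rvalue**2), C=C, tau=tau,
                         defined=defined, corrected=corrected)


def compute_image_difficulty(image_stats: pd.DataFrame, fit: RegressionFit) -> pd.Series:
    """Image difficulty ``M = m + B/A`` (log10 units).

    Under the coincidence model the expected log10 search time is
    ``M*(1 - A*Z) - B/A``, so M is the quantity periodic in the
    missing-component count.
    """
    if not fit.defined:
        raise ParameterError("image difficulty requires a fit with positive slope A")
    return image_stats["m"] + fit.B / fit.A


def _wrapped_fractions(M_values: np.ndarray, kappa: float) -> np.ndarray:
    """Fractional parts of M/kappa wrapped to [-0.5, 0.5)."""
    return ((np.asarray(M_values, dtype=float) / kappa + 0.5) % 1.0) - 0.5


@dataclass
class PeriodScan:
    kappa: float
    fraction_at_peak: float
    kappa_grid: np.ndarray = field(repr=False)
    fraction_curve: np.ndarray = field(repr=False)
    quarter_bin_proportions: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)


def scan_period(
    M_values,
    kappa_min: float = 0.5,
    kappa_max: float = 5.0,
    step: float = 0.01,
    window: float = 0.125,
) -> PeriodScan:
    """Grid-scan for the period kappa of the difficulty distribution.

    For each kappa on the grid the statistic is the fraction of images
    whose wrapped fractional part of ``M/kappa`` falls within ``window`` of
    0.  Because the count statistic can plateau over an interval of grid
    values (any kappa that keeps every value inside the window ties at the
    maximum), ties are resolved first by the smallest mean absolute wrapped
    fraction (the best-centred period) and then toward the largest kappa
    (so exact-multiple inputs do not collapse onto a harmonic).
    """
    M = np.asarray(M_values, dtype=float)
    if M.size < 1:
        raise ParameterError("need at least one difficulty value")
    grid = np.round(np.arange(round(kappa_min / step), round(kappa_max / step) + 1) * step, 10)
    fracs = np.empty(grid.size)
    for i, k in enumerate(grid):
        fracs[i] = np.mean(np.abs(_wrapped_fractions(M, k)) < window)
    tied = np.nonzero(fracs == fracs.max())[0]
    centering = np.array([np.mean(np.abs(_wrapped_fractions(M, grid[i]))) for i in tied])
    best_centred = tied[np.abs(centering - centering.min()) < 1e-12]
    best = int(best_centred[-1])  # largest kappa among equally centred ties
    kappa = float(grid[best])
    w = _wrapped_fractions(M, kappa)
    props = tuple(
        float(np.mean((np.abs(_wrapped_fractions(M - c * kappa, kappa)) < window)))
        for c in (0.0, 0.25, 0.5, 0.75)
    )
    return PeriodScan(
        kappa=kappa,
        fraction_at_peak=float(fracs[best]),
        kappa_grid=grid,
        fraction_curve=fracs,
        quarter_bin_proportions=props,
    )


def test_quarter_proportions(M_values, kappa: float) -> pd.DataFrame:
    """Two-proportion z tests: center quarter bin vs bins at 0.25, 0.5, 0.75.

    The wrapped fractional parts of M/kappa are binned into four quarter
    intervals centered at 0, 0.25, 0.5 and 0.75; the proportion in the
    center bin is compared with each other bin by the pooled-variance
    score-form z statistic for two population proportions (one-tailed,
    alternative: center larger).
    """
    if kappa <= 0:
        raise ParameterError("kappa must be positive")
    M = np.asarray(M_values, dtype=float)
    n = M.size
    if n == 0:
        raise ParameterError("need at least one difficulty value")
    f = _wrapped_fractions(M, kappa)
    counts = {
        0.0: int(np.sum(np.abs(f) < 0.125)),
        0.25: int(np.sum((f >= 0.125) & (f < 0.375))),
        0.5: int(np.sum((f >= 0.375) | (f < -0.375))),
        0.75: int(np.sum((f >= -0.375) & (f < -0.125))),
    }
    x1 = counts[0.0]
    rows = []
    for center in (0.25, 0.5, 0.75):
        x2 = counts[center]
        pooled = (x1 + x2) / (2.0 * n)
        se = math.sqrt(pooled * (1.0 - pooled) * (2.0 / n)) if 0 < pooled < 1 else 0.0
        z = (x1 - x2) / (n * se) if se > 0 else 0.0
        rows.append(
            {
                "bin_center": center,
                "prop_center": x1 / n,
                "prop_other": x2 / n,
                "z": z,
                "p_one_tailed": float(stats.norm.sf(z)),
            }
        )
    return pd.DataFrame(rows)


def assign_nu(M_values, kappa: float) -> np.ndarray:
    """Missing-component counts: ``nu = round(M/kappa)``, floored at 1.

    Ties at .5 round half-up (platform-independent).  A rounded value of 0
    is set to 1: a zero-component image would have zero search time after
    the interval correction, which observed search times rule out.
    """
    if kappa <= 0:
        raise ParameterError("kappa must be positive")
    nu = np.floor(np.asarray(M_values, dtype=float) / kappa + 0.5).astype(int)
    return np.maximum(nu, 1)


def select_interval_correction(
    per_candidate_subthreshold_counts: dict[float, int],
    nu_peak_counts: dict[int, int],
    subthreshold_ratios: dict[int, float],
) -> tuple[float, float]:
    """Select the interval-correction delta from sub-threshold SD counts.

    ``expected = sum_nu ratio(nu) * count(nu)`` is the number of images
    whose fitted SD is expected below the 0.557 floor purely from sampling
    fluctuation; the selected candidate is the one whose observed
    sub-threshold count is the smallest count that is still >= expected
    ("closest to and not more than" read from the expectation side).

    Returns ``(delta, expected_count)``.  Raises if every observed count is
    below the expectation (selection undefined).
    """
    expected = sum(
        subthreshold_ratios.get(nu, 0.0) * count for nu, count in nu_peak_counts.items()
    )
    eligible = {
        delta: cnt
        for delta, cnt in per_candidate_subthreshold_counts.items()
        if cnt >= expected
    }
    if not eligible:
        raise ParameterError(
            f"all observed sub-threshold counts fall below the expected {expected:.2f}; "
            "selection undefined"
        )
    best_count = min(eligible.values())
    # among equal counts prefer the largest reduction (most corrected)
    delta = max(d for d, c in eligible.items() if c == best_count)
    return float(delta), float(expected)


def replicate_model_experiment(
    nu_list,
    z_values,
    pop: PopulationParams,
    n_reps: int = 100,
    rng_seed: int | np.random.Generator | None = None,
    time_limit: float | None = None,
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Monte Carlo replication of the experiment from model parameters.

    For each replicate and each image (one per entry of ``nu_list``),
    ``len(z_values)`` search times are drawn from the coincidence model
    (rate ``p**nu/tau`` with p mapped from each subject's Z) and the
    per-image m and sigma are fitted exactly as in the experiment.  If
    ``z_values`` is None a fresh standard-normal capability sample is drawn
    per replicate.  With ``time_limit`` set, times beyond it are censored
    before fitting.

    Returns the ensemble table (rep, nu, m, sigma) and the per-nu
    probability that a fitted sigma falls below the 0.557 floor.
    """
    rng = np.random.default_rng(rng_seed)
    nu_list = np.asarray(nu_list, dtype=int)
    fixed_z = None if z_values is None else np.asarray(z_values, dtype=float)
    n_subj = pop.n_subjects if fixed_z is None else fixed_z.size
    rows = []
    for rep in range(n_reps):
        z = rng.standard_normal(n_subj) if fixed_z is None else fixed_z
        p = pop.p_of_z(z)
        for nu in nu_list:
            rate = p**nu / pop.tau
            t = rng.exponential(1.0 / rate)
            if time_limit is not None:
                t = t[t <= time_limit]
            try:
                m, sigma, _ = fit_log_normal(t, n_subj)
            except (InsufficientDataError, DegenerateFitError):
                continue
            rows.append({"rep": rep, "nu": int(nu), "m": m, "sigma": sigma})
    ensemble = pd.DataFrame(rows)
    ratios = {}
    for nu in np.unique(nu_list):
        sub = ensemble[ensemble["nu"] == nu]
        ratios[int(nu)] = float(np.mean(sub["sigma"] < SD_LOG10_EXPONENTIAL)) if len(sub) else float("nan")
    return ensemble, ratios


def prediction_interval_coverage(
    z_scores: pd.DataFrame,
    capability_image_ids,
    level: float = 0.95,
) -> float:
    """Coverage of per-subject prediction intervals on held-out images.

    For each subject, the interval is built from the mean and SD of the
    subject's z-scores over the capability images; coverage is the
    fraction of the subject's z-scores on the *other* images falling inside
    mean +/- z_crit*SD.  Since z = -(log10 t - m)/sigma, this equals the
    coverage of the corresponding prediction interval for log10 t.
    """
    crit = stats.norm.ppf(0.5 + level / 2.0)
    cap_ids = set(capability_image_ids)
    inside = total = 0
    for _, grp in z_scores.groupby("subject_id"):
        ref = grp[grp["image_id"].isin(cap_ids)]["z"]
        held = grp[~grp["image_id"].isin(cap_ids)]["z"]
        if len(ref) < 2 or held.empty:
            continue
        lo = ref.mean() - crit * ref.std(ddof=1)
        hi = ref.mean() + crit * ref.std(ddof=1)
        inside += int(((held >= lo) & (held <= hi)).sum())
        total += len(held)
    if total == 0:
        raise InsufficientDataError("no held-out observations for coverage")
    return inside / total


@dataclass
class ERResults:
    """Everything one pipeline run produces."""

    image_stats: pd.DataFrame
    z_scores: pd.DataFrame
    subject_scores: pd.DataFrame
    fit: RegressionFit
    scan: PeriodScan
    corrected: bool
    delta: float
    kappa: float
    p0: float

    @property
    def nu(self) -> pd.Series:
        return self.image_stats.set_index("image_id")["nu"]


def analyze_er_study(
    trials: pd.DataFrame,
    n_subjects: int | None = None,
    corrected: bool = True,
    delta: float = 0.30,
    capability_mode: str | None = None,
) -> ERResults:
    """Run the full analysis on a trial table.

    In corrected mode the interval correction (``delta`` seconds) is
    applied to all search times, per-image SDs are converted to
    between-subject SDs, and z-scores/capabilities use sigma_between.
    """
    search = compute_search_times(trials, n_subjects)
    if corrected and delta > 0:
        search = apply_interval_correction(search, delta)
    image_stats = fit_images(search, corrected=corrected)
    fit = regress_sigma_on_m(image_stats, corrected=corrected)
    image_stats = image_stats.copy()
    image_stats["M"] = compute_image_difficulty(image_stats, fit)
    scan = scan_period(image_stats["M"].to_numpy())
    image_stats["nu"] = assign_nu(image_stats["M"].to_numpy(), scan.kappa)
    z_scores = compute_z_scores(search, image_stats, corrected=corrected)
    mode = capability_mode or ("corrected" if corrected else "uncorrected")
    subject_scores = estimate_capability(z_scores, image_stats, mode=mode)
    return ERResults(
        image_stats=image_stats,
        z_scores=z_scores,
        subject_scores=subject_scores,
        fit=fit,
        scan=scan,
        corrected=corrected,
        delta=delta if corrected else 0.0,
        kappa=scan.kappa,
        p0=10.0 ** (-scan.kappa),
    )
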