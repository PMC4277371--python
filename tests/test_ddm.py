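"""Drift-diffusion simulator, closed forms and the PDM comparison analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emrec import ddm
from emrec.coincidence import ParameterError
from emrec.ddm import (
    DDMParams,
    PDMPopulation,
    analyze_decision_times,
    build_latency_probability,
    ddm_closed_forms,
    regress_drift_on_difficulty,
    simulate_ddm,
    simulate_pdm_study,
)


class TestClosedForms:
    def test_zero_drift_martingale_limit(self):
        p, mdt = ddm_closed_forms(1.0, 0.3, 0.0)
        assert p == pytest.approx(0.3)
        assert mdt == pytest.approx(0.3 * 0.7)

    def test_centred_start_logistic_and_tanh(self):
        a, u, s = 1.4, 0.9, 1.0
        p, mdt = ddm_closed_forms(a, a / 2, u, s)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-u * a / s**2)))
        assert mdt == pytest.approx((a / (2 * u)) * math.tanh(u * a / (2 * s**2)))

    def test_small_drift_continuity(self):
        p0, m0 = ddm_closed_forms(1.0, 0.5, 0.0)
        p1, m1 = ddm_closed_forms(1.0, 0.5, 1e-7)
        assert p1 == pytest.approx(p0, abs=1e-4)
        assert m1 == pytest.approx(m0, rel=1e-3)
        assert m0 == pytest.approx(0.25)  # a^2/(4 s^2)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ParameterError):
            ddm_closed_forms(1.0, 1.5, 0.3)


class TestSimulator:
    def test_start_range_must_stay_inside_boundaries(self):
        with pytest.raises(ParameterError):
            DDMParams(a=1.0, z_start=0.5, u_by_class={1: 1.0}, s_z=1.2)

    def test_symmetric_zero_drift_is_fair_coin(self):
        params = DDMParams(a=1.0, z_start=0.5, u_by_class={1: 0.0}, t0=0.0)
        tr = simulate_ddm(params, 20_000, rng_seed=0)
        face = tr[tr["true_category"] == "face"]
        se = 0.5 / math.sqrt(len(face))
        assert abs((face["choice"] == "face").mean() - 0.5) < 3 * se

    def test_vanishing_noise_deterministic_limit(self):
        params = DDMParams(a=1.0, z_start=0.5, u_by_class={1: 1.0}, t0=0.0, s=1e-4)
        tr = simulate_ddm(params, 200, rng_seed=1)
        face = tr[tr["true_category"] == "face"]
        assert face["correct"].all()
        assert face["decision_time"].mean() == pytest.approx(0.5, abs=0.01)

    def test_accuracy_and_mean_time_match_closed_forms(self):
        params = DDMParams(a=1.0, z_start=0.5, u_by_class={1: 1.0}, t0=0.0, dt=0.001)
        tr = simulate_ddm(params, 30_000, rng_seed=5)
        face = tr[tr["true_category"] == "face"]
        p_true, mdt_true = ddm_closed_forms(1.0, 0.5, 1.0)
        assert face["correct"].mean() == pytest.approx(p_true, abs=0.015)
        assert face["decision_time"].mean() == pytest.approx(mdt_true, rel=0.10)

    def test_euler_bias_shrinks_with_dt(self):
        p_true, mdt_true = ddm_closed_forms(1.0, 0.5, 1.0)
        errs = []
        for dt in (0.01, 0.001):
            params = DDMParams(a=1.0, z_start=0.5, u_by_class={1: 1.0}, t0=0.0, dt=dt)
            tr = simulate_ddm(params, 30_000, rng_seed=5)
            face = tr[tr["true_category"] == "face"]
            errs.append(abs(face["decision_time"].mean() - mdt_true))
        assert errs[1] < errs[0]

    def test_reproducible_under_seed(self):
        params = DDMParams(a=1.0, z_start=0.5, u_by_class={1: 1.0, 2: 2.0}, s_u=0.3, s_z=0.4)
        a = simulate_ddm(params, 100, rng_seed=3)
        b = simulate_ddm(params, 100, rng_seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestLatencyProbability:
    def test_all_correct_gives_single_branch_at_p_one(self):
        tr = pd.DataFrame(
            {
                "class": [1, 1, 2, 2],
                "true_category": "face",
                "correct": True,
                "rt": [0.4, 0.5, 0.6, 0.7],
            }
        )
        lp = build_latency_probability(tr, class_pairs=((1, 2),))
        assert set(lp["branch"]) == {"correct"}
        assert lp["probability"].iloc[0] == 1.0

    def test_zero_drift_symmetric_branches(self):
        params = DDMParams(a=1.0, z_start=0.5, u_by_class={1: 0.0}, t0=0.2)
        tr = simulate_ddm(params, 20_000, rng_seed=2)
        lp = build_latency_probability(tr, class_pairs=((1,),))
        face = lp[lp["category"] == "face"].set_index("branch")
        assert face.loc["correct", "probability"] == pytest.approx(0.5, abs=0.02)
        assert face.loc["correct", "mean_rt"] == pytest.approx(
            face.loc["error", "mean_rt"], rel=0.05
        )

    def test_fast_errors_under_start_point_variability(self):
        # high drift + wide starting-point range: classic fast guesses
        params = DDMParams(a=1.5, z_start=0.75, u_by_class={9: 4.0}, t0=0.3,
                           s_u=0.0, s_z=1.3)
        tr = simulate_ddm(params, 6000, rng_seed=21)
        face = tr[tr["true_category"] == "face"]
        assert face[~face["correct"]]["rt"].mean() < face[face["correct"]]["rt"].mean() - 0.05

    def test_slow_errors_under_drift_variability(self):
        # low drift + across-trial drift variability: classic slow errors
        params = DDMParams(a=1.5, z_start=0.75, u_by_class={1: 0.6}, t0=0.3,
                           s_u=1.0, s_z=0.0)
        tr = simulate_ddm(params, 6000, rng_seed=21)
        face = tr[tr["true_category"] == "face"]
        assert face[~face["correct"]]["rt"].mean() > face[face["correct"]]["rt"].mean() + 0.02


class TestDriftDifficultyFit:
    def test_exact_line(self):
        d = np.array([-0.9, -0.7, -0.5])
        u = -10.0 * (d - (-0.36))
        fit = regress_drift_on_difficulty(u, d)
        assert fit.k == pytest.approx(10.0)
        assert fit.d0 == pytest.approx(-0.36)
        # drift vanishes at the d-axis intercept by construction
        assert fit.k * (fit.d0 - fit.d0) == pytest.approx(0.0)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(0)
        d = np.linspace(-0.8, -0.45, 10)
        u = 12.0 * (-0.36 - d) + rng.normal(0, 0.05, size=10)
        fit = regress_drift_on_difficulty(u, d)
        assert fit.k == pytest.approx(12.0, rel=0.1)
        assert fit.d0 == pytest.approx(-0.36, abs=0.03)

    def test_positive_slope_flagged_inconsistent(self):
        d = np.array([-0.9, -0.7, -0.5])
        fit = regress_drift_on_difficulty(np.array([1.0, 2.0, 3.0]), d)
        assert not fit.consistent


@pytest.fixture(scope="module")
def study():
    popn = PDMPopulation()
    return simulate_pdm_study(popn, 20, rng_seed=11)


class TestDecisionTimeAnalysis:

    def test_identical_subjects_have_near_zero_capabilities(self):
        popn = PDMPopulation(n_subjects=12, a_sd=0.0, t0_sd=0.0, k_sd=0.0)
        trials, t0s, _ = simulate_pdm_study(popn, 20, rng_seed=4)
        res = analyze_decision_times(trials, t0s)
        assert abs(res.capabilities["mean_z"].mean()) < 0.1
        assert res.capabilities["mean_z"].std() < 0.35

    def test_capability_anticorrelated_with_boundary_separation(self, study):
        trials, t0s, subj = study
        res = analyze_decision_times(trials, t0s)
        merged = res.capabilities.merge(subj, on="subject_id")
        r = stats.pearsonr(merged["mean_z"], merged["a"]).statistic
        assert r < -0.5

    def test_image_fits_cover_all_classes(self, study):
        trials, t0s, _ = study
        res = analyze_decision_times(trials, t0s)
        assert set(res.image_stats["class"]) == set(range(1, 11))
        assert res.class_stats is not None and len(res.class_stats) == 20
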