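"""Univariable MR estimators against closed-form and brute-force oracles."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from calcmr import (
    EstimationError,
    InputError,
    WaldRatioSet,
    beta_to_or,
    ivw_estimate,
    single_snp_wald,
    wald_ratios,
    weighted_median_estimate,
    weighted_mode_estimate,
)
from calcmr.mr_core import (
    EggerEstimator,
    IVWEstimator,
    WeightedModeEstimator,
    _weighted_median,
    _weighted_mode,
)
from calcmr.summary_data import HarmonizedInstrumentSet
import pandas as pd


def _wrs(ratio, se_ratio):
    ratio = np.asarray(ratio, dtype=float)
    return WaldRatioSet(
        snp_ids=np.array([f"rs{i}" for i in range(len(ratio))]),
        ratio=ratio,
        se_ratio=np.asarray(se_ratio, dtype=float),
    )


def _hset(gamma, se_gamma, Gamma, se_Gamma):
    n = len(gamma)
    table = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "chrom": "1",
            "pos": np.arange(n) * 20_000_000 + 1,
            "effect_allele": "A",
            "other_allele": "G",
            "beta.exposure": gamma,
            "se.exposure": se_gamma,
            "eaf.exposure": 0.3,
            "pval.exposure": 1e-9,
            "n.exposure": 100_000,
            "beta.outcome": Gamma,
            "se.outcome": se_Gamma,
            "eaf.outcome": 0.3,
            "pval.outcome": 0.5,
            "n.outcome": 100_000,
        }
    )
    return HarmonizedInstrumentSet(table=table, labels=["outcome"])


class TestWaldRatios:
    def test_hand_example(self):
        h = _hset([0.2], [0.01], [0.05], [0.01])
        w = wald_ratios(h)
        assert w.ratio[0] == pytest.approx(0.25)
        assert w.se_ratio[0] == pytest.approx(0.05)

    def test_zero_outcome_effect_gives_zero_ratio(self):
        w = wald_ratios(_hset([1.0], [0.01], [0.0], [0.1]))
        assert w.ratio[0] == 0.0

    def test_joint_negation_invariance(self):
        w1 = wald_ratios(_hset([0.2, 0.3], [0.01, 0.01], [0.05, 0.06], [0.01, 0.01]))
        w2 = wald_ratios(_hset([-0.2, -0.3], [0.01, 0.01], [-0.05, -0.06], [0.01, 0.01]))
        np.testing.assert_allclose(w1.ratio, w2.ratio)
        np.testing.assert_allclose(w1.se_ratio, w2.se_ratio)

    def test_zero_exposure_effects_excluded(self):
        w = wald_ratios(_hset([0.2, 0.0], [0.01, 0.01], [0.05, 0.01], [0.01, 0.01]))
        assert w.nsnp == 1

    def test_all_zero_exposure_is_input_error(self):
        with pytest.raises(InputError):
            wald_ratios(_hset([0.0], [0.01], [0.05], [0.01]))


class TestIVW:
    def test_three_snp_closed_form(self):
        w = _wrs([0.1, 0.2, 0.4], [0.1, 0.1, 0.2])
        est = ivw_estimate(w)
        # weights (100, 100, 25): beta = 40/225, fixed se = 1/15
        assert est.beta == pytest.approx(40 / 225, abs=1e-12)
        assert est.se == pytest.approx(1 / 15, abs=1e-12)
        assert est.effects_model == "fixed"

    def test_homogeneous_ratios_give_exact_beta_and_zero_q(self):
        w = _wrs([0.3, 0.3, 0.3], [0.1, 0.2, 0.05])
        est = ivw_estimate(w)
        assert est.beta == pytest.approx(0.3, abs=1e-14)
        ivw = IVWEstimator().fit(np.ones(3), np.full(3, 0.3), se_y=np.array([0.1, 0.2, 0.05]))
        assert ivw.q_stat_ == pytest.approx(0.0, abs=1e-20)
        assert ivw.q_p_ == 1.0

    def test_single_snp_is_error(self):
        with pytest.raises(EstimationError):
            ivw_estimate(_wrs([0.1], [0.1]))
        est = single_snp_wald(_wrs([0.1], [0.05]))
        assert est.beta == 0.1 and est.se == 0.05

    def test_matches_no_intercept_wls_oracle(self, rng):
        gamma = rng.normal(0.1, 0.02, 20)
        Gamma = 0.25 * gamma + rng.normal(0, 0.005, 20)
        se_G = np.full(20, 0.005)
        est = IVWEstimator(q_alpha=0.0).fit(gamma, Gamma, se_y=se_G)  # force fixed
        # oracle: weighted least squares through the origin
        w = 1 / se_G**2
        beta_wls = np.sum(w * gamma * Gamma) / np.sum(w * gamma**2)
        se_wls = np.sum(w * gamma**2) ** -0.5
        assert est.beta_ == pytest.approx(beta_wls, abs=1e-12)
        assert est.se_ == pytest.approx(se_wls, abs=1e-12)

    def test_random_effects_inflates_se_never_shrinks(self, rng):
        gamma = rng.normal(0.1, 0.02, 30)
        Gamma = 0.2 * gamma + rng.normal(0, 0.05, 30)  # strong heterogeneity
        se_G = np.full(30, 0.005)
        est = IVWEstimator().fit(gamma, Gamma, se_y=se_G)
        fixed_se = np.sum((gamma / se_G) ** 2) ** -0.5
        assert est.effects_model_ == "random"
        assert est.se_ >= fixed_se


class TestEgger:
    def test_exact_linear_data(self):
        est = EggerEstimator().fit(
            np.array([1.0, 2.0, 3.0]), np.array([0.6, 1.1, 1.6]), se_y=np.full(3, 0.1)
        )
        assert est.beta_ == pytest.approx(0.5, abs=1e-10)
        assert est.intercept_ == pytest.approx(0.1, abs=1e-10)

    def test_proportional_data_zero_intercept(self):
        g = np.array([0.5, 1.0, 2.0, 3.0])
        est = EggerEstimator().fit(g, 0.5 * g, se_y=np.full(4, 0.1))
        assert est.intercept_ == pytest.approx(0.0, abs=1e-12)
        assert est.beta_ == pytest.approx(0.5, abs=1e-12)

    def test_weighted_four_point_vs_normal_equations(self):
        g = np.array([0.5, 1.0, 1.5, 2.5])
        G = np.array([0.30, 0.45, 0.90, 1.20])
        se = np.array([0.05, 0.10, 0.08, 0.20])
        est = EggerEstimator().fit(g, G, se_y=se)
        # oracle: solve the 2x2 weighted normal equations directly
        w = 1 / se**2
        X = np.column_stack([np.ones(4), g])
        A = X.T @ (w[:, None] * X)
        b = X.T @ (w * G)
        intercept, slope = np.linalg.solve(A, b)
        assert est.intercept_ == pytest.approx(intercept, abs=1e-10)
        assert est.beta_ == pytest.approx(slope, abs=1e-10)

    def test_negative_gamma_reoriented(self):
        g = np.array([0.5, 1.0, 2.0, 3.0])
        G = 0.1 + 0.5 * g
        est_pos = EggerEstimator().fit(g, G, se_y=np.full(4, 0.1))
        est_mix = EggerEstimator().fit(
            g * np.array([1, -1, 1, -1]), G * np.array([1, -1, 1, -1]), se_y=np.full(4, 0.1)
        )
        assert est_mix.beta_ == pytest.approx(est_pos.beta_, abs=1e-12)
        assert est_mix.intercept_ == pytest.approx(est_pos.intercept_, abs=1e-12)

    def test_two_snps_is_error(self):
        with pytest.raises(EstimationError):
            EggerEstimator().fit(np.array([1.0, 2.0]), np.array([0.5, 1.0]), se_y=np.full(2, 0.1))


class TestWeightedMedian:
    def test_interpolation_example(self):
        assert _weighted_median(
            np.array([0.1, 0.2, 0.3, 0.4, 0.5]), np.array([1.0, 1, 4, 1, 1])
        ) == pytest.approx(0.3)

    def test_equal_weights_reduce_to_median(self):
        r = np.array([0.5, 0.1, 0.9, 0.3, 0.7])
        assert _weighted_median(r, np.ones(5)) == pytest.approx(np.median(r))

    def test_degenerate_identical_ratios(self):
        est = weighted_median_estimate(_wrs([0.2] * 4, [0.1] * 4), n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_bootstrap_se_positive_and_seeded(self):
        w = _wrs([0.1, 0.25, 0.3, 0.4], [0.05, 0.05, 0.1, 0.2])
        a = weighted_median_estimate(w, n_boot=200, seed=7)
        b = weighted_median_estimate(w, n_boot=200, seed=7)
        c = weighted_median_estimate(w, n_boot=200, seed=8)
        assert a.se > 0
        assert a.se == b.se
        assert a.se != c.se


class TestWeightedMode:
    def test_cluster_maximum(self):
        w = _wrs([0.29, 0.30, 0.31, 1.5], [0.1] * 4)
        est = weighted_mode_estimate(w, n_boot=50, seed=1)
        assert abs(est.beta - 0.30) < 0.02

    def test_matches_dense_grid_oracle(self):
        ratio = np.array([0.29, 0.30, 0.31, 1.5])
        weight = np.ones(4)
        est = _weighted_mode(ratio, weight, 1.0)
        # oracle: brute-force density maximization on a much denser grid
        sd = np.std(ratio, ddof=1)
        iqr = np.subtract(*np.percentile(ratio, [75, 25]))
        h = 0.9 * min(sd, iqr / 1.349) * 4 ** (-1 / 5)
        grid = np.linspace(ratio.min(), ratio.max(), 200_001)
        dens = np.exp(-0.5 * ((grid[:, None] - ratio) / h) ** 2).sum(axis=1)
        assert est == pytest.approx(grid[np.argmax(dens)], abs=1e-4)

    def test_degenerate_identical_ratios(self):
        est = weighted_mode_estimate(_wrs([0.42] * 5, [0.1] * 5))
        assert est.beta == 0.42
        assert est.se == 0.0

    def test_weight_scale_invariance(self):
        ratio = np.array([0.1, 0.12, 0.13, 0.6])
        w = np.array([1.0, 2.0, 1.5, 0.5])
        assert _weighted_mode(ratio, w, 1.0) == pytest.approx(
            _weighted_mode(ratio, 2 * w, 1.0), abs=1e-9
        )


class TestSharedProperties:
    def test_all_estimators_consistent_at_tiny_noise(self, rng):
        gamma = rng.uniform(0.05, 0.2, 30)
        se_G = np.full(30, 1e-4)
        Gamma = 0.17 * gamma + rng.normal(0, 1e-4, 30)
        w = WaldRatioSet.from_effects(gamma, Gamma, se_G)
        ests = [
            ivw_estimate(w).beta,
            EggerEstimator().fit(gamma, Gamma, se_y=se_G).beta_,
            weighted_median_estimate(w, n_boot=50, seed=0).beta,
            weighted_mode_estimate(w, n_boot=50, seed=0).beta,
        ]
        for b in ests:
            assert abs(b - 0.17) < 1e-2

    def test_sign_equivariance(self, rng):
        gamma = rng.uniform(0.05, 0.2, 12)
        Gamma = 0.2 * gamma + rng.normal(0, 0.01, 12)
        se_G = np.full(12, 0.01)
        for fit in (
            lambda g, G: ivw_estimate(WaldRatioSet.from_effects(g, G, se_G)).beta,
            lambda g, G: EggerEstimator().fit(g, G, se_y=se_G).beta_,
            lambda g, G: weighted_median_estimate(
                WaldRatioSet.from_effects(g, G, se_G), n_boot=50, seed=0
            ).beta,
        ):
            assert fit(-gamma, Gamma) == pytest.approx(-fit(gamma, Gamma), rel=1e-9)

    def test_sklearn_params_and_clone(self):
        est = WeightedModeEstimator(bandwidth_factor=2.0, n_boot=11, seed=3)
        assert est.get_params() == {"bandwidth_factor": 2.0, "n_boot": 11, "seed": 3}
        est2 = clone(est).set_params(seed=5)
        assert est2.seed == 5 and est2.bandwidth_factor == 2.0

    def test_predict_returns_fitted_line(self):
        ivw = IVWEstimator().fit(np.array([0.1, 0.2]), np.array([0.02, 0.04]),
                                 se_y=np.array([0.01, 0.01]))
        np.testing.assert_allclose(ivw.predict(np.array([0.5])), [0.5 * ivw.beta_])


class TestBetaToOr:
    @pytest.mark.parametrize(
        "beta, expected",
        [(0.175, 1.191), (0.0, 1.0), (0.174, 1.190)],
    )
    def test_point_estimates_at_three_decimals(self, beta, expected):
        or_point, _, _ = beta_to_or(beta, 0.05)
        assert round(or_point, 3) == expected

    def test_interval_uses_z95(self):
        orp, orl, orh = beta_to_or(0.1, 0.02)
        assert orl == pytest.approx(math.exp(0.1 - 1.96 * 0.02))
        assert orh == pytest.approx(math.exp(0.1 + 1.96 * 0.02))

    def test_negative_se_rejected(self):
        with pytest.raises(InputError):
            beta_to_or(0.1, -0.01)
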