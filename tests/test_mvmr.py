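"""Multivariable MR: instrument assembly, MV-IVW/median/LASSO estimators."""

import numpy as np
import pytest

from calcmr import (
    EstimationError,
    InputError,
    IVWEstimator,
    MvInstrumentSet,
    assemble_mv_instruments,
    mvmr_any_significant,
    mvmr_ivw,
    mvmr_lasso,
    mvmr_median,
    weighted_median_estimate,
)
from calcmr.mr_core import WaldRatioSet
from calcmr.mvmr import MVIVWEstimator, MVLassoEstimator, MVMedianEstimator

from conftest import make_record


def _mvset(X, Gamma, se_Gamma, se_X=None, labels=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    return MvInstrumentSet(
        snp_ids=np.array([f"rs{i}" for i in range(n)]),
        X=X,
        se_X=np.full((n, k), 0.001) if se_X is None else se_X,
        Gamma=np.asarray(Gamma, dtype=float),
        se_Gamma=np.asarray(se_Gamma, dtype=float),
        labels=labels or [f"x{j}" for j in range(k)],
    )


def _noisy_fixture(rng, n=50, theta=(0.3, -0.2), noise=0.002, pleio_idx=(), pleio=0.0):
    X = rng.uniform(0.05, 0.2, size=(n, 2))
    se_G = np.full(n, noise)
    Gamma = X @ np.asarray(theta) + rng.normal(0, noise, n)
    for i in pleio_idx:
        Gamma[i] += pleio
    return _mvset(X, Gamma, se_G)


class TestAssemble:
    def _records(self, ids, start_pos=1_000_000, pval=1e-9, beta=0.1, chrom="1"):
        return [
            make_record(snp_id=s, chrom=chrom, pos=start_pos + i * 20_000_000,
                        pval=pval, beta=beta)
            for i, s in enumerate(ids)
        ]

    def test_disjoint_unions(self):
        a = self._records([f"a{i}" for i in range(10)])
        b = self._records([f"b{i}" for i in range(10)], chrom="2")
        # every SNP must exist in every trait table: concatenate cross-entries
        a_all = a + [make_record(snp_id=r.snp_id, pos=r.pos, pval=0.5, beta=0.001) for r in b]
        b_all = b + [make_record(snp_id=r.snp_id, pos=r.pos, pval=0.5, beta=0.001) for r in a]
        outcome = [
            make_record(snp_id=r.snp_id, pos=r.pos, pval=0.9, beta=0.01) for r in a + b
        ]
        m = assemble_mv_instruments({"A": a_all, "B": b_all}, outcome)
        assert m.nsnp == 20
        assert m.k == 2

    def test_snp_missing_in_covariate_dropped(self):
        a = self._records(["rs1", "rs2"])
        b = [make_record(snp_id="rs1", pval=1e-9, beta=0.2)]
        outcome = [make_record(snp_id=s, pos=1_000_000 + i * 20_000_000, pval=0.5, beta=0.01)
                   for i, s in enumerate(["rs1", "rs2", "rs3"])]
        # nsnp(1) <= k(2) -> the assembly itself raises
        with pytest.raises(InputError):
            assemble_mv_instruments({"A": a, "B": b}, outcome)

    def test_single_exposure_is_error(self):
        a = self._records(["rs1", "rs2"])
        with pytest.raises(InputError, match="2 exposures"):
            assemble_mv_instruments({"A": a}, a)

    def test_joint_reclumping_uses_lowest_p(self):
        # two traits with correlated top hits 1 Mb apart: only the lower p survives
        a = self._records(["rs1"], start_pos=1_000_000, pval=1e-20)
        b = self._records(["rs2"], start_pos=2_000_000, pval=1e-9)
        far = [make_record(snp_id="rs8", pos=500_000_000, chrom="8", pval=1e-12),
               make_record(snp_id="rs9", pos=500_000_000, chrom="9", pval=1e-12)]
        a_all = a + [make_record(snp_id="rs2", pos=2_000_000, pval=0.5)] + far
        b_all = b + [make_record(snp_id="rs1", pos=1_000_000, pval=0.5)] + far
        outcome = [make_record(snp_id=s, pos=p, chrom=c, pval=0.7, beta=0.01)
                   for s, p, c in [("rs1", 1_000_000, "1"), ("rs2", 2_000_000, "1"),
                                   ("rs8", 500_000_000, "8"), ("rs9", 500_000_000, "9")]]
        m = assemble_mv_instruments({"A": a_all, "B": b_all}, outcome)
        assert set(m.snp_ids) == {"rs1", "rs8", "rs9"}


class TestMvIvw:
    def test_recovers_known_coefficients(self, rng):
        m = _noisy_fixture(rng, n=50, theta=(0.3, -0.2), noise=1e-5)
        res = mvmr_ivw(m)
        assert res.estimates[0].beta == pytest.approx(0.3, abs=1e-3)
        assert res.estimates[1].beta == pytest.approx(-0.2, abs=1e-3)

    def test_matches_normal_equations_oracle(self, rng):
        m = _noisy_fixture(rng, n=12, noise=0.01)
        res = mvmr_ivw(m)
        w = 1 / m.se_Gamma**2
        A = m.X.T @ (w[:, None] * m.X)
        b = m.X.T @ (w * m.Gamma)
        theta = np.linalg.solve(A, b)
        np.testing.assert_allclose([e.beta for e in res.estimates], theta, atol=1e-10)

    def test_null_covariate_column_reduces_to_univariable(self, rng):
        # a covariate whose effect column is weighted-orthogonal to both the
        # exposure effects and the outcome effects gets coefficient 0, and the
        # exposure estimate collapses to the univariable IVW on the same SNPs
        n = 30
        X1 = rng.uniform(0.05, 0.2, n)
        se_G = np.full(n, 0.01)
        Gamma = 0.25 * X1 + rng.normal(0, 0.01, n)
        w = 1 / se_G**2
        raw = rng.normal(0, 0.05, n)
        basis = np.column_stack([X1, Gamma])
        coef, *_ = np.linalg.lstsq(np.sqrt(w)[:, None] * basis, np.sqrt(w) * raw, rcond=None)
        X2 = raw - basis @ coef
        res = mvmr_ivw(_mvset(np.column_stack([X1, X2]), Gamma, se_G))
        uni = IVWEstimator(q_alpha=0.0).fit(X1, Gamma, se_y=se_G)
        assert res.estimates[1].beta == pytest.approx(0.0, abs=1e-10)
        assert res.estimates[0].beta == pytest.approx(uni.beta_, abs=1e-10)

    def test_all_zero_column_is_input_error(self, rng):
        n = 10
        X = np.column_stack([rng.uniform(0.1, 0.2, n), np.zeros(n)])
        with pytest.raises(InputError, match="all-zero"):
            _mvset(X, np.zeros(n), np.full(n, 0.01))

    def test_nsnp_equal_k_is_error(self, rng):
        X = rng.uniform(0.1, 0.2, size=(2, 2))
        with pytest.raises(InputError):
            _mvset(X, np.zeros(2), np.full(2, 0.01))

    def test_collinear_exposures_named(self, rng):
        x = rng.uniform(0.05, 0.2, 10)
        X = np.column_stack([x, 2 * x])
        m = _mvset(X, 0.3 * x, np.full(10, 0.01), labels=["bmi", "bmi2"])
        with pytest.raises(EstimationError, match="bmi"):
            mvmr_ivw(m)

    def test_overdispersion_floor_never_shrinks_se(self, rng):
        m = _noisy_fixture(rng, n=40, noise=0.002)
        m_het = _mvset(m.X, m.Gamma + rng.normal(0, 0.02, 40), m.se_Gamma)
        res_clean = mvmr_ivw(m)
        res_het = mvmr_ivw(m_het)
        assert res_het.q_stat > res_clean.q_stat
        assert res_het.estimates[0].se > res_clean.estimates[0].se

    def test_intercept_diagnostic_reported(self, rng):
        res = mvmr_ivw(_noisy_fixture(rng, n=40))
        assert res.intercept_p is not None
        assert 0 <= res.intercept_p <= 1


class TestMvMedian:
    def test_clean_data_matches_ivw(self, rng):
        m = _noisy_fixture(rng, n=60, noise=0.001)
        med = mvmr_median(m, n_boot=100, seed=2)
        ivw = mvmr_ivw(m)
        for a, b in zip(med.estimates, ivw.estimates):
            assert a.beta == pytest.approx(b.beta, abs=1e-2)

    def test_robust_to_pleiotropic_minority(self, rng):
        bad = tuple(range(10))  # 20% of 50 SNPs
        m = _noisy_fixture(rng, n=50, theta=(0.3, -0.2), noise=0.002,
                           pleio_idx=bad, pleio=0.15)
        med = mvmr_median(m, n_boot=50, seed=3)
        ivw = mvmr_ivw(m)
        assert abs(med.estimates[0].beta - 0.3) < abs(ivw.estimates[0].beta - 0.3)

    def test_k1_close_to_univariable_weighted_median(self, rng):
        n = 50
        x = rng.uniform(0.05, 0.2, n)
        se_G = np.full(n, 0.003)
        Gamma = 0.2 * x + rng.normal(0, 0.003, n)
        est = MVMedianEstimator(n_boot=50, seed=1).fit(
            x.reshape(-1, 1), Gamma, se_y=se_G
        )
        uni = weighted_median_estimate(
            WaldRatioSet.from_effects(x, Gamma, se_G), n_boot=50, seed=1
        )
        assert est.coef_[0] == pytest.approx(uni.beta, abs=0.05)

    def test_bootstrap_seeded(self, rng):
        m = _noisy_fixture(rng, n=20)
        a = mvmr_median(m, n_boot=50, seed=5)
        b = mvmr_median(m, n_boot=50, seed=5)
        assert a.estimates[0].se == b.estimates[0].se


class TestMvLasso:
    def test_clean_low_noise_retains_all_and_matches_ivw(self, rng):
        m = _noisy_fixture(rng, n=40, noise=0.005)
        # scale noise down so retained-set heterogeneity is tiny
        m = _mvset(m.X, m.X @ np.array([0.3, -0.2]) + rng.normal(0, 1e-4, 40),
                   np.full(40, 0.005))
        res = mvmr_lasso(m)
        assert len(res.retained_snps) == 40
        ivw = mvmr_ivw(m)
        np.testing.assert_allclose(
            [e.beta for e in res.estimates], [e.beta for e in ivw.estimates], atol=1e-10
        )

    def test_planted_pleiotropy_excluded(self, rng):
        n = 50
        X = rng.uniform(0.05, 0.2, size=(n, 2))
        se_G = np.full(n, 0.003)
        Gamma = X @ np.array([0.3, -0.2]) + rng.normal(0, 1e-4, n)
        planted = [4, 17, 33]
        Gamma[planted] += 0.5
        m = _mvset(X, Gamma, se_G)
        res = mvmr_lasso(m)
        excluded = set(m.snp_ids) - set(res.retained_snps)
        assert {f"rs{i}" for i in planted} <= excluded
        assert res.estimates[0].beta == pytest.approx(0.3, abs=0.01)
        assert res.estimates[1].beta == pytest.approx(-0.2, abs=0.01)

    def test_infinite_penalty_equals_ivw_on_all_snps(self, rng):
        m = _noisy_fixture(rng, n=30, noise=0.01)
        res = mvmr_lasso(m, lambda_=1e12)
        ivw = mvmr_ivw(m)
        assert len(res.retained_snps) == 30
        np.testing.assert_allclose(
            [e.beta for e in res.estimates], [e.beta for e in ivw.estimates], atol=1e-12
        )

    def test_estimator_exposes_selected_lambda(self, rng):
        m = _noisy_fixture(rng, n=30, noise=0.002)
        est = MVLassoEstimator().fit(m.X, m.Gamma, se_y=m.se_Gamma)
        assert est.selected_lambda_ > 0
        assert est.retained_.sum() >= m.k + 2


class TestSignificanceRule:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ((0.01, 0.2, 0.9), True),
            ((0.2, 0.01, 0.9), True),
            ((0.9, 0.2, 0.04), True),
            ((0.06, 0.2, 0.9), False),
            ((0.05, 0.05, 0.05), False),  # strict inequality
            ((0.01, 0.01, 0.01), True),
        ],
    )
    def test_at_least_one_truth_table(self, pvals, expected):
        assert mvmr_any_significant(pvals, alpha=0.05) is expected


class TestMvCoverage:
    def test_mv_ivw_ci_coverage_with_correlated_exposures(self):
        """MV-IVW 95% CIs cover (0.25, 0.0) in 93-97% of seeded replicates."""
        from calcmr import SimulationSpec, simulate_mv_dataset

        truth = np.array([0.25, 0.0])
        cover = np.zeros(2)
        n_rep = 500
        for rep in range(n_rep):
            spec = SimulationSpec(n_snps=100, seed=50_000 + rep)
            tables, out_df, _ = simulate_mv_dataset(
                spec, k=2, effect_vector=truth, exposure_correlation=0.5
            )
            X = np.column_stack([t["beta"].to_numpy() for t in tables])
            res = MVIVWEstimator().fit(X, out_df["beta"].to_numpy(),
                                       se_y=out_df["se"].to_numpy())
            lo = res.coef_ - 1.96 * res.se_
            hi = res.coef_ + 1.96 * res.se_
            cover += (lo <= truth) & (truth <= hi)
        for rate in cover / n_rep:
            assert 0.93 <= rate <= 0.97
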