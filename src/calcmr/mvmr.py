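"""Multivariable MR: direct effects of several exposures on one outcome.

Instruments are the union of each exposure's genome-wide-significant clumped
SNPs, re-clumped jointly and harmonized to the outcome. Three estimators of
the direct-effect vector theta (SNP-outcome effects regressed on the
nSNP x k matrix of SNP-exposure effects, weights 1/se_Gamma^2, no intercept):

* MV-IVW - weighted least squares, SEs carrying the multiplicative
  over-dispersion floor max(1, sqrt(Q_mv/(nSNP-k))); a companion fit with an
  intercept provides the Egger-style pleiotropy test.
* MV-median - minimizes the weighted L1 objective sum_j w_j |Gamma_j -
  theta'gamma_j| by iteratively reweighted least squares; bootstrap SEs.
* MV-LASSO - per-SNP pleiotropy intercepts alpha_j are L1-penalized
  (causal effects unpenalized); the penalty is chosen by a heterogeneity
  stopping rule and theta is re-estimated by MV-IVW on the retained
  (alpha_j = 0) SNPs.

A causal relationship is considered to survive adjustment when at least one
of the three methods is significant.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._utils import EstimationError, InputError, safe_z_p
from .instruments import LdMatrix, select_instruments
from .mr_core import MREstimate
from .summary_data import SummaryStatRecord, harmonize, records_to_frame

logger = logging.getLogger(__name__)


@dataclass
class MvInstrumentSet:
    """Joint instruments for k exposures against one outcome."""

    snp_ids: np.ndarray
    X: np.ndarray  # (nsnp, k) SNP-exposure effects
    se_X: np.ndarray  # (nsnp, k)
    Gamma: np.ndarray
    se_Gamma: np.ndarray
    labels: list[str]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.se_X = np.atleast_2d(np.asarray(self.se_X, dtype=float))
        self.Gamma = np.asarray(self.Gamma, dtype=float)
        self.se_Gamma = np.asarray(self.se_Gamma, dtype=float)
        n, k = self.X.shape
        if n <= k:
            raise InputError(f"MVMR needs nsnp > k exposures (got {n} SNPs, k={k})")
        zero_cols = [self.labels[j] for j in range(k) if np.all(self.X[:, j] == 0)]
        if zero_cols:
            raise InputError(f"all-zero exposure effect column(s): {zero_cols}")

    @property
    def nsnp(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def subset(self, mask: np.ndarray) -> "MvInstrumentSet":
        return MvInstrumentSet(
            snp_ids=self.snp_ids[mask],
            X=self.X[mask],
            se_X=self.se_X[mask],
            Gamma=self.Gamma[mask],
            se_Gamma=self.se_Gamma[mask],
            labels=list(self.labels),
            provenance=list(self.provenance),
        )


def assemble_mv_instruments(
    exposure_sets: Mapping[str, Sequence[SummaryStatRecord] | pd.DataFrame],
    outcome: Sequence[SummaryStatRecord] | pd.DataFrame,
    ld: LdMatrix | None = None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
    palindrome_eaf_window: float = 0.08,
) -> MvInstrumentSet:
    """Union of per-exposure instruments, jointly re-clumped and harmonized.

    Each trait's genome-wide-significant clumped SNPs are pooled; the union is
    re-clumped with each SNP ranked by its lowest p across traits; the
    retained SNPs are harmonized to the outcome, and any SNP missing from a
    trait's table is dropped (logged in provenance).
    """
    if len(exposure_sets) < 2:
        raise InputError("multivariable MR needs at least 2 exposures")
    frames = {lab: records_to_frame(recs) for lab, recs in exposure_sets.items()}

    selected = {}
    for lab, df in frames.items():
        sel = select_instruments(
            df, ld=ld, p_threshold=p_threshold, r2_threshold=r2_threshold, window_kb=window_kb
        )
        selected[lab] = sel
        logger.info("assemble_mv_instruments: %s contributes %d SNP(s)", lab, len(sel))

    # one orientation/position row per union SNP: the row from the trait where
    # the SNP is most significant
    pooled = pd.concat(
        [frames[lab][frames[lab]["snp_id"].isin(selected[lab]["snp_id"])] for lab in frames],
        ignore_index=True,
    )
    if pooled.empty:
        raise InputError("no exposure contributes any instrument")
    pooled = pooled.sort_values(["pval", "snp_id"], kind="mergesort").drop_duplicates(
        "snp_id", keep="first"
    )
    reclumped = select_instruments(
        pooled, ld=ld, p_threshold=p_threshold, r2_threshold=r2_threshold, window_kb=window_kb
    )

    others = {lab: frames[lab] for lab in frames}
    others["outcome"] = records_to_frame(outcome)
    h = harmonize(reclumped, others, palindrome_eaf_window=palindrome_eaf_window)

    labels = list(frames)
    m = MvInstrumentSet(
        snp_ids=h.snp_ids,
        X=np.column_stack([h.beta(lab) for lab in labels]),
        se_X=np.column_stack([h.se(lab) for lab in labels]),
        Gamma=h.beta("outcome"),
        se_Gamma=h.se("outcome"),
        labels=labels,
        provenance=list(h.provenance),
    )
    return m


# ---------------------------------------------------------------------------
# estimators


def _check_rank(Xw: np.ndarray, labels: list[str]):
    if np.linalg.matrix_rank(Xw) < Xw.shape[1]:
        corr = np.corrcoef(Xw, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise EstimationError(
            f"rank-deficient exposure design; most collinear pair: "
            f"{labels[i]} ~ {labels[j]} (r={corr[i, j]:.3f})"
        )


class _MVBase(RegressorMixin, BaseEstimator):
    def _validate(self, X, y, se_y, se_X=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).reshape(-1)
        se_y = np.asarray(se_y, dtype=float).reshape(-1)
        if X.shape[0] != len(y) or len(se_y) != len(y):
            raise InputError("X, y, se_y shapes disagree")
        if X.shape[0] <= X.shape[1]:
            raise EstimationError("MVMR needs nsnp > k")
        if np.any(se_y <= 0):
            raise InputError("se_y must be positive")
        if se_X is not None:
            se_X = np.atleast_2d(np.asarray(se_X, dtype=float))
            if se_X.shape != X.shape:
                raise InputError("se_X shape must match X")
        return X, y, se_y, se_X

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.atleast_2d(np.asarray(X, dtype=float)) @ self.coef_

    def estimates(self, labels: Sequence[str] | None = None) -> list[MREstimate]:
        check_is_fitted(self, "coef_")
        labels = list(labels) if labels is not None else [
            f"x{j}" for j in range(len(self.coef_))
        ]
        return [
            MREstimate.from_beta_se(f"{self._method_label} ({lab})", b, s, self.nsnp_)
            for lab, b, s in zip(labels, self.coef_, self.se_)
        ]


class MVIVWEstimator(_MVBase):
    """Multivariable IVW: no-intercept WLS with over-dispersion-floored SEs."""

    _method_label = "MV-IVW"

    def fit(self, X, y, se_y=None, labels=None):
        import statsmodels.api as sm

        X, y, se_y, _ = self._validate(X, y, se_y)
        n, k = X.shape
        labels = list(labels) if labels else [f"x{j}" for j in range(k)]
        w = 1.0 / np.square(se_y)
        _check_rank(X * np.sqrt(w)[:, None], labels)
        res = sm.WLS(y, X, weights=w).fit()
        q_mv = float(res.ssr)  # weighted RSS
        factor = max(1.0, math.sqrt(q_mv / (n - k)))
        bse_unit = np.sqrt(np.diag(res.normalized_cov_params))
        self.coef_ = np.asarray(res.params, dtype=float)
        self.se_ = np.asarray(bse_unit * factor, dtype=float)
        self.pval_ = np.array([safe_z_p(b, s) for b, s in zip(self.coef_, self.se_)])
        self.q_stat_ = q_mv
        self.q_df_ = n - k
        self.q_p_ = float(stats.chi2.sf(q_mv, n - k))
        self.nsnp_ = n
        self.labels_ = labels

        res_i = sm.WLS(y, sm.add_constant(X), weights=w).fit()
        scale_i = float(res_i.scale)
        factor_i = max(1.0, math.sqrt(scale_i))
        int_se = float(np.sqrt(res_i.normalized_cov_params[0, 0]) * factor_i)
        self.intercept_ = float(res_i.params[0])
        self.intercept_se_ = int_se
        self.intercept_p_ = safe_z_p(self.intercept_, int_se)
        return self


def _irls_l1(X, y, w, tol=1e-8, max_iter=200, eps=1e-10, theta0=None):
    """Minimize sum_j w_j |y_j - X_j theta| by iteratively reweighted WLS."""
    sqw = np.sqrt(w)
    theta = (
        np.linalg.lstsq(X * sqw[:, None], y * sqw, rcond=None)[0]
        if theta0 is None
        else np.asarray(theta0, dtype=float)
    )
    for _ in range(max_iter):
        r = y - X @ theta
        wi = w / np.maximum(np.abs(r), eps)
        sqwi = np.sqrt(wi)
        theta_new = np.linalg.lstsq(X * sqwi[:, None], y * sqwi, rcond=None)[0]
        if np.max(np.abs(theta_new - theta)) < tol:
            return theta_new
        theta = theta_new
    return theta


class MVMedianEstimator(_MVBase):
    """Multivariable median regression (weighted L1, IRLS) with bootstrap SEs."""

    _method_label = "MV-median"

    def __init__(self, n_boot: int = 1000, seed: int = 0, tol: float = 1e-8, eps: float = 1e-10):
        self.n_boot = n_boot
        self.seed = seed
        self.tol = tol
        self.eps = eps

    def fit(self, X, y, se_y=None, se_X=None, labels=None):
        X, y, se_y, se_X = self._validate(X, y, se_y, se_X)
        n, k = X.shape
        w = 1.0 / np.square(se_y)
        _check_rank(X * np.sqrt(w)[:, None], list(labels) if labels else [str(j) for j in range(k)])
        theta = _irls_l1(X, y, w, tol=self.tol, eps=self.eps)
        rng = np.random.default_rng(self.seed)
        boots = np.empty((self.n_boot, k))
        for b in range(self.n_boot):
            yb = y + rng.normal(0.0, se_y)
            Xb = X if se_X is None else X + rng.normal(0.0, se_X)
            boots[b] = _irls_l1(Xb, yb, w, tol=self.tol, eps=self.eps, theta0=theta)
        self.coef_ = theta
        self.se_ = boots.std(axis=0, ddof=1)
        self.pval_ = np.array([safe_z_p(t, s) for t, s in zip(theta, self.se_)])
        self.nsnp_ = n
        self.labels_ = list(labels) if labels else [f"x{j}" for j in range(k)]
        return self


def _lasso_alpha_fit(X, y, w, lam, tol=1e-8, max_iter=500):
    """Alternating minimization of sum w_j (y_j - X theta - alpha_j)^2 + lam sum|alpha_j|."""
    sqw = np.sqrt(w)
    alpha = np.zeros(len(y))
    theta = np.linalg.lstsq(X * sqw[:, None], y * sqw, rcond=None)[0]
    for _ in range(max_iter):
        r = y - X @ theta
        thresh = lam / (2.0 * w)
        alpha_new = np.sign(r) * np.maximum(np.abs(r) - thresh, 0.0)
        theta_new = np.linalg.lstsq(
            X * sqw[:, None], (y - alpha_new) * sqw, rcond=None
        )[0]
        if np.max(np.abs(theta_new - theta)) < tol and np.max(np.abs(alpha_new - alpha)) < tol:
            return theta_new, alpha_new
        theta, alpha = theta_new, alpha_new
    return theta, alpha


class MVLassoEstimator(_MVBase):
    """MV-LASSO: L1-penalized per-SNP pleiotropy intercepts.

    The penalty grid runs log-spaced from lambda_max (the smallest lambda
    zeroing every alpha_j) down to ``lambda_min_ratio * lambda_max``. Scanning
    from the largest lambda downward, the selected penalty is the first whose
    retained (alpha_j = 0) SNPs are homogeneous (Q <= degrees of freedom);
    theta is then re-estimated by MV-IVW on the retained SNPs.
    """

    _method_label = "MV-LASSO"

    def __init__(
        self,
        n_lambda: int = 50,
        lambda_min_ratio: float = 1e-4,
        lambda_: float | None = None,
    ):
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.lambda_ = lambda_

    def fit(self, X, y, se_y=None, labels=None):
        X, y, se_y, _ = self._validate(X, y, se_y)
        n, k = X.shape
        labels = list(labels) if labels else [f"x{j}" for j in range(k)]
        w = 1.0 / np.square(se_y)
        sqw = np.sqrt(w)
        _check_rank(X * sqw[:, None], labels)

        theta0 = np.linalg.lstsq(X * sqw[:, None], y * sqw, rcond=None)[0]
        r0 = y - X @ theta0
        lam_max = 2.0 * float(np.max(w * np.abs(r0))) * (1.0 + 1e-6)
        if lam_max == 0:
            lam_max = 1.0
        if self.lambda_ is not None:
            grid = [float(self.lambda_)]
        else:
            grid = np.geomspace(lam_max, lam_max * self.lambda_min_ratio, self.n_lambda)

        chosen = None
        for lam in grid:
            theta, alpha = _lasso_alpha_fit(X, y, w, lam)
            retained = np.abs(alpha) < 1e-12
            n_ret = int(retained.sum())
            if n_ret < k + 2:
                continue
            sub = MVIVWEstimator().fit(X[retained], y[retained], se_y=se_y[retained], labels=labels)
            if self.lambda_ is not None or sub.q_stat_ <= sub.q_df_:
                chosen = (lam, alpha, retained, sub)
                break
        if chosen is None:
            raise EstimationError(
                "MV-LASSO: no penalty on the grid retains k+2 homogeneous SNPs"
            )
        lam, alpha, retained, sub = chosen
        self.selected_lambda_ = float(lam)
        self.alpha_ = alpha
        self.retained_ = retained
        self.coef_ = sub.coef_
        self.se_ = sub.se_
        self.pval_ = sub.pval_
        self.q_stat_ = sub.q_stat_
        self.q_df_ = sub.q_df_
        self.q_p_ = sub.q_p_
        self.nsnp_ = int(retained.sum())
        self.labels_ = labels
        return self


# ---------------------------------------------------------------------------
# functional wrappers


@dataclass(frozen=True)
class MvmrResult:
    """Per-exposure direct-effect estimates plus heterogeneity/pleiotropy diagnostics."""

    estimates: list[MREstimate]
    q_stat: float
    q_df: int
    q_p: float
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None
    retained_snps: Optional[list[str]] = None
    selected_lambda: Optional[float] = None


def mvmr_ivw(m: MvInstrumentSet) -> MvmrResult:
    est = MVIVWEstimator().fit(m.X, m.Gamma, se_y=m.se_Gamma, labels=m.labels)
    return MvmrResult(
        estimates=est.estimates(m.labels),
        q_stat=est.q_stat_,
        q_df=est.q_df_,
        q_p=est.q_p_,
        intercept=est.intercept_,
        intercept_se=est.intercept_se_,
        intercept_p=est.intercept_p_,
    )


def mvmr_median(m: MvInstrumentSet, n_boot: int = 1000, seed: int = 0) -> MvmrResult:
    est = MVMedianEstimator(n_boot=n_boot, seed=seed).fit(
        m.X, m.Gamma, se_y=m.se_Gamma, se_X=m.se_X, labels=m.labels
    )
    w = 1.0 / np.square(m.se_Gamma)
    r = m.Gamma - m.X @ est.coef_
    q = float(np.sum(w * r**2))
    df = m.nsnp - m.k
    return MvmrResult(
        estimates=est.estimates(m.labels), q_stat=q, q_df=df, q_p=float(stats.chi2.sf(q, df))
    )


def mvmr_lasso(m: MvInstrumentSet, n_lambda: int = 50, lambda_min_ratio: float = 1e-4,
               lambda_: float | None = None) -> MvmrResult:
    est = MVLassoEstimator(
        n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio, lambda_=lambda_
    ).fit(m.X, m.Gamma, se_y=m.se_Gamma, labels=m.labels)
    return MvmrResult(
        estimates=est.estimates(m.labels),
        q_stat=est.q_stat_,
        q_df=est.q_df_,
        q_p=est.q_p_,
        retained_snps=[str(s) for s in m.snp_ids[est.retained_]],
        selected_lambda=est.selected_lambda_,
    )


def mvmr_any_significant(pvals: Sequence[float], alpha: float = 0.05) -> bool:
    """At-least-one rule: adjusted causal relation persists if any method's p < alpha."""
    return any(p < alpha for p in pvals)
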