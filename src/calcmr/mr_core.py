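"""Univariable two-sample MR estimators.

Given harmonized SNP-exposure effects gamma_j (SE se_gamma_j) and SNP-outcome
effects Gamma_j (SE se_Gamma_j), each SNP provides a Wald ratio
Gamma_j / gamma_j with first-order SE se_Gamma_j / |gamma_j|. Four estimators
combine the ratios:

* IVW - inverse-variance-weighted mean of the ratios; a fixed-effects model
  unless Cochran's Q flags heterogeneity (p < 0.05), in which case the SE is
  inflated by the multiplicative factor sqrt(Q / (nSNP - 1)), floored at 1.
* MR-Egger - weighted regression of Gamma on gamma with a free intercept; the
  intercept estimates average directional pleiotropy.
* Weighted median - consistent when instruments carrying >= 50% of the weight
  are valid; SE from a parametric bootstrap.
* Weighted mode - the maximum of a weighted Gaussian kernel density over the
  ratios; consistent when the largest cluster of instruments is valid.

All estimators follow the scikit-learn fit API (``fit(X, y, se_y=...)`` with
X the SNP-exposure effects) and expose fitted attributes ``beta_``, ``se_``,
``pval_`` plus method-specific diagnostics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._utils import Z95, EstimationError, InputError, safe_z_p
from .summary_data import HarmonizedInstrumentSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class MREstimate:
    """One causal-effect estimate on the log-odds (or SD-unit) scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_point: float
    or_low: float
    or_high: float
    nsnp: int
    effects_model: Optional[str] = None  # "fixed" | "random" (IVW only)

    @classmethod
    def from_beta_se(
        cls, method: str, beta: float, se: float, nsnp: int, effects_model: str | None = None
    ) -> "MREstimate":
        orp, orl, orh = beta_to_or(beta, se)
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            ci_low=float(beta - Z95 * se),
            ci_high=float(beta + Z95 * se),
            pval=safe_z_p(beta, se),
            or_point=orp,
            or_low=orl,
            or_high=orh,
            nsnp=int(nsnp),
            effects_model=effects_model,
        )


@dataclass(frozen=True)
class WaldRatioSet:
    """Per-SNP Wald ratios with first-order SEs and IVW weights."""

    snp_ids: np.ndarray
    ratio: np.ndarray
    se_ratio: np.ndarray

    @property
    def weight(self) -> np.ndarray:
        return 1.0 / np.square(self.se_ratio)

    @property
    def nsnp(self) -> int:
        return len(self.ratio)

    def subset(self, mask: np.ndarray) -> "WaldRatioSet":
        return WaldRatioSet(self.snp_ids[mask], self.ratio[mask], self.se_ratio[mask])

    @classmethod
    def from_effects(
        cls,
        gamma: np.ndarray,
        Gamma: np.ndarray,
        se_Gamma: np.ndarray,
        snp_ids: np.ndarray | None = None,
    ) -> "WaldRatioSet":
        gamma = np.asarray(gamma, dtype=float)
        Gamma = np.asarray(Gamma, dtype=float)
        se_Gamma = np.asarray(se_Gamma, dtype=float)
        if snp_ids is None:
            snp_ids = np.array([f"snp{i}" for i in range(len(gamma))])
        usable = gamma != 0
        n_dropped = int((~usable).sum())
        if n_dropped:
            logger.info("wald_ratios: excluded %d SNP(s) with zero exposure effect", n_dropped)
        if usable.sum() < 1:
            raise InputError("no usable SNP with nonzero exposure effect")
        g, G, sG = gamma[usable], Gamma[usable], se_Gamma[usable]
        return cls(
            snp_ids=np.asarray(snp_ids)[usable],
            ratio=G / g,
            se_ratio=sG / np.abs(g),
        )


def wald_ratios(h: HarmonizedInstrumentSet) -> WaldRatioSet:
    """Per-SNP Wald ratios Gamma_j/gamma_j with SE se_Gamma_j/|gamma_j|."""
    return WaldRatioSet.from_effects(h.gamma, h.Gamma, h.se_Gamma, h.snp_ids)


def beta_to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Log-odds effect and SE to odds ratio with 95% CI."""
    if se < 0:
        raise InputError("se must be >= 0")
    with np.errstate(over="ignore"):
        return (
            float(np.exp(beta)),
            float(np.exp(beta - Z95 * se)),
            float(np.exp(beta + Z95 * se)),
        )


# ---------------------------------------------------------------------------
# numerical cores (shared by the sklearn classes and the wrappers)


def _cochran_q(ratio: np.ndarray, weight: np.ndarray, beta: float) -> tuple[float, int, float]:
    q = float(np.sum(weight * np.square(ratio - beta)))
    df = len(ratio) - 1
    return q, df, float(stats.chi2.sf(q, df))


def _ivw_core(ratio, weight, q_alpha):
    beta = float(np.sum(weight * ratio) / np.sum(weight))
    se_fixed = float(np.sum(weight) ** -0.5)
    q, df, q_p = _cochran_q(ratio, weight, beta)
    if q_p < q_alpha:
        se = se_fixed * max(1.0, math.sqrt(q / df))
        model = "random"
    else:
        se = se_fixed
        model = "fixed"
    return beta, se, q, df, q_p, model


def _weighted_median(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio, kind="stable")
    r = ratio[order]
    w = weight[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def _mode_bandwidth(ratio: np.ndarray, bandwidth_factor: float) -> float:
    sd = float(np.std(ratio, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratio, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return bandwidth_factor * 0.9 * spread * len(ratio) ** (-1 / 5)


def _weighted_mode(ratio: np.ndarray, weight: np.ndarray, bandwidth_factor: float) -> float:
    if np.ptp(ratio) == 0:
        return float(ratio[0])
    h = _mode_bandwidth(ratio, bandwidth_factor)
    if h <= 0:
        return float(ratio[np.argmax(weight)])
    w = weight / weight.sum()

    def density(x):
        z = (np.asarray(x)[..., None] - ratio) / h
        return np.sum(w * np.exp(-0.5 * z * z), axis=-1)

    grid = np.linspace(ratio.min(), ratio.max(), 512)
    dens = density(grid)
    i = int(np.argmax(dens))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda x: -density(x), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def _parametric_bootstrap(estimate_fn, ratio, se_ratio, n_boot, seed):
    rng = np.random.default_rng(seed)
    draws = rng.normal(ratio, se_ratio, size=(n_boot, len(ratio)))
    reps = np.array([estimate_fn(d) for d in draws])
    return float(np.std(reps, ddof=1))


# ---------------------------------------------------------------------------
# sklearn-style estimators


class _MRRegressorBase(RegressorMixin, BaseEstimator):
    """Shared validation and prediction for univariable MR estimators."""

    _min_nsnp = 2

    def _validate_effects(self, X, y, se_y):
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if se_y is None:
            raise InputError("se_y (SNP-outcome standard errors) is required")
        se_y = np.asarray(se_y, dtype=float).reshape(-1)
        if not (len(X) == len(y) == len(se_y)):
            raise InputError("X, y, se_y must have equal length")
        if np.any(se_y <= 0) or not np.all(np.isfinite(se_y)):
            raise InputError("se_y must be positive and finite")
        if np.any(X == 0):
            raise InputError("zero exposure effects; filter with WaldRatioSet.from_effects")
        if len(X) < self._min_nsnp:
            raise EstimationError(
                f"{type(self).__name__} needs at least {self._min_nsnp} SNPs, got {len(X)}"
            )
        return X, y, se_y

    def predict(self, X):
        """Predicted SNP-outcome effects beta_ * gamma_j."""
        check_is_fitted(self, "beta_")
        return self.beta_ * np.asarray(X, dtype=float).reshape(-1)

    def _finish(self, beta, se, nsnp, effects_model=None):
        self.beta_ = float(beta)
        self.se_ = float(se)
        self.pval_ = safe_z_p(beta, se)
        self.ci_ = (beta - Z95 * se, beta + Z95 * se)
        self.nsnp_ = int(nsnp)
        self.effects_model_ = effects_model
        return self

    def to_estimate(self, method: str | None = None) -> MREstimate:
        check_is_fitted(self, "beta_")
        return MREstimate.from_beta_se(
            method or self._method_label, self.beta_, self.se_, self.nsnp_, self.effects_model_
        )


class IVWEstimator(_MRRegressorBase):
    """Inverse-variance-weighted MR with the fixed/random-effects decision.

    A fixed-effects model is used unless Cochran's Q across the Wald ratios
    is significant at ``q_alpha``, in which case the SE is multiplied by
    max(1, sqrt(Q/(nSNP-1))) (multiplicative random effects; the factor never
    shrinks the fixed-effects SE).
    """

    _method_label = "IVW"
    _min_nsnp = 2

    def __init__(self, q_alpha: float = 0.05):
        self.q_alpha = q_alpha

    def fit(self, X, y, se_y=None):
        X, y, se_y = self._validate_effects(X, y, se_y)
        ratio = y / X
        weight = np.square(X / se_y)
        beta, se, q, df, q_p, model = _ivw_core(ratio, weight, self.q_alpha)
        self.q_stat_, self.q_df_, self.q_p_ = q, df, q_p
        return self._finish(beta, se, len(X), model)


class EggerEstimator(_MRRegressorBase):
    """MR-Egger: weighted regression of Gamma on gamma with a free intercept.

    gamma_j are re-oriented positive (flipping Gamma_j jointly); weights are
    1/se_Gamma_j^2, and both slope and intercept SEs carry the multiplicative
    over-dispersion factor max(1, sqrt(RSS/(n-2))).
    """

    _method_label = "MR-Egger"
    _min_nsnp = 3

    def fit(self, X, y, se_y=None):
        import statsmodels.api as sm

        X, y, se_y = self._validate_effects(X, y, se_y)
        flip = np.sign(X)
        g = X * flip
        G = y * flip
        res = sm.WLS(G, sm.add_constant(g), weights=1.0 / np.square(se_y)).fit()
        scale = float(res.scale)  # weighted RSS / (n - 2)
        factor = max(1.0, math.sqrt(scale))
        bse_unit = np.sqrt(np.diag(res.normalized_cov_params))
        intercept, slope = res.params
        int_se, slope_se = bse_unit * factor
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(int_se)
        self.intercept_p_ = safe_z_p(intercept, int_se)
        self.residual_scale_ = scale
        return self._finish(slope, slope_se, len(X))

    def predict(self, X):
        check_is_fitted(self, "beta_")
        X = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ * np.sign(X) + self.beta_ * X


class WeightedMedianEstimator(_MRRegressorBase):
    """Weighted median of the Wald ratios.

    The estimate interpolates the ordered ratios at standardized cumulative
    weight 0.5; the SE comes from a parametric bootstrap resampling
    ratio_j ~ Normal(ratio_j, se_ratio_j) with fixed weights.
    """

    _method_label = "Weighted median"
    _min_nsnp = 3

    def __init__(self, n_boot: int = 1000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y, se_y=None):
        X, y, se_y = self._validate_effects(X, y, se_y)
        ratio = y / X
        se_ratio = se_y / np.abs(X)
        weight = 1.0 / np.square(se_ratio)
        beta = _weighted_median(ratio, weight)
        se = _parametric_bootstrap(
            lambda r: _weighted_median(r, weight), ratio, se_ratio, self.n_boot, self.seed
        )
        return self._finish(beta, se, len(X))


class WeightedModeEstimator(_MRRegressorBase):
    """Weighted kernel-density mode of the Wald ratios.

    Gaussian kernels weighted by 1/se_ratio_j^2, bandwidth
    ``bandwidth_factor * 0.9 * min(sd, IQR/1.349) * n^(-1/5)``; the argmax is
    located on a 512-point grid and refined by bounded golden-section search.
    SE by parametric bootstrap. All ratios identical returns that value with
    SE 0.
    """

    _method_label = "Weighted mode"
    _min_nsnp = 3

    def __init__(self, bandwidth_factor: float = 1.0, n_boot: int = 1000, seed: int = 0):
        self.bandwidth_factor = bandwidth_factor
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y, se_y=None):
        X, y, se_y = self._validate_effects(X, y, se_y)
        ratio = y / X
        se_ratio = se_y / np.abs(X)
        weight = 1.0 / np.square(se_ratio)
        beta = _weighted_mode(ratio, weight, self.bandwidth_factor)
        if np.ptp(ratio) == 0:
            return self._finish(beta, 0.0, len(X))
        se = _parametric_bootstrap(
            lambda r: _weighted_mode(r, weight, self.bandwidth_factor),
            ratio,
            se_ratio,
            self.n_boot,
            self.seed,
        )
        return self._finish(beta, se, len(X))


# ---------------------------------------------------------------------------
# functional wrappers over the estimator classes


def _effects_from(w: WaldRatioSet):
    # A WaldRatioSet is equivalent to unit exposure effects with the ratio SEs.
    return np.ones(w.nsnp), w.ratio, w.se_ratio


def ivw_estimate(w: WaldRatioSet | HarmonizedInstrumentSet, q_alpha: float = 0.05) -> MREstimate:
    """IVW estimate (see :class:`IVWEstimator`); needs at least 2 SNPs."""
    if isinstance(w, HarmonizedInstrumentSet):
        w = wald_ratios(w)
    est = IVWEstimator(q_alpha=q_alpha).fit(*_effects_from(w))
    return est.to_estimate()


def egger_regression(
    h: HarmonizedInstrumentSet | WaldRatioSet,
) -> tuple[MREstimate, float, float, float]:
    """MR-Egger slope estimate plus (intercept, intercept SE, intercept p)."""
    if isinstance(h, HarmonizedInstrumentSet):
        est = EggerEstimator().fit(h.gamma, h.Gamma, se_y=h.se_Gamma)
    else:
        raise InputError("egger_regression needs gamma/Gamma effects, not ratios")
    return est.to_estimate(), est.intercept_, est.intercept_se_, est.intercept_p_


def weighted_median_estimate(
    w: WaldRatioSet | HarmonizedInstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    if isinstance(w, HarmonizedInstrumentSet):
        w = wald_ratios(w)
    return WeightedMedianEstimator(n_boot=n_boot, seed=seed).fit(*_effects_from(w)).to_estimate()


def weighted_mode_estimate(
    w: WaldRatioSet | HarmonizedInstrumentSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    if isinstance(w, HarmonizedInstrumentSet):
        w = wald_ratios(w)
    est = WeightedModeEstimator(
        bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed
    ).fit(*_effects_from(w))
    return est.to_estimate()


def single_snp_wald(w: WaldRatioSet) -> MREstimate:
    """Wald-ratio estimate for the single-instrument case."""
    if w.nsnp != 1:
        raise EstimationError("single_snp_wald requires exactly one SNP")
    return MREstimate.from_beta_se("Wald ratio", w.ratio[0], w.se_ratio[0], 1)
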