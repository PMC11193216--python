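"""Heterogeneity, pleiotropy, influence, and outlier diagnostics.

Covers the standard two-sample MR sensitivity battery: Cochran's Q across the
Wald ratios (chi-square with nSNP-1 df under homogeneity), the MR-Egger
intercept test for directional pleiotropy, leave-one-out IVW re-estimation,
and a re-implementation of the MR-PRESSO global / outlier / distortion tests
(simulation-based residual-sum-of-squares comparison against a parametric
null).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._utils import EstimationError
from .mr_core import (
    EggerEstimator,
    MREstimate,
    WaldRatioSet,
    _cochran_q,
    ivw_estimate,
    wald_ratios,
)
from .summary_data import HarmonizedInstrumentSet

logger = logging.getLogger(__name__)


def cochran_q(w: WaldRatioSet, beta_ivw: float) -> tuple[float, int, float]:
    """Cochran's Q = sum_j w_j (ratio_j - beta_ivw)^2 with nSNP-1 df."""
    if w.nsnp < 2:
        raise EstimationError("Cochran's Q needs at least 2 SNPs")
    return _cochran_q(w.ratio, w.weight, beta_ivw)


def leave_one_out(h: HarmonizedInstrumentSet | WaldRatioSet, q_alpha: float = 0.05) -> pd.DataFrame:
    """IVW re-estimated with each SNP removed in turn.

    Returns one row per dropped SNP (snp_id, beta, se, pval, effects_model);
    the fixed/random-effects decision is re-applied on every subset.
    """
    w = wald_ratios(h) if isinstance(h, HarmonizedInstrumentSet) else h
    if w.nsnp < 3:
        raise EstimationError("leave-one-out needs at least 3 SNPs")
    rows = []
    for j in range(w.nsnp):
        mask = np.ones(w.nsnp, dtype=bool)
        mask[j] = False
        est = ivw_estimate(w.subset(mask), q_alpha=q_alpha)
        rows.append(
            {
                "snp_id": w.snp_ids[j],
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "effects_model": est.effects_model,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, outlier, and distortion test results."""

    global_p: float
    rss_obs: float
    outliers: list[str]
    outlier_pvals: dict[str, float]  # Bonferroni-adjusted per-SNP p
    distortion_p: Optional[float]
    corrected: Optional[MREstimate]


def _loo_ivw_predictions(ratio, weight):
    """Fixed-effects IVW estimate excluding each SNP in turn (vectorized)."""
    sw = np.sum(weight)
    swr = np.sum(weight * ratio)
    return (swr - weight * ratio) / (sw - weight)


def mr_presso(
    h: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """Simulation-based outlier detection (MR-PRESSO construction).

    Global test: the observed residual sum of squares of Gamma_j about its
    leave-one-out IVW prediction beta_(-j)*gamma_j (residuals standardized by
    se_Gamma_j) is compared against ``n_sim`` parametric simulations drawing
    Gamma*_j ~ N(beta_(-j)*gamma_j, se_Gamma_j^2), gamma*_j ~ N(gamma_j,
    se_gamma_j^2). Outlier test: per-SNP simulated squared residuals vs the
    observed one, Bonferroni-adjusted by nSNP. Distortion test: the shift of
    the IVW estimate after removing the flagged outliers is compared against
    removal of equally many random SNPs. All Monte-Carlo p-values use the
    (r+1)/(n+1) correction.
    """
    if h.nsnp < 4:
        raise EstimationError("MR-PRESSO needs at least 4 SNPs")
    gamma, se_gamma = h.gamma, h.se_gamma
    Gamma, se_Gamma = h.Gamma, h.se_Gamma
    n = h.nsnp
    ratio = Gamma / gamma
    weight = np.square(gamma / se_Gamma)

    beta_loo = _loo_ivw_predictions(ratio, weight)
    resid_obs = (Gamma - beta_loo * gamma) / se_Gamma
    rss_obs = float(np.sum(resid_obs**2))

    rng = np.random.default_rng(seed)
    g_sim = gamma + rng.normal(0.0, se_gamma, size=(n_sim, n))
    G_sim = beta_loo * gamma + rng.normal(0.0, se_Gamma, size=(n_sim, n))
    g_sim = np.where(g_sim == 0, np.finfo(float).tiny, g_sim)
    ratio_sim = G_sim / g_sim
    w_sim = np.square(g_sim / se_Gamma)
    sw = w_sim.sum(axis=1, keepdims=True)
    swr = (w_sim * ratio_sim).sum(axis=1, keepdims=True)
    beta_loo_sim = (swr - w_sim * ratio_sim) / (sw - w_sim)
    resid_sim = (G_sim - beta_loo_sim * g_sim) / se_Gamma
    rss_sim = np.sum(resid_sim**2, axis=1)

    global_p = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))

    per_snp_p = (np.sum(resid_sim**2 >= resid_obs**2, axis=0) + 1) / (n_sim + 1)
    p_adj = np.minimum(1.0, per_snp_p * n)
    flagged = p_adj < outlier_alpha
    outliers = [str(s) for s in h.snp_ids[flagged]]
    outlier_pvals = {str(s): float(p) for s, p in zip(h.snp_ids[flagged], p_adj[flagged])}

    if not flagged.any():
        return PressoResult(global_p, rss_obs, [], {}, None, None)

    keep = ~flagged
    beta_all = float(np.sum(weight * ratio) / np.sum(weight))
    beta_kept = float(np.sum(weight[keep] * ratio[keep]) / np.sum(weight[keep]))
    obs_shift = beta_all - beta_kept
    k_out = int(flagged.sum())
    shifts = np.empty(n_sim)
    for s in range(n_sim):
        drop = rng.choice(n, size=k_out, replace=False)
        m = np.ones(n, dtype=bool)
        m[drop] = False
        shifts[s] = beta_all - np.sum(weight[m] * ratio[m]) / np.sum(weight[m])
    distortion_p = float((np.sum(np.abs(shifts) >= abs(obs_shift)) + 1) / (n_sim + 1))
    corrected = ivw_estimate(wald_ratios(h).subset(keep))
    return PressoResult(global_p, rss_obs, outliers, outlier_pvals, distortion_p, corrected)


@dataclass
class SensitivityReport:
    """Combined sensitivity diagnostics for one exposure-outcome analysis."""

    q_stat: float
    q_df: int
    q_p: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    loo_table: pd.DataFrame
    presso_global_p: Optional[float] = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_outlier_pvals: dict[str, float] = field(default_factory=dict)
    presso_distortion_p: Optional[float] = None
    presso_corrected: Optional[MREstimate] = None


def sensitivity_report(
    h: HarmonizedInstrumentSet,
    seed: int = 0,
    n_sim: int = 1000,
    q_alpha: float = 0.05,
    outlier_alpha: float = 0.05,
) -> SensitivityReport:
    """Run the full diagnostic battery on a harmonized instrument set.

    MR-PRESSO is skipped (fields left None/empty) below 4 SNPs; Cochran's Q
    uses the IVW point estimate; the leave-one-out table re-applies the
    fixed/random decision per subset.
    """
    w = wald_ratios(h)
    ivw = ivw_estimate(w, q_alpha=q_alpha)
    q, df, q_p = cochran_q(w, ivw.beta)
    egger = EggerEstimator().fit(h.gamma, h.Gamma, se_y=h.se_Gamma)
    loo = leave_one_out(w, q_alpha=q_alpha)
    report = SensitivityReport(
        q_stat=q,
        q_df=df,
        q_p=q_p,
        egger_intercept=egger.intercept_,
        egger_intercept_se=egger.intercept_se_,
        egger_intercept_p=egger.intercept_p_,
        loo_table=loo,
    )
    if h.nsnp >= 4:
        presso = mr_presso(h, n_sim=n_sim, outlier_alpha=outlier_alpha, seed=seed)
        report.presso_global_p = presso.global_p
        report.presso_outliers = presso.outliers
        report.presso_outlier_pvals = presso.outlier_pvals
        report.presso_distortion_p = presso.distortion_p
        report.presso_corrected = presso.corrected
    else:
        logger.info("sensitivity_report: <4 SNPs, MR-PRESSO skipped")
    return report
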