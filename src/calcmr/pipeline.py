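"""Three-stage study orchestration and report tables.

Stage 1 estimates the total effect of every exposure on every outcome with
four univariable MR methods plus the sensitivity battery, and repeats the
analysis with the roles reversed (reverse MR). Stage 2 runs two-step
mediation for every exposure-outcome pair whose stage-1 IVW estimate is
significant: exposure->mediator (beta1) and mediator->outcome (beta2) MR,
the eligibility rule, and the proportion mediated (beta1*beta2)/beta0.
Stage 3 re-estimates each significant exposure's effect jointly with one
cardiometabolic covariate at a time (multivariable MR: IVW, median, LASSO)
and applies the at-least-one-significant rule.

Significance taxonomy: p < alpha_nominal/#exposures (Bonferroni) is
"significant", alpha_bonferroni <= p < alpha_nominal is "nominal", else
"null". The Bonferroni threshold is always computed from the configured
exposure count, never hard-coded.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import (
    CalcmrError,
    ConfigError,
    InputError,
    spawn_int_seed,
)
from .instruments import LdMatrix, instrument_strength, select_instruments
from .mediation import MediationResult, mediation_eligibility, proportion_mediated
from .mr_core import (
    MREstimate,
    ivw_estimate,
    wald_ratios,
    weighted_median_estimate,
    weighted_mode_estimate,
)
from .mvmr import assemble_mv_instruments, mvmr_any_significant, mvmr_ivw, mvmr_lasso, mvmr_median
from .mr_core import EggerEstimator
from .sensitivity import SensitivityReport, sensitivity_report
from .summary_data import harmonize, read_summary_stats

logger = logging.getLogger(__name__)

STAGE1_COLUMNS = [
    "exposure", "outcome", "method", "nsnp", "beta", "se", "pval",
    "or", "or_low", "or_high", "effects_model",
    "egger_intercept", "egger_intercept_p", "q_stat", "q_p",
    "presso_global_p", "significance",
]
MEDIATION_COLUMNS = [
    "exposure", "mediator", "outcome", "nsnp1", "nsnp2",
    "beta0", "se0", "beta1", "se1", "pval1", "beta2", "se2", "pval2",
    "indirect", "se_indirect", "proportion_pct", "proportion_ci_low_pct",
    "proportion_ci_high_pct", "proportion_p", "eligible", "reason",
]
MVMR_COLUMNS = [
    "exposure", "outcome", "adjustment", "method", "nsnp", "beta", "se",
    "pval", "or", "or_low", "or_high", "q_stat", "q_p",
    "egger_intercept", "egger_intercept_p", "any_method_significant",
    "significance",
]


def classify_significance(
    p: float, alpha_nominal: float = 0.05, alpha_bonferroni: float = 0.0125
) -> str:
    """Label a p-value: "significant" (< Bonferroni), "nominal", or "null"."""
    if not (0 < p <= 1):
        raise InputError(f"p-value outside (0, 1]: {p}")
    if alpha_bonferroni > alpha_nominal:
        raise ConfigError("alpha_bonferroni must be <= alpha_nominal")
    if p < alpha_bonferroni:
        return "significant"
    if p < alpha_nominal:
        return "nominal"
    return "null"


@dataclass
class StudyConfig:
    """Inputs and thresholds for one three-stage study."""

    exposures: dict[str, str]
    outcomes: dict[str, str]
    mediators: dict[str, str] = field(default_factory=dict)
    covariates: dict[str, str] = field(default_factory=dict)
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    f_min: float = 10.0
    alpha_nominal: float = 0.05
    q_alpha: float = 0.05
    palindrome_eaf_window: float = 0.08
    presso_nsim: int = 1000
    n_boot: int = 1000
    stage2_trigger: str = "nominal"  # or "bonferroni"
    ld_path: Optional[str] = None
    column_map: Optional[dict[str, str]] = None
    seed: int = 0

    def __post_init__(self):
        if not self.exposures or not self.outcomes:
            raise ConfigError("config needs at least one exposure and one outcome")
        if self.stage2_trigger not in ("nominal", "bonferroni"):
            raise ConfigError("stage2_trigger must be 'nominal' or 'bonferroni'")

    @property
    def alpha_bonferroni(self) -> float:
        """alpha_nominal divided by the number of exposures (computed, not stored)."""
        return self.alpha_nominal / len(self.exposures)

    @property
    def stage2_alpha(self) -> float:
        return self.alpha_nominal if self.stage2_trigger == "nominal" else self.alpha_bonferroni

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad config {path}: {exc}") from exc

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StudyReport:
    """All tables of one three-stage run plus run metadata."""

    stage1: pd.DataFrame
    reverse: pd.DataFrame
    mediation: pd.DataFrame
    mvmr: pd.DataFrame
    metadata: dict


@dataclass
class _UnivariableAnalysis:
    """Internal bundle from one exposure-outcome univariable analysis."""

    estimates: dict[str, MREstimate]
    sens: SensitivityReport
    nsnp: int
    harmonized: "object"


def _prepare_instruments(records, cfg: StudyConfig, ld: LdMatrix | None):
    sel = select_instruments(
        records,
        ld=ld,
        p_threshold=cfg.p_threshold,
        r2_threshold=cfg.clump_r2,
        window_kb=cfg.clump_kb,
    )
    if len(sel) == 0:
        return []
    _, retained = instrument_strength(sel, f_min=cfg.f_min)
    return retained


def _univariable_analysis(
    exp_records, out_records, cfg: StudyConfig, seed: int, ld: LdMatrix | None
) -> Optional[_UnivariableAnalysis]:
    instruments = _prepare_instruments(exp_records, cfg, ld)
    if len(instruments) == 0:
        return None
    h = harmonize(
        instruments, {"outcome": out_records}, palindrome_eaf_window=cfg.palindrome_eaf_window
    )
    if h.nsnp < 3:
        logger.warning("univariable analysis skipped: only %d harmonized SNP(s)", h.nsnp)
        return None
    w = wald_ratios(h)
    estimates = {
        "IVW": ivw_estimate(w, q_alpha=cfg.q_alpha),
        "MR-Egger": EggerEstimator().fit(h.gamma, h.Gamma, se_y=h.se_Gamma).to_estimate(),
        "Weighted median": weighted_median_estimate(w, n_boot=cfg.n_boot, seed=seed),
        "Weighted mode": weighted_mode_estimate(w, n_boot=cfg.n_boot, seed=seed + 1),
    }
    sens = sensitivity_report(
        h, seed=seed + 2, n_sim=cfg.presso_nsim, q_alpha=cfg.q_alpha
    )
    return _UnivariableAnalysis(estimates=estimates, sens=sens, nsnp=h.nsnp, harmonized=h)


def _stage1_rows(exposure, outcome, ua: _UnivariableAnalysis, cfg: StudyConfig):
    rows = []
    for method, est in ua.estimates.items():
        rows.append(
            {
                "exposure": exposure,
                "outcome": outcome,
                "method": method,
                "nsnp": est.nsnp,
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "or": est.or_point,
                "or_low": est.or_low,
                "or_high": est.or_high,
                "effects_model": est.effects_model or "",
                "egger_intercept": ua.sens.egger_intercept,
                "egger_intercept_p": ua.sens.egger_intercept_p,
                "q_stat": ua.sens.q_stat,
                "q_p": ua.sens.q_p,
                "presso_global_p": (
                    np.nan if ua.sens.presso_global_p is None else ua.sens.presso_global_p
                ),
                "significance": classify_significance(
                    est.pval, cfg.alpha_nominal, cfg.alpha_bonferroni
                ),
            }
        )
    return rows


def estimate_mediation(
    exp_records,
    med_records,
    out_records,
    beta0_estimate: MREstimate | None = None,
    cfg: StudyConfig | None = None,
    ld: LdMatrix | None = None,
    p_threshold: float = 5e-8,
    clump_r2: float = 0.001,
    clump_kb: int = 10_000,
    f_min: float = 10.0,
    q_alpha: float = 0.05,
) -> MediationResult:
    """Two-step mediation chain from raw summary statistics.

    Runs the same instrument-selection -> harmonization -> IVW sequence the
    pipeline's stage 2 uses: exposure->mediator for beta1 (exposure
    instruments), mediator->outcome for beta2 (mediator instruments), and -
    unless a stage-1 total effect is supplied - exposure->outcome for beta0.
    """
    if cfg is not None:
        p_threshold, clump_r2, clump_kb = cfg.p_threshold, cfg.clump_r2, cfg.clump_kb
        f_min, q_alpha = cfg.f_min, cfg.q_alpha

    def _ivw_link(a_records, b_records):
        sel = select_instruments(
            a_records, ld=ld, p_threshold=p_threshold, r2_threshold=clump_r2, window_kb=clump_kb
        )
        _, kept = instrument_strength(sel, f_min=f_min)
        h = harmonize(kept, {"outcome": b_records})
        return ivw_estimate(wald_ratios(h), q_alpha=q_alpha)

    step1 = _ivw_link(exp_records, med_records)
    step2 = _ivw_link(med_records, out_records)
    beta0 = beta0_estimate if beta0_estimate is not None else _ivw_link(exp_records, out_records)
    return proportion_mediated(
        step1.beta, step1.se, step2.beta, step2.se, beta0.beta, beta0.se
    )


def run_three_stage(config: StudyConfig) -> StudyReport:
    """Run the full three-stage analysis described in the module docstring.

    Branches that yield zero instruments are skipped with a logged warning.
    All stochastic steps derive their seeds deterministically from
    ``config.seed``, so identical configs reproduce every number.
    """
    ld = LdMatrix.read_ld(config.ld_path) if config.ld_path else None
    tables: dict[str, object] = {}

    def _load(label, path):
        if label not in tables:
            tables[label] = read_summary_stats(path, column_map=config.column_map)
        return tables[label]

    ss = np.random.SeedSequence(config.seed)
    stage1_rows, reverse_rows, mediation_rows, mvmr_rows = [], [], [], []
    stage1_ivw: dict[tuple[str, str], tuple[MREstimate, SensitivityReport]] = {}

    # ---- stage 1: total effects + reverse MR -----------------------------
    for e_label, e_path in config.exposures.items():
        for o_label, o_path in config.outcomes.items():
            seed = spawn_int_seed(ss.spawn(1)[0])
            try:
                ua = _univariable_analysis(
                    _load(e_label, e_path), _load(o_label, o_path), config, seed, ld
                )
            except CalcmrError as exc:
                logger.warning("stage 1 %s->%s failed: %s", e_label, o_label, exc)
                ua = None
            if ua is None:
                logger.warning("stage 1 %s->%s skipped (no usable instruments)", e_label, o_label)
                continue
            stage1_rows.extend(_stage1_rows(e_label, o_label, ua, config))
            stage1_ivw[(e_label, o_label)] = (ua.estimates["IVW"], ua.sens)

            seed_r = spawn_int_seed(ss.spawn(1)[0])
            try:
                ua_r = _univariable_analysis(
                    _load(o_label, o_path), _load(e_label, e_path), config, seed_r, ld
                )
            except CalcmrError as exc:
                logger.warning("reverse MR %s->%s failed: %s", o_label, e_label, exc)
                ua_r = None
            if ua_r is None:
                logger.warning("reverse MR %s->%s skipped", o_label, e_label)
            else:
                reverse_rows.extend(_stage1_rows(o_label, e_label, ua_r, config))

    # ---- stage 2: two-step mediation -------------------------------------
    for (e_label, o_label), (beta0_est, _sens0) in stage1_ivw.items():
        if not beta0_est.pval < config.stage2_alpha:
            continue
        for m_label, m_path in config.mediators.items():
            seed = spawn_int_seed(ss.spawn(1)[0])
            try:
                ua1 = _univariable_analysis(
                    _load(e_label, config.exposures[e_label]), _load(m_label, m_path),
                    config, seed, ld,
                )
                ua2 = _univariable_analysis(
                    _load(m_label, m_path), _load(o_label, config.outcomes[o_label]),
                    config, seed + 7, ld,
                )
            except CalcmrError as exc:
                logger.warning("stage 2 %s->%s->%s failed: %s", e_label, m_label, o_label, exc)
                continue
            if ua1 is None or ua2 is None:
                logger.warning("stage 2 %s->%s->%s skipped", e_label, m_label, o_label)
                continue
            est1, est2 = ua1.estimates["IVW"], ua2.estimates["IVW"]
            eligible, reason = mediation_eligibility(
                (est1, ua1.sens), (est2, ua2.sens), alpha=config.alpha_nominal
            )
            row = {
                "exposure": e_label,
                "mediator": m_label,
                "outcome": o_label,
                "nsnp1": est1.nsnp,
                "nsnp2": est2.nsnp,
                "beta0": beta0_est.beta,
                "se0": beta0_est.se,
                "beta1": est1.beta,
                "se1": est1.se,
                "pval1": est1.pval,
                "beta2": est2.beta,
                "se2": est2.se,
                "pval2": est2.pval,
                "eligible": eligible,
                "reason": reason,
            }
            if eligible:
                med: MediationResult = proportion_mediated(
                    est1.beta, est1.se, est2.beta, est2.se, beta0_est.beta, beta0_est.se
                )
                row.update(
                    indirect=med.indirect,
                    se_indirect=med.se_indirect,
                    proportion_pct=med.proportion_pct,
                    proportion_ci_low_pct=100 * med.proportion_ci_low,
                    proportion_ci_high_pct=100 * med.proportion_ci_high,
                    proportion_p=med.proportion_p,
                )
            else:
                row.update(
                    indirect=np.nan, se_indirect=np.nan, proportion_pct=np.nan,
                    proportion_ci_low_pct=np.nan, proportion_ci_high_pct=np.nan,
                    proportion_p=np.nan,
                )
            mediation_rows.append(row)

    # ---- stage 3: multivariable adjustment -------------------------------
    for (e_label, o_label), (beta0_est, _sens0) in stage1_ivw.items():
        if not beta0_est.pval < config.stage2_alpha:
            continue
        for c_label, c_path in config.covariates.items():
            seed = spawn_int_seed(ss.spawn(1)[0])
            try:
                m = assemble_mv_instruments(
                    {e_label: _load(e_label, config.exposures[e_label]),
                     c_label: _load(c_label, c_path)},
                    _load(o_label, config.outcomes[o_label]),
                    ld=ld,
                    p_threshold=config.p_threshold,
                    r2_threshold=config.clump_r2,
                    window_kb=config.clump_kb,
                    palindrome_eaf_window=config.palindrome_eaf_window,
                )
                results = {
                    "MV-IVW": mvmr_ivw(m),
                    "MV-median": mvmr_median(m, n_boot=config.n_boot, seed=seed),
                    "MV-LASSO": mvmr_lasso(m),
                }
            except CalcmrError as exc:
                logger.warning(
                    "stage 3 %s + %s -> %s failed: %s", e_label, c_label, o_label, exc
                )
                continue
            exp_idx = m.labels.index(e_label)
            exp_pvals = [res.estimates[exp_idx].pval for res in results.values()]
            any_sig = mvmr_any_significant(exp_pvals, alpha=config.alpha_nominal)
            ivw_res = results["MV-IVW"]
            for method, res in results.items():
                est = res.estimates[exp_idx]
                mvmr_rows.append(
                    {
                        "exposure": e_label,
                        "outcome": o_label,
                        "adjustment": c_label,
                        "method": method,
                        "nsnp": est.nsnp,
                        "beta": est.beta,
                        "se": est.se,
                        "pval": est.pval,
                        "or": est.or_point,
                        "or_low": est.or_low,
                        "or_high": est.or_high,
                        "q_stat": res.q_stat,
                        "q_p": res.q_p,
                        "egger_intercept": (
                            np.nan if ivw_res.intercept is None else ivw_res.intercept
                        ),
                        "egger_intercept_p": (
                            np.nan if ivw_res.intercept_p is None else ivw_res.intercept_p
                        ),
                        "any_method_significant": any_sig,
                        "significance": classify_significance(
                            est.pval, config.alpha_nominal, config.alpha_bonferroni
                        ),
                    }
                )

    metadata = {
        "package_version": __version__,
        "seed": config.seed,
        "alpha_nominal": config.alpha_nominal,
        "alpha_bonferroni": config.alpha_bonferroni,
        "n_exposures": len(config.exposures),
        "thresholds": {
            "p_threshold": config.p_threshold,
            "clump_r2": config.clump_r2,
            "clump_kb": config.clump_kb,
            "f_min": config.f_min,
            "q_alpha": config.q_alpha,
            "palindrome_eaf_window": config.palindrome_eaf_window,
            "presso_nsim": config.presso_nsim,
            "n_boot": config.n_boot,
            "stage2_trigger": config.stage2_trigger,
        },
    }
    return StudyReport(
        stage1=pd.DataFrame(stage1_rows, columns=STAGE1_COLUMNS),
        reverse=pd.DataFrame(reverse_rows, columns=STAGE1_COLUMNS),
        mediation=pd.DataFrame(mediation_rows, columns=MEDIATION_COLUMNS),
        mvmr=pd.DataFrame(mvmr_rows, columns=MVMR_COLUMNS),
        metadata=metadata,
    )


def write_report(report: StudyReport, outdir: str | Path) -> list[Path]:
    """Write the study tables (TSV) and run metadata (YAML) to ``outdir``."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc
    paths = []
    for name, df in (
        ("stage1", report.stage1),
        ("reverse", report.reverse),
        ("mediation", report.mediation),
        ("mvmr", report.mvmr),
    ):
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths.append(p)
    meta_path = outdir / "run_metadata.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(report.metadata, fh, sort_keys=True)
    paths.append(meta_path)
    return paths
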