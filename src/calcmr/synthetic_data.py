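"""Synthetic GWAS summary-statistics generator with known causal structure.

Generates the tab-separated per-SNP association tables the pipeline consumes
- exposure, mediator, outcome, covariate - from an explicit causal model, so
every stage (instrument selection, harmonization, the four univariable
estimators, MR-PRESSO, mediation, multivariable adjustment) can be exercised
against known ground truth without downloading any real GWAS.

Model. Per SNP j: an allele frequency is drawn uniformly, the true
SNP-exposure effect gamma_j is a folded normal floored so the SNP passes
genome-wide significance at the exposure sample size (effect alleles are
oriented to the exposure-increasing allele, the usual reporting convention;
this also makes directional pleiotropy directional on the Wald-ratio scale).
Standard errors use the standard approximation 1/sqrt(2*maf*(1-maf)*N);
observed effects add normal noise at that SE, and p-values are exactly
consistent with (beta, se). SNP-outcome effects follow the causal chain:
Gamma_j = total_effect * gamma_j + alpha_j, with alpha_j a per-SNP pleiotropy
offset (zero for valid instruments). Mediation datasets add a mediator trait
delta_j = b1*gamma_j (+ mediator-specific instruments), with
Gamma_j = direct*gamma_j + b2*delta_j, so the implied total effect is
direct + b1*b2 and the true proportion mediated is b1*b2/(direct + b1*b2).

Default sample sizes mirror the study conditions: exposure N = 659,316
(62,892 cases + 596,424 controls, T2DM scale, log-odds effects with the
effective-N argument), mediator N = 400,792 (UK Biobank serum calcium),
outcome N = 28,655 (coronary artery calcification).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import InputError
from .summary_data import COLUMNS

#: z-threshold for genome-wide significance p < 5e-8 (two-sided)
Z_GWS = float(stats.norm.isf(5e-8 / 2))

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass(frozen=True)
class PleiotropySpec:
    """Fraction and distribution of invalid (pleiotropic) instruments.

    ``directional=True`` draws alpha_j ~ Normal(mean, sd); balanced
    pleiotropy gives each offset a random sign.
    """

    fraction: float = 0.0
    mean: float = 0.0
    sd: float = 0.0
    directional: bool = True

    def __post_init__(self):
        if not (0 <= self.fraction < 1):
            raise InputError("pleiotropy fraction must be in [0, 1)")


@dataclass
class SimulationSpec:
    """Conditions for one synthetic study."""

    n_snps: int = 100
    true_effect: float = 0.1
    direct_effect: Optional[float] = None
    mediator_effects: Optional[tuple[float, float]] = None  # (b1, b2)
    pleiotropy: Optional[PleiotropySpec] = None
    n_x: int = 659_316
    n_y: int = 28_655
    n_mediator: int = 400_792
    n_mediator_snps: Optional[int] = None  # defaults to n_snps
    effect_sd: float = 0.02
    mediator_effect_sd: float = 0.02
    eaf_range: tuple[float, float] = (0.05, 0.95)
    sig_margin: float = 5.0  # extra z so observed effects also pass 5e-8
    n_decoys: int = 0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.eaf_range
        if not (0 < lo < hi < 1):
            raise InputError("eaf_range must satisfy 0 < lo < hi < 1")
        if self.n_snps < 1:
            raise InputError("n_snps must be positive")
        if self.mediator_effects is not None and self.direct_effect is not None:
            b1, b2 = self.mediator_effects
            implied = self.direct_effect + b1 * b2
            if abs(implied - self.true_effect) > 1e-9:
                raise InputError(
                    f"inconsistent spec: direct + b1*b2 = {implied} != "
                    f"true_effect = {self.true_effect}"
                )

    @property
    def resolved_direct_effect(self) -> float:
        if self.mediator_effects is None:
            return self.true_effect
        if self.direct_effect is not None:
            return self.direct_effect
        b1, b2 = self.mediator_effects
        return self.true_effect - b1 * b2


@dataclass
class SimulationTruth:
    """Ground truth accompanying a generated dataset."""

    snp_ids: list[str]
    gamma: dict[str, np.ndarray]  # per-trait true SNP effects
    beta0: float
    beta1: Optional[float] = None
    beta2: Optional[float] = None
    direct: Optional[float] = None
    proportion: Optional[float] = None
    invalid_snps: list[str] = field(default_factory=list)
    effect_vector: Optional[np.ndarray] = None


def _positions(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome/position layout keeping same-chromosome SNPs >= 20 Mb apart."""
    idx = np.arange(n)
    chrom = (idx % 22 + 1).astype(str)
    pos = 1_000_000 + (idx // 22) * 20_000_000
    return chrom, pos


def _se_approx(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _table(snp_ids, chrom, pos, ea, oa, eaf, beta_hat, se, n) -> pd.DataFrame:
    pval = 2.0 * stats.norm.sf(np.abs(beta_hat / se))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta_hat,
            "se": se,
            "pval": pval,
            "n": n,
        },
        columns=COLUMNS,
    )


def _base_variants(spec: SimulationSpec, rng: np.random.Generator, n: int, offset: int = 0):
    snp_ids = [f"rs{offset + j + 1}" for j in range(n)]
    chrom, pos = _positions(n + offset)
    chrom, pos = chrom[offset:], pos[offset:]
    lo, hi = spec.eaf_range
    eaf = rng.uniform(lo, hi, n)
    maf = np.minimum(eaf, 1 - eaf)
    pairs = rng.integers(0, len(_ALLELE_PAIRS), n)
    ea = np.array([_ALLELE_PAIRS[p][0] for p in pairs])
    oa = np.array([_ALLELE_PAIRS[p][1] for p in pairs])
    return snp_ids, chrom, pos, ea, oa, eaf, maf


def _instrument_effects(
    rng: np.random.Generator, n: int, sd: float, se: np.ndarray, margin: float
) -> np.ndarray:
    """Folded-normal effects floored so instruments pass genome-wide significance."""
    raw = np.abs(rng.normal(0.0, sd, n))
    return np.maximum(raw, (Z_GWS + margin) * se)


def simulate_univariable_dataset(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Exposure and outcome tables for a single causal effect (plus pleiotropy).

    Returns (exposure table, outcome table, truth); tables are canonical
    summary-statistics DataFrames (see :data:`calcmr.summary_data.COLUMNS`).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_snps + spec.n_decoys
    snp_ids, chrom, pos, ea, oa, eaf, maf = _base_variants(spec, rng, n)
    se_x = _se_approx(maf, spec.n_x)
    gamma = _instrument_effects(rng, n, spec.effect_sd, se_x, spec.sig_margin)
    if spec.n_decoys:
        # sub-threshold decoys: true z-score about 1
        gamma[spec.n_snps :] = se_x[spec.n_snps :]
    gamma_hat = gamma + rng.normal(0.0, se_x)

    alpha = np.zeros(n)
    invalid: list[str] = []
    if spec.pleiotropy is not None and spec.pleiotropy.fraction > 0:
        k = int(round(spec.pleiotropy.fraction * spec.n_snps))
        idx = rng.choice(spec.n_snps, size=k, replace=False)
        offsets = rng.normal(spec.pleiotropy.mean, spec.pleiotropy.sd, k)
        if not spec.pleiotropy.directional:
            offsets *= rng.choice([-1.0, 1.0], k)
        alpha[idx] = offsets
        invalid = [snp_ids[i] for i in sorted(idx)]

    se_y = _se_approx(maf, spec.n_y)
    Gamma = spec.true_effect * gamma + alpha
    Gamma_hat = Gamma + rng.normal(0.0, se_y)

    exp_df = _table(snp_ids, chrom, pos, ea, oa, eaf, gamma_hat, se_x, spec.n_x)
    out_df = _table(snp_ids, chrom, pos, ea, oa, eaf, Gamma_hat, se_y, spec.n_y)
    truth = SimulationTruth(
        snp_ids=list(snp_ids),
        gamma={"exposure": gamma, "outcome": Gamma},
        beta0=spec.true_effect,
        invalid_snps=invalid,
    )
    return exp_df, out_df, truth


def simulate_mediation_dataset(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Exposure, mediator, and outcome tables for an exposure->mediator->outcome chain.

    The exposure's instruments influence the mediator through b1 and the
    outcome through both the direct path and b1*b2; a second block of
    mediator-specific instruments (null for the exposure) identifies b2.
    """
    if spec.mediator_effects is None:
        raise InputError("simulate_mediation_dataset requires mediator_effects=(b1, b2)")
    b1, b2 = spec.mediator_effects
    direct = spec.resolved_direct_effect
    beta0 = direct + b1 * b2

    rng = np.random.default_rng(spec.seed)
    n_x_snps = spec.n_snps
    n_m_snps = spec.n_mediator_snps if spec.n_mediator_snps is not None else spec.n_snps
    n = n_x_snps + n_m_snps
    snp_ids, chrom, pos, ea, oa, eaf, maf = _base_variants(spec, rng, n)
    se_x = _se_approx(maf, spec.n_x)
    se_m = _se_approx(maf, spec.n_mediator)
    se_y = _se_approx(maf, spec.n_y)

    gamma = np.zeros(n)
    gamma[:n_x_snps] = _instrument_effects(
        rng, n_x_snps, spec.effect_sd, se_x[:n_x_snps], spec.sig_margin
    )
    delta = b1 * gamma
    delta[n_x_snps:] = _instrument_effects(
        rng, n_m_snps, spec.mediator_effect_sd, se_m[n_x_snps:], spec.sig_margin
    )
    Gamma = direct * gamma + b2 * delta

    gamma_hat = gamma + rng.normal(0.0, se_x)
    delta_hat = delta + rng.normal(0.0, se_m)
    Gamma_hat = Gamma + rng.normal(0.0, se_y)

    exp_df = _table(snp_ids, chrom, pos, ea, oa, eaf, gamma_hat, se_x, spec.n_x)
    med_df = _table(snp_ids, chrom, pos, ea, oa, eaf, delta_hat, se_m, spec.n_mediator)
    out_df = _table(snp_ids, chrom, pos, ea, oa, eaf, Gamma_hat, se_y, spec.n_y)
    truth = SimulationTruth(
        snp_ids=list(snp_ids),
        gamma={"exposure": gamma, "mediator": delta, "outcome": Gamma},
        beta0=beta0,
        beta1=b1,
        beta2=b2,
        direct=direct,
        proportion=b1 * b2 / beta0,
    )
    return exp_df, med_df, out_df, truth


def simulate_mv_dataset(
    spec: SimulationSpec,
    k: int = 2,
    effect_vector: Sequence[float] = (0.25, 0.0),
    exposure_correlation: float = 0.5,
) -> tuple[list[pd.DataFrame], pd.DataFrame, SimulationTruth]:
    """k correlated exposure tables plus an outcome from their linear combination.

    SNP effects on the k exposures are multivariate normal with pairwise
    correlation ``exposure_correlation``; each SNP is rescaled, if needed, so
    it reaches genome-wide significance for at least one exposure.
    """
    if k < 2:
        raise InputError("simulate_mv_dataset needs k >= 2 exposures")
    effect_vector = np.asarray(effect_vector, dtype=float)
    if len(effect_vector) != k:
        raise InputError("effect_vector length must equal k")
    if not abs(exposure_correlation) < 1:
        raise InputError("|exposure_correlation| must be < 1")
    R = np.full((k, k), exposure_correlation)
    np.fill_diagonal(R, 1.0)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise InputError("implied exposure covariance not positive definite") from exc

    rng = np.random.default_rng(spec.seed)
    n = spec.n_snps
    snp_ids, chrom, pos, ea, oa, eaf, maf = _base_variants(spec, rng, n)
    se_x = _se_approx(maf, spec.n_x)

    B = rng.standard_normal((n, k)) @ L.T * spec.effect_sd
    # orient to the allele increasing the first exposure, then rescale rows
    # whose strongest association would miss genome-wide significance
    flip = np.where(B[:, 0] < 0, -1.0, 1.0)
    B *= flip[:, None]
    zmax = np.max(np.abs(B), axis=1) / se_x
    need = (Z_GWS + spec.sig_margin) / np.maximum(zmax, 1e-12)
    B *= np.maximum(need, 1.0)[:, None]

    se_y = _se_approx(maf, spec.n_y)
    Gamma = B @ effect_vector
    if spec.pleiotropy is not None and spec.pleiotropy.fraction > 0:
        kk = int(round(spec.pleiotropy.fraction * n))
        idx = rng.choice(n, size=kk, replace=False)
        offs = rng.normal(spec.pleiotropy.mean, spec.pleiotropy.sd, kk)
        if not spec.pleiotropy.directional:
            offs *= rng.choice([-1.0, 1.0], kk)
        Gamma = Gamma.copy()
        Gamma[idx] += offs

    exposure_tables = []
    B_hat = B + rng.normal(0.0, 1.0, size=(n, k)) * se_x[:, None]
    for j in range(k):
        exposure_tables.append(
            _table(snp_ids, chrom, pos, ea, oa, eaf, B_hat[:, j], se_x, spec.n_x)
        )
    Gamma_hat = Gamma + rng.normal(0.0, se_y)
    out_df = _table(snp_ids, chrom, pos, ea, oa, eaf, Gamma_hat, se_y, spec.n_y)

    truth = SimulationTruth(
        snp_ids=list(snp_ids),
        gamma={f"exposure{j + 1}": B[:, j] for j in range(k)} | {"outcome": Gamma},
        beta0=float(effect_vector[0]),
        effect_vector=effect_vector,
    )
    return exposure_tables, out_df, truth


def simulate_study_dataset(
    spec: SimulationSpec,
    covariate_outcome_effect: float = 0.2,
    covariate_loading: float = 0.3,
) -> tuple[dict[str, pd.DataFrame], SimulationTruth]:
    """One coherent four-trait study: exposure, mediator, covariate, outcome.

    Four instrument blocks of ``n_snps`` SNPs each: exposure instruments
    (affecting the mediator through b1, the covariate through
    ``covariate_loading``, and the outcome through the direct path),
    mediator-specific, covariate-specific, and outcome-specific instruments
    (the last make reverse MR estimable). The outcome is
    direct*gamma + b2*mediator + covariate_outcome_effect*covariate (+ its
    own instrument effects), so the exposure's total effect is
    direct + b1*b2 + covariate_outcome_effect*covariate_loading.

    Every trait table reports all SNPs, as real GWAS do.
    """
    if spec.mediator_effects is None:
        raise InputError("simulate_study_dataset requires mediator_effects=(b1, b2)")
    b1, b2 = spec.mediator_effects
    direct = spec.resolved_direct_effect

    rng = np.random.default_rng(spec.seed)
    nb = spec.n_snps
    n = 4 * nb
    blocks = {"x": slice(0, nb), "m": slice(nb, 2 * nb), "c": slice(2 * nb, 3 * nb),
              "o": slice(3 * nb, 4 * nb)}
    snp_ids, chrom, pos, ea, oa, eaf, maf = _base_variants(spec, rng, n)
    se_x = _se_approx(maf, spec.n_x)
    se_m = _se_approx(maf, spec.n_mediator)
    se_c = _se_approx(maf, spec.n_x)
    se_y = _se_approx(maf, spec.n_y)

    gamma = np.zeros(n)
    gamma[blocks["x"]] = _instrument_effects(
        rng, nb, spec.effect_sd, se_x[blocks["x"]], spec.sig_margin
    )
    mediator = b1 * gamma
    mediator[blocks["m"]] = _instrument_effects(
        rng, nb, spec.mediator_effect_sd, se_m[blocks["m"]], spec.sig_margin
    )
    covariate = covariate_loading * gamma
    covariate[blocks["c"]] = _instrument_effects(
        rng, nb, spec.effect_sd, se_c[blocks["c"]], spec.sig_margin
    )
    outcome = direct * gamma + b2 * mediator + covariate_outcome_effect * covariate
    outcome[blocks["o"]] += _instrument_effects(
        rng, nb, spec.effect_sd, se_y[blocks["o"]], spec.sig_margin
    )

    tables = {
        "exposure": _table(snp_ids, chrom, pos, ea, oa, eaf,
                           gamma + rng.normal(0.0, se_x), se_x, spec.n_x),
        "mediator": _table(snp_ids, chrom, pos, ea, oa, eaf,
                           mediator + rng.normal(0.0, se_m), se_m, spec.n_mediator),
        "covariate": _table(snp_ids, chrom, pos, ea, oa, eaf,
                            covariate + rng.normal(0.0, se_c), se_c, spec.n_x),
        "outcome": _table(snp_ids, chrom, pos, ea, oa, eaf,
                          outcome + rng.normal(0.0, se_y), se_y, spec.n_y),
    }
    beta0 = direct + b1 * b2 + covariate_outcome_effect * covariate_loading
    truth = SimulationTruth(
        snp_ids=list(snp_ids),
        gamma={"exposure": gamma, "mediator": mediator, "covariate": covariate,
               "outcome": outcome},
        beta0=beta0,
        beta1=b1,
        beta2=b2,
        direct=direct,
        proportion=b1 * b2 / beta0,
    )
    return tables, truth


def write_tables(tables: dict[str, pd.DataFrame], outdir) -> dict[str, str]:
    """Write generated tables as TSVs; returns {label: path}."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for label, df in tables.items():
        p = outdir / f"{label}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[label] = str(p)
    return paths


def spec_to_dict(spec: SimulationSpec) -> dict:
    return dataclasses.asdict(spec)
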