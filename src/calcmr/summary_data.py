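"""Reading, validation, and allele harmonization of GWAS summary statistics.

Two-sample MR combines per-SNP effect estimates taken from different GWAS.
Before any estimator runs, every trait's effect for a given SNP must refer to
the same effect allele; tables from different consortia disagree in allele
order and sometimes in strand convention, so harmonization swaps and
strand-flips alleles, negating betas and reflecting allele frequencies as
needed, and drops SNPs whose orientation cannot be resolved (ambiguous
palindromic variants, irreconcilable allele pairs).
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import ConfigError, InputError

logger = logging.getLogger(__name__)

#: canonical column order for summary-statistics tables
COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_REQUIRED = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pval"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_PALINDROMIC_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True, slots=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds for
    binary traits), ``eaf`` its frequency (may be NaN when the source GWAS
    did not report it).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    def problems(self) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        out = []
        if self.effect_allele not in _COMPLEMENT:
            out.append(f"effect_allele {self.effect_allele!r} not in A/C/G/T")
        if self.other_allele not in _COMPLEMENT:
            out.append(f"other_allele {self.other_allele!r} not in A/C/G/T")
        if self.effect_allele == self.other_allele:
            out.append("effect_allele == other_allele")
        if not np.isfinite(self.beta):
            out.append("beta not finite")
        if not (np.isfinite(self.se) and self.se > 0):
            out.append("se must be > 0")
        if not (0 < self.pval <= 1):
            out.append("pval outside (0, 1]")
        if np.isfinite(self.eaf) and not (0 < self.eaf < 1):
            out.append("eaf outside (0, 1)")
        if np.isfinite(self.n) and self.n <= 0:
            out.append("n must be positive")
        if np.isfinite(self.pos) and self.pos < 1:
            out.append("pos must be >= 1 (1-based)")
        return out

    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in _PALINDROMIC_PAIRS


def records_to_frame(records: Sequence[SummaryStatRecord] | pd.DataFrame) -> pd.DataFrame:
    """Coerce a record sequence (or an already-canonical frame) to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in _REQUIRED if c not in records.columns]
        if missing:
            raise ConfigError(f"summary-statistics frame lacks columns: {missing}")
        df = records.copy()
        for col in COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[COLUMNS].reset_index(drop=True)
    else:
        df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=COLUMNS)
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    return df


def frame_to_records(df: pd.DataFrame) -> list[SummaryStatRecord]:
    return [
        SummaryStatRecord(
            snp_id=str(row.snp_id),
            chrom=str(row.chrom),
            pos=int(row.pos) if np.isfinite(float(row.pos)) else -1,
            effect_allele=str(row.effect_allele),
            other_allele=str(row.other_allele),
            eaf=float(row.eaf),
            beta=float(row.beta),
            se=float(row.se),
            pval=float(row.pval),
            n=float(row.n),
        )
        for row in df.itertuples()
    ]


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SummaryStatRecord]:
    """Read a tab-separated GWAS summary-statistics table.

    Parameters
    ----------
    path
        TSV file with a header row; gzip-compressed input is accepted.
    column_map
        Mapping from canonical names (see :data:`COLUMNS`) to the file's
        column names, for sources with non-standard headers.

    Rows violating type/range invariants are dropped with a logged count;
    duplicated ``snp_id`` keeps the lowest-p row. A >10% discrepancy between
    |beta/se| and the z-score implied by ``pval`` is logged as a warning
    (real GWAS round both), never treated as an error.
    """
    df = pd.read_csv(path, sep="\t", compression="infer", dtype={"chrom": str})
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise ConfigError(f"{path}: mapped columns not in file: {missing}")
        df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: required columns missing: {missing}")
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[COLUMNS].copy()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    valid = (
        df["effect_allele"].isin(list(_COMPLEMENT))
        & df["other_allele"].isin(list(_COMPLEMENT))
        & (df["effect_allele"] != df["other_allele"])
        & np.isfinite(df["beta"])
        & (df["se"] > 0)
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & (df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)))
        & (df["n"].isna() | (df["n"] > 0))
        & (df["pos"].isna() | (df["pos"] >= 1))
    )
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("%s: dropped %d invalid row(s)", path, n_dropped)
    df = df[valid]

    dups = df["snp_id"].duplicated(keep=False)
    if dups.any():
        logger.warning(
            "%s: %d duplicated snp_id row(s); keeping lowest p per SNP",
            path,
            int(dups.sum()),
        )
        df = df.sort_values(["pval", "snp_id"], kind="mergesort").drop_duplicates(
            "snp_id", keep="first"
        )
    if df.empty:
        raise InputError(f"{path}: no valid rows after validation")

    with np.errstate(divide="ignore"):
        z_obs = np.abs(df["beta"] / df["se"])
        z_imp = stats.norm.isf(np.clip(df["pval"], 1e-300, 1.0) / 2)
    mask = (z_imp > 0) & (np.abs(z_obs - z_imp) > 0.1 * np.maximum(z_imp, 1e-12))
    if bool(np.any(mask)):
        logger.warning(
            "%s: %d row(s) with >10%% beta/se vs pval z-score discrepancy",
            path,
            int(np.sum(mask)),
        )
    df = df.sort_values(["chrom", "pos", "snp_id"], kind="mergesort")
    return frame_to_records(df.reset_index(drop=True))


@dataclass
class HarmonizedInstrumentSet:
    """Per-SNP effects of several traits aligned to one effect allele.

    ``table`` holds one row per retained SNP with columns ``snp_id``,
    ``chrom``, ``pos``, ``effect_allele``, ``other_allele`` and, for the
    exposure and every other trait label, suffixed groups
    ``beta.<label>``, ``se.<label>``, ``eaf.<label>``, ``pval.<label>``,
    ``n.<label>``. The exposure label is ``"exposure"``.
    """

    table: pd.DataFrame
    labels: list[str]
    provenance: list[str] = dataclasses.field(default_factory=list)

    # -- accessors ---------------------------------------------------------
    @property
    def nsnp(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    def beta(self, label: str) -> np.ndarray:
        return self.table[f"beta.{label}"].to_numpy(dtype=float)

    def se(self, label: str) -> np.ndarray:
        return self.table[f"se.{label}"].to_numpy(dtype=float)

    @property
    def gamma(self) -> np.ndarray:
        """SNP-exposure effects γ_j."""
        return self.beta("exposure")

    @property
    def se_gamma(self) -> np.ndarray:
        return self.se("exposure")

    @property
    def _outcome_label(self) -> str:
        return "outcome" if "outcome" in self.labels else self.labels[0]

    @property
    def Gamma(self) -> np.ndarray:
        """SNP-outcome effects Γ_j."""
        return self.beta(self._outcome_label)

    @property
    def se_Gamma(self) -> np.ndarray:
        return self.se(self._outcome_label)

    def subset(self, mask: np.ndarray) -> "HarmonizedInstrumentSet":
        return HarmonizedInstrumentSet(
            table=self.table[mask].reset_index(drop=True),
            labels=list(self.labels),
            provenance=list(self.provenance),
        )

    def records(self, label: str) -> list[SummaryStatRecord]:
        """Re-export one trait as summary-statistic records (exposure orientation)."""
        df = pd.DataFrame(
            {
                "snp_id": self.table["snp_id"],
                "chrom": self.table["chrom"],
                "pos": self.table["pos"],
                "effect_allele": self.table["effect_allele"],
                "other_allele": self.table["other_allele"],
                "eaf": self.table[f"eaf.{label}"],
                "beta": self.table[f"beta.{label}"],
                "se": self.table[f"se.{label}"],
                "pval": self.table[f"pval.{label}"],
                "n": self.table[f"n.{label}"],
            }
        )
        return frame_to_records(df)

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HarmonizedInstrumentSet":
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str})
        labels = [
            c.split(".", 1)[1]
            for c in table.columns
            if c.startswith("beta.") and c != "beta.exposure"
        ]
        return cls(table=table, labels=labels)


def _orientation_masks(ea, oa, ea_ref, oa_ref):
    """Boolean masks for the four reconcilable allele configurations."""
    c_ea = ea.map(_COMPLEMENT)
    c_oa = oa.map(_COMPLEMENT)
    same = (ea == ea_ref) & (oa == oa_ref)
    swap = (ea == oa_ref) & (oa == ea_ref)
    flip = (c_ea == ea_ref) & (c_oa == oa_ref)
    flip_swap = (c_ea == oa_ref) & (c_oa == ea_ref)
    return same, swap, flip, flip_swap


def harmonize(
    exposure: Sequence[SummaryStatRecord] | pd.DataFrame,
    others: Mapping[str, Sequence[SummaryStatRecord] | pd.DataFrame]
    | Sequence[SummaryStatRecord]
    | pd.DataFrame,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedInstrumentSet:
    """Align one or more trait tables to the exposure's effect alleles.

    Only SNPs present in every input are considered. Per SNP and trait:
    alleles identical to the exposure are kept as-is; swapped alleles negate
    the beta and reflect the allele frequency; complement-base (strand-flip)
    configurations are reconciled the same way; anything else is dropped.
    Palindromic (A/T, C/G) SNPs are oriented by allele frequency and dropped
    as ambiguous when any trait's minor-allele frequency lies within
    ``palindrome_eaf_window`` of 0.5, or when any frequency is missing.
    """
    if isinstance(others, (pd.DataFrame,)) or (
        not isinstance(others, Mapping)
    ):
        others = {"outcome": others}
    exp = records_to_frame(exposure)
    exp.index = pd.Index(exp["snp_id"], name="snp")
    if exp.index.duplicated().any():
        raise InputError("exposure table contains duplicated snp_id")

    provenance: list[str] = []
    common = exp.index
    frames = {}
    for label, recs in others.items():
        odf = records_to_frame(recs)
        odf.index = pd.Index(odf["snp_id"], name="snp")
        if odf.index.duplicated().any():
            raise InputError(f"{label} table contains duplicated snp_id")
        frames[label] = odf
        common = common.intersection(odf.index)
    if len(common) == 0:
        raise InputError("no SNPs shared by all input tables")
    # deterministic order: genomic
    exp = exp.loc[common].sort_values(["chrom", "pos", "snp_id"], kind="mergesort")
    common = exp.index

    ea_ref = exp["effect_allele"]
    oa_ref = exp["other_allele"]
    palindromic = pd.Series(
        [frozenset(p) in _PALINDROMIC_PAIRS for p in zip(ea_ref, oa_ref)],
        index=common,
    )

    def _ambiguous_maf(eaf: pd.Series) -> pd.Series:
        maf = np.minimum(eaf, 1 - eaf)
        return (0.5 - maf) <= palindrome_eaf_window

    drop = pd.Series(False, index=common)
    # exposure-side palindromic ambiguity
    amb = palindromic & exp["eaf"].notna() & _ambiguous_maf(exp["eaf"])
    no_eaf = palindromic & exp["eaf"].isna()
    for snp in common[amb]:
        provenance.append(f"{snp}: dropped (palindromic-ambiguous; trait=exposure)")
    for snp in common[no_eaf]:
        provenance.append(f"{snp}: dropped (palindromic-missing-eaf; trait=exposure)")
    drop |= amb | no_eaf

    out_cols = {
        "snp_id": exp["snp_id"],
        "chrom": exp["chrom"],
        "pos": exp["pos"],
        "effect_allele": ea_ref,
        "other_allele": oa_ref,
        "beta.exposure": exp["beta"],
        "se.exposure": exp["se"],
        "eaf.exposure": exp["eaf"],
        "pval.exposure": exp["pval"],
        "n.exposure": exp["n"],
    }

    for label, odf in frames.items():
        odf = odf.loc[common]
        same, swap, flip, flip_swap = _orientation_masks(
            odf["effect_allele"], odf["other_allele"], ea_ref, oa_ref
        )
        beta = odf["beta"].copy()
        eaf = odf["eaf"].copy()

        keep_as_is = same | flip
        negate = (swap | flip_swap) & ~keep_as_is
        irreconcilable = ~(keep_as_is | negate)

        # Palindromic SNPs: allele labels cannot distinguish strand flip from
        # swap; orient by which side of 0.5 the frequency falls on.
        pal = palindromic & ~irreconcilable
        pal_missing = pal & (eaf.isna() | exp["eaf"].isna())
        pal_known = pal & ~pal_missing
        pal_amb = pal_known & _ambiguous_maf(eaf)
        pal_ok = pal_known & ~pal_amb & ~(
            palindromic & exp["eaf"].notna() & _ambiguous_maf(exp["eaf"])
        )
        freq_mismatch = pal_ok & ((eaf < 0.5) != (exp["eaf"] < 0.5))
        negate = (negate & ~pal) | freq_mismatch

        beta = beta.where(~negate, -beta)
        eaf = eaf.where(~negate, 1 - eaf)

        for snp in common[irreconcilable]:
            provenance.append(f"{snp}: dropped (incompatible-alleles; trait={label})")
        for snp in common[pal_missing]:
            provenance.append(f"{snp}: dropped (palindromic-missing-eaf; trait={label})")
        for snp in common[pal_amb]:
            provenance.append(f"{snp}: dropped (palindromic-ambiguous; trait={label})")
        for snp in common[negate]:
            provenance.append(f"{snp}: {label} beta negated (aligned to exposure allele)")
        drop |= irreconcilable | pal_missing | pal_amb

        out_cols[f"beta.{label}"] = beta
        out_cols[f"se.{label}"] = odf["se"]
        out_cols[f"eaf.{label}"] = eaf
        out_cols[f"pval.{label}"] = odf["pval"]
        out_cols[f"n.{label}"] = odf["n"]

    table = pd.DataFrame(out_cols, index=common)
    table = table[~drop].reset_index(drop=True)
    if drop.any():
        logger.info("harmonize: dropped %d SNP(s)", int(drop.sum()))
    return HarmonizedInstrumentSet(
        table=table, labels=list(frames), provenance=provenance
    )
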