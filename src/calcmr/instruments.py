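"""Instrument selection: significance filtering, LD clumping, strength checks.

Instrumental variables are SNPs robustly associated with the exposure
(p < 5e-8), approximately independent of each other (pairwise r-squared below
0.001 within a 10,000 kb window, greedy clumping in ascending-p order), and
strong enough to avoid weak-instrument bias: variance explained
r2 = 2*MAF*(1-MAF)*beta^2 and F = r2*(N-2)/(1-r2), keeping SNPs with F
strictly greater than 10.
"""

from __future__ import annotations

import bisect
import logging
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import InputError
from .summary_data import SummaryStatRecord, frame_to_records, records_to_frame

logger = logging.getLogger(__name__)


class LdMatrix:
    """Pairwise r-squared lookups between SNPs.

    Stores a sparse mapping; pairs absent from the table are treated as
    independent (r2 = 0). The diagonal is implicitly 1.
    """

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        for (a, b), v in (pairs or {}).items():
            self.set(a, b, v)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0 <= r2 <= 1):
            raise InputError(f"r2 for ({a}, {b}) outside [0, 1]: {r2}")
        if a != b:
            self._r2[self._key(a, b)] = float(r2)

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def read_ld(cls, path: str | Path) -> "LdMatrix":
        """Read either the 3-column long form (snp_a, snp_b, r2) or a square
        matrix with SNP ids as header row and first column."""
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] == 3 and not np.issubdtype(df.dtypes.iloc[1], np.number):
            out = cls()
            for a, b, r2 in df.itertuples(index=False):
                out.set(str(a), str(b), float(r2))
            return out
        # square form: first column holds ids
        ids = df.iloc[:, 0].astype(str).tolist()
        mat = df.iloc[:, 1:].to_numpy(dtype=float)
        if mat.shape[0] != mat.shape[1] or list(df.columns[1:]) != ids:
            raise InputError(f"{path}: square LD matrix ids mismatch")
        if not np.allclose(mat, mat.T, atol=1e-12):
            raise InputError(f"{path}: LD matrix not symmetric")
        if not np.allclose(np.diag(mat), 1.0, atol=1e-12):
            raise InputError(f"{path}: LD matrix diagonal != 1")
        out = cls()
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                if mat[i, j] != 0:
                    out.set(a, ids[j], mat[i, j])
        return out


@dataclass(frozen=True, slots=True)
class InstrumentStrength:
    """Instrument-strength summary for one SNP."""

    snp_id: str
    maf: float
    beta: float
    n: float
    r2: float
    f_stat: float


def select_instruments(
    records: Sequence[SummaryStatRecord] | pd.DataFrame,
    ld: LdMatrix | None = None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> list[SummaryStatRecord] | pd.DataFrame:
    """Greedy p-value clumping of genome-wide-significant SNPs.

    SNPs with ``pval < p_threshold`` are visited in ascending p (ties broken
    by chrom, pos, snp_id so the result is independent of input row order).
    A candidate is rejected when it lies within ``window_kb`` of an already
    kept SNP on the same chromosome and their r2 is at least ``r2_threshold``;
    with no LD information the distance criterion alone rejects.

    Returns the same container type as the input (records in genomic order).
    """
    as_frame = isinstance(records, pd.DataFrame)
    df = records_to_frame(records)
    df = df[df["pval"] < p_threshold]
    if df.empty:
        logger.info("select_instruments: no SNP passes p < %g", p_threshold)
        empty = df.reset_index(drop=True)
        return empty if as_frame else []
    if df["pos"].isna().any() or df["chrom"].isna().any():
        bad = df.loc[df["pos"].isna() | df["chrom"].isna(), "snp_id"].tolist()
        raise InputError(f"clumping requires chrom/pos; missing for {bad[:5]}")

    df = df.sort_values(["pval", "chrom", "pos", "snp_id"], kind="mergesort")
    window = window_kb * 1000
    kept_pos: dict[str, list[int]] = {}
    kept_ids: dict[str, list[str]] = {}
    keep_idx = []
    for row in df.itertuples():
        chrom, pos = str(row.chrom), int(row.pos)
        positions = kept_pos.setdefault(chrom, [])
        ids = kept_ids.setdefault(chrom, [])
        lo = bisect.bisect_left(positions, pos - window)
        hi = bisect.bisect_right(positions, pos + window)
        rejected = False
        for k in range(lo, hi):
            if ld is None or ld.get(row.snp_id, ids[k]) >= r2_threshold:
                rejected = True
                break
        if rejected:
            continue
        at = bisect.bisect_left(positions, pos)
        positions.insert(at, pos)
        ids.insert(at, row.snp_id)
        keep_idx.append(row.Index)
    out = (
        df.loc[keep_idx]
        .sort_values(["chrom", "pos", "snp_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out if as_frame else frame_to_records(out)


def variance_explained(maf: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """r2 = 2*MAF*(1-MAF)*beta^2."""
    return 2.0 * maf * (1.0 - maf) * np.square(beta)


def f_statistic(r2: np.ndarray, n: np.ndarray) -> np.ndarray:
    """F = r2*(N-2)/(1-r2)."""
    return r2 * (n - 2.0) / (1.0 - r2)


def instrument_strength(
    records: Sequence[SummaryStatRecord] | pd.DataFrame,
    f_min: float = 10.0,
) -> tuple[list[InstrumentStrength], list[SummaryStatRecord] | pd.DataFrame]:
    """Per-SNP variance explained and F-statistic; retain SNPs with F > f_min.

    Strict inequality: an instrument with F exactly ``f_min`` is removed.
    """
    as_frame = isinstance(records, pd.DataFrame)
    df = records_to_frame(records)
    missing = df.loc[df["eaf"].isna() | df["n"].isna(), "snp_id"].tolist()
    if missing:
        raise InputError(
            f"instrument_strength requires eaf and n; missing for {missing[:5]}"
        )
    maf = np.minimum(df["eaf"].to_numpy(), 1 - df["eaf"].to_numpy())
    r2 = variance_explained(maf, df["beta"].to_numpy())
    f = f_statistic(r2, df["n"].to_numpy())
    strengths = [
        InstrumentStrength(
            snp_id=str(s), maf=float(m), beta=float(b), n=float(nn), r2=float(rr), f_stat=float(ff)
        )
        for s, m, b, nn, rr, ff in zip(
            df["snp_id"], maf, df["beta"], df["n"], r2, f
        )
    ]
    keep = f > f_min
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("instrument_strength: removed %d weak instrument(s)", n_removed)
    retained = df[keep].reset_index(drop=True)
    return strengths, (retained if as_frame else frame_to_records(retained))
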