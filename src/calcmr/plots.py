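"""Optional diagnostic plots (scatter and leave-one-out forest).

All quantitative content lives in the TSV report tables; these figures are
visual aids only and are never produced by default.
"""

from __future__ import annotations

from collections.abc import Mapping
from pathlib import Path

import pandas as pd

from .mr_core import MREstimate
from .summary_data import HarmonizedInstrumentSet


def scatter_plot(
    h: HarmonizedInstrumentSet,
    estimates: Mapping[str, MREstimate],
    path: str | Path | None = None,
):
    """SNP-outcome vs SNP-exposure effects with one fitted line per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        h.gamma, h.Gamma, xerr=h.se_gamma, yerr=h.se_Gamma,
        fmt="o", ms=3, lw=0.6, color="0.4", zorder=1,
    )
    xs = [0, float(max(abs(h.gamma)) * 1.05)]
    for label, est in estimates.items():
        ax.plot(xs, [est.beta * x for x in xs], label=label, lw=1.2)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def loo_plot(loo_table: pd.DataFrame, path: str | Path | None = None):
    """Forest plot of the leave-one-out IVW estimates."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 0.18 * len(loo_table) + 1))
    y = range(len(loo_table))
    ax.errorbar(
        loo_table["beta"], list(y), xerr=1.96 * loo_table["se"],
        fmt="o", ms=3, lw=0.8, color="0.2",
    )
    ax.set_yticks(list(y))
    ax.set_yticklabels(loo_table["snp_id"], fontsize=6)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel("IVW estimate without this SNP")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
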