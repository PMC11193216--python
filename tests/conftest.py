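import numpy as np
import pytest

from calcmr.summary_data import SummaryStatRecord


def make_record(
    snp_id="rs1",
    chrom="1",
    pos=1_000_000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pval=1e-9,
    n=100_000,
) -> SummaryStatRecord:
    return SummaryStatRecord(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def write_tsv(path, rows, header=None):
    """Write a list of dict rows as a TSV file."""
    import pandas as pd

    df = pd.DataFrame(rows)
    if header is not None:
        df = df[header]
    df.to_csv(path, sep="\t", index=False)
    return path
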