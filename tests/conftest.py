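import numpy as np
import pandas as pd
import pytest

from cellmr.sumstats import LDMatrix


def make_gwas(
    snps, chrom="1", pos=None, beta=None, se=0.01, p=None, eaf=0.3, n=100_000.0,
    ea="A", oa="G",
) -> pd.DataFrame:
    k = len(snps)
    pos = pos if pos is not None else np.arange(1, k + 1) * 1000
    beta = beta if beta is not None else np.full(k, 0.05)
    df = pd.DataFrame(
        {
            "snp": snps,
            "chr": chrom,
            "pos": pos,
            "ea": ea,
            "oa": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "p": p if p is not None else np.full(k, 1e-10),
            "n": n,
        }
    )
    return df


@pytest.fixture
def identity_ld():
    def _make(snps):
        return LDMatrix(list(snps), np.eye(len(snps)))

    return _make


@pytest.fixture
def toy_instruments():
    """Three homogeneous instruments with ratio exactly 0.5."""
    return pd.DataFrame(
        {
            "snp": ["rs1", "rs2", "rs3"],
            "ea": "A",
            "oa": "G",
            "eaf_exp": 0.3,
            "beta_exp": [0.1, 0.2, 0.15],
            "se_exp": 0.005,
            "p_exp": 1e-20,
            "eaf_out": 0.3,
            "beta_out": [0.05, 0.10, 0.075],
            "se_out": [0.01, 0.02, 0.015],
            "context": "cellA",
            "provenance": "original",
        }
    )
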