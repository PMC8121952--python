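import numpy as np
import pandas as pd
import pytest

from rssnet.datatypes import (GeneCatalog, GwasSummary, LDMatrix,
                              RegulatoryNetwork, SnpTable)


@pytest.fixture
def toy_genes():
    """Five genes on two chromosomes, one a TF."""
    return GeneCatalog(pd.DataFrame({
        "gene_id": ["gA", "gB", "gC", "gD", "gE"],
        "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
        "tx_start": [100_000, 600_000, 2_500_000, 50_000, 400_000],
        "tx_end": [120_000, 650_000, 2_550_000, 80_000, 450_000],
        "is_tf": [True, False, False, False, False],
    }))


@pytest.fixture
def toy_snps():
    return SnpTable(pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(6)],
        "chrom": ["chr1", "chr1", "chr1", "chr1", "chr2", "chr2"],
        "pos": [110_000, 500_000, 1_700_000, 4_000_000, 60_000, 900_000],
        "a1": ["A"] * 6,
        "a2": ["G"] * 6,
    }))


@pytest.fixture
def toy_network():
    """TF gA regulates gC (distal from most SNPs) and gD."""
    edges = pd.DataFrame({
        "tf": ["gA", "gA"],
        "tg": ["gC", "gD"],
        "weight": [0.5, 0.8],
    })
    return RegulatoryNetwork(edges, name="toy")


def random_vb_instance(rng, p, banded=True, max_corr_rank=None):
    """A random well-posed GWAS/LD/prior instance for VB tests."""
    a = rng.normal(size=(max_corr_rank or 4 * p, p))
    r = np.corrcoef(a.T)
    se = rng.uniform(0.5, 1.5, p)
    betahat = rng.normal(0.0, 1.0, p)
    gwas = GwasSummary(betahat, se, 1000.0)
    ld = LDMatrix.from_dense(r, p - 1)
    pi = rng.uniform(0.05, 0.6, p)
    sigma2 = rng.uniform(0.1, 2.0, p)
    return gwas, ld, r, pi, sigma2
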