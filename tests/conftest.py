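import numpy as np
import pandas as pd
import pytest

from xtrait import simulate
from xtrait.sumstats import (HarmonizedPair, LDReference, SummaryStats,
                             harmonize_pair)


def make_sumstats(snp_ids, betas, pvalues=None, ses=None, n=10_000,
                  chrom="1", ea="A", oa="G", eaf=np.nan, pos=None):
    """Build a small valid SummaryStats table by hand."""
    m = len(snp_ids)
    betas = np.asarray(betas, dtype=float)
    if ses is None:
        ses = np.full(m, 0.05)
    if pvalues is None:
        from scipy import stats
        pvalues = 2 * stats.norm.sf(np.abs(betas / np.asarray(ses)))
        pvalues = np.clip(pvalues, 1e-300, 1.0)
    if pos is None:
        pos = (np.arange(m) + 1) * 1000
    df = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa,
        "beta": betas, "se": ses, "pvalue": pvalues, "n": n, "eaf": eaf,
    })
    return SummaryStats.from_dataframe(df)


@pytest.fixture
def five_row_frame():
    return pd.DataFrame({
        "SNP": ["rs1", "rs2", "rs3", "rs4", "rs5"],
        "CHR": ["1"] * 5,
        "BP": [100, 200, 300, 400, 500],
        "A1": ["A", "C", "G", "T", "A"],
        "A2": ["G", "T", "A", "C", "C"],
        "BETA": [0.1, -0.2, 0.05, 0.0, 0.3],
        "SE": [0.05, 0.04, 0.06, 0.05, 0.1],
        "P": [0.04, 1e-6, 0.4, 1.0, 0.003],
        "N": [1000] * 5,
        "FRQ": [0.3, 0.5, 0.2, 0.6, 0.9],
    })


@pytest.fixture
def small_pair():
    """A 6-SNP harmonized pair with mixed signs and a spread of p-values."""
    a = make_sumstats([f"rs{i}" for i in range(1, 7)],
                      betas=[0.2, -0.1, 0.3, -0.4, 0.05, -0.02],
                      pvalues=[1e-8, 1e-4, 0.2, 0.01, 0.5, 0.9])
    b = make_sumstats([f"rs{i}" for i in range(1, 7)],
                      betas=[0.1, -0.2, -0.1, -0.3, 0.02, 0.01],
                      pvalues=[1e-5, 1e-3, 0.3, 0.02, 0.6, 0.8])
    return harmonize_pair(a, b)


@pytest.fixture(scope="session")
def null_pair():
    """Independent null traits (h2 = 0, rg = 0) on 1000 unlinked SNPs."""
    cfg = simulate.SynthConfig(m_snps=1000, block_size=1, rho=0.0,
                               h2_1=0.0, h2_2=0.0, rg=0.0,
                               n1=20_000, n2=20_000, seed=99)
    ld = simulate.gen_ld_reference(cfg.m_snps, 1, 0.0)
    s1, s2, _ = simulate.gen_joint_sumstats(cfg, ld)
    return harmonize_pair(s1, s2), ld


@pytest.fixture(scope="session")
def correlated_dataset():
    """A moderately sized correlated-trait dataset with block LD."""
    cfg = simulate.SynthConfig(m_snps=4000, block_size=20, rho=0.5,
                               h2_1=0.2, h2_2=0.2, rg=0.6,
                               n1=50_000, n2=50_000, seed=7)
    ld = simulate.gen_ld_reference(cfg.m_snps, cfg.block_size, cfg.rho)
    s1, s2, truth = simulate.gen_joint_sumstats(cfg, ld)
    return cfg, ld, s1, s2, truth
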