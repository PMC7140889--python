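"""SNP-effect concordance analysis (SECA).

Cross-tabulates effect directions of two harmonized GWAS within nested
p-value subsets.  Independent SNPs (after p-value-informed clumping) are
partitioned by twelve p-value cutoffs per trait (0.01, 0.05, 0.1, 0.2, ...,
0.9, 1.0), giving a 12 x 12 grid of 144 SNP subsets.  Each cell receives a
two-sided Fisher exact test of sign concordance between the traits; grid
summaries are the number of cells with OR > 1 and p <= 0.05 (excess-subset
binomial test) and permutation-based empirical p-values obtained by
randomly flipping trait-2 effect signs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .sumstats import HarmonizedPair, LDReference, pvalue_informed_clump

__all__ = [
    "THRESHOLDS", "SecaGrid", "SecaPermutation", "fisher_exact_2x2",
    "build_grid", "concordance_test", "binomial_subset_test",
    "permutation_null", "run_seca",
]

#: the twelve fixed p-value cutpoints defining the subset grid
THRESHOLDS = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def _log_hyper_pmf(x: np.ndarray, m1: np.ndarray, m2: np.ndarray,
                   n1: np.ndarray) -> np.ndarray:
    """Log pmf of the central hypergeometric at x given margins.

    Table layout: row sums (m1, m2), first column sum n1; x is the top-left
    cell count.
    """
    return (
        gammaln(m1 + 1) - gammaln(x + 1) - gammaln(m1 - x + 1)
        + gammaln(m2 + 1) - gammaln(n1 - x + 1) - gammaln(m2 - (n1 - x) + 1)
        - (gammaln(m1 + m2 + 1) - gammaln(n1 + 1) - gammaln(m1 + m2 - n1 + 1))
    )


def fisher_exact_2x2(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Fisher exact test for a batch of 2x2 tables.

    Parameters
    ----------
    tables
        Integer array of shape ``(..., 2, 2)``.

    Returns
    -------
    or_, p
        Sample odds ratio ``ad / bc`` (NaN when a margin is zero, matching a
        degenerate table) and the conditional two-sided p-value that sums
        hypergeometric probabilities not exceeding the observed one.
    """
    t = np.asarray(tables, dtype=np.int64)
    shape = t.shape[:-2]
    t = t.reshape(-1, 2, 2)
    a, b = t[:, 0, 0], t[:, 0, 1]
    c, d = t[:, 1, 0], t[:, 1, 1]
    m1, m2 = a + b, c + d         # row margins
    n1 = a + c                    # first column margin
    with np.errstate(divide="ignore", invalid="ignore"):
        or_ = (a * d) / (b * c)
    or_ = np.where((m1 == 0) | (m2 == 0) | (n1 == 0) | (b + d == 0),
                   np.nan, or_)

    lo = np.maximum(0, n1 - m2)
    hi = np.minimum(m1, n1)
    width = int((hi - lo).max()) + 1 if len(t) else 1
    support = lo[:, None] + np.arange(width)[None, :]
    valid = support <= hi[:, None]
    logpmf = _log_hyper_pmf(np.where(valid, support, 0),
                            m1[:, None], m2[:, None], n1[:, None])
    logpmf = np.where(valid, logpmf, -np.inf)
    log_obs = _log_hyper_pmf(a, m1, m2, n1)
    # include all tables whose probability is <= observed (with slack for
    # floating-point ties), as the conditional two-sided test prescribes
    include = logpmf <= (log_obs[:, None] + 1e-7)
    pmf = np.exp(logpmf, where=np.isfinite(logpmf), out=np.zeros_like(logpmf))
    p = np.minimum((pmf * include).sum(axis=1), 1.0)
    p = np.where((m1 == 0) | (m2 == 0) | (n1 == 0) | (b + d == 0), 1.0, p)
    return or_.reshape(shape), p.reshape(shape)


def concordance_test(cell: np.ndarray | Sequence[Sequence[int]],
                     ) -> tuple[float, float]:
    """Fisher exact concordance test for one cell's 2x2 sign table.

    The table cross-tabulates (trait-1 effect up/down) x (trait-2 effect
    up/down); concordant counts sit on the main diagonal.  Degenerate margins
    (all effects one sign in a trait) leave the odds ratio undefined (NaN)
    with p = 1.
    """
    or_, p = fisher_exact_2x2(np.asarray(cell, dtype=np.int64)[None])
    return float(or_[0]), float(p[0])


@dataclass
class SecaGrid:
    """The 144-cell concordance grid.

    ``cells`` has one row per (P1 cutoff, P2 cutoff) pair with columns
    ``p1_cutoff, p2_cutoff, n_concordant, n_discordant, n_snps, proportion,
    or_ft, p_ft``.  The raw per-SNP sign/bin arrays are retained so
    permutations can rebuild the grid cheaply.
    """

    cells: pd.DataFrame
    bin1: np.ndarray
    bin2: np.ndarray
    sign1: np.ndarray
    sign2: np.ndarray
    n_zero_beta: int = 0

    @property
    def n_sig_subsets(self) -> int:
        sig = (self.cells["or_ft"] > 1) & (self.cells["p_ft"] <= 0.05)
        return int(sig.sum())

    @property
    def min_p_ft(self) -> float:
        return float(np.nanmin(self.cells["p_ft"].to_numpy()))


def _cell_tables(bin1: np.ndarray, bin2: np.ndarray, sign1: np.ndarray,
                 sign2: np.ndarray) -> np.ndarray:
    """Cumulative 2x2 sign tables for all 144 cells, shape (12, 12, 2, 2)."""
    k = len(THRESHOLDS)
    cat = (sign1 < 0) * 2 + (sign2 < 0)  # 0:(+,+) 1:(+,-) 2:(-,+) 3:(-,-)
    counts = np.zeros((k, k, 4), dtype=np.int64)
    np.add.at(counts, (bin1, bin2, cat), 1)
    counts = counts.cumsum(axis=0).cumsum(axis=1)
    tables = counts.reshape(k, k, 2, 2)
    return tables


def build_grid(pair: HarmonizedPair, independent_snps: Sequence[str],
               run_tests: bool = True) -> SecaGrid:
    """Build the 12 x 12 subset grid over the clumped SNPs.

    Each cell (c1, c2) holds the independent SNPs with trait-1 p <= c1 and
    trait-2 p <= c2; a SNP is concordant when its aligned effects share a
    sign.  SNPs with a zero effect in either trait carry no direction and are
    excluded (counted in ``n_zero_beta``).
    """
    if len(independent_snps) == 0:
        raise ValueError("clumped SNP list is empty")
    t = pair.table.set_index("snp_id").loc[list(independent_snps)]
    b1, b2 = t["beta_1"].to_numpy(), t["beta_2"].to_numpy()
    nonzero = (b1 != 0) & (b2 != 0)
    n_zero = int((~nonzero).sum())
    t = t[nonzero]
    b1, b2 = b1[nonzero], b2[nonzero]

    thr = np.asarray(THRESHOLDS)
    bin1 = np.searchsorted(thr, t["p_1"].to_numpy(), side="left")
    bin2 = np.searchsorted(thr, t["p_2"].to_numpy(), side="left")
    sign1 = np.sign(b1).astype(np.int8)
    sign2 = np.sign(b2).astype(np.int8)

    tables = _cell_tables(bin1, bin2, sign1, sign2)
    conc = tables[:, :, 0, 0] + tables[:, :, 1, 1]
    disc = tables[:, :, 0, 1] + tables[:, :, 1, 0]
    total = conc + disc
    with np.errstate(invalid="ignore"):
        prop = np.where(total > 0, conc / np.maximum(total, 1), np.nan)

    k = len(THRESHOLDS)
    cells = pd.DataFrame({
        "p1_cutoff": np.repeat(thr, k),
        "p2_cutoff": np.tile(thr, k),
        "n_concordant": conc.ravel(),
        "n_discordant": disc.ravel(),
        "n_snps": total.ravel(),
        "proportion": prop.ravel(),
    })
    if run_tests:
        or_, p = fisher_exact_2x2(tables)
        empty = total == 0  # no SNPs at all: test missing, not degenerate
        p = np.where(empty, np.nan, p)
        cells["or_ft"] = or_.ravel()
        cells["p_ft"] = p.ravel()
    else:
        cells["or_ft"] = np.nan
        cells["p_ft"] = np.nan
    return SecaGrid(cells=cells, bin1=bin1, bin2=bin2, sign1=sign1,
                    sign2=sign2, n_zero_beta=n_zero)


def binomial_subset_test(grid: SecaGrid, p0: float = 0.025) -> tuple[int, float]:
    """Excess-subset binomial test.

    Counts grid cells that are both nominally significant (p <= 0.05) and
    concordant in direction (OR > 1), and returns the one-sided binomial
    tail P(X >= count) with X ~ Binomial(144, p0).  The default null cell
    probability 0.025 is the chance that a cell is simultaneously nominally
    significant and in the concordant direction under the null.
    """
    count = grid.n_sig_subsets
    n_cells = len(grid.cells)
    p = float(stats.binom.sf(count - 1, n_cells, p0)) if count > 0 else 1.0
    return count, p


@dataclass
class SecaPermutation:
    """Permutation summary for a SECA analysis."""

    n_perm: int
    observed_n_sig: int
    observed_min_p: float
    p_fsig: float
    p_fsig_ci: tuple[float, float]
    p_ftmin: float


def _clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = stats.beta.ppf(alpha / 2, x, n - x + 1) if x > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, x + 1, n - x) if x < n else 1.0
    return float(lo), float(hi)


def permutation_null(pair: HarmonizedPair, independent_snps: Sequence[str],
                     n_perm: int = 1000, seed: int = 0) -> SecaPermutation:
    """Empirical permutation p-values for the grid summaries.

    Each permutation independently flips trait-2 effect signs with
    probability one half per SNP (p-values are preserved, so the subset
    membership is fixed and only the sign tables change), rebuilds the grid
    and recomputes the number of significant cells and the minimum cell p.
    Empirical p-values use the add-one rule ``(1 + #extreme) / (n_perm + 1)``
    and the count of extreme permutations carries a Clopper-Pearson 95% CI
    on the p-value scale.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    grid = build_grid(pair, independent_snps)
    obs_sig = grid.n_sig_subsets
    obs_min = grid.min_p_ft

    rng = np.random.default_rng(seed)
    m = len(grid.sign1)
    n_sig_null = np.empty(n_perm, dtype=np.int64)
    min_p_null = np.empty(n_perm)
    for it in range(n_perm):
        flip = rng.random(m) < 0.5
        s2 = np.where(flip, -grid.sign2, grid.sign2)
        tables = _cell_tables(grid.bin1, grid.bin2, grid.sign1, s2)
        or_, p = fisher_exact_2x2(tables)
        n_sig_null[it] = int(((or_ > 1) & (p <= 0.05)).sum())
        min_p_null[it] = np.nanmin(p)

    x_sig = int((n_sig_null >= obs_sig).sum())
    x_min = int((min_p_null <= obs_min).sum())
    p_fsig = (1 + x_sig) / (n_perm + 1)
    p_ftmin = (1 + x_min) / (n_perm + 1)
    ci = _clopper_pearson(1 + x_sig, n_perm + 1)
    return SecaPermutation(n_perm=n_perm, observed_n_sig=obs_sig,
                           observed_min_p=obs_min, p_fsig=p_fsig,
                           p_fsig_ci=ci, p_ftmin=p_ftmin)


def run_seca(pair: HarmonizedPair, ld: LDReference, r2_max: float = 0.1,
             n_perm: int = 1000, seed: int = 0,
             ) -> tuple[SecaGrid, tuple[int, float], SecaPermutation]:
    """Full SECA analysis: clump, grid + Fisher tests, binomial and permutation."""
    snps = pvalue_informed_clump(pair, ld, r2_max=r2_max, which_p="p_1")
    grid = build_grid(pair, snps)
    binom = binomial_subset_test(grid)
    perm = permutation_null(pair, snps, n_perm=n_perm, seed=seed)
    return grid, binom, perm
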