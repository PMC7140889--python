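"""LD-score regression: SNP heritability and cross-trait genetic correlation.

Univariate regression of per-SNP chi-square statistics on ``n * l_j / m``
(with ``l_j`` the LD score, the sum of squared correlations between SNP j
and its neighbours) estimates the observed-scale SNP heritability as the
slope; the intercept captures confounding inflation and equals one in its
absence.  The bivariate analogue regresses the cross-trait z-score product
on ``sqrt(n1 n2) * l_j / m`` to estimate the genetic covariance, from which
the genetic correlation is ``rg = gencov / sqrt(h2_1 h2_2)``.  Standard
errors come from a delete-a-block jackknife over contiguous SNP blocks.
For case-control traits the observed-scale heritability is mapped to the
liability scale from the sample and population prevalences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedPair, LDReference, SummaryStats, harmonize_pair

logger = logging.getLogger(__name__)

__all__ = [
    "LdscFit", "compute_ld_scores", "fit_h2", "obs_to_liability",
    "liability_factor", "fit_rg",
]


@dataclass
class LdscFit:
    """Result of a univariate or bivariate LD-score regression."""

    h2_obs: float | None = None
    h2_obs_se: float | None = None
    h2_liab: float | None = None
    h2_liab_ci: tuple[float, float] | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_constrained: bool = False
    rg: float | None = None
    rg_se: float | None = None
    rg_p: float | None = None
    gencov: float | None = None
    gencov_intercept: float | None = None
    gencov_intercept_constrained: bool = False
    n_snps_used: int = 0
    jackknife_blocks: int = 0


def compute_ld_scores(ld: LDReference) -> pd.Series:
    """Per-SNP LD scores ``l_j = sum_k r_jk**2`` within the SNP's block.

    The self-correlation is included, so ``l_j >= 1``.
    """
    ids: list[str] = []
    scores: list[np.ndarray] = []
    for block_ids, r in ld.blocks:
        ids.extend(block_ids)
        scores.append((r ** 2).sum(axis=1))
    return pd.Series(np.concatenate(scores), index=ids, name="ldscore")


def _jackknife(est_full: float, est_del: np.ndarray) -> float:
    """Delete-a-block jackknife standard error."""
    b = len(est_del)
    return float(np.sqrt((b - 1) / b * np.sum((est_del - est_del.mean()) ** 2)))


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray,
         intercept: float | None) -> tuple[float, float]:
    """Weighted least squares of y on x; returns (slope, intercept).

    With ``intercept`` given, the regression is through that fixed offset.
    """
    if intercept is not None:
        num = np.sum(w * x * (y - intercept))
        den = np.sum(w * x * x)
        return num / den, intercept
    sw = np.sum(w)
    mx, my = np.sum(w * x) / sw, np.sum(w * y) / sw
    sxx = np.sum(w * (x - mx) ** 2)
    if sxx <= 0:
        raise ValueError("regressor (n * ldscore / m) has no variation; "
                         "a free-intercept LD-score fit is unidentifiable")
    sxy = np.sum(w * (x - mx) * (y - my))
    slope = sxy / sxx
    return slope, my - slope * mx


def _block_bounds(m: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _resolve_blocks(m: int, n_blocks: int) -> int:
    if m < 2 * n_blocks:
        new = max(2, m // 2)
        logger.warning("reducing jackknife blocks from %d to %d for m=%d",
                       n_blocks, new, m)
        return new
    return n_blocks


def fit_h2(stats_: SummaryStats, ldscores: pd.Series,
           constrain_intercept: float | None = None,
           sample_prev: float | None = None, pop_prev: float | None = None,
           n_blocks: int = 200, min_snps: int = 200) -> LdscFit:
    """Univariate LD-score regression for SNP heritability.

    Regresses chi-square statistics on ``n_j l_j / m`` with
    heteroscedasticity weights ``1 / (l_j (1 + n h2 l_j / m)**2)`` where the
    h2 entering the weights comes from an unweighted pre-fit.  Chi-square
    values above ``max(80, 0.001 n)`` are removed before regression.  When
    prevalences are supplied, the slope is also reported on the liability
    scale with a symmetric 95% CI.
    """
    t = stats_.table.sort_values(["chrom", "pos"], kind="mergesort")
    matched = t[t["snp_id"].isin(ldscores.index)]
    if len(matched) < min_snps:
        raise ValueError(f"only {len(matched)} SNPs with LD scores; >= {min_snps} required")
    l = ldscores.loc[matched["snp_id"]].to_numpy()
    z = matched["beta"].to_numpy() / matched["se"].to_numpy()
    chi2 = z ** 2
    n = matched["n"].to_numpy(float)
    m = len(matched)

    cap = max(80.0, 0.001 * np.median(n))
    keep = chi2 <= cap
    if (~keep).any():
        logger.info("removed %d SNPs with chi-square above %.1f", int((~keep).sum()), cap)
    l, chi2, n = l[keep], chi2[keep], n[keep]
    x = n * l / m
    n_blocks = _resolve_blocks(len(x), n_blocks)

    # unweighted pre-fit supplies the heritability entering the weights
    pre_slope, _ = _wls(x, chi2, np.ones_like(x), constrain_intercept)
    h2_prior = float(np.clip(pre_slope, 0.0, 1.0))
    w = 1.0 / (l * (1.0 + h2_prior * x) ** 2)

    slope, icpt = _wls(x, chi2, w, constrain_intercept)
    bounds = _block_bounds(len(x), n_blocks)
    del_slope = np.empty(n_blocks)
    del_icpt = np.empty(n_blocks)
    for b in range(n_blocks):
        mask = np.ones(len(x), dtype=bool)
        mask[bounds[b]:bounds[b + 1]] = False
        s_b, i_b = _wls(x[mask], chi2[mask], w[mask], constrain_intercept)
        del_slope[b], del_icpt[b] = s_b, i_b
    h2_se = _jackknife(slope, del_slope)
    icpt_se = None if constrain_intercept is not None else _jackknife(icpt, del_icpt)

    fit = LdscFit(
        h2_obs=float(slope), h2_obs_se=h2_se,
        intercept=float(icpt), intercept_se=icpt_se,
        intercept_constrained=constrain_intercept is not None,
        n_snps_used=len(x), jackknife_blocks=n_blocks,
    )
    if sample_prev is not None and pop_prev is not None:
        factor = liability_factor(sample_prev, pop_prev)
        fit.h2_liab = fit.h2_obs * factor
        half = 1.96 * h2_se * factor
        fit.h2_liab_ci = (fit.h2_liab - half, fit.h2_liab + half)
    return fit


def liability_factor(sample_prev: float, pop_prev: float) -> float:
    """Observed-to-liability scale conversion factor for case-control data.

    ``K**2 (1-K)**2 / (K_s (1-K_s) phi(z)**2)`` with ``K`` the population
    prevalence, ``K_s`` the sample prevalence and ``z`` the standard-normal
    quantile at ``1 - K``.
    """
    for name, v in (("sample_prev", sample_prev), ("pop_prev", pop_prev)):
        if not 0 < v < 1:
            raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
    k, ks = pop_prev, sample_prev
    z = stats.norm.isf(k)
    phi = stats.norm.pdf(z)
    return k ** 2 * (1 - k) ** 2 / (ks * (1 - ks) * phi ** 2)


def obs_to_liability(h2_obs: float, sample_prev: float, pop_prev: float) -> float:
    """Convert an observed-scale heritability to the liability scale."""
    return h2_obs * liability_factor(sample_prev, pop_prev)


def fit_rg(s1: SummaryStats | HarmonizedPair, s2: SummaryStats | None,
           ldscores: pd.Series,
           constrain_i1: float | None = None, constrain_i2: float | None = None,
           constrain_gencov: bool = True,
           n_blocks: int = 200, min_snps: int = 200) -> LdscFit:
    """Bivariate cross-trait LD-score regression for genetic correlation.

    Accepts two summary-statistics tables (harmonized internally) or an
    already-harmonized pair with ``s2=None``.  The genetic covariance slope
    comes from regressing ``z1 z2`` on ``sqrt(n1 n2) l / m``; per-trait
    heritabilities are fitted under the given intercept constraints, and
    ``rg = gencov / sqrt(h2_1 h2_2)``.  With no sample overlap the genetic
    covariance intercept is constrained to zero (the default); otherwise it
    is estimated.  The standard error and the normal-approximation p-value
    for rg come from a delete-a-block jackknife of the full ratio.
    """
    if isinstance(s1, HarmonizedPair):
        pair = s1
    else:
        pair = harmonize_pair(s1, s2)
    t = pair.table.sort_values(["chrom", "pos"], kind="mergesort")
    t = t[t["snp_id"].isin(ldscores.index)]
    if len(t) < min_snps:
        raise ValueError(f"only {len(t)} harmonized SNPs with LD scores; >= {min_snps} required")
    l = ldscores.loc[t["snp_id"]].to_numpy()
    z1 = t["beta_1"].to_numpy() / t["se_1"].to_numpy()
    z2 = t["beta_2"].to_numpy() / t["se_2"].to_numpy()
    n1 = t["n_1"].to_numpy(float)
    n2 = t["n_2"].to_numpy(float)
    m = len(t)

    cap1 = max(80.0, 0.001 * np.median(n1))
    cap2 = max(80.0, 0.001 * np.median(n2))
    keep = (z1 ** 2 <= cap1) & (z2 ** 2 <= cap2)
    l, z1, z2, n1, n2 = l[keep], z1[keep], z2[keep], n1[keep], n2[keep]
    n_blocks = _resolve_blocks(len(l), n_blocks)

    x1, x2 = n1 * l / m, n2 * l / m
    xg = np.sqrt(n1 * n2) * l / m
    y1, y2, yg = z1 ** 2, z2 ** 2, z1 * z2
    gencov_icpt = 0.0 if constrain_gencov else None

    pre1, _ = _wls(x1, y1, np.ones(len(l)), constrain_i1)
    pre2, _ = _wls(x2, y2, np.ones(len(l)), constrain_i2)
    h2p1 = float(np.clip(pre1, 0.0, 1.0))
    h2p2 = float(np.clip(pre2, 0.0, 1.0))
    w1 = 1.0 / (l * (1.0 + h2p1 * x1) ** 2)
    w2 = 1.0 / (l * (1.0 + h2p2 * x2) ** 2)
    # cross-product variance is (1 + n1 h2_1 l/m)(1 + n2 h2_2 l/m) + gencov
    # terms; the leading factors dominate at desk scale
    wg = 1.0 / (l * (1.0 + h2p1 * x1) * (1.0 + h2p2 * x2))

    def estimate(mask: np.ndarray) -> tuple[float, float, float, float]:
        s1_, _ = _wls(x1[mask], y1[mask], w1[mask], constrain_i1)
        s2_, _ = _wls(x2[mask], y2[mask], w2[mask], constrain_i2)
        sg_, ig_ = _wls(xg[mask], yg[mask], wg[mask], gencov_icpt)
        if s1_ <= 0 or s2_ <= 0:
            return np.nan, s1_, s2_, sg_
        return sg_ / np.sqrt(s1_ * s2_), s1_, s2_, sg_

    full = np.ones(len(l), dtype=bool)
    rg, h2_1, h2_2, gencov = estimate(full)
    if not np.isfinite(rg):
        logger.warning("non-positive heritability estimate (h2_1=%.4g, h2_2=%.4g); "
                       "rg undefined", h2_1, h2_2)
        return LdscFit(h2_obs=h2_1, gencov=gencov, rg=None,
                       n_snps_used=len(l), jackknife_blocks=n_blocks,
                       gencov_intercept=gencov_icpt,
                       gencov_intercept_constrained=constrain_gencov)

    bounds = _block_bounds(len(l), n_blocks)
    del_rg = np.empty(n_blocks)
    for b in range(n_blocks):
        mask = np.ones(len(l), dtype=bool)
        mask[bounds[b]:bounds[b + 1]] = False
        del_rg[b] = estimate(mask)[0]
    del_rg = del_rg[np.isfinite(del_rg)]
    rg_se = _jackknife(rg, del_rg) if len(del_rg) >= 2 else np.nan
    rg_p = float(2 * stats.norm.sf(abs(rg) / rg_se)) if rg_se and np.isfinite(rg_se) else np.nan

    _, ig = _wls(xg, yg, wg, gencov_icpt)
    return LdscFit(
        h2_obs=float(h2_1), rg=float(rg), rg_se=float(rg_se), rg_p=rg_p,
        gencov=float(gencov),
        gencov_intercept=float(ig) if not constrain_gencov else 0.0,
        gencov_intercept_constrained=constrain_gencov,
        n_snps_used=len(l), jackknife_blocks=n_blocks,
    )
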