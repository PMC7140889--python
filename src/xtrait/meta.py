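"""Cross-disorder meta-analysis: fixed-effect, Cochran's Q, and the
Han-Eskin RE2 random-effects statistic.

The fixed-effect (FE) model combines two studies' per-SNP log-odds by
inverse-variance weighting.  The RE2 statistic is the likelihood-ratio test
of ``(mu, tau2) = (0, 0)`` against a free mean and non-negative
between-study variance under the marginal model ``b_i ~ N(mu, se_i**2 +
tau2)``; its null distribution is the equal mixture ``0.5 chi2_1 + 0.5
chi2_2``, which retains power under effect heterogeneity where FE loses it.
The asymptotic mixture tail is used throughout; for two studies it is
slightly conservative relative to tabulated small-sample corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .sumstats import HarmonizedPair, LDReference

__all__ = [
    "fixed_effect_meta", "cochran_q", "re2_meta", "re2_loglik",
    "meta_analyze", "classify_loci",
    "GENOME_WIDE_P", "SUGGESTIVE_P",
]

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-5


def fixed_effect_meta(b1, se1, b2, se2):
    """Inverse-variance-weighted fixed-effect combination of two estimates.

    Accepts scalars or aligned arrays; returns ``(beta_fe, se_fe, p_fe)``
    with a two-sided normal p-value.
    """
    b1, se1, b2, se2 = map(np.asarray, (b1, se1, b2, se2))
    w1, w2 = 1.0 / se1 ** 2, 1.0 / se2 ** 2
    beta = (w1 * b1 + w2 * b2) / (w1 + w2)
    se = 1.0 / np.sqrt(w1 + w2)
    p = 2 * stats.norm.sf(np.abs(beta) / se)
    if beta.ndim == 0:
        return float(beta), float(se), float(p)
    return beta, se, p


def cochran_q(betas, ses, pooled=None):
    """Cochran's Q heterogeneity statistic about a pooled estimate.

    ``Q = sum w_i (b_i - pooled)**2`` with ``w_i = 1/se_i**2``; df = k - 1;
    p from the chi-square tail.  When ``pooled`` is omitted the
    inverse-variance-weighted mean is used.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise ValueError("Cochran's Q requires at least two estimates")
    w = 1.0 / s ** 2
    if pooled is None:
        pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    df = b.size - 1
    return q, df, float(stats.chi2.sf(q, df))


def re2_loglik(mu: float, tau2: float, b: np.ndarray, se: np.ndarray) -> float:
    """Marginal log-likelihood of ``b_i ~ N(mu, se_i**2 + tau2)``."""
    v = se ** 2 + tau2
    return float(np.sum(-0.5 * np.log(2 * np.pi * v) - (b - mu) ** 2 / (2 * v)))


def _profile_mu(tau2: float, b: np.ndarray, se: np.ndarray) -> float:
    w = 1.0 / (se ** 2 + tau2)
    return float(np.sum(w * b) / np.sum(w))


def re2_meta(b1, se1, b2, se2) -> tuple[float, float]:
    """Han-Eskin RE2 statistic and p-value for two estimates.

    Maximizes the marginal likelihood over ``mu`` (profiled in closed form)
    and ``tau2 >= 0`` (bounded scalar optimization with an explicit check of
    the ``tau2 = 0`` boundary), and compares against the null likelihood at
    ``(0, 0)``.  P-value from the ``0.5 chi2_1 + 0.5 chi2_2`` mixture tail.
    """
    b = np.array([b1, b2], dtype=float)
    se = np.array([se1, se2], dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")

    ll_null = re2_loglik(0.0, 0.0, b, se)

    def neg_profile(tau2: float) -> float:
        return -re2_loglik(_profile_mu(tau2, b, se), tau2, b, se)

    # between-study variance cannot usefully exceed the spread of estimates
    hi = max((b1 - b2) ** 2, float(np.max(se) ** 2)) * 4 + 1e-12
    res = minimize_scalar(neg_profile, bounds=(0.0, hi), method="bounded",
                          options={"xatol": 1e-12})
    if not res.success:
        raise RuntimeError(f"RE2 profile optimization failed: {res.message}")
    ll_alt = max(-res.fun, -neg_profile(0.0))
    stat = max(0.0, 2 * (ll_alt - ll_null))
    p = 0.5 * stats.chi2.sf(stat, 1) + 0.5 * stats.chi2.sf(stat, 2)
    return float(stat), float(p)


def meta_analyze(pair: HarmonizedPair, het_alpha: float = 0.05) -> pd.DataFrame:
    """Score every harmonized SNP with FE, Cochran's Q and RE2.

    Returns one row per SNP with ``beta_fe, se_fe, p_fe, q, p_q, stat_re2,
    p_re2``, a ``model`` column naming the preferred model per SNP (RE2 when
    the heterogeneity p falls below ``het_alpha``, FE otherwise) and the
    significance ``class`` of the preferred model's p-value: ``genome-wide``
    (p < 5e-8), ``suggestive`` (p < 1e-5) or ``none``.
    """
    t = pair.table
    beta, se, p = fixed_effect_meta(t["beta_1"].to_numpy(), t["se_1"].to_numpy(),
                                    t["beta_2"].to_numpy(), t["se_2"].to_numpy())
    w1 = 1.0 / t["se_1"].to_numpy() ** 2
    w2 = 1.0 / t["se_2"].to_numpy() ** 2
    q = w1 * (t["beta_1"].to_numpy() - beta) ** 2 + w2 * (t["beta_2"].to_numpy() - beta) ** 2
    p_q = stats.chi2.sf(q, 1)

    stat_re2 = np.empty(len(t))
    p_re2 = np.empty(len(t))
    for i, (b1, s1, b2, s2) in enumerate(zip(t["beta_1"], t["se_1"],
                                             t["beta_2"], t["se_2"])):
        stat_re2[i], p_re2[i] = re2_meta(b1, s1, b2, s2)

    model = np.where(p_q < het_alpha, "re2", "fe")
    p_model = np.where(model == "re2", p_re2, p)
    cls = np.where(p_model < GENOME_WIDE_P, "genome-wide",
                   np.where(p_model < SUGGESTIVE_P, "suggestive", "none"))
    return pd.DataFrame({
        "snp_id": t["snp_id"], "chrom": t["chrom"], "pos": t["pos"],
        "beta_fe": beta, "se_fe": se, "p_fe": p,
        "q": q, "p_q": p_q, "stat_re2": stat_re2, "p_re2": p_re2,
        "model": model, "p_model": p_model, "class": cls,
    })


def classify_loci(rows: pd.DataFrame, ld: LDReference, model: str = "re2",
                  p_threshold: float = SUGGESTIVE_P) -> pd.DataFrame:
    """Group significant SNPs into loci by LD-block membership.

    SNPs with the chosen model's p-value below ``p_threshold`` are grouped by
    the LD block they belong to (SNPs absent from the reference form
    singleton loci); the per-locus index SNP is the member with the smallest
    p.  Returns one row per locus with the index SNP, member count and
    membership list, sorted by index p.
    """
    pcol = {"fe": "p_fe", "re2": "p_re2"}.get(model)
    if pcol is None:
        raise ValueError(f"model must be 'fe' or 're2', got {model!r}")
    sig = rows[rows[pcol] < p_threshold]
    if sig.empty:
        return pd.DataFrame(columns=["locus", "index_snp", "index_p",
                                     "n_snps", "members"])
    keys = []
    for sid in sig["snp_id"]:
        blk = ld.block_of(sid)
        keys.append(f"block_{blk}" if blk is not None else f"singleton_{sid}")
    sig = sig.assign(locus=keys)
    out = []
    for locus, grp in sig.groupby("locus", sort=False):
        best = grp.loc[grp[pcol].idxmin()]
        out.append({
            "locus": locus, "index_snp": best["snp_id"],
            "index_p": float(best[pcol]), "n_snps": len(grp),
            "members": ",".join(grp["snp_id"]),
        })
    return pd.DataFrame(out).sort_values("index_p").reset_index(drop=True)
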