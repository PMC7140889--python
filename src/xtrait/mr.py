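"""Two-sample Mendelian randomization from GWAS summary statistics.

Instruments are genome-wide-significant, mutually independent exposure SNPs
harmonized against the outcome study.  Each instrument contributes a Wald
ratio ``by / bx``; estimators combine the ratios: inverse-variance weighting
(fixed or multiplicative random effects), MR-Egger weighted regression with
a free intercept capturing average directional pleiotropy, the interpolated
weighted median (consistent if less than half the weight is pleiotropic),
and kernel-mode estimators.  Sensitivity diagnostics are Cochran's Q about
the IVW fit, Q' about the Egger fit, leave-one-out refits and approximate
per-instrument F-statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import (HarmonizedPair, LDReference, SummaryStats,
                       harmonize_pair, pvalue_informed_clump)

logger = logging.getLogger(__name__)

__all__ = [
    "MRData", "MRFit", "select_instruments", "wald_ratio", "f_approx",
    "ivw", "egger", "weighted_median", "mode_estimators", "heterogeneity",
    "leave_one_out", "mr_all",
]


@dataclass
class MRData:
    """Instrument table: one row per independent genome-wide-significant SNP.

    Columns: ``snp_id, beta_exposure, se_exposure, p_exposure, beta_outcome,
    se_outcome, p_outcome, wald_ratio, se_ratio, f_approx``.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ratios(self) -> np.ndarray:
        return self.table["wald_ratio"].to_numpy()

    @property
    def se_ratios(self) -> np.ndarray:
        return self.table["se_ratio"].to_numpy()

    def drop(self, snp_id: str) -> "MRData":
        return MRData(self.table[self.table["snp_id"] != snp_id].reset_index(drop=True))

    @classmethod
    def from_pair(cls, pair: HarmonizedPair, second_order_se: bool = False) -> "MRData":
        """Attach Wald ratios and F-statistics to a harmonized instrument table.

        Trait 1 is the exposure and trait 2 the outcome.
        """
        t = pair.table
        if (t["beta_1"] == 0).any():
            raise ValueError("instrument with zero exposure effect: Wald ratio undefined")
        ratio, se_ratio = wald_ratio(t["beta_1"].to_numpy(), t["se_1"].to_numpy(),
                                     t["beta_2"].to_numpy(), t["se_2"].to_numpy(),
                                     second_order=second_order_se)
        return cls(pd.DataFrame({
            "snp_id": t["snp_id"],
            "effect_allele": t.get("effect_allele"),
            "other_allele": t.get("other_allele"),
            "beta_exposure": t["beta_1"], "se_exposure": t["se_1"],
            "p_exposure": t["p_1"],
            "beta_outcome": t["beta_2"], "se_outcome": t["se_2"],
            "p_outcome": t["p_2"],
            "wald_ratio": ratio, "se_ratio": se_ratio,
            "f_approx": f_approx(t["beta_1"].to_numpy(), t["se_1"].to_numpy()),
        }).reset_index(drop=True))


@dataclass
class MRFit:
    """One estimator's result."""

    method: str
    n_snps: int
    beta: float
    se: float
    p: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q: float | None = None
    q_df: int | None = None
    q_p: float | None = None

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        lo, hi = self.ci
        return (float(np.exp(lo)), float(np.exp(hi)))


def wald_ratio(bx, sx, by, sy, second_order: bool = False):
    """Per-instrument Wald ratio ``by / bx`` and its standard error.

    First order: ``se = sy / |bx|``.  The second-order form adds the
    delta-method term from the exposure uncertainty:
    ``se**2 = sy**2/bx**2 + by**2 sx**2 / bx**4``.
    """
    bx, sx, by, sy = map(np.asarray, (bx, sx, by, sy))
    if np.any(bx == 0):
        raise ValueError("Wald ratio undefined for zero exposure effect")
    ratio = by / bx
    if second_order:
        se = np.sqrt(sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4)
    else:
        se = sy / np.abs(bx)
    if ratio.ndim == 0:
        return float(ratio), float(se)
    return ratio, se


def f_approx(bx, sx):
    """Approximate instrument-strength F-statistic ``(bx / sx)**2``."""
    bx, sx = np.asarray(bx, dtype=float), np.asarray(sx, dtype=float)
    if np.any(sx <= 0):
        raise ValueError("exposure standard errors must be positive")
    out = (bx / sx) ** 2
    return float(out) if out.ndim == 0 else out


def select_instruments(exposure: SummaryStats, outcome: SummaryStats,
                       ld: LDReference, p_thresh: float = 5e-8,
                       r2: float = 0.001, drop_palindromic: bool = True,
                       ) -> MRData:
    """Select, clump and harmonize instruments for two-sample MR.

    Exposure SNPs below ``p_thresh`` are harmonized against the outcome
    (instruments absent from the outcome are dropped and logged; no proxy
    search) and clumped at ``r2`` prioritizing the exposure p-value.
    """
    sig = exposure.table[exposure.table["pvalue"] < p_thresh]
    n_sig = len(sig)
    if n_sig == 0:
        raise ValueError(f"no exposure SNPs below p_thresh={p_thresh}")
    pair = harmonize_pair(SummaryStats(table=sig.reset_index(drop=True)), outcome,
                          drop_palindromic=drop_palindromic)
    n_absent = n_sig - len(pair) - pair.n_dropped_palindromic - pair.n_dropped_mismatch
    if n_absent:
        logger.info("%d significant exposure SNPs absent from outcome dropped", n_absent)
    kept = pvalue_informed_clump(pair, ld, r2_max=r2, which_p="p_1")
    t = pair.table[pair.table["snp_id"].isin(kept)].reset_index(drop=True)
    if len(t) < 2:
        raise ValueError(
            "fewer than 2 instruments survive selection: "
            f"{n_sig} significant, {n_absent} absent from outcome, "
            f"{pair.n_dropped_palindromic} palindromic, "
            f"{pair.n_dropped_mismatch} allele-mismatched, "
            f"{len(pair) - len(t)} removed by clumping")
    return MRData.from_pair(HarmonizedPair(table=t))


def ivw(data: MRData, mode: str = "multiplicative_re") -> MRFit:
    """Inverse-variance-weighted combination of the Wald ratios.

    ``mode='fixed'`` uses ``se = 1/sqrt(sum w)``; ``'multiplicative_re'``
    (the default) scales it by ``max(1, sqrt(Q / (k - 1)))`` so that
    overdispersion among the ratios widens the interval.  P-values are
    two-sided normal.
    """
    if mode not in ("fixed", "multiplicative_re"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    r, s = data.ratios, data.se_ratios
    k = len(r)
    w = 1.0 / s ** 2
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    if mode == "multiplicative_re" and k > 1:
        q = float(np.sum(w * (r - beta) ** 2))
        se *= max(1.0, np.sqrt(q / (k - 1)))
    p = float(2 * stats.norm.sf(abs(beta) / se))
    return MRFit(method=f"ivw_{mode}", n_snps=k, beta=beta, se=se, p=p)


def egger(data: MRData) -> MRFit:
    """MR-Egger weighted regression with a free pleiotropy intercept.

    Exposure effects are oriented positive (flipping outcome signs with
    them); the outcome effect is regressed on the exposure effect with
    weights ``1/se_outcome**2``.  The slope estimates the causal effect and
    the intercept the average directional pleiotropy.  Standard errors use
    the residual scale bounded below by one (no under-dispersion credit) and
    p-values the t distribution with k - 2 df.
    """
    t = data.table
    k = len(t)
    if k < 2:
        raise ValueError("MR-Egger requires at least 2 instruments")
    if k < 3:
        logger.warning("MR-Egger with %d instruments: exact fit, no residual df", k)
    sgn = np.sign(t["beta_exposure"].to_numpy())
    bx = t["beta_exposure"].to_numpy() * sgn
    by = t["beta_outcome"].to_numpy() * sgn
    sy = t["se_outcome"].to_numpy()
    w = 1.0 / sy ** 2

    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtx_inv = np.linalg.inv(X.T @ WX)
    coef = xtx_inv @ (WX.T @ by)
    resid = by - X @ coef
    dof = k - 2
    sigma2 = float(np.sum(w * resid ** 2) / dof) if dof > 0 else 1.0
    scale = max(1.0, sigma2)
    ses = np.sqrt(np.diag(xtx_inv) * scale)
    if dof > 0:
        pvals = 2 * stats.t.sf(np.abs(coef) / ses, dof)
    else:
        pvals = np.array([np.nan, np.nan])
    q_prime = float(np.sum(w * resid ** 2))
    return MRFit(method="egger", n_snps=k,
                 beta=float(coef[1]), se=float(ses[1]), p=float(pvals[1]),
                 intercept=float(coef[0]), intercept_se=float(ses[0]),
                 intercept_p=float(pvals[0]),
                 q=q_prime, q_df=max(dof, 0),
                 q_p=float(stats.chi2.sf(q_prime, dof)) if dof > 0 else np.nan)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(data: MRData, n_boot: int = 5000, seed: int = 0) -> MRFit:
    """Interpolated weighted median of the Wald ratios.

    Weights are inverse squared ratio standard errors; the standardized
    cumulative weight ``(cum_i - w_i/2) / sum w`` is interpolated at one
    half.  The standard error is a seeded parametric bootstrap that redraws
    exposure and outcome effects from their reported sampling distributions.
    """
    t = data.table
    k = len(t)
    if k < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    w = 1.0 / data.se_ratios ** 2
    beta = _weighted_median_point(data.ratios, w)

    rng = np.random.default_rng(seed)
    bx = t["beta_exposure"].to_numpy()
    sx = t["se_exposure"].to_numpy()
    by = t["beta_outcome"].to_numpy()
    sy = t["se_outcome"].to_numpy()
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx_b = bx + sx * rng.standard_normal(k)
        by_b = by + sy * rng.standard_normal(k)
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        r_b = by_b / bx_b
        w_b = bx_b ** 2 / sy ** 2
        boots[i] = _weighted_median_point(r_b, w_b)
    se = float(boots.std(ddof=1))
    p = float(2 * stats.norm.sf(abs(beta) / se))
    return MRFit(method="weighted_median", n_snps=k, beta=beta, se=se, p=p)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, h: float) -> float:
    lo = ratios.min() - 3 * h
    hi = ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = np.sum(weights[None, :]
                  * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2),
                  axis=1)
    return float(grid[np.argmax(dens)])


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    mad = stats.median_abs_deviation(ratios, scale="normal")
    s = 0.9 * min(ratios.std(ddof=1), mad) / len(ratios) ** 0.2
    if s <= 0:
        s = max(1e-6, abs(ratios).max() * 1e-3 + 1e-9)
    return phi * s


def mode_estimators(data: MRData, phi: float = 1.0, n_boot: int = 2000,
                    seed: int = 0) -> tuple[MRFit, MRFit]:
    """Simple and weighted kernel-mode estimators of the ratio distribution.

    The mode of a Gaussian kernel density over the Wald ratios, unweighted
    (simple mode) or inverse-variance weighted (weighted mode).  The
    bandwidth is ``phi * 0.9 min(sd, mad) k**-0.2``; standard errors come
    from a seeded parametric bootstrap of the ratios.
    """
    r, s = data.ratios, data.se_ratios
    k = len(r)
    if k < 3:
        raise ValueError("mode estimators require at least 3 instruments")
    h = _mode_bandwidth(r, phi)
    w_simple = np.ones(k)
    w_inv = 1.0 / s ** 2
    beta_simple = _kde_mode(r, w_simple, h)
    beta_weighted = _kde_mode(r, w_inv, h)

    rng = np.random.default_rng(seed)
    bs = np.empty((n_boot, 2))
    for i in range(n_boot):
        r_b = r + s * rng.standard_normal(k)
        h_b = _mode_bandwidth(r_b, phi)
        bs[i, 0] = _kde_mode(r_b, w_simple, h_b)
        bs[i, 1] = _kde_mode(r_b, w_inv, h_b)
    se_simple, se_weighted = bs.std(axis=0, ddof=1)
    fits = []
    for name, beta, se in (("simple_mode", beta_simple, se_simple),
                           ("weighted_mode", beta_weighted, se_weighted)):
        p = float(2 * stats.t.sf(abs(beta) / se, k - 1))
        fits.append(MRFit(method=name, n_snps=k, beta=beta, se=float(se), p=p))
    return fits[0], fits[1]


def heterogeneity(data: MRData, about: str = "ivw") -> tuple[float, int, float]:
    """Cochran's Q about the IVW estimate or Q' about the Egger fit."""
    r, s = data.ratios, data.se_ratios
    w = 1.0 / s ** 2
    k = len(r)
    if about == "ivw":
        beta = np.sum(w * r) / np.sum(w)
        q = float(np.sum(w * (r - beta) ** 2))
        df = k - 1
    elif about == "egger":
        fit = egger(data)
        q, df = fit.q, fit.q_df
    else:
        raise ValueError(f"about must be 'ivw' or 'egger', got {about!r}")
    return q, df, float(stats.chi2.sf(q, df)) if df > 0 else np.nan


def leave_one_out(data: MRData, method=ivw, **kwargs) -> pd.DataFrame:
    """Refit an estimator k times, each omitting one instrument."""
    rows = []
    for sid in data.table["snp_id"]:
        fit = method(data.drop(sid), **kwargs)
        rows.append({"omitted_snp": sid, "beta": fit.beta, "se": fit.se, "p": fit.p})
    return pd.DataFrame(rows)


def mr_all(data: MRData, seed: int = 0, n_boot: int = 5000) -> dict[str, MRFit]:
    """Run the full estimator battery on one instrument table."""
    fits = {"ivw": ivw(data), "egger": egger(data)}
    if len(data) >= 3:
        fits["weighted_median"] = weighted_median(data, n_boot=n_boot, seed=seed)
        simple, weighted = mode_estimators(data, seed=seed)
        fits["simple_mode"] = simple
        fits["weighted_mode"] = weighted
    q, qdf, qp = heterogeneity(data, about="ivw")
    fits["ivw"].q, fits["ivw"].q_df, fits["ivw"].q_p = q, qdf, qp
    return fits
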