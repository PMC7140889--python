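"""Over-representation analysis of a gene list against GMT gene sets.

Each term receives a hypergeometric upper-tail p-value for the overlap
between the query list and the term's members within an explicit background
universe, after restricting terms to a size window.  Multiple-testing
adjustment is Benjamini-Hochberg by default, with an optional empirical
family-wise mode that calibrates the per-family 0.05 quantile by random
query resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["Term", "GeneSetDB", "read_gmt", "write_gmt_db", "enrich"]


@dataclass
class Term:
    term_id: str
    name: str
    genes: list[str]
    source: str = ""


@dataclass
class GeneSetDB:
    """A gene-set collection plus the background gene universe."""

    terms: list[Term]
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen = set()
        for t in self.terms:
            if t.term_id in seen:
                raise ValueError(f"duplicate term id {t.term_id}")
            seen.add(t.term_id)
        if not self.background:
            self.background = {g for t in self.terms for g in t.genes}

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path, background: Iterable[str] | None = None) -> GeneSetDB:
    """Parse a GMT file (term, description, member genes...).

    Malformed lines (fewer than two fields) are skipped with a warning;
    duplicate members within a term are deduplicated preserving order.
    """
    terms = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                n_bad += 1
                continue
            term_id, desc, *genes = parts
            genes = list(dict.fromkeys(g for g in genes if g))
            terms.append(Term(term_id=term_id, name=desc, genes=genes))
    if n_bad:
        logger.warning("skipped %d malformed GMT lines", n_bad)
    return GeneSetDB(terms=terms,
                     background=set(background) if background is not None else set())


def write_gmt_db(db: GeneSetDB, path) -> None:
    with open(path, "w") as fh:
        for t in db.terms:
            fh.write("\t".join([t.term_id, t.name, *t.genes]) + "\n")


def enrich(query: Sequence[str], db: GeneSetDB, min_size: int = 5,
           max_size: int = 350, adjust: str = "bh", alpha: float = 0.05,
           n_perm: int = 200, seed: int = 0) -> pd.DataFrame:
    """Hypergeometric over-representation test per term.

    Query genes outside the background are dropped (logged); terms are
    intersected with the background and filtered to ``[min_size, max_size]``
    members.  ``p_hyper`` is the upper hypergeometric tail P(overlap >= k).
    ``adjust='bh'`` applies Benjamini-Hochberg; ``'empirical_fwe'`` instead
    estimates, by drawing ``n_perm`` random queries of the same size, the
    null distribution of the family's minimum p and reports the fraction of
    null minima at or below each observed p (a permutation family-wise
    error rate).  Rows are sorted by adjusted p; ``significant`` flags
    ``p_adj < alpha``.
    """
    bg = db.background
    q = set(query) & bg
    dropped = len(set(query)) - len(q)
    if dropped:
        logger.warning("%d query genes outside the background dropped", dropped)
    if not q:
        raise ValueError("query is empty after intersection with background")

    kept = []
    for t in db.terms:
        members = set(t.genes) & bg
        if min_size <= len(members) <= max_size:
            kept.append((t, members))
    n_, N = len(q), len(bg)
    rows = []
    for t, members in kept:
        K = len(members)
        k = len(q & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_)) if k > 0 else 1.0
        rows.append({
            "term_id": t.term_id, "term_name": t.name, "source": t.source,
            "k": k, "K": K, "n": n_, "N": N,
            "overlap_genes": ",".join(sorted(q & members)),
            "p_hyper": p,
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out

    if adjust == "bh":
        out["p_adj"] = multipletests(out["p_hyper"], method="fdr_bh")[1]
    elif adjust == "empirical_fwe":
        rng = np.random.default_rng(seed)
        bg_arr = np.asarray(sorted(bg), dtype=object)
        member_sets = [members for _, members in kept]
        null_min = np.empty(n_perm)
        for i in range(n_perm):
            draw = set(rng.choice(bg_arr, size=n_, replace=False))
            pmin = 1.0
            for members in member_sets:
                k = len(draw & members)
                if k > 0:
                    pmin = min(pmin, stats.hypergeom.sf(k - 1, N, len(members), n_))
            null_min[i] = pmin
        out["p_adj"] = [
            (1 + int((null_min <= p).sum())) / (n_perm + 1) for p in out["p_hyper"]
        ]
        out["p_adj"] = np.maximum(out["p_adj"], out["p_hyper"])
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["significant"] = out["p_adj"] < alpha
    return out.sort_values(["p_adj", "p_hyper"], kind="mergesort").reset_index(drop=True)
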