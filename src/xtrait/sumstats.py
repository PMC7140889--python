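"""GWAS summary statistics: reading, validation, harmonization and LD clumping.

The per-SNP association table (:class:`SummaryStats`) is the currency of every
downstream analysis.  Tables are stored as pandas DataFrames with a fixed set
of canonical columns; readers map arbitrary column names onto them.  Linkage
disequilibrium is represented as a block-diagonal correlation structure
(:class:`LDReference`): correlation is exact within a block and assumed zero
across blocks.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of a summary-statistics table
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pvalue", "n", "eaf",
]

#: default column-name dialect of tab-separated GWAS files
DEFAULT_DIALECT: Mapping[str, str] = {
    "snp_id": "SNP", "chrom": "CHR", "pos": "BP",
    "effect_allele": "A1", "other_allele": "A2",
    "beta": "BETA", "se": "SE", "pvalue": "P", "n": "N", "eaf": "FRQ",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")


class SumstatsError(ValueError):
    """Raised for invalid summary-statistics input."""


@dataclass
class SummaryStats:
    """One trait's per-SNP association table.

    Parameters
    ----------
    table
        DataFrame with the canonical columns ``snp_id, chrom, pos,
        effect_allele, other_allele, beta, se, pvalue, n`` and optionally
        ``eaf``.  Use :meth:`from_dataframe` to validate arbitrary input.
    n_dropped
        Number of rows removed during validation.
    """

    table: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS[:-1] if c not in self.table.columns]
        if missing:
            raise SumstatsError(f"summary statistics missing columns: {missing}")
        if "eaf" not in self.table.columns:
            self.table = self.table.assign(eaf=np.nan)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> pd.Series:
        return self.table["snp_id"]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SummaryStats":
        """Validate a canonical-column DataFrame, dropping offending rows.

        Rows are dropped (and counted) when the variant ID is missing or
        blank, the standard error or p-value is non-positive, the p-value
        exceeds one, beta is non-finite, alleles are not single A/C/G/T
        bases, the two alleles coincide, or the ID is a duplicate.
        """
        df = df.copy()
        if "eaf" not in df.columns:
            df["eaf"] = np.nan
        df = df[CANONICAL_COLUMNS]
        n_in = len(df)

        df["snp_id"] = df["snp_id"].astype("string").str.strip()
        df["effect_allele"] = df["effect_allele"].astype("string").str.upper().str.strip()
        df["other_allele"] = df["other_allele"].astype("string").str.upper().str.strip()
        for col in ("beta", "se", "pvalue", "n", "eaf"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        df["pos"] = pd.to_numeric(df["pos"], errors="coerce")

        ok = (
            df["snp_id"].notna() & (df["snp_id"] != "")
            & df["pos"].notna()
            & df["effect_allele"].isin(_VALID_ALLELES)
            & df["other_allele"].isin(_VALID_ALLELES)
            & (df["effect_allele"] != df["other_allele"])
            & np.isfinite(df["beta"].to_numpy(float))
            & (df["se"] > 0)
            & (df["pvalue"] > 0) & (df["pvalue"] <= 1)
            & (df["n"] > 0)
        )
        df = df[ok]
        df = df[~df["snp_id"].duplicated(keep=False) | ~df["snp_id"].duplicated(keep="first")]
        df = df.drop_duplicates(subset="snp_id", keep="first")
        df = df.astype({"pos": np.int64}).reset_index(drop=True)
        n_dropped = n_in - len(df)
        if n_dropped:
            logger.warning("dropped %d invalid summary-statistics rows", n_dropped)
        if len(df) == 0:
            raise SumstatsError("no valid summary-statistics rows after validation")
        return cls(table=df, n_dropped=n_dropped)


def read_sumstats(path: str | os.PathLike, dialect: Mapping[str, str] | None = None,
                  sep: str = "\t") -> SummaryStats:
    """Read a (possibly gzipped) tab-separated summary-statistics file.

    ``dialect`` maps canonical field names to the file's column names;
    unspecified fields fall back to :data:`DEFAULT_DIALECT`.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    try:
        df = pd.read_csv(path, sep=sep, dtype={mapping["snp_id"]: "string"})
    except OSError as exc:
        raise SumstatsError(f"cannot read summary statistics from {path}: {exc}") from exc
    rename = {}
    for canon, col in mapping.items():
        if col in df.columns:
            rename[col] = canon
        elif canon != "eaf":
            raise SumstatsError(f"column {col!r} (field {canon!r}) absent from {path}")
    df = df.rename(columns=rename)
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    return SummaryStats.from_dataframe(df[CANONICAL_COLUMNS])


def write_sumstats(stats: SummaryStats, path: str | os.PathLike,
                   dialect: Mapping[str, str] | None = None) -> None:
    """Write a summary-statistics table as tab-separated text."""
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    out = stats.table.rename(columns=mapping)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LD reference
# ---------------------------------------------------------------------------

@dataclass
class LDReference:
    """Block-diagonal SNP correlation structure.

    ``blocks`` is an ordered list of ``(snp_ids, r)`` pairs where ``r`` is the
    within-block correlation matrix (unit diagonal, symmetric, PSD).  SNPs in
    different blocks are treated as exactly uncorrelated.  Every SNP appears
    in at most one block; SNPs absent from the reference are treated as
    singleton blocks by consumers that permit it.
    """

    blocks: list[tuple[list[str], np.ndarray]]
    _index: dict[str, tuple[int, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for b, (ids, r) in enumerate(self.blocks):
            r = np.asarray(r, dtype=float)
            if r.shape != (len(ids), len(ids)):
                raise SumstatsError(f"LD block {b}: matrix shape {r.shape} != {len(ids)} SNPs")
            if not np.allclose(r, r.T, atol=1e-8):
                raise SumstatsError(f"LD block {b}: correlation matrix not symmetric")
            if not np.allclose(np.diag(r), 1.0, atol=1e-6):
                raise SumstatsError(f"LD block {b}: diagonal must be 1")
            if np.any(np.abs(r) > 1 + 1e-8):
                raise SumstatsError(f"LD block {b}: entries outside [-1, 1]")
            if len(ids) > 1:
                lam = np.linalg.eigvalsh(r)
                if lam[0] < -1e-6:
                    raise SumstatsError(f"LD block {b}: matrix not positive semi-definite")
            self.blocks[b] = (list(ids), r)
            for i, sid in enumerate(ids):
                if sid in self._index:
                    raise SumstatsError(f"SNP {sid} appears in more than one LD block")
                self._index[sid] = (b, i)

    @property
    def n_snps(self) -> int:
        return len(self._index)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def block_of(self, snp_id: str) -> int | None:
        loc = self._index.get(snp_id)
        return None if loc is None else loc[0]

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two SNPs (0 across blocks or if unknown)."""
        if a == b:
            return 1.0
        la, lb = self._index.get(a), self._index.get(b)
        if la is None or lb is None or la[0] != lb[0]:
            return 0.0
        return float(self.blocks[la[0]][1][la[1], lb[1]] ** 2)

    def submatrix(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Correlation matrix for a set of SNPs (identity across blocks)."""
        k = len(snp_ids)
        out = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                la, lb = self._index.get(snp_ids[i]), self._index.get(snp_ids[j])
                if la is not None and lb is not None and la[0] == lb[0]:
                    out[i, j] = out[j, i] = self.blocks[la[0]][1][la[1], lb[1]]
        return out

    @classmethod
    def independent(cls, snp_ids: Sequence[str]) -> "LDReference":
        """Reference asserting full pairwise independence (singleton blocks)."""
        return cls(blocks=[([sid], np.ones((1, 1))) for sid in snp_ids])


def write_ld_reference(ld: LDReference, directory: str | os.PathLike) -> None:
    """Write each block as ``block_<i>.tsv`` (SNP ids, then the matrix rows)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for b, (ids, r) in enumerate(ld.blocks):
        with open(directory / f"block_{b:05d}.tsv", "w") as fh:
            fh.write("\t".join(ids) + "\n")
            for row in r:
                fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")


def load_ld_reference(path: str | os.PathLike) -> LDReference:
    """Load a per-block LD reference directory written by :func:`write_ld_reference`.

    A path whose basename is the sentinel string ``independent`` is rejected:
    construct :meth:`LDReference.independent` from a SNP list instead.
    """
    path = Path(path)
    if not path.is_dir():
        raise SumstatsError(f"LD reference directory not found: {path}")
    blocks = []
    for f in sorted(path.glob("block_*.tsv")):
        with open(f) as fh:
            ids = fh.readline().rstrip("\n").split("\t")
            r = np.loadtxt(fh, delimiter="\t", ndmin=2)
        blocks.append((ids, r))
    if not blocks:
        raise SumstatsError(f"no block_*.tsv files in {path}")
    return LDReference(blocks=blocks)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedPair:
    """Two traits' effects aligned to a common effect allele per SNP.

    ``table`` carries both traits' statistics with suffixes ``_1``/``_2``; the
    effect allele of trait 1 is the reference orientation.  Bookkeeping counts
    record how each SNP in the ID intersection was treated.
    """

    table: pd.DataFrame
    n_flipped: int = 0
    n_dropped_palindromic: int = 0
    n_dropped_mismatch: int = 0

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_kept(self) -> int:
        return len(self.table)

    def swapped(self) -> "HarmonizedPair":
        """Return the pair with dataset roles exchanged (trait 2 becomes trait 1)."""
        t = self.table.copy()
        ren = {}
        for c in t.columns:
            if c.endswith("_1"):
                ren[c] = c[:-2] + "_2"
            elif c.endswith("_2"):
                ren[c] = c[:-2] + "_1"
        return HarmonizedPair(
            table=t.rename(columns=ren),
            n_flipped=self.n_flipped,
            n_dropped_palindromic=self.n_dropped_palindromic,
            n_dropped_mismatch=self.n_dropped_mismatch,
        )


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return ea.map(_COMPLEMENT) == oa


def harmonize_pair(a: SummaryStats, b: SummaryStats, drop_palindromic: bool = True,
                   eaf_resolve: bool = False, eaf_margin: float = 0.08) -> HarmonizedPair:
    """Align trait b's per-SNP effects to trait a's effect allele.

    The ID intersection is taken; then for each SNP the allele pair of b is
    matched to a's directly, after swapping (beta sign flipped, EAF
    complemented), after strand complement, or after both.  Irreconcilable
    allele pairs are dropped and counted.  Palindromic SNPs (A/T or C/G) are
    strand-ambiguous: they are dropped when ``drop_palindromic`` is set,
    unless ``eaf_resolve`` is also set and both allele frequencies are far
    enough from 0.5 (``|eaf - 0.5| > eaf_margin``) to orient them.
    """
    ta = a.table.set_index("snp_id")
    tb = b.table.set_index("snp_id")
    common = ta.index.intersection(tb.index)
    ta, tb = ta.loc[common], tb.loc[common]

    ea1, oa1 = ta["effect_allele"], ta["other_allele"]
    ea2, oa2 = tb["effect_allele"], tb["other_allele"]
    cea2, coa2 = ea2.map(_COMPLEMENT), oa2.map(_COMPLEMENT)

    same = (ea2 == ea1) & (oa2 == oa1)
    swap = (ea2 == oa1) & (oa2 == ea1)
    strand = (cea2 == ea1) & (coa2 == oa1) & ~same & ~swap
    strand_swap = (cea2 == oa1) & (coa2 == ea1) & ~same & ~swap
    keep_as_is = same | strand
    flip = swap | strand_swap
    match = keep_as_is | flip

    pal = _is_palindromic(ea1, oa1)
    drop_pal = pd.Series(False, index=common)
    if drop_palindromic:
        drop_pal = pal & match
        if eaf_resolve:
            f1 = ta["eaf"]
            # b's frequency for a's effect allele under the apparent orientation
            f2_aligned = tb["eaf"].where(~flip, 1 - tb["eaf"])
            resolvable = (
                pal & match
                & f1.notna() & f2_aligned.notna()
                & ((f1 - 0.5).abs() > eaf_margin) & ((f2_aligned - 0.5).abs() > eaf_margin)
            )
            # frequencies on the same side of 0.5 confirm the apparent
            # orientation; opposite sides indicate the reports refer to
            # complementary strands, so the apparent orientation is inverted
            agree = ((f1 - 0.5) * (f2_aligned - 0.5)) > 0
            invert = resolvable & ~agree
            new_keep = (keep_as_is & ~invert) | (flip & invert)
            new_flip = (flip & ~invert) | (keep_as_is & invert)
            keep_as_is, flip = new_keep, new_flip
            drop_pal = pal & match & ~resolvable

    kept = match & ~drop_pal
    n_mismatch = int((~match).sum())
    n_pal = int(drop_pal.sum())
    n_flip = int((flip & kept).sum())
    if n_mismatch:
        logger.warning("harmonization dropped %d SNPs with irreconcilable alleles", n_mismatch)
    if n_pal:
        logger.warning("harmonization dropped %d palindromic SNPs", n_pal)

    sign = np.where(flip[kept], -1.0, 1.0)
    out = pd.DataFrame({
        "snp_id": common[kept],
        "chrom": ta.loc[kept, "chrom"].to_numpy(),
        "pos": ta.loc[kept, "pos"].to_numpy(),
        "effect_allele": ea1[kept].to_numpy(),
        "other_allele": oa1[kept].to_numpy(),
        "beta_1": ta.loc[kept, "beta"].to_numpy(),
        "se_1": ta.loc[kept, "se"].to_numpy(),
        "p_1": ta.loc[kept, "pvalue"].to_numpy(),
        "n_1": ta.loc[kept, "n"].to_numpy(),
        "eaf_1": ta.loc[kept, "eaf"].to_numpy(),
        "beta_2": tb.loc[kept, "beta"].to_numpy() * sign,
        "se_2": tb.loc[kept, "se"].to_numpy(),
        "p_2": tb.loc[kept, "pvalue"].to_numpy(),
        "n_2": tb.loc[kept, "n"].to_numpy(),
        "eaf_2": np.where(sign < 0, 1 - tb.loc[kept, "eaf"].to_numpy(),
                          tb.loc[kept, "eaf"].to_numpy()),
    }).reset_index(drop=True)
    return HarmonizedPair(table=out, n_flipped=n_flip,
                          n_dropped_palindromic=n_pal, n_dropped_mismatch=n_mismatch)


# ---------------------------------------------------------------------------
# p-value-informed clumping
# ---------------------------------------------------------------------------

def pvalue_informed_clump(pair: HarmonizedPair, ld: LDReference,
                          r2_max: float = 0.1, which_p: str = "p_1") -> list[str]:
    """Greedy p-value-informed LD clumping.

    SNPs are visited in ascending order of the selected p-value column (ties
    broken by chromosome, position, then ID for determinism); a SNP is
    retained iff its squared correlation with every already-retained SNP is
    below ``r2_max``.  SNPs absent from the LD reference act as singleton
    blocks (retained, logged).
    """
    if not (0 < r2_max <= 1):
        raise ValueError(f"r2_max must be in (0, 1], got {r2_max}")
    t = pair.table
    if which_p not in t.columns:
        raise ValueError(f"unknown p-value column {which_p!r}")
    order = t.sort_values([which_p, "chrom", "pos", "snp_id"],
                          kind="mergesort").index
    n_unknown = sum(1 for sid in t["snp_id"] if sid not in ld)
    if n_unknown:
        logger.info("%d SNPs absent from LD reference treated as independent", n_unknown)

    kept_by_block: dict[int, list[str]] = {}
    kept: list[str] = []
    for idx in order:
        sid = t.at[idx, "snp_id"]
        blk = ld.block_of(sid)
        if blk is None:
            kept.append(sid)
            continue
        if all(ld.r2(sid, other) < r2_max for other in kept_by_block.get(blk, ())):
            kept.append(sid)
            kept_by_block.setdefault(blk, []).append(sid)
    return kept
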