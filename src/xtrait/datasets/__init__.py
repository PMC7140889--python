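"""Bundled reference tables from the endometriosis-migraine comorbidity study.

Small published summary tables shipped as plain TSV so the worked analyses
can be reproduced without consortium-held genotype-level data:

- ``mr_instruments``: the 11 independent genome-wide-significant
  endometriosis instruments with their migraine (outcome) effects, Wald
  ratios, ratio standard errors and approximate F-statistics.
- ``concordance_grid_diagonal``: the diagonal of the 12 x 12 SNP-effect
  concordance grid (matched P1 = P2 cutoffs) with concordant/discordant
  counts, Fisher odds ratios and p-values.
- ``gene_overlap_counts``: raw and effective gene counts per gene-p
  threshold for both traits, with overlap counts and reported binomial
  p-values (endometriosis as discovery, migraine as target).
- ``combined_genes``: the three genes reaching genome-wide significance on
  their Fisher's combined p across the two traits.
"""

from importlib.resources import files

import pandas as pd

__all__ = [
    "load_mr_instruments", "load_concordance_grid_diagonal",
    "load_gene_overlap_counts", "load_combined_genes",
]


def _read(name: str) -> pd.DataFrame:
    with (files(__package__) / name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_mr_instruments() -> pd.DataFrame:
    """Per-instrument exposure (endometriosis) and outcome (migraine) effects."""
    return _read("mr_instruments.tsv")


def load_concordance_grid_diagonal() -> pd.DataFrame:
    """Matched-cutoff diagonal of the SNP-effect concordance grid."""
    return _read("concordance_grid_diagonal.tsv")


def load_gene_overlap_counts() -> pd.DataFrame:
    """Raw/effective gene counts and overlap binomial tests per threshold."""
    return _read("gene_overlap_counts.tsv")


def load_combined_genes() -> pd.DataFrame:
    """Genome-wide significant genes by Fisher's combined p across the traits."""
    return _read("combined_genes.tsv")
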