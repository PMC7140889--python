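"""End-to-end orchestration of the cross-trait analysis from one config file.

The pipeline runs, in order: harmonization and clumping, SNP-effect
concordance (SECA), LD-score regression (per-trait heritability and
cross-trait genetic correlation), cross-disorder meta-analysis, two-sample
Mendelian randomization, gene-based tests with overlap statistics, and
gene-set enrichment.  Each stage writes its own TSV/JSON outputs; a summary
report collects the headline statistics.  A stage failure halts the run
with the failing stage named, preserving earlier outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import enrichment, genes, ldsc, meta, mr, seca
from .sumstats import (LDReference, harmonize_pair, load_ld_reference,
                       read_sumstats)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``sumstats_1`` is the conditioning/exposure/discovery trait throughout
    (SECA dataset 1, MR exposure, overlap discovery set).
    """

    sumstats_1: str
    sumstats_2: str
    ld_reference: str
    output_dir: str
    annotation: str | None = None
    gene_sets: str | None = None
    seed: int = 0
    seca_r2: float = 0.1
    seca_n_perm: int = 1000
    mr_p_thresh: float = 5e-8
    mr_clump_r2: float = 0.001
    gene_n_sim: int = 1000
    overlap_thresholds: tuple[float, ...] = (0.01, 0.05, 0.1)
    enrich_min_size: int = 5
    enrich_max_size: int = 350
    sample_prev_1: float | None = None
    pop_prev_1: float | None = None
    sample_prev_2: float | None = None
    pop_prev_2: float | None = None
    constrain_intercept_1: float | None = 1.0
    constrain_intercept_2: float | None = None
    constrain_gencov: bool = True
    jackknife_blocks: int = 200
    extra: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("sumstats_1", "sumstats_2", "ld_reference"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        for name in ("annotation", "gene_sets"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = {f for f in PipelineConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    if "overlap_thresholds" in kwargs:
        kwargs["overlap_thresholds"] = tuple(kwargs["overlap_thresholds"])
    cfg = PipelineConfig(**kwargs, extra=extra)
    cfg.validate()
    return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute every stage, writing outputs under ``cfg.output_dir``.

    Returns the summary report (also written as ``report.json``).
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {}
    stage = "load"
    try:
        s1 = read_sumstats(cfg.sumstats_1)
        s2 = read_sumstats(cfg.sumstats_2)
        ld = load_ld_reference(cfg.ld_reference)
        pair = harmonize_pair(s1, s2)
        report["harmonization"] = {
            "n_kept": pair.n_kept, "n_flipped": pair.n_flipped,
            "n_dropped_palindromic": pair.n_dropped_palindromic,
            "n_dropped_mismatch": pair.n_dropped_mismatch,
        }
        pair.table.to_csv(out / "harmonized.tsv", sep="\t", index=False)

        stage = "seca"
        grid, (n_sig, binom_p), perm = seca.run_seca(
            pair, ld, r2_max=cfg.seca_r2, n_perm=cfg.seca_n_perm, seed=cfg.seed)
        grid.cells.to_csv(out / "seca_grid.tsv", sep="\t", index=False)
        report["seca"] = {
            "n_independent_snps": int(grid.cells["n_snps"].iloc[-1]),
            "n_sig_subsets": n_sig, "binomial_p": binom_p,
            "p_fsig_permuted": perm.p_fsig, "p_fsig_ci": list(perm.p_fsig_ci),
            "p_ftmin_permuted": perm.p_ftmin,
        }

        stage = "ldsc"
        scores = ldsc.compute_ld_scores(ld)
        fit1 = ldsc.fit_h2(s1, scores, constrain_intercept=cfg.constrain_intercept_1,
                           sample_prev=cfg.sample_prev_1, pop_prev=cfg.pop_prev_1,
                           n_blocks=cfg.jackknife_blocks)
        fit2 = ldsc.fit_h2(s2, scores, constrain_intercept=cfg.constrain_intercept_2,
                           sample_prev=cfg.sample_prev_2, pop_prev=cfg.pop_prev_2,
                           n_blocks=cfg.jackknife_blocks)
        rg_fit = ldsc.fit_rg(pair, None, scores,
                             constrain_i1=cfg.constrain_intercept_1,
                             constrain_i2=cfg.constrain_intercept_2,
                             constrain_gencov=cfg.constrain_gencov,
                             n_blocks=cfg.jackknife_blocks)
        report["ldsc"] = {
            "h2_obs_1": fit1.h2_obs, "h2_obs_se_1": fit1.h2_obs_se,
            "h2_liab_1": fit1.h2_liab,
            "h2_obs_2": fit2.h2_obs, "h2_obs_se_2": fit2.h2_obs_se,
            "h2_liab_2": fit2.h2_liab,
            "intercept_2": fit2.intercept,
            "rg": rg_fit.rg, "rg_se": rg_fit.rg_se, "rg_p": rg_fit.rg_p,
        }

        stage = "meta"
        rows = meta.meta_analyze(pair)
        rows.to_csv(out / "meta.tsv", sep="\t", index=False)
        loci = meta.classify_loci(rows, ld, model="re2",
                                  p_threshold=meta.SUGGESTIVE_P)
        loci.to_csv(out / "meta_loci.tsv", sep="\t", index=False)
        report["meta"] = {
            "n_genome_wide": int((rows["class"] == "genome-wide").sum()),
            "n_suggestive": int((rows["class"] == "suggestive").sum()),
            "n_loci": len(loci),
        }

        stage = "mr"
        try:
            data = mr.select_instruments(s1, s2, ld, p_thresh=cfg.mr_p_thresh,
                                         r2=cfg.mr_clump_r2)
            data.table.to_csv(out / "mr_instruments.tsv", sep="\t", index=False)
            fits = mr.mr_all(data, seed=cfg.seed)
            report["mr"] = {
                name: {"beta": f.beta, "se": f.se, "p": f.p,
                       "or": f.odds_ratio, "n_snps": f.n_snps}
                for name, f in fits.items()
            }
            report["mr"]["egger_intercept"] = {
                "value": fits["egger"].intercept,
                "se": fits["egger"].intercept_se,
                "p": fits["egger"].intercept_p,
            }
        except ValueError as exc:
            logger.warning("MR stage skipped: %s", exc)
            report["mr"] = {"skipped": str(exc)}

        if cfg.annotation is not None:
            stage = "genes"
            ann = genes.read_gene_annotation(cfg.annotation)
            t1 = genes.gene_table(s1, ann, ld, n_sim=cfg.gene_n_sim, seed=cfg.seed)
            t2 = genes.gene_table(s2, ann, ld, n_sim=cfg.gene_n_sim,
                                  seed=cfg.seed + 1)
            t1.table.to_csv(out / "genes_trait1.tsv", sep="\t", index=False)
            t2.table.to_csv(out / "genes_trait2.tsv", sep="\t", index=False)
            me = max(t1.effective_genes, t2.effective_genes)
            thr = genes.genomewide_threshold(me)
            merged = t1.table.merge(t2.table, on="gene", suffixes=("_1", "_2"))
            merged["fcp"] = genes.fisher_combined(merged["gene_p_1"],
                                                  merged["gene_p_2"])
            merged.to_csv(out / "genes_combined.tsv", sep="\t", index=False)
            overlaps = {}
            for th in cfg.overlap_thresholds:
                try:
                    res = genes.overlap_binomial(t1, t2, th, ld_discovery=ld,
                                                 ld_target=ld)
                    overlaps[str(th)] = {
                        "raw_overlap": res.raw_overlap,
                        "eff_overlap": res.eff_overlap,
                        "expected": res.expected_proportion,
                        "observed": res.observed_proportion,
                        "binomial_p": res.binomial_p,
                    }
                except ValueError as exc:
                    overlaps[str(th)] = {"skipped": str(exc)}
            report["genes"] = {
                "total_genes": t1.total_genes,
                "effective_genes": me,
                "genomewide_threshold": thr,
                "n_fcp_significant": int((merged["fcp"] < thr).sum()),
                "overlap": overlaps,
            }

            if cfg.gene_sets is not None:
                stage = "enrichment"
                db = enrichment.read_gmt(cfg.gene_sets,
                                         background=t1.table["gene"])
                query_thr = max(cfg.overlap_thresholds)
                query = sorted(set(t1.table[t1.table["gene_p"] < query_thr]["gene"])
                               & set(t2.table[t2.table["gene_p"] < query_thr]["gene"]))
                if query:
                    enr = enrichment.enrich(query, db,
                                            min_size=cfg.enrich_min_size,
                                            max_size=cfg.enrich_max_size,
                                            seed=cfg.seed)
                    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                    report["enrichment"] = {
                        "n_terms_tested": len(enr),
                        "n_significant": int(enr["significant"].sum())
                        if not enr.empty else 0,
                    }
                else:
                    report["enrichment"] = {"skipped": "no overlapping query genes"}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    return report
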