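"""End-to-end orchestration of the divergence analysis.

Stages run in study order — trim alignments to conserved blocks, select a
best-fit amino-acid model per gene, build the gene tree, derive the
patristic distance matrix, compute relative rates, and run the group
statistics — with every stage's output written as a plain file (FASTA,
Newick, TSV, JSON) so stages can be re-run or replaced independently
(e.g. trees imported from an external ML program).  A manifest records
every effective parameter, including defaults that filled unspecified
choices.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import block_trim, divergence_stats, io_formats, phylo_models, tree_build
from .io_formats import Msa, read_fasta, read_gene_table, write_fasta
from .synthetic_data import FOCAL
from .tree_build import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    focal: str = FOCAL
    # trimming
    trim: bool = True
    b1: int | None = None
    b2: int | None = None
    b3: int = 8
    b4: int = 10
    gap_policy: str = "none"
    # model selection
    select_models: bool = True
    candidates: tuple[str, ...] = ("JTT", "JTT+G", "LG", "LG+G", "Dayhoff", "Dayhoff+G", "WAG", "WAG+G")
    fallback_model: str = "JTT+G"
    # tree building
    refine_branch_lengths: bool = False
    seed: int = 0

    def to_manifest(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GeneResult:
    gene: str
    group: str
    msa: Msa
    trimmed: Msa | None = None
    kept_fraction: float | None = None
    model_name: str | None = None
    tree_newick: str | None = None
    dm: DistanceMatrix | None = None


def analyze_families(
    families: Mapping[str, Msa],
    groups: Mapping[str, str],
    config: PipelineConfig | None = None,
    nucleotides: Mapping[str, int] | None = None,
) -> dict:
    """Run trim -> model-select -> tree -> distances -> rates -> stats.

    ``families`` maps gene name to an aligned protein MSA containing the
    focal taxon.  Returns a results bundle with per-gene artifacts, the
    rate records and the statistics, plus the manifest.
    """
    config = config or PipelineConfig()
    if not families:
        raise ValueError("no gene families supplied")
    gene_results: list[GeneResult] = []
    for gene, msa in families.items():
        gr = GeneResult(gene=gene, group=groups.get(gene, ""), msa=msa)
        work = msa
        if config.trim:
            selection = block_trim.trim_alignment(
                msa, b1=config.b1, b2=config.b2, b3=config.b3, b4=config.b4,
                gap_policy=config.gap_policy)
            if selection.kept:
                work, gr.kept_fraction = block_trim.apply_blocks(msa, selection)
            else:
                logger.warning("gene %s: trimming kept nothing; using full alignment", gene)
                gr.kept_fraction = 1.0
        gr.trimmed = work
        guide_model = phylo_models.model_from_name(config.fallback_model, work)
        guide_dm = tree_build.ml_distance_matrix(work, guide_model)
        guide_tree = tree_build.nj_tree(guide_dm)
        if config.select_models:
            best, _table = phylo_models.select_model(work, guide_tree, list(config.candidates))
            gr.model_name = best.name
            model = best
        else:
            model = guide_model
            gr.model_name = guide_model.name
        dm = tree_build.ml_distance_matrix(work, model)
        tree = tree_build.nj_tree(dm)
        if config.refine_branch_lengths:
            tree, _ = tree_build.optimize_branch_lengths(tree, work, model)
        gr.tree_newick = io_formats.write_newick(tree)
        gr.dm = tree_build.patristic_matrix(tree)
        gene_results.append(gr)

    matrices = {gr.gene: gr.dm for gr in gene_results}
    covariates = {
        gr.gene: {
            "nucleotides": (nucleotides or {}).get(gr.gene, gr.trimmed.n_cols * 3),
            "model_name": gr.model_name,
        }
        for gr in gene_results
    }
    records = divergence_stats.relative_rates(matrices, config.focal, groups, covariates)
    stats = compute_statistics(records)
    return {
        "genes": gene_results,
        "records": records,
        "stats": stats,
        "manifest": config.to_manifest(),
    }


def compute_statistics(records) -> dict:
    """The study's full statistics block from per-gene rate records.

    Statistics whose preconditions the data cannot meet (a group with a
    single gene, constant covariate, a single model name) are skipped with
    a warning rather than failing the run.
    """
    out = {}

    def attempt(key, fn):
        try:
            out[key] = fn()
        except ValueError as exc:
            logger.warning("skipping %s: %s", key, exc)

    attempt(
        "group_summaries",
        lambda: {n: dataclasses.asdict(s) for n, s in divergence_stats.group_summaries(records).items()},
    )
    if all(r.model_name for r in records):
        table = divergence_stats.model_frequency_table(records)
        out["model_frequency_table"] = table.to_dict()
        if table.shape[1] >= 2:  # Fisher needs at least two model columns
            attempt("model_fisher_p", lambda: divergence_stats.fisher_exact_2xk(table.to_numpy()))
        attempt(
            "model_diversity_fisher_p",
            lambda: divergence_stats.fisher_exact_2xk(divergence_stats.model_diversity_table(records)),
        )
    if all(r.nucleotides for r in records):
        attempt(
            "rate_vs_length",
            lambda: dict(zip(("slope", "r", "t", "p"), divergence_stats.regress_rate_on_length(records))),
        )
        attempt("ancova_group", lambda: dict(zip(("t", "p"), divergence_stats.ancova_group_effect(records))))
        attempt("residual_anova", lambda: dict(zip(("F", "p"), divergence_stats.residual_anova(records))))
    return out


def stats_from_table(path=None) -> dict:
    """Reproduce the group statistics directly from a printed study table."""
    rows = read_gene_table(path)
    records = divergence_stats.records_from_table(rows)
    return compute_statistics(records)


def write_results(results: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in results["records"]:
        rows.append(
            {"gene": r.gene, "group": r.group, "focal_mean": r.focal_mean,
             "relative_rate": r.relative_rate, "nucleotides": r.nucleotides,
             "model": r.model_name}
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(outdir / "rates.tsv", sep="\t", index=False)
    (outdir / "stats.json").write_text(json.dumps(results["stats"], indent=2, default=float) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(results["manifest"], indent=2) + "\n")
    for gr in results.get("genes", []):
        if gr.tree_newick:
            (outdir / f"{gr.gene}.nwk").write_text(gr.tree_newick + "\n")
        if gr.dm is not None:
            (outdir / f"{gr.gene}.dm.tsv").write_text(gr.dm.to_tsv())
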