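"""End-to-end orchestration of the analysis graph.

``run_pipeline`` executes replicate aggregation -> KSEA -> motif KSEA
-> kinase-motif association -> seed-match rank enrichment -> cohort
GSEA on a synthetic study (or on data generated beforehand with the
``simulate`` subcommand), writing every stage's result TSV plus a run
manifest (effective configuration, seed, per-stage row counts) next to
the outputs.  Reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from kinflux import __version__
from kinflux.expression import call_fold_change, filter_probesets, gsea_es, rank_by_median_diff
from kinflux.io_formats import write_fasta, write_kinase_map, write_ratio_table
from kinflux.kinase_motif import associate_kinases, filter_networkin
from kinflux.ksea import run_ksea
from kinflux.motifs import parse_pattern, run_motif_ksea
from kinflux.ratio_stats import (
    add_site_statistics,
    call_dysregulated,
    compute_experiment_stats,
)
from kinflux.simulate import (
    SimConfig,
    gen_expression_cohort,
    gen_kinase_map,
    gen_networkin,
    gen_phospho_experiment,
    gen_proteome,
    gen_utr_cohort,
)
from kinflux.target_seed import (
    flag_seed_genes,
    rank_by_fold_change,
    seed_rank_ks,
    select_candidates,
)

log = logging.getLogger(__name__)

#: default motif patterns probed by the motif KSEA stage (15-mers)
DEFAULT_PATTERNS = [
    ".......[ST]P......",    # proline-directed
    ".......[ST]Q......",    # ATM/ATR consensus
    "......R[ST].......",    # basophilic -1 arginine
]


@dataclass
class PipelineConfig:
    """Every threshold of the analysis, at its study default."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    contrast: str = "treat_vs_ctrl"
    min_group_size: int = 10
    motif_min_occurrence: int = 50
    networkin_min_score: float = 3.0
    min_n_mk: int = 100
    top_k: int = 10
    fold_change: float = 1.5
    abs_log2_cutoff: float = 0.58
    fdr_cutoff: float = 0.1
    expr_floor: float = 5.0
    mirmap_threshold: float = 75.0
    top_n_candidates: int = 8
    seed_motif: str = "CTATAGT"
    patterns: list = field(default_factory=lambda: list(DEFAULT_PATTERNS))
    sim: SimConfig = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.sim is None:
            self.sim = SimConfig(
                seed=self.seed, motif_kinase="KIN01", seed_motif=self.seed_motif
            )


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(_config_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_inputs(config: PipelineConfig, out_dir: Path) -> dict:
    """Generate and write every synthetic input file; return the objects."""
    sim = config.sim
    proteome, catalogue = gen_proteome(sim)
    kmap = gen_kinase_map(catalogue)
    table, phospho_truth = gen_phospho_experiment(
        sim, kmap, catalogue, contrast=config.contrast
    )
    utrs, gene_ratios, utr_truth = gen_utr_cohort(sim)
    matrix, planted_set, expected_counts = gen_expression_cohort(sim)
    networkin, planted_motif = gen_networkin(sim)

    write_fasta(proteome, out_dir / "proteome.fasta")
    write_kinase_map(kmap, out_dir / "kinase_map.tsv")
    write_ratio_table(table, out_dir / "ratios.tsv")
    write_fasta(utrs, out_dir / "utrs.fasta")
    gene_ratios.rename("log2_ratio").to_frame().rename_axis("gene").to_csv(
        out_dir / "gene_ratios.tsv", sep="\t"
    )
    networkin.to_csv(out_dir / "networkin.tsv", sep="\t", index=False)
    return {
        "proteome": proteome,
        "catalogue": catalogue,
        "kmap": kmap,
        "table": table,
        "phospho_truth": phospho_truth,
        "utrs": utrs,
        "gene_ratios": gene_ratios,
        "utr_truth": utr_truth,
        "matrix": matrix,
        "planted_set": planted_set,
        "expected_counts": expected_counts,
        "networkin": networkin,
        "planted_motif": planted_motif,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis graph on a synthetic study.

    Returns a result bundle (in-memory objects) and writes all result
    TSVs plus ``manifest.json`` under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contrast = config.contrast
    inputs = write_inputs(config, out_dir)
    counts: dict[str, int] = {}

    # --- phospho statistics -------------------------------------------------
    table = add_site_statistics(inputs["table"])
    stats = compute_experiment_stats(table, contrast)
    calls = call_dysregulated(
        table, contrast, config.abs_log2_cutoff, config.fdr_cutoff
    )
    write_ratio_table(table, out_dir / "ratios_aggregated.tsv")
    calls.to_csv(out_dir / "dysregulation_calls.tsv", sep="\t", index=False)
    counts["aggregated_sites"] = int(stats.n_total)
    counts["dysregulated_up"] = int((calls["label"] == "up").sum())
    counts["dysregulated_down"] = int((calls["label"] == "down").sum())

    # --- kinase KSEA --------------------------------------------------------
    ksea = run_ksea(inputs["kmap"], table, stats, contrast, config.min_group_size)
    ksea.to_csv(out_dir / "ksea.tsv", sep="\t", index=False)
    counts["substrate_groups"] = len(ksea)

    # --- motif KSEA ---------------------------------------------------------
    windows = {
        (p, int(pos)): w
        for p, pos, w in zip(
            inputs["catalogue"]["protein"],
            inputs["catalogue"]["position"],
            inputs["catalogue"]["window15"],
        )
    }
    patterns = [parse_pattern(p) for p in config.patterns]
    motif_ksea = run_motif_ksea(
        windows, patterns, table, stats, contrast, config.motif_min_occurrence
    )
    motif_ksea.to_csv(out_dir / "motif_ksea.tsv", sep="\t", index=False)
    counts["motif_groups"] = len(motif_ksea)

    # --- kinase-motif association -------------------------------------------
    filtered = filter_networkin(inputs["networkin"], config.networkin_min_score)
    assoc = associate_kinases(
        [parse_pattern(inputs["planted_motif"])],
        filtered,
        top_k=config.top_k,
        min_n=config.min_n_mk,
    )
    assoc.scores.to_csv(out_dir / "kinase_motif_scores.tsv", sep="\t", index=False)
    assoc.selection.to_csv(out_dir / "kinase_motif_selection.tsv", sep="\t", index=False)
    counts["networkin_kept"] = len(filtered)
    counts["kinase_motif_selected"] = len(assoc.selection)
    counts["distinct_kinases"] = assoc.distinct_kinases

    # --- seed-match rank enrichment -----------------------------------------
    from kinflux.target_seed import select_longest_utr

    utr_records = select_longest_utr(inputs["utrs"])
    ranked = flag_seed_genes(
        rank_by_fold_change(inputs["gene_ratios"]), utr_records, config.seed_motif
    )
    ks = seed_rank_ks(ranked)
    ranked.to_csv(out_dir / "seed_ranking.tsv", sep="\t", index=False)
    counts["seed_genes"] = int(ranked["has_motif"].sum())
    # synthetic prediction scores: seeded genes get high scores so the
    # candidate rule has something to act on
    scores = pd.Series(
        [90.0 if has else 10.0 for has in ranked["has_motif"]],
        index=ranked["gene"].values,
    )
    candidates = select_candidates(
        ranked, scores, config.mirmap_threshold, config.top_n_candidates
    )
    candidates.to_csv(out_dir / "candidate_targets.tsv", sep="\t", index=False)
    counts["candidate_targets"] = len(candidates)

    # --- cohort GSEA ---------------------------------------------------------
    filtered_matrix, filter_counts = filter_probesets(
        inputs["matrix"], config.expr_floor
    )
    cohort_ranked = rank_by_median_diff(filtered_matrix, "g1", "g2")
    enrich = gsea_es(cohort_ranked, set(inputs["planted_set"]))
    cohort_ranked.to_csv(out_dir / "cohort_ranking.tsv", sep="\t", index=False)
    counts["probes_surviving_filter"] = len(filtered_matrix.values)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": _config_dict(config),
        "stage_counts": counts,
        "probe_filter_counts": filter_counts,
        "seed_ks": {"D": ks.D, "p": ks.p, "method": ks.method},
        "cohort_gsea": {"ES": enrich.ES, "p": enrich.p, "set_size": enrich.set_size},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return {
        "table": table,
        "stats": stats,
        "calls": calls,
        "ksea": ksea,
        "motif_ksea": motif_ksea,
        "association": assoc,
        "seed_ranking": ranked,
        "seed_ks": ks,
        "candidates": candidates,
        "cohort_ranking": cohort_ranked,
        "cohort_gsea": enrich,
        "filter_counts": filter_counts,
        "manifest": manifest,
        "inputs": inputs,
    }
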