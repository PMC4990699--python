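"""Generate the synthetic study.

Writes every input the downstream analyses consume — triplicate
phosphopeptide log2 ratios with four planted kinase-activity shifts
(and a planted proline-directed motif on KIN01's substrates), the
kinase-substrate map, the proteome FASTA, NetworKIN-style predictions
with one planted kinase-motif link, a 3'UTR cohort with planted seed
matches, and a 9-vs-17 patient expression cohort with a planted
up-regulated gene set — plus the ground-truth tables.

Run from the repository root:  python analysis/01_simulate_study.py
"""

import sys
from pathlib import Path

import pandas as pd

from kinflux.io_formats import write_fasta, write_kinase_map, write_ratio_table
from kinflux.simulate import (
    SimConfig,
    gen_expression_cohort,
    gen_kinase_map,
    gen_networkin,
    gen_phospho_experiment,
    gen_proteome,
    gen_utr_cohort,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/data")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED, motif_kinase="KIN01")

    proteome, catalogue = gen_proteome(cfg)
    kmap = gen_kinase_map(catalogue)
    table, phospho_truth = gen_phospho_experiment(cfg, kmap, catalogue)
    write_fasta(proteome, OUT / "proteome.fasta")
    write_kinase_map(kmap, OUT / "kinase_map.tsv")
    write_ratio_table(table, OUT / "ratios.tsv")
    phospho_truth.to_csv(OUT / "truth_phospho.tsv", sep="\t", index=False)

    utrs, gene_ratios, utr_truth = gen_utr_cohort(cfg)
    write_fasta(utrs, OUT / "utrs.fasta")
    gene_ratios.rename("log2_ratio").to_frame().rename_axis("gene").to_csv(
        OUT / "gene_ratios.tsv", sep="\t"
    )
    utr_truth.to_csv(OUT / "truth_utr.tsv", sep="\t", index=False)

    matrix, planted_set, expected_counts = gen_expression_cohort(cfg)
    matrix.values.rename_axis("probe").to_csv(OUT / "cohort_expression.tsv", sep="\t")
    rows = [(p, g) for p, genes in matrix.probe_genes.items()
            for g in (genes or [""])]
    pd.DataFrame(rows, columns=["probe", "gene"]).to_csv(
        OUT / "cohort_probe_map.tsv", sep="\t", index=False
    )
    matrix.groups.rename("group").to_frame().rename_axis("sample").to_csv(
        OUT / "cohort_groups.tsv", sep="\t"
    )
    pd.Series(planted_set, name="gene").to_csv(
        OUT / "truth_gene_set.tsv", sep="\t", index=False
    )

    networkin, planted_motif = gen_networkin(cfg)
    networkin.to_csv(OUT / "networkin.tsv", sep="\t", index=False)
    (OUT / "planted_motif_11.txt").write_text(planted_motif + "\n")

    print(f"seed {SEED}: wrote {len(table.df)} phosphosites, "
          f"{len(kmap)} kinase-substrate pairs, {len(utrs)} UTRs, "
          f"{matrix.values.shape[0]} probes x {matrix.values.shape[1]} samples, "
          f"{len(networkin)} NetworKIN records -> {OUT}/")


if __name__ == "__main__":
    main()
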