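"""Per-site phosphopeptide statistics.

Aggregates the triplicate log2 ratios (sites detected in fewer than two
replicates are discarded), tests each aggregated ratio against zero,
attaches local FDRs, and calls dysregulated sites at |log2| > 0.58 and
local FDR <= 0.1.

Run after 01:  python analysis/02_phospho_site_stats.py
"""

from pathlib import Path

from kinflux.io_formats import read_ratio_table, write_ratio_table
from kinflux.ratio_stats import (
    add_site_statistics,
    call_dysregulated,
    compute_experiment_stats,
)

CONTRAST = "treat_vs_ctrl"
DATA, OUT = Path("results/data"), Path("results")


def main():
    table = read_ratio_table(DATA / "ratios.tsv", [CONTRAST])
    table = add_site_statistics(table)
    stats = compute_experiment_stats(table, CONTRAST)
    calls = call_dysregulated(table, CONTRAST)

    write_ratio_table(table, OUT / "site_statistics.tsv")
    calls.to_csv(OUT / "dysregulation_calls.tsv", sep="\t", index=False)

    n_detected = len(table.df)
    counts = calls["label"].value_counts()
    print(f"{n_detected} sites read; {stats.n_total} aggregated "
          f"(>=2 of 3 replicates); population mean {stats.mu:+.3f}, "
          f"SD {stats.s:.3f}")
    print(f"dysregulated: {counts.get('up', 0)} up, {counts.get('down', 0)} down, "
          f"{counts.get('unchanged', 0)} unchanged "
          f"(|log2|>0.58, local FDR<=0.1)")


if __name__ == "__main__":
    main()
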