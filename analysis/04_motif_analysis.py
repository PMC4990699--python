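"""Phospho-motif analysis.

Extracts 7+1+7 windows around every detected site from the proteome
(sites within seven residues of a terminus are dropped), runs
motif-group KSEA for a panel of positional patterns, and performs the
pS/pTQ (ATM/ATR consensus) analysis: position-residue logo counts and
a Fisher exact test of upregulation among SQ sites.

Run after 02:  python analysis/04_motif_analysis.py
"""

from pathlib import Path

from kinflux.io_formats import NEAR_TERMINUS, read_fasta, read_ratio_table
from kinflux.motifs import (
    classify_sq,
    extract_window,
    fisher_sq_dysregulation,
    logo_counts,
    parse_pattern,
    run_motif_ksea,
)
from kinflux.ratio_stats import (
    add_site_statistics,
    call_dysregulated,
    compute_experiment_stats,
)

CONTRAST = "treat_vs_ctrl"
DATA, OUT = Path("results/data"), Path("results")
# occurrence floor scaled to this study's ~600 detected sites
MIN_OCCURRENCE = 30
PATTERNS = [
    ".......[ST]P......",   # proline-directed (planted on KIN01 substrates)
    ".......[ST]Q......",   # ATM/ATR consensus
    "......R[ST].......",   # basophilic -1 arginine
]


def main():
    table = add_site_statistics(read_ratio_table(DATA / "ratios.tsv", [CONTRAST]))
    stats = compute_experiment_stats(table, CONTRAST)
    proteome = read_fasta(DATA / "proteome.fasta")
    windows = {
        (prot, int(pos)): extract_window(proteome[prot], int(pos))
        for prot, pos in zip(table.df.protein, table.df.position)
    }
    usable = {k: w for k, w in windows.items() if w != NEAR_TERMINUS}

    res = run_motif_ksea(usable, [parse_pattern(p) for p in PATTERNS],
                         table, stats, CONTRAST, MIN_OCCURRENCE)
    res.to_csv(OUT / "motif_ksea.tsv", sep="\t", index=False)
    print(f"{len(usable)}/{len(windows)} sites with full windows; "
          f"{len(res)} motif groups met the {MIN_OCCURRENCE}-occurrence floor")
    for _, row in res.iterrows():
        flag = "*" if row.q_z <= 0.05 else " "
        print(f" {flag} {row.motif}: N={row.N}, fcount {row.fcount:+.2f}, "
              f"q_z {row.q_z:.2e}")

    # pS/pTQ analysis on the detected sites
    calls = call_dysregulated(table, CONTRAST)
    sq = [classify_sq(windows.get((p, int(q)), NEAR_TERMINUS))
          for p, q in zip(calls.protein, calls.position)]
    sq_windows = [windows[(p, int(q))]
                  for p, q, flag in zip(calls.protein, calls.position, sq) if flag]
    if sq_windows:
        logo_counts(sq_windows).to_csv(OUT / "sq_logo_counts.tsv", sep="\t")
    odds, p = fisher_sq_dysregulation(calls, sq)
    print(f"pS/pTQ sites: {sum(sq)} of {len(calls)} "
          f"(Fisher up-vs-SQ: OR {odds:.2f}, p {p:.3f})")


if __name__ == "__main__":
    main()
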