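"""Kinase-motif association over NetworKIN-style predictions.

Filters mappings to networkin_score > 3, simplifies the 15-residue
motif panel to the 11-residue windows the prediction table carries,
scores every (motif, kinase) pair with ES_{m,k} and a two-sided Fisher
test, and selects per motif the top-10 kinases with n_mk >= 100.

Run after 01:  python analysis/05_kinase_motif_association.py
"""

from pathlib import Path

from kinflux.io_formats import read_networkin
from kinflux.kinase_motif import associate_kinases, filter_networkin, simplify_motif_11
from kinflux.motifs import parse_pattern

DATA, OUT = Path("results/data"), Path("results")
PANEL_15 = [
    ".......[ST]P......",
    ".......[ST]Q......",
    "......R[ST].......",
    ".......SP....K.",    # needs a 6+1+6 format: dropped at simplification
]


def main():
    records = read_networkin(DATA / "networkin.tsv")
    kept = filter_networkin(records, min_score=3.0)
    print(f"NetworKIN filter (score > 3): kept {len(kept)} of {len(records)}")

    motifs11 = []
    for text in PANEL_15:
        out = simplify_motif_11(parse_pattern(text))
        if out is None:
            print(f"  motif {text!r} removed: not expressible as 5+1+5")
        else:
            motifs11.append(out)
    planted = parse_pattern((DATA / "planted_motif_11.txt").read_text().strip())
    motifs11.append(planted)
    motifs11 = list({m.text: m for m in motifs11}.values())

    res = associate_kinases(motifs11, kept, top_k=10, min_n=100)
    res.scores.to_csv(OUT / "kinase_motif_scores.tsv", sep="\t", index=False)
    res.selection.to_csv(OUT / "kinase_motif_selection.tsv", sep="\t", index=False)
    print(f"{len(res.scores)} (motif, kinase) pairs scored; "
          f"{len(res.selection)} selected (top-10 by p, n_mk >= 100); "
          f"{res.distinct_kinases} distinct kinases")
    for _, row in res.selection.iterrows():
        print(f"  {row.motif} <- {row.kinase}: ES {row.ES:.2f}, "
              f"n_mk {row.n_mk}, q {row.q:.2e}")


if __name__ == "__main__":
    main()
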