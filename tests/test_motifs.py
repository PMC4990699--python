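from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from kinflux.io_formats import NEAR_TERMINUS
from kinflux.motifs import (
    build_motif_groups,
    classify_sq,
    extract_window,
    fisher_sq_dysregulation,
    logo_counts,
    logo_frequencies,
    match_motif,
    parse_pattern,
    run_motif_ksea,
)
from kinflux.ratio_stats import add_site_statistics, compute_experiment_stats
from kinflux.simulate import SimConfig, gen_kinase_map, gen_phospho_experiment, gen_proteome

from conftest import CONTRAST, make_ratio_table


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by enumeration of all tables with the observed
    margins, summing probabilities <= that of the observed table."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestExtractWindow:
    def test_full_window_is_15_residues_centred(self):
        seq = "ABCDEFGSIJKLMNOPQRST"  # length 20, S at position 8
        win = extract_window(seq, 8)
        assert win == seq[0:15] and len(win) == 15 and win[7] == "S"

    @pytest.mark.parametrize("position", [1, 7, 14, 20])
    def test_near_terminus_sentinel(self, position):
        seq = "A" * 20
        assert extract_window(seq, position) == NEAR_TERMINUS

    def test_position_outside_sequence_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            extract_window("A" * 20, 21)
        with pytest.raises(ValueError, match="outside"):
            extract_window("A" * 20, 0)

    def test_planted_sites_yield_catalogued_windows(self, phospho_study):
        """Windows recorded by the generator equal fresh extraction."""
        proteome = phospho_study["proteome"]
        for _, row in phospho_study["catalogue"].head(50).iterrows():
            win = extract_window(proteome[row.protein], row.position)
            assert win == row.window15
            assert win[7] == row.residue


class TestMatchMotif:
    def test_literal_positions_must_agree(self):
        pat = parse_pattern(".......SP......")
        assert match_motif("AAAAAAASPAAAAAA", pat)
        assert not match_motif("AAAAAAATPAAAAAA", pat)

    def test_class_token_matches_either_residue(self):
        pat = parse_pattern(".......[ST]P......")
        assert match_motif("AAAAAAASPAAAAAA", pat)
        assert match_motif("AAAAAAATPAAAAAA", pat)
        assert not match_motif("AAAAAAAYPAAAAAA", pat)

    def test_all_wildcard_matches_any_st_centre(self):
        pat = parse_pattern(".......[ST].......")
        assert match_motif("AAAAAAASAAAAAAA", pat)
        assert match_motif("AAAAAAATAAAAAAA", pat)

    def test_ambiguous_residue_matches_only_wildcard(self):
        pat = parse_pattern("......KSP......")
        assert not match_motif("AAAAAAXSPAAAAAA", pat)
        wild = parse_pattern(".......S.......")
        assert match_motif("AAAAAAXSPAAAAAA", wild)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="length"):
            match_motif("AAASAAA", parse_pattern(".......S......."))

    def test_pattern_centre_must_be_st(self):
        with pytest.raises(ValueError, match="centre"):
            parse_pattern(".......Y.......")


class TestBuildMotifGroups:
    def windows_for(self, table, suffix="PAAAAA"):
        return {
            (p, int(pos)): f"AAAAAAA{r}{suffix}"[:15].ljust(15, "A")
            for p, pos, r in zip(table.df.protein, table.df.position, table.df.residue)
        }

    def test_occurrence_floor(self):
        table = add_site_statistics(make_ratio_table([(0.1, 0.2)] * 49))
        windows = self.windows_for(table)
        pat = parse_pattern(".......[ST]P......")
        assert build_motif_groups(windows, [pat], table, CONTRAST, 50) == []
        groups = build_motif_groups(windows, [pat], table, CONTRAST, 1)
        assert len(groups) == 1 and groups[0].N == 49

    def test_nested_pattern_membership_containment(self):
        rng = np.random.default_rng(0)
        reps = [(0.1, 0.2)] * 80
        table = add_site_statistics(make_ratio_table(reps))
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        windows = {}
        for p, pos in zip(table.df.protein, table.df.position):
            w = rng.choice(aas, size=15)
            w[7] = "S"
            windows[(p, int(pos))] = "".join(w)
        general = parse_pattern(".......S.......")
        specific = parse_pattern(".......SP......")
        gg, gs = build_motif_groups(
            windows, [general, specific], table, CONTRAST, min_occurrence=1
        ), None
        members = {g.kinase: set(g.members) for g in gg}
        if specific.text in members:
            assert members[specific.text] <= members[general.text]
        # brute-force check of the general group
        expected = {k for k, w in windows.items() if w[7] == "S"}
        assert members[general.text] == expected


class TestMotifKsea:
    def test_planted_motif_recovered_across_seeds(self):
        """The proline-directed group is recovered at q_z <= 0.05 with
        positive fcount, and an unplanted pattern stays null, in >= 90%
        of seeded runs (occurrence floor scaled to the study size)."""
        planted = parse_pattern(".......[ST]P......")
        unplanted = parse_pattern("......R[ST].......")
        hits = 0
        for seed in range(20):
            cfg = SimConfig(seed=seed, motif_kinase="KIN01")
            _, cat = gen_proteome(cfg)
            kmap = gen_kinase_map(cat)
            table, _ = gen_phospho_experiment(cfg, kmap, cat)
            table = add_site_statistics(table)
            est = compute_experiment_stats(table, CONTRAST)
            windows = {
                (p, int(pos)): w
                for p, pos, w in zip(cat.protein, cat.position, cat.window15)
            }
            res = run_motif_ksea(windows, [planted, unplanted], table, est,
                                 CONTRAST, min_occurrence=10).set_index("motif")
            ok = (planted.text in res.index
                  and res.loc[planted.text, "q_z"] <= 0.05
                  and res.loc[planted.text, "fcount"] > 0)
            if unplanted.text in res.index:
                ok = ok and res.loc[unplanted.text, "q_z"] > 0.05
            hits += ok
        assert hits >= 18

    def test_planted_proline_motif_recovered(self):
        cfg = SimConfig(seed=3, motif_kinase="KIN01")
        proteome, cat = gen_proteome(cfg)
        kmap = gen_kinase_map(cat)
        table, _ = gen_phospho_experiment(cfg, kmap, cat)
        table = add_site_statistics(table)
        stats = compute_experiment_stats(table, CONTRAST)
        windows = {
            (p, int(pos)): w
            for p, pos, w in zip(cat.protein, cat.position, cat.window15)
        }
        patterns = [
            parse_pattern(".......[ST]P......"),
            parse_pattern(".......[ST]......."),  # background: everything
        ]
        res = run_motif_ksea(windows, patterns, table, stats, CONTRAST,
                             min_occurrence=30)
        res = res.set_index("motif")
        assert res.loc[".......[ST]P......", "q_z"] <= 0.05
        assert res.loc[".......[ST]P......", "fcount"] > 0


class TestClassifySq:
    @pytest.mark.parametrize(
        "centre, plus1, expected",
        [("S", "Q", True), ("T", "Q", True), ("S", "P", False), ("Y", "Q", False)],
    )
    def test_centre_and_plus_one(self, centre, plus1, expected):
        window = "AAAAAAA" + centre + plus1 + "AAAAAA"
        assert classify_sq(window) is expected

    def test_sentinel_is_never_sq(self):
        assert classify_sq(NEAR_TERMINUS) is False

    def test_random_proteome_sq_rate(self):
        """Over uniform residues, P(SQ) = P(centre S/T) * 1/20."""
        rng = np.random.default_rng(1)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        n = 20000
        wins = ["".join(rng.choice(aas, size=15)) for _ in range(n)]
        rate = np.mean([classify_sq(w) for w in wins])
        expected = (2 / 20) * (1 / 20)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rate - expected) < 4 * se


class TestFisherSqDysregulation:
    def make_calls(self, up_sq, up_other, rest_sq, rest_other):
        labels = (["up"] * (up_sq + up_other)
                  + ["unchanged"] * (rest_sq + rest_other))
        sq = ([True] * up_sq + [False] * up_other
              + [True] * rest_sq + [False] * rest_other)
        calls = pd.DataFrame({
            "protein": [f"P{i}" for i in range(len(labels))],
            "position": range(len(labels)),
            "label": labels,
        })
        return calls, sq

    def test_matches_enumeration_oracle(self):
        calls, sq = self.make_calls(8, 2, 20, 70)
        _, p = fisher_sq_dysregulation(calls, sq)
        assert p == pytest.approx(fisher_two_sided_oracle(8, 2, 20, 70), rel=1e-9)

    def test_independent_table(self):
        calls, sq = self.make_calls(5, 5, 50, 50)
        odds, p = fisher_sq_dysregulation(calls, sq)
        assert odds == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_perfect_separation_significant(self):
        calls, sq = self.make_calls(5, 0, 0, 15)
        _, p = fisher_sq_dysregulation(calls, sq)
        assert p < 0.05
        assert p == pytest.approx(fisher_two_sided_oracle(5, 0, 0, 15), rel=1e-9)

    def test_empty_margin_warns_p_one(self):
        calls, sq = self.make_calls(0, 0, 10, 10)
        calls["label"] = "unchanged"
        _, p = fisher_sq_dysregulation(calls, sq)
        assert p == 1.0


class TestLogoCounts:
    def test_identical_windows(self):
        counts = logo_counts(["ASQ"] * 3)
        assert counts.at[1, "A"] == 3 and counts.at[2, "S"] == 3
        assert counts.to_numpy().sum() == 9

    def test_column_sums_equal_window_count(self):
        wins = ["ASQ", "TSQ", "AYP"]
        counts = logo_counts(wins)
        assert (counts.sum(axis=1) == 3).all()

    def test_frequencies_sum_to_one(self):
        freqs = logo_frequencies(logo_counts(["ASQ", "TSP"]))
        np.testing.assert_allclose(freqs.sum(axis=1), 1.0)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            logo_counts(["ASQ", "ASQA"])
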