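from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinflux.ksea import (
    adjust_bh,
    build_substrate_groups,
    compute_fcount,
    hypergeom_enrichment,
    run_ksea,
    ztest_group_mean,
)
from kinflux.ratio_stats import (
    ExperimentStats,
    add_site_statistics,
    compute_experiment_stats,
)
from kinflux.simulate import (
    SimConfig,
    gen_kinase_map,
    gen_phospho_experiment,
    gen_proteome,
)

from conftest import CONTRAST, make_ratio_table


def enumerate_tail_p(background_signs, n_draw, threshold):
    """Oracle: P(X >= threshold positives) by exhaustive enumeration of
    all n-subsets of the background."""
    hits = total = 0
    for subset in combinations(background_signs, n_draw):
        total += 1
        if sum(1 for s in subset if s > 0) >= threshold:
            hits += 1
    return hits / total


class TestFcount:
    @pytest.mark.parametrize(
        "ratios, expected",
        [
            ([1] * 8 + [-1] * 2, 0.6),
            ([1] * 5 + [-1] * 5, 0.0),
            ([1] * 10, 1.0),
            ([-1] * 10, -1.0),
        ],
    )
    def test_values(self, ratios, expected):
        assert compute_fcount(ratios) == pytest.approx(expected)

    def test_zero_ratios_are_uncounted(self):
        assert compute_fcount([1, 1, 0, 0, -1]) == pytest.approx(1 / 3)

    def test_all_zero_is_undefined(self):
        assert np.isnan(compute_fcount([0.0, 0.0]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-5, 5, allow_nan=False).filter(lambda v: v != 0),
                    min_size=3, max_size=15))
    def test_sign_matches_median_when_one_sided(self, ratios):
        """fcount sign equals the sign of the median for strictly
        one-sided member distributions."""
        if all(r > 0 for r in ratios) or all(r < 0 for r in ratios):
            assert np.sign(compute_fcount(ratios)) == np.sign(np.median(ratios))


class TestHypergeomEnrichment:
    def test_small_instance_closed_form(self):
        # M=10 background, K=5 positive; group of 4 all positive:
        # P = C(5,4) C(5,0) / C(10,4) = 5/210
        bg = [1] * 5 + [-1] * 5
        res = hypergeom_enrichment([1, 1, 1, 1], bg)
        assert res.p_increased == pytest.approx(5 / 210)
        assert res.p == res.p_increased

    def test_matches_exhaustive_enumeration(self):
        """Agreement with subset enumeration for all backgrounds M <= 12."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            M = int(rng.integers(4, 13))
            bg = rng.choice([-1.0, 1.0], size=M)
            n = int(rng.integers(1, M + 1))
            grp = rng.choice(bg, size=n, replace=False)
            res = hypergeom_enrichment(grp, bg)
            n_i = int(np.sum(grp > 0))
            n_d = int(np.sum(grp < 0))
            p_inc = enumerate_tail_p(bg, n, n_i)
            p_dec = enumerate_tail_p(-bg, n, n_d)
            assert res.p_increased == pytest.approx(p_inc, abs=1e-12)
            assert res.p_decreased == pytest.approx(p_dec, abs=1e-12)

    def test_group_matching_background_is_not_enriched(self):
        bg = [1] * 6 + [-1] * 6
        res = hypergeom_enrichment([1, 1, -1, -1], bg)
        assert res.p >= 0.5

    def test_degenerate_empty_tail(self):
        bg = [-1.0] * 8
        res = hypergeom_enrichment([-1.0, -1.0], bg)
        assert res.p_increased == 1.0

    def test_group_larger_than_background_rejected(self):
        with pytest.raises(ValueError, match="larger than background"):
            hypergeom_enrichment([1] * 5, [1] * 3)


class TestZTest:
    def test_arithmetic(self):
        z, p = ztest_group_mean(0.5, ExperimentStats(0.0, 1.0, 1000), 16)
        assert z == pytest.approx(2.0)
        assert p == pytest.approx(0.04550026, abs=1e-7)

    def test_group_at_population_mean(self):
        z, p = ztest_group_mean(0.3, ExperimentStats(0.3, 1.0, 1000), 25)
        assert z == 0.0 and p == 1.0

    def test_zero_sd_is_an_error(self):
        with pytest.raises(ValueError, match="positive"):
            ztest_group_mean(0.5, ExperimentStats(0.0, 0.0, 10), 4)


class TestAdjustBH:
    def test_step_up_rule(self):
        # hand-applied: q3 = 0.03; q2 = min(0.02*3/2, q3) = 0.03; q1 = 0.03
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert adjust_bh([0.04])[0] == pytest.approx(0.04)

    def test_all_ones(self):
        assert np.all(adjust_bh([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 0.0])
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    def test_q_never_below_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, 200)
        assert np.all(adjust_bh(p) >= p)


class TestBuildSubstrateGroups:
    def make_inputs(self):
        reps = [(0.5, 0.5, 0.5)] * 12 + [(0.2, 0.2, 0.2)] * 9
        table = add_site_statistics(make_ratio_table(reps))
        from kinflux.io_formats import KinaseSubstrateMap

        df = table.df
        entries = []
        for i in range(12):
            entries.append(("A", df.protein[i], df.position[i], "S"))
        for i in range(12, 21):
            entries.append(("B", df.protein[i], df.position[i], "S"))
        kmap = KinaseSubstrateMap(
            df=pd.DataFrame(entries, columns=["kinase", "protein", "position", "residue"])
        )
        return kmap, table

    def test_size_floor(self):
        kmap, table = self.make_inputs()
        groups = build_substrate_groups(kmap, table, CONTRAST, min_size=10)
        assert [g.kinase for g in groups] == ["A"]
        groups = build_substrate_groups(kmap, table, CONTRAST, min_size=1)
        assert [g.kinase for g in groups] == ["A", "B"]

    def test_multi_membership(self):
        kmap, table = self.make_inputs()
        # map one of B's sites to A as well: it must appear in both groups
        extra = kmap.df.iloc[[12]].assign(kinase="A")
        kmap.df = pd.concat([kmap.df, extra], ignore_index=True)
        groups = build_substrate_groups(kmap, table, CONTRAST, min_size=1)
        key = (kmap.df.protein[12], int(kmap.df.position[12]))
        assert all(key in g.members for g in groups)

    def test_residue_mismatch_dropped(self):
        kmap, table = self.make_inputs()
        kmap.df.loc[0, "residue"] = "Y"  # disagrees with the table's S
        groups = build_substrate_groups(kmap, table, CONTRAST, min_size=1)
        a = next(g for g in groups if g.kinase == "A")
        assert a.N == 11


class TestRunKsea:
    def test_planted_kinase_recovered(self, phospho_study):
        res = run_ksea(
            phospho_study["kmap"], phospho_study["table"],
            phospho_study["stats"], CONTRAST,
        )
        hits = set(res.loc[res["q_z"] <= 0.05, "kinase"])
        assert hits == {"KIN01", "KIN02", "KIN03", "KIN04"}
        signs = res.set_index("kinase")["fcount"]
        assert signs["KIN01"] > 0 and signs["KIN02"] < 0

    def test_null_experiment_makes_no_discoveries(self):
        cfg = SimConfig(seed=11, perturbed_kinases={})
        _, cat = gen_proteome(cfg)
        kmap = gen_kinase_map(cat)
        table, _ = gen_phospho_experiment(cfg, kmap, cat)
        table = add_site_statistics(table)
        stats = compute_experiment_stats(table, CONTRAST)
        res = run_ksea(kmap, table, stats, CONTRAST)
        assert (res["q_z"] <= 0.05).sum() == 0

    def test_empty_map_gives_empty_result(self):
        from kinflux.io_formats import KinaseSubstrateMap

        table = add_site_statistics(make_ratio_table([(0.1, 0.2, 0.3)] * 5))
        stats = compute_experiment_stats(table, CONTRAST)
        res = run_ksea(KinaseSubstrateMap(), table, stats, CONTRAST)
        assert len(res) == 0
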