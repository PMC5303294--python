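"""Group-level classification: UTH, MPV additivity, ELD, restoration,
singleton complementation."""

import numpy as np
import pandas as pd
import pytest

from homoeoflow import (SimConfig, boxplot_stats, classify_groups,
                        mid_parent_pseudosample, simulate_counts,
                        simulate_universe)
from homoeoflow.classify import (classify_additivity, classify_eld,
                                 restoration_analysis,
                                 singleton_complementation, uth_analysis,
                                 uth_table)


class TestMidParent:
    def test_arithmetic_mean(self):
        pab = pd.DataFrame({"P_AB_1": [10], "P_AB_2": [14]})
        pdd = pd.DataFrame({"P_D_1": [20], "P_D_2": [18]})
        mpv = mid_parent_pseudosample(pab, pdd)
        assert list(mpv.iloc[0]) == [15, 16]

    def test_one_silent_parent(self):
        pab = pd.DataFrame({"P_AB_1": [30.0]})
        pdd = pd.DataFrame({"P_D_1": [0.0]})
        mpv = mid_parent_pseudosample(pab, pdd)
        assert mpv.iloc[0, 0] == 15

    def test_matches_independent_recomputation(self, rng):
        pab = pd.DataFrame(rng.uniform(0, 500, (40, 2)),
                           columns=["P_AB_1", "P_AB_2"])
        pdd = pd.DataFrame(rng.uniform(0, 500, (40, 2)),
                           columns=["P_D_1", "P_D_2"])
        mpv = mid_parent_pseudosample(pab, pdd)
        for j in range(2):
            expected = np.rint((pab.iloc[:, j] + pdd.iloc[:, j]) / 2)
            assert np.array_equal(mpv.iloc[:, j].to_numpy(), expected)


def _res(calls, lfcs):
    return pd.DataFrame({"call": calls, "log2fc": lfcs})


class TestEldRule:
    def test_eld_ab_with_higher_parent(self):
        # progeny ~ AABB parent, different from the (lower) DD parent
        out = classify_eld(_res(["ns"], [0.1]), _res(["up"], [1.4]),
                           _res(["down"], [-1.5]))
        assert out.iloc[0]["eld"] == "ELD-ab"
        assert out.iloc[0]["direction"] == "higher_parent"

    def test_eld_d_with_lower_parent(self):
        out = classify_eld(_res(["down"], [-1.4]), _res(["ns"], [0.0]),
                           _res(["down"], [-1.5]))
        assert out.iloc[0]["eld"] == "ELD-d"
        assert out.iloc[0]["direction"] == "lower_parent"

    def test_parents_equal_blocks_eld(self):
        out = classify_eld(_res(["ns"], [0.0]), _res(["up"], [1.0]),
                           _res(["ns"], [0.0]))
        assert out.iloc[0]["eld"] == "none"
        assert out.iloc[0]["reason"] == "parents_ns"

    def test_both_ns_insufficient_resolution(self):
        out = classify_eld(_res(["ns"], [0.0]), _res(["ns"], [0.1]),
                           _res(["down"], [-1.5]))
        assert out.iloc[0]["eld"] == "none"
        assert out.iloc[0]["reason"] == "progeny_similar_to_both"

    def test_transgressive_same_direction(self):
        out = classify_eld(_res(["up"], [1.0]), _res(["up"], [2.0]),
                           _res(["down"], [-1.0]))
        assert out.iloc[0]["eld"] == "transgressive_up"

    def test_additivity_mapping(self):
        mpv = _res(["up", "down", "ns"], [1.0, -1.0, 0.0])
        assert list(classify_additivity(mpv)) == \
            ["nonadd_up", "nonadd_down", "additive"]


class TestBoxplotStats:
    def test_manual_quartiles_and_whiskers(self):
        data = [0, 1, 2, 3, 4, 5, 6, 7, 8, 100]
        st = boxplot_stats(data)
        assert st["q1"] == 2.25
        assert st["median"] == 4.5
        assert st["q3"] == 6.75
        # high fence = 6.75 + 1.5 * 4.5 = 13.5 -> whisker stops at 8
        assert st["whisker_high"] == 8
        assert st["whisker_low"] == 0

    def test_symmetric_data_zero_median(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 501), [0.0]])
        vals = np.concatenate([vals, -vals])
        assert boxplot_stats(vals)["median"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_input(self):
        st = boxplot_stats([])
        assert st["n"] == 0 and np.isnan(st["median"])


class TestRestorationCalls:
    def test_rule_application(self):
        f1 = pd.DataFrame({"call": ["down", "down", "up", "ns"],
                           "log2fc": [-2, -2, 1.5, 0.0]},
                          index=list("abcd"))
        s1 = pd.DataFrame({"call": ["ns", "down", "up", "ns"],
                           "log2fc": [-0.1, -1.8, 1.2, 0.0]},
                          index=list("abcd"))
        genomes = pd.Series({"a": "D", "b": "D", "c": "A", "d": "B"})
        calls, stats = restoration_analysis(f1, s1, genomes)
        assert list(calls.index) == list("abc")
        assert calls.loc["a", "restoration"] == "restored"
        assert calls.loc["b", "restoration"] == "maintained"
        assert calls.loc["c", "restoration"] == "maintained"

    def test_boxplot_stats_match_oracle(self, rng):
        n = 60
        f1 = pd.DataFrame({"call": ["down"] * n,
                           "log2fc": rng.normal(-2, 0.3, n)},
                          index=[f"g{i}" for i in range(n)])
        s1 = pd.DataFrame({"call": ["ns"] * n,
                           "log2fc": rng.normal(0, 0.3, n)},
                          index=f1.index)
        genomes = pd.Series("D", index=f1.index)
        _, stats = restoration_analysis(f1, s1, genomes)
        row = stats[(stats["generation"] == "F1")].iloc[0]
        q1, med, q3 = np.percentile(f1["log2fc"], [25, 50, 75])
        assert row["q1"] == pytest.approx(q1)
        assert row["median"] == pytest.approx(med)
        assert row["q3"] == pytest.approx(q3)


class TestUth:
    def _experiment(self, left_counts, right_counts):
        """30 equal triplet groups plus one planted unequal A:B pair."""
        rng = np.random.default_rng(5)
        n = 31
        groups = pd.DataFrame({
            "group_id": [f"HG{i:05d}" for i in range(1, n + 1)],
            "class": "triplet",
            "gene_A": [f"HG{i:05d}A" for i in range(1, n + 1)],
            "gene_B": [f"HG{i:05d}B" for i in range(1, n + 1)],
            "gene_D": [f"HG{i:05d}D" for i in range(1, n + 1)],
        })
        genes = [g for i in range(1, n + 1)
                 for g in (f"HG{i:05d}A", f"HG{i:05d}B", f"HG{i:05d}D")]
        base = rng.integers(80, 120, n * 3)
        cols = ["P_AB_1", "P_AB_2", "P_D_1", "P_D_2",
                "F1_1", "F1_2", "S1_1", "S1_2"]
        counts = pd.DataFrame(
            {c: rng.poisson(base) for c in cols}, index=genes)
        pab = ["P_AB_1", "P_AB_2"]
        pdd = ["P_D_1", "P_D_2"]
        for i, g in enumerate(genes):
            if g.endswith("D"):
                counts.loc[g, pab] = 0
            else:
                counts.loc[g, pdd] = 0
        counts.loc["HG00001A", ["F1_1", "F1_2"]] = left_counts
        counts.loc["HG00001B", ["F1_1", "F1_2"]] = right_counts
        samples = pd.DataFrame({
            "sample": cols,
            "genotype": [c.rsplit("_", 1)[0] for c in cols],
            "replicate": [int(c.rsplit("_", 1)[1]) for c in cols],
        })
        lengths = pd.Series(1000, index=counts.index)
        return counts, samples, groups, lengths

    def test_equal_counts_ns(self):
        counts, samples, groups, lengths = self._experiment([100, 100],
                                                            [100, 100])
        calls = uth_analysis(counts, samples, groups, lengths,
                             pd.Index(groups["group_id"]))
        row = calls[(calls["setting"] == "F1") & (calls["pair"] == "A:B")
                    & (calls["group_id"] == "HG00001")]
        assert row.iloc[0]["call"] == "ns"

    def test_planted_imbalance_called_left_greater(self):
        counts, samples, groups, lengths = self._experiment([200, 200],
                                                            [50, 50])
        calls = uth_analysis(counts, samples, groups, lengths,
                             pd.Index(groups["group_id"]))
        row = calls[(calls["setting"] == "F1") & (calls["pair"] == "A:B")
                    & (calls["group_id"] == "HG00001")]
        assert row.iloc[0]["call"] == "left>"

    def test_table_percentages_self_consistent(self):
        counts, samples, groups, lengths = self._experiment([200, 200],
                                                            [50, 50])
        calls = uth_analysis(counts, samples, groups, lengths,
                             pd.Index(groups["group_id"]))
        table = uth_table(calls)
        from homoeoflow.report import percentage
        for _, row in table.iterrows():
            assert row["pct_left_gt"] == percentage(row["left_gt"],
                                                    row["n_tested"])


class TestSingletons:
    def _fpkm(self):
        groups = pd.DataFrame({
            "group_id": ["S1g", "S2g", "S3g"],
            "class": ["singleton_A", "singleton_D", "singleton_D"],
            "gene_A": ["sa", "", ""],
            "gene_B": ["", "", ""],
            "gene_D": ["", "sd1", "sd2"],
        })
        cols = ["P_AB_1", "P_D_1", "F1_1", "S1_1"]
        fpkm = pd.DataFrame(
            [[5.0, 0.0, 3.0, 2.0],     # sa: own parent + progeny
             [0.0, 4.0, 2.0, 0.0],     # sd1: DD parent + F1 only
             [0.0, 0.0, 0.0, 0.0]],    # sd2: silent everywhere
            index=["sa", "sd1", "sd2"], columns=cols)
        samples = pd.DataFrame({
            "sample": cols,
            "genotype": ["P_AB", "P_D", "F1", "S1"],
            "replicate": [1, 1, 1, 1],
        })
        return fpkm, samples, groups

    def test_memberships_and_single_parent_transcription(self):
        fpkm, samples, groups = self._fpkm()
        out = singleton_complementation(fpkm, samples, groups)
        assert out["expressed"]["F1"] == {"sa", "sd1"}
        assert out["expressed"]["S1"] == {"sa"}
        assert "sd2" not in set().union(*out["expressed"].values())
        assert out["single_parent_transcription"] == ["sa", "sd1"]

    def test_venn_partitions_universe(self):
        fpkm, samples, groups = self._fpkm()
        out = singleton_complementation(fpkm, samples, groups)
        assert int(out["venn_regions"]["n_genes"].sum()) == 3


@pytest.fixture(scope="module")
def classified():
    cfg = SimConfig(n_triplets=120, n_duplets=40, n_singletons_per_genome=10,
                    baseline_mean_range=(100.0, 500.0),
                    frac_restored_in_s1=0.5, seed=78)
    genes, groups, truth = simulate_universe(cfg)
    counts, samples, _ = simulate_counts(truth, cfg)
    lengths = genes.set_index("gene_id")["length"]
    res = classify_groups(counts, samples, groups, lengths)
    return res, truth, counts, groups


class TestFullClassification:

    def test_every_eligible_group_gets_one_category_per_generation(
            self, classified):
        res = classified[0]
        cls = res["classification"]
        for gen in ("F1", "S1"):
            assert cls[f"additivity_{gen}"].isin(
                ["additive", "nonadd_up", "nonadd_down"]).all()
            assert cls[f"eld_{gen}"].isin(
                ["none", "ELD-ab", "ELD-d", "transgressive_up",
                 "transgressive_down"]).all()
            has_dir = cls[f"eld_{gen}"].isin(["ELD-ab", "ELD-d"])
            assert (cls.loc[has_dir, f"eld_direction_{gen}"]
                    .isin(["higher_parent", "lower_parent"])).all()
            assert (cls.loc[~has_dir, f"eld_direction_{gen}"] == "na").all()

    def test_uth_frequency_drops_after_genome_doubling(self, classified):
        res = classified[0]
        table = res["uth_table"].set_index(["setting", "pair"])
        f1 = table.loc[("F1", "A:D"), "pct_uth"] \
            + table.loc[("F1", "B:D"), "pct_uth"]
        s1 = table.loc[("S1", "A:D"), "pct_uth"] \
            + table.loc[("S1", "B:D"), "pct_uth"]
        assert s1 < f1

    def test_group_totals_sum_members(self, classified):
        res, truth, counts, groups = classified
        totals = res["totals"]
        tr = truth.set_index("gene_id")
        for gid in totals.index[::17]:
            members = tr.index[tr["group_id"] == gid]
            expected = counts.loc[members].sum(axis=0)
            assert (totals.loc[gid] == expected).all()
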