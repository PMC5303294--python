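"""Synthetic-experiment generator: structure, determinism, planted effects."""

import itertools

import numpy as np
import pandas as pd
import pytest

from homoeoflow import (SimConfig, expected_pairwise_identity,
                        simulate_counts, simulate_reads, simulate_sequences,
                        simulate_universe, truth_group_summary,
                        write_experiment)
from homoeoflow.simulate import _nb_draw


class TestUniverse:
    def test_degenerate_singletons_only(self):
        cfg = SimConfig(n_triplets=0, n_duplets=0, n_singletons_per_genome=1)
        genes, groups, truth = simulate_universe(cfg)
        assert len(genes) == 3
        assert len(groups) == 3
        assert groups["class"].str.startswith("singleton").all()

    def test_gene_arithmetic(self):
        cfg = SimConfig(n_triplets=100, n_duplets=60,
                        n_singletons_per_genome=50)
        genes, groups, truth = simulate_universe(cfg)
        assert len(genes) == 100 * 3 + 60 * 2 + 150 == 570
        counts = groups["class"].str.split("_").str[0].value_counts()
        assert counts["triplet"] == 100
        assert counts["duplet"] == 60
        assert counts["singleton"] == 150

    def test_every_gene_in_exactly_one_group(self, small_experiment):
        genes = small_experiment["genes"]
        groups = small_experiment["groups"]
        members = pd.concat([groups[f"gene_{g}"] for g in "ABD"])
        members = members[members != ""]
        assert sorted(members) == sorted(genes["gene_id"])
        assert members.is_unique

    def test_truth_class_consistent_with_group_class(self, small_experiment):
        truth = small_experiment["truth"]
        groups = small_experiment["groups"].set_index("group_id")
        eld_or_na = truth[truth["class"].isin(
            ["eld_ab", "eld_d", "nonadd_up", "nonadd_down"])]
        kinds = groups.loc[eld_or_na["group_id"].unique(), "class"]
        assert set(kinds) <= {"triplet", "duplet_AD", "duplet_BD"}
        singles = truth[truth["class"].str.startswith("singleton")]
        assert groups.loc[singles["group_id"].unique(), "class"] \
            .str.startswith("singleton").all()

    def test_category_fraction_overflow_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(frac_eld_ab=0.7, frac_eld_d=0.4).validate()

    def test_seeded_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(n_triplets=5, n_duplets=3, n_singletons_per_genome=2,
                        gene_length_range=(150, 300),
                        baseline_mean_range=(10.0, 30.0), seed=99)
        d1, d2 = tmp_path / "one", tmp_path / "two"
        p1 = write_experiment(d1, cfg, with_reads=True)
        p2 = write_experiment(d2, cfg, with_reads=True)
        assert set(p1) == set(p2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key


class TestSequences:
    def test_zero_divergence_identical_members(self):
        cfg = SimConfig(n_triplets=5, n_duplets=0, n_singletons_per_genome=0,
                        divergence_rate=0.0, seed=3)
        genes, _, _ = simulate_universe(cfg)
        seqs = simulate_sequences(genes, cfg)
        for _, sub in seqs.groupby("group_id"):
            assert sub["transcript"].nunique() == 1

    def test_singleton_groups_have_one_sequence(self):
        cfg = SimConfig(n_triplets=0, n_duplets=0, n_singletons_per_genome=4,
                        seed=4)
        genes, _, _ = simulate_universe(cfg)
        seqs = simulate_sequences(genes, cfg)
        assert (seqs.groupby("group_id").size() == 1).all()

    def test_pairwise_identity_matches_closed_form(self):
        cfg = SimConfig(n_triplets=200, n_duplets=0,
                        n_singletons_per_genome=0, divergence_rate=0.02,
                        gene_length_range=(999, 999), seed=5)
        genes, _, _ = simulate_universe(cfg)
        seqs = simulate_sequences(genes, cfg)
        idents = []
        for _, sub in seqs.groupby("group_id"):
            ts = sub["transcript"].tolist()
            for s1, s2 in itertools.combinations(ts, 2):
                same = sum(a == b for a, b in zip(s1, s2))
                idents.append(same / len(s1))
        expected = expected_pairwise_identity(0.02)
        assert abs(np.mean(idents) - expected) < 0.01 * expected

    def test_proteins_are_full_length_translations(self, small_config):
        genes, _, _ = simulate_universe(small_config)
        seqs = simulate_sequences(genes, small_config)
        assert (seqs["protein"].str.len() * 3
                == seqs["transcript"].str.len()).all()
        assert not seqs["protein"].str.contains(r"\*").any()


class TestCounts:
    def test_structural_zeros_in_parents(self, small_experiment):
        counts = small_experiment["counts"]
        truth = small_experiment["truth"].set_index("gene_id")
        d_genes = truth.index[truth["genome"] == "D"]
        ab_genes = truth.index[truth["genome"].isin(["A", "B"])]
        pab = [c for c in counts.columns if c.startswith("P_AB")]
        pdd = [c for c in counts.columns if c.startswith("P_D")]
        assert counts.loc[d_genes, pab].to_numpy().sum() == 0
        assert counts.loc[ab_genes, pdd].to_numpy().sum() == 0

    def test_poisson_limit_variance_mean_ratio(self, rng):
        draws = _nb_draw(rng, np.full(50_000, 500.0), 0.0)
        assert abs(draws.var() / draws.mean() - 1.0) < 0.03

    def test_planted_f1_suppression_hits_target_mean(self):
        cfg = SimConfig(n_triplets=1000, n_duplets=0,
                        n_singletons_per_genome=0,
                        baseline_mean_range=(400.0, 400.0),
                        frac_f1_d_down=1.0, frac_restored_in_s1=0.0,
                        frac_eld_ab=0.0, frac_eld_d=0.0,
                        frac_nonadditive_up=0.0, frac_nonadditive_down=0.0,
                        f1_down_log2fc=-2.0, seed=6)
        genes, _, truth = simulate_universe(cfg)
        counts, samples, factors = simulate_counts(truth, cfg)
        d_genes = truth.set_index("gene_id")
        d_genes = d_genes.index[d_genes["genome"] == "D"]
        f1_cols = [c for c in counts.columns if c.startswith("F1")]
        for col in f1_cols:
            depth_free = counts.loc[d_genes, col] / factors[col]
            assert abs(depth_free.mean() - 100.0) < 5.0

    def test_library_size_range_enforced(self):
        cfg = SimConfig(n_triplets=50, n_duplets=0, n_singletons_per_genome=0,
                        library_size_range=(30_000, 40_000), seed=7)
        _, _, truth = simulate_universe(cfg)
        counts, _, _ = simulate_counts(truth, cfg)
        totals = counts.sum(axis=0)
        # NB noise around the drawn target: allow a small margin
        assert (totals > 27_000).all() and (totals < 44_000).all()


class TestReads:
    def test_read_conservation_and_audit_tags(self, small_config):
        cfg = SimConfig(n_triplets=3, n_duplets=2, n_singletons_per_genome=1,
                        baseline_mean_range=(5.0, 15.0), seed=8)
        genes, _, truth = simulate_universe(cfg)
        seqs = simulate_sequences(genes, cfg)
        counts, _, _ = simulate_counts(truth, cfg)
        per_sample = {}
        per_gene = {}
        for sample, rid, read in simulate_reads(seqs, counts, cfg):
            per_sample[sample] = per_sample.get(sample, 0) + 1
            gene = rid.split("|")[0]
            per_gene[(sample, gene)] = per_gene.get((sample, gene), 0) + 1
            assert len(read) == cfg.read_length
        for sample in counts.columns:
            assert per_sample.get(sample, 0) == int(counts[sample].sum())
        for (sample, gene), n in per_gene.items():
            assert n == int(counts.loc[gene, sample])

    def test_error_free_reads_are_exact_substrings(self):
        cfg = SimConfig(n_triplets=2, n_duplets=0, n_singletons_per_genome=0,
                        baseline_mean_range=(10.0, 20.0),
                        read_error_rate=0.0, seed=9)
        genes, _, truth = simulate_universe(cfg)
        seqs = simulate_sequences(genes, cfg).set_index("gene_id")
        counts, _, _ = simulate_counts(truth, cfg)
        for sample, rid, read in simulate_reads(seqs.reset_index(), counts,
                                                cfg):
            gene = rid.split("|")[0]
            assert read in seqs.loc[gene, "transcript"]

    def test_error_rate_within_binomial_bounds(self):
        import edlib

        cfg = SimConfig(n_triplets=0, n_duplets=0, n_singletons_per_genome=1,
                        gene_length_range=(3000, 3000),
                        baseline_mean_range=(250.0, 250.0),
                        read_error_rate=0.01, read_length=100, seed=10)
        genes, _, truth = simulate_universe(cfg)
        truth.loc[:, "class"] = "singleton_expressed"
        for gt in ("P_AB", "P_D", "F1", "S1"):
            truth[f"mean_{gt}"] = 250.0
        seqs = simulate_sequences(genes, cfg).set_index("gene_id")
        counts, _, _ = simulate_counts(truth, cfg)
        errors = 0
        bases = 0
        for sample, rid, read in simulate_reads(seqs.reset_index(), counts,
                                                cfg):
            gene = rid.split("|")[0]
            res = edlib.align(read, seqs.loc[gene, "transcript"], mode="HW")
            errors += res["editDistance"]
            bases += len(read)
            if bases >= 100_000:
                break
        p = 0.01
        sd = np.sqrt(p * (1 - p) / bases)
        assert abs(errors / bases - p) < 3 * sd

    def test_read_length_exceeding_gene_length_rejected(self):
        with pytest.raises(ValueError, match="read_length"):
            SimConfig(gene_length_range=(80, 120), read_length=100).validate()


class TestTruthLedger:
    def test_group_summary_planted_deviations(self, small_experiment):
        tg = truth_group_summary(small_experiment["truth"])
        tg = tg.set_index("group_id")
        neutral = tg[tg["cls"] == "neutral"]
        multi = neutral[(neutral["n_ab"] > 0) & (neutral["n_d"] > 0)]
        assert np.allclose(multi["mpv_dev_f1"], 0.0, atol=1e-9)
        assert np.allclose(multi["parent_dev"].dropna(), 0.0, atol=1e-9)
        eld = tg[tg["cls"].isin(["eld_ab", "eld_d"])]
        assert (eld["parent_dev"].abs().round(6) == 1.5).all()
        na_up = tg[tg["cls"] == "nonadd_up"]
        assert (na_up["mpv_dev_f1"] > 0.5).all()
        na_down = tg[tg["cls"] == "nonadd_down"]
        assert (na_down["mpv_dev_f1"] < -0.5).all()
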