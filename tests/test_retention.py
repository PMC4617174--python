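"""Copy-class retention, flanking-neighbor extraction and the permutation test."""

import numpy as np
import pandas as pd
import pytest

from famevol.retention import (
    SUBGENOMES,
    SyntenyTableError,
    copy_counts,
    extract_neighbors,
    preferential_retention_test,
    retention_distribution,
    subgenome_retention,
    validate_synteny_table,
)
from famevol.simulate import SimulationConfig, ancestral_gene_order, gene_ids, simulate_fractionation


def make_order(genes_per_chrom):
    rows = []
    for c, genes in genes_per_chrom.items():
        for pos, g in enumerate(genes, start=1):
            rows.append((c, pos, g))
    return pd.DataFrame(rows, columns=["chrom", "position", "gene_id"])


class TestExtractNeighbors:
    def test_interior_focal_genes_yield_2k_neighbors_each(self):
        config = SimulationConfig(seed=0, n_genes=500, n_chromosomes=1)
        order = ancestral_gene_order(config)
        ids = gene_ids(config)
        focal = [ids[i] for i in range(50, 500, 45)][:10]
        sets = extract_neighbors(order, focal, k=10)
        assert sum(len(s.neighbor_ids) for s in sets) == 200

    def test_truncation_at_chromosome_start(self):
        order = make_order({"c1": [f"g{i}" for i in range(1, 30)]})
        (ns,) = extract_neighbors(order, ["g3"], k=10)
        assert len(ns.neighbor_ids) == 12  # 2 upstream + 10 downstream

    def test_matches_brute_force_window_scan(self):
        genes = [f"g{i}" for i in range(20)]
        order = make_order({"c1": genes})
        focal = ["g5", "g6", "g12"]
        k = 3
        sets = {s.focal_id: s.neighbor_ids for s in extract_neighbors(order, focal, k)}
        for f in focal:
            i = genes.index(f)
            expected = tuple(
                g
                for g in genes[max(0, i - k): i] + genes[i + 1: i + 1 + k]
                if g not in focal
            )
            assert sets[f] == expected

    def test_adjacent_focal_genes_excluded_but_windows_overlap(self):
        genes = [f"g{i}" for i in range(20)]
        order = make_order({"c1": genes})
        sets = extract_neighbors(order, ["g9", "g10"], k=1)
        assert sets[0].neighbor_ids == ("g8",)
        assert sets[1].neighbor_ids == ("g11",)

    def test_absent_focal_gene_raises(self):
        order = make_order({"c1": ["a", "b"]})
        with pytest.raises(KeyError):
            extract_neighbors(order, ["zzz"], k=2)


class TestRetentionDistribution:
    def test_family_fixture_reproduces_published_split(self, copy_table):
        genes = sorted(copy_table["ancestral_id"].unique())
        summary = retention_distribution(copy_table, genes)
        assert summary.percentages == {0: 0.0, 1: 60.0, 2: 30.0, 3: 10.0}
        assert summary.total_copies == 15

    def test_no_loss_gives_all_triplets(self):
        config = SimulationConfig(
            seed=1, n_genes=50, loss_prob={"LF": 0.0, "MF1": 0.0, "MF2": 0.0}
        )
        table = simulate_fractionation(config)
        summary = retention_distribution(table, gene_ids(config))
        assert summary.percentages[3] == 100.0

    def test_matches_per_gene_brute_force_tally(self):
        config = SimulationConfig(seed=9, n_genes=50)
        table = simulate_fractionation(config)
        ids = gene_ids(config)
        summary = retention_distribution(table, ids)
        brute = {c: 0 for c in range(4)}
        for g in ids:
            brute[len(table[table["ancestral_id"] == g])] += 1
        assert dict(summary.counts) == brute

    def test_percentages_sum_to_100_and_row_order_irrelevant(self):
        config = SimulationConfig(seed=2, n_genes=200)
        table = simulate_fractionation(config)
        ids = gene_ids(config)
        s1 = retention_distribution(table, ids)
        s2 = retention_distribution(table.sample(frac=1, random_state=0), ids)
        assert sum(s1.percentages.values()) == pytest.approx(100.0)
        assert s1.counts == s2.counts

    def test_empty_gene_list_rejected(self, copy_table):
        with pytest.raises(ValueError):
            retention_distribution(copy_table, [])

    def test_absent_genes_count_as_lost(self, copy_table):
        summary = retention_distribution(copy_table, ["not_a_gene", "SnRK2.1"])
        assert summary.counts[0] == 1 and summary.counts[3] == 1


class TestSubgenomeRetention:
    def test_no_loss_gives_equal_counts(self):
        config = SimulationConfig(
            seed=1, n_genes=40, loss_prob={"LF": 0.0, "MF1": 0.0, "MF2": 0.0}
        )
        table = simulate_fractionation(config)
        counts = subgenome_retention(table, gene_ids(config))
        assert len(set(counts.values())) == 1

    def test_biased_loss_orders_subgenomes(self):
        config = SimulationConfig(seed=3, n_genes=10000)
        table = simulate_fractionation(config)
        counts = subgenome_retention(table, gene_ids(config))
        assert counts["LF"] > counts["MF1"] > counts["MF2"]

    def test_family_fixture_is_lf_dominant(self, copy_table):
        genes = sorted(copy_table["ancestral_id"].unique())
        counts = subgenome_retention(copy_table, genes)
        assert counts["LF"] >= counts["MF1"] and counts["LF"] >= counts["MF2"]
        assert sum(counts.values()) == 15


class TestTableValidation:
    def test_duplicate_subgenome_copy_rejected(self):
        table = pd.DataFrame(
            {
                "ancestral_id": ["g1", "g1"],
                "copy_id": ["a", "b"],
                "subgenome": ["LF", "LF"],
            }
        )
        with pytest.raises(SyntenyTableError):
            validate_synteny_table(table)

    def test_unknown_subgenome_rejected(self):
        table = pd.DataFrame(
            {"ancestral_id": ["g1"], "copy_id": ["a"], "subgenome": ["XX"]}
        )
        with pytest.raises(SyntenyTableError):
            validate_synteny_table(table)


class TestPreferentialRetentionTest:
    def test_identical_groups_give_null_result(self):
        res = preferential_retention_test([1, 2, 3], [1, 2, 3], n_perm=199, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_small_n_perm_rejected(self):
        with pytest.raises(ValueError):
            preferential_retention_test([1], [2], n_perm=99)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(0)
        f = rng.integers(0, 4, 10)
        n = rng.integers(0, 4, 200)
        r1 = preferential_retention_test(f, n, n_perm=299, seed=5)
        r2 = preferential_retention_test(f, n, n_perm=299, seed=5)
        assert r1 == r2

    def test_null_rejection_rate_is_near_nominal(self):
        """Quick calibration check (the full 1000-run suite is in the
        acceptance tests): under exchangeable groups the 0.05-level
        rejection rate stays near 0.05."""
        rng = np.random.default_rng(123)
        keep_prob = [0.7, 0.45, 0.35]
        rejections = 0
        runs = 200
        for _ in range(runs):
            counts = rng.binomial(1, keep_prob, size=(210, 3)).sum(axis=1)
            res = preferential_retention_test(
                counts[:10], counts[10:], n_perm=299, seed=int(rng.integers(2**31))
            )
            rejections += res.p_value < 0.05
        assert 0.01 <= rejections / runs <= 0.11

    def test_detects_planted_retention_bias(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(50):
            focal = rng.binomial(1, [0.91, 0.835, 0.805], size=(10, 3)).sum(axis=1)
            neigh = rng.binomial(1, [0.7, 0.45, 0.35], size=(200, 3)).sum(axis=1)
            res = preferential_retention_test(
                focal, neigh, n_perm=299, seed=int(rng.integers(2**31))
            )
            hits += res.p_value < 0.05
        assert hits / 50 >= 0.5

    def test_fisher_contingency_secondary_check(self):
        res = preferential_retention_test(
            [1] * 8, [0] * 8 + [1] * 2, n_perm=199, seed=1
        )
        assert res.fisher_p < 0.05
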