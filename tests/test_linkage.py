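import numpy as np
import pytest

from ssrid.errors import UndefinedStatisticError, ValidationError
from ssrid.linkage import ld_test_pair, linkage_groups, select_representatives
from ssrid.synthetic_data import SimConfig, simulate_dataset

from conftest import build_matrix

# the six multi-locus groups reported for the 36-marker panel
REPORTED_GROUPS = [
    ["Cred35", "Cred229", "Cred277"],
    ["Cred47", "Cred298"],
    ["Cred231", "Cred249", "Cred253", "Cred262"],
    ["Cred281", "Cred297"],
    ["Cred603", "Cred683"],
    ["Cred640", "Cred678", "Cred682"],
]
OTHER_LOCI = [f"CredX{k}" for k in range(36 - sum(len(g) for g in REPORTED_GROUPS))]
ALL_LOCI = [l for g in REPORTED_GROUPS for l in g] + OTHER_LOCI


class TestLdTestPair:
    def test_perfect_linkage_is_significant(self):
        cfg = SimConfig(n_pops=1, pop_sizes=(50,), n_loci=2, alleles_min=3, alleles_max=3,
                        linked_groups=[[0, 1]], seed=5)
        m, _ = simulate_dataset(cfg)
        p = ld_test_pair(m, "L001", "L002", reps=10_000, seed=42)
        assert p <= 0.001

    def test_degenerate_single_cell_table(self):
        m = build_matrix([[(1, 1), (2, 2)], [(1, 1), (2, 2)], [(1, 1), (2, 2)]])
        assert ld_test_pair(m, "L1", "L2", reps=100, seed=0) == 1.0

    def test_too_few_shared_individuals(self):
        m = build_matrix([[(1, 1), None], [None, (2, 2)], [(1, 2), (2, 3)]])
        with pytest.raises(UndefinedStatisticError):
            ld_test_pair(m, "L1", "L2", reps=100, seed=0)

    def test_requires_seed(self, toy_matrix):
        with pytest.raises(ValueError, match="seed"):
            ld_test_pair(toy_matrix, "L1", "L2", reps=100)

    def test_independent_loci_p_roughly_uniform(self):
        # rejection rate at alpha = 0.05 should sit near 0.05
        rejections = 0
        n_pairs = 1000
        for seed in range(n_pairs):
            cfg = SimConfig(n_pops=1, pop_sizes=(50,), n_loci=2, alleles_min=3,
                            alleles_max=3, seed=seed)
            m, _ = simulate_dataset(cfg)
            p = ld_test_pair(m, "L001", "L002", reps=200, seed=10_000 + seed)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_pairs <= 0.07


class TestLinkageGroups:
    def test_transitive_closure(self):
        loci = ["L1", "L2", "L3", "L4"]
        pvals = {("L1", "L2"): 1e-5, ("L2", "L3"): 1e-4, ("L1", "L3"): 0.5, ("L3", "L4"): 0.9}
        s = linkage_groups(pvals, loci, alpha=0.001)
        assert ["L1", "L2", "L3"] in s.groups
        assert ["L4"] in s.groups

    def test_no_significant_pairs_all_singletons(self):
        loci = ["L1", "L2", "L3"]
        pvals = {("L1", "L2"): 0.5, ("L2", "L3"): 0.2, ("L1", "L3"): 0.9}
        s = linkage_groups(pvals, loci, alpha=0.001)
        assert sorted(map(tuple, s.groups)) == [("L1",), ("L2",), ("L3",)]

    def test_reported_six_group_structure(self):
        # synthetic p-values: within-group pairs significant, all others not
        pvals = {}
        for g in REPORTED_GROUPS:
            for i in range(len(g)):
                for j in range(i + 1, len(g)):
                    pvals[tuple(sorted((g[i], g[j])))] = 1e-6
        s = linkage_groups(pvals, ALL_LOCI, alpha=0.001)
        multi = [g for g in s.groups if len(g) > 1]
        assert sorted(len(g) for g in multi) == [2, 2, 2, 3, 3, 4]
        for g in REPORTED_GROUPS:
            assert sorted(g) in s.groups
        # 36 loci - 16 grouped + 6 representatives = 26 usable
        s = select_representatives(s, {l: 0.5 for l in ALL_LOCI})
        assert len(s.representatives) == 26

    def test_partition_covers_locus_set(self):
        pvals = {("L1", "L2"): 1e-9}
        s = linkage_groups(pvals, ["L1", "L2", "L3"], alpha=0.001)
        flattened = sorted(l for g in s.groups for l in g)
        assert flattened == ["L1", "L2", "L3"]

    def test_grouping_independent_of_input_order(self):
        pvals = {("L1", "L2"): 1e-5, ("L2", "L3"): 1e-5}
        a = linkage_groups(pvals, ["L1", "L2", "L3", "L4"], alpha=0.001)
        b = linkage_groups(dict(reversed(list(pvals.items()))),
                           ["L4", "L3", "L2", "L1"], alpha=0.001)
        assert a.groups == b.groups

    def test_adding_edge_never_increases_group_count(self):
        rng = np.random.default_rng(0)
        loci = [f"L{k}" for k in range(8)]
        pvals = {}
        prev = len(linkage_groups(pvals, loci).groups)
        for _ in range(15):
            i, j = rng.choice(8, size=2, replace=False)
            pvals[tuple(sorted((loci[i], loci[j])))] = 0.0
            now = len(linkage_groups(pvals, loci).groups)
            assert now <= prev
            prev = now

    def test_clique_method_splits_non_clique_chain(self):
        pvals = {("L1", "L2"): 1e-5, ("L2", "L3"): 1e-5, ("L1", "L3"): 0.9}
        s = linkage_groups(pvals, ["L1", "L2", "L3"], alpha=0.001, method="cliques")
        assert all(len(g) <= 2 for g in s.groups)


class TestRepresentatives:
    def test_lowest_pi_wins(self):
        s = linkage_groups({("a", "b"): 1e-9}, ["a", "b"], alpha=0.001)
        s = select_representatives(s, {"a": 0.3, "b": 0.2})
        assert s.representatives == ["b"]

    def test_tie_breaks_lexicographically(self):
        s = linkage_groups({("a", "b"): 1e-9}, ["a", "b"], alpha=0.001)
        s = select_representatives(s, {"a": 0.2, "b": 0.2})
        assert s.representatives == ["a"]

    def test_missing_pi_names_locus(self):
        s = linkage_groups({("a", "b"): 1e-9}, ["a", "b"], alpha=0.001)
        with pytest.raises(ValidationError, match="b"):
            select_representatives(s, {"a": 0.2})

    def test_representative_pi_is_group_minimum(self):
        rng = np.random.default_rng(1)
        loci = [f"L{k}" for k in range(10)]
        pvals = {}
        for _ in range(6):
            i, j = rng.choice(10, size=2, replace=False)
            pvals[tuple(sorted((loci[i], loci[j])))] = 0.0
        pis = {l: float(rng.uniform(0.05, 0.9)) for l in loci}
        s = select_representatives(linkage_groups(pvals, loci), pis)
        for g in s.groups:
            rep = s.representative_of[tuple(g)]
            assert pis[rep] <= min(pis[l] for l in g)
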