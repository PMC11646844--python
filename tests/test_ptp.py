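import math

import numpy as np
import pytest

from clonedelim.partition import Partition
from clonedelim.metrics import repertoire_metrics
from clonedelim.ptp import (
    Delimitation,
    TreeIndex,
    delimit_clones,
    enumerate_delimitations,
    exponential_fit,
    score_delimitation,
    search_delimitation,
)
from clonedelim.trees import midpoint_root, nj_tree, pairwise_distances, parse_newick
from conftest import random_binary_tree, two_regime_tree


class TestExponentialFit:
    def test_unit_lengths(self):
        rate, loglik = exponential_fit([1, 1, 1, 1])
        assert rate == pytest.approx(1.0)
        assert loglik == pytest.approx(-4.0)

    def test_single_observation(self):
        rate, loglik = exponential_fit([2])
        assert rate == pytest.approx(0.5)
        assert loglik == pytest.approx(math.log(0.5) - 1)

    def test_ml_consistency(self):
        rng = np.random.default_rng(0)
        sample = rng.exponential(1 / 3, size=10_000)
        rate, _ = exponential_fit(sample)
        se = 3 / math.sqrt(sample.size)  # asymptotic SE of the ML rate
        assert abs(rate - 3) < 3 * se

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            exponential_fit([])

    def test_short_branches_floored(self):
        rate_floored, _ = exponential_fit([0.0, 1.0], min_branch_length=1e-3)
        assert rate_floored == pytest.approx(2 / 1.001)


class TestScoreDelimitation:
    def test_null_model_closed_form(self):
        # rooted 3-leaf tree: 4 edges of 0.5 each
        tree = parse_newick("((A:0.5,B:0.5):0.5,C:0.5);")
        idx = TreeIndex(tree)
        score = score_delimitation(Delimitation(idx, frozenset()))
        assert score.k == 1
        assert score.rates["coalescent"] == pytest.approx(2.0)
        assert score.loglik == pytest.approx(4 * (math.log(2) - 1))
        assert score.aic == pytest.approx(2 - 8 * (math.log(2) - 1))

    def test_aic_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            idx = TreeIndex(random_binary_tree(7, rng))
            for d in enumerate_delimitations(idx):
                for mode in ("single_rate", "multi_rate"):
                    s = score_delimitation(d, mode)
                    assert s.aic == pytest.approx(2 * s.k - 2 * s.loglik)

    def test_single_and_multi_agree_with_one_coalescent_subtree(self):
        # root's children: a leaf (zero-edge subtree) and a 3-leaf clade
        tree = parse_newick("(((A:0.1,B:0.2):0.3,C:0.4):0.5,D:0.6);")
        idx = TreeIndex(tree)
        root_only = Delimitation(idx, frozenset({idx.root}))
        single = score_delimitation(root_only, "single_rate")
        multi = score_delimitation(root_only, "multi_rate")
        assert single.loglik == pytest.approx(multi.loglik)
        assert single.k == multi.k == 2

    def test_multi_rate_k_dominates_single_rate(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            idx = TreeIndex(random_binary_tree(8, rng))
            for d in enumerate_delimitations(idx):
                s1 = score_delimitation(d, "single_rate")
                s2 = score_delimitation(d, "multi_rate")
                nonempty = sum(1 for lens in d.coalescent_edge_lengths() if lens.size)
                assert s2.k >= s1.k
                if nonempty <= 1:
                    assert s2.k == s1.k


class TestEnumeration:
    def test_two_leaf_tree_has_two_delimitations(self):
        idx = TreeIndex(parse_newick("(A:1,B:2);"))
        delims = enumerate_delimitations(idx)
        assert len(delims) == 2
        assert sorted(len(d.speciation_nodes) for d in delims) == [0, 1]

    def test_balanced_four_leaf_tree_has_five(self):
        idx = TreeIndex(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        assert idx.count_delimitations() == 5
        assert len(enumerate_delimitations(idx)) == 5

    def test_count_matches_enumeration_on_random_trees(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            idx = TreeIndex(random_binary_tree(int(rng.integers(3, 10)), rng))
            assert len(enumerate_delimitations(idx)) == idx.count_delimitations()

    def test_max_count_violation(self):
        idx = TreeIndex(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        with pytest.raises(ValueError, match="exceed"):
            enumerate_delimitations(idx, max_count=1)

    def test_delimitations_partition_all_leaves(self):
        rng = np.random.default_rng(4)
        idx = TreeIndex(random_binary_tree(9, rng))
        leaves = {idx.leaf_name[i] for i in range(len(idx.nodes)) if idx.is_leaf[i]}
        for d in enumerate_delimitations(idx):
            families = d.families()
            flat = [name for fam in families for name in fam]
            assert sorted(flat) == sorted(leaves)


class TestSearch:
    def test_matches_exhaustive_minimum_on_small_trees(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            idx = TreeIndex(random_binary_tree(int(rng.integers(4, 11)), rng))
            best = min(score_delimitation(d).aic for d in enumerate_delimitations(idx))
            _, score = search_delimitation(idx)
            assert score.aic == pytest.approx(best)

    def test_two_clade_tree_recovers_both_families(self):
        rng = np.random.default_rng(6)
        tree = two_regime_tree(2, 5, 1 / 2.0, 1 / 0.001, rng)
        d, _ = search_delimitation(tree)
        families = sorted(sorted(f) for f in d.families())
        assert len(families) == 2
        assert all(len(f) == 5 for f in families)
        assert {f[0][:2] for f in families} == {"f0", "f1"}

    def test_null_model_wins_when_edges_are_homogeneous(self):
        # with identical edge lengths no split can improve the likelihood,
        # so the extra rate parameter makes every alternative lose on AIC
        rng = np.random.default_rng(1000)
        tree = random_binary_tree(10, rng)
        for node in tree.traverse(include_self=False):
            node.length = 0.3
        d, score = search_delimitation(tree)
        assert d.n_families == 1
        assert score.k == 1

    def test_fewer_families_under_single_regime_than_two_regime(self):
        # iid-exponential trees lack the between/within signal, so the
        # delimiter splits them far less than genuinely two-regime trees
        single, double = [], []
        for t in range(20):
            rng = np.random.default_rng(3000 + t)
            d1, _ = search_delimitation(random_binary_tree(12, rng, mean_edge=0.3))
            single.append(d1.n_families)
            rng = np.random.default_rng(4000 + t)
            d2, _ = search_delimitation(two_regime_tree(6, 2, 1.0, 100.0, rng))
            double.append(d2.n_families)
        assert np.mean(single) < np.mean(double)

    def test_two_regime_recovery_rate(self):
        hits = 0
        for t in range(25):
            rng = np.random.default_rng(2000 + t)
            tree = two_regime_tree(6, 6, 1.0, 100.0, rng)
            d, _ = search_delimitation(tree)
            hits += d.n_families == 6
        assert hits >= 22


class TestDelimitClones:
    def test_partition_covers_every_leaf_once(self):
        rng = np.random.default_rng(7)
        tree = two_regime_tree(4, 5, 1.0, 100.0, rng)
        part, score = delimit_clones(tree)
        assert sorted(part.ids()) == sorted(t.name for t in tree.tips())
        assert score.aic == pytest.approx(2 * score.k - 2 * score.loglik)

    def test_unrooted_input_is_midpoint_rooted_with_warning(self):
        unrooted = parse_newick("(A:1,B:1,(C:0.01,D:0.01):1);")
        assert len(unrooted.children) == 3
        with pytest.warns(UserWarning, match="midpoint"):
            part, _ = delimit_clones(unrooted)
        assert sorted(part.ids()) == ["A", "B", "C", "D"]

    def test_beats_random_partition_on_simulated_repertoire(self, repertoire_low_shm):
        truth = repertoire_low_shm.truth_partition()
        dm = pairwise_distances(repertoire_low_shm.sequences(), model="edit")
        tree = midpoint_root(nj_tree(dm))
        part, _ = delimit_clones(tree)
        ptp_f1 = repertoire_metrics(truth, part, drop_singletons=False).mean_f1

        rng = np.random.default_rng(11)
        ids = list(part.assignment)
        labels = list(part.assignment.values())
        rng.shuffle(labels)  # random partition with identical cluster sizes
        random_part = Partition(dict(zip(ids, labels)))
        random_f1 = repertoire_metrics(truth, random_part, drop_singletons=False).mean_f1
        assert ptp_f1 > random_f1
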