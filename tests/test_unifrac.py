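"""The UniFrac distance, its permutation test and branch significance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_unifrac, make_embedding, make_tree
from scunifrac import (CountMatrix, RunConfig, compare_pair,
                       permutation_test, unifrac_distance)
from scunifrac.tree import BranchCounts, ClusterAssignment
from scunifrac.unifrac import significant_branches


def counts_from_leaves(tree, leaf_a, leaf_b):
    M = tree.leaf_membership()
    leaf_a = np.asarray(leaf_a)
    leaf_b = np.asarray(leaf_b)
    return BranchCounts(a=M @ leaf_a, b=M @ leaf_b,
                        a_total=int(leaf_a.sum()), b_total=int(leaf_b.sum()),
                        label_a="A", label_b="B")


# rooted binary shapes with 2-4 leaves: (parent array, k)
TOPOLOGIES = {
    "star2": ([2, 2, -1], 2),
    "three": ([3, 3, 4, 4, -1], 3),                 # ((1,2),3)
    "caterpillar4": ([4, 4, 5, 6, 5, 6, -1], 4),    # (((1,2),3),4)
    "balanced4": ([4, 4, 5, 5, 6, 6, -1], 4),       # ((1,2),(3,4))
}


class TestDistance:
    def test_equal_proportions_give_zero(self):
        parent, k = TOPOLOGIES["three"]
        tree = make_tree(parent, [1.0, 0.5, 2.0, 0.7, 0.0], k)
        c = counts_from_leaves(tree, [4, 2, 6], [8, 4, 12])
        assert unifrac_distance(tree, c) == pytest.approx(0.0, abs=1e-15)

    def test_hand_worked_star_values(self):
        tree = make_tree([2, 2, -1], [1.0, 1.0, 0.0], 2)
        assert unifrac_distance(tree, counts_from_leaves(tree, [10, 0], [0, 10])) \
            == pytest.approx(1.0, abs=1e-12)
        assert unifrac_distance(tree, counts_from_leaves(tree, [8, 2], [2, 8])) \
            == pytest.approx(0.6, abs=1e-12)

    def test_disjoint_samples_give_one(self):
        # whenever every branch is pure, the numerator telescopes to the denominator
        rng = np.random.default_rng(0)
        for _ in range(50):
            name = rng.choice(list(TOPOLOGIES))
            parent, k = TOPOLOGIES[name]
            tree = make_tree(parent, rng.uniform(0.1, 3, 2 * k - 1), k)
            split = rng.integers(1, k)
            leaf_a = np.zeros(k, int)
            leaf_b = np.zeros(k, int)
            leaf_a[:split] = rng.integers(1, 9, split)
            leaf_b[split:] = rng.integers(1, 9, k - split)
            d = unifrac_distance(tree, counts_from_leaves(tree, leaf_a, leaf_b))
            # D = 1 needs every branch pure, which depends on how the split
            # aligns with the topology; assert the oracle value and the range
            assert d == pytest.approx(
                brute_force_unifrac(tree, leaf_a, leaf_b), abs=1e-12)
            assert 0 <= d <= 1 + 1e-12

    def test_fully_separated_star_is_one(self):
        parent, k = TOPOLOGIES["balanced4"]
        tree = make_tree(parent, [0.3, 0.9, 1.2, 0.4, 0.8, 0.5, 0.0], 4)
        d = unifrac_distance(tree, counts_from_leaves(tree, [3, 5, 0, 0],
                                                      [0, 0, 2, 7]))
        assert d == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self):
        parent, k = TOPOLOGIES["caterpillar4"]
        tree = make_tree(parent, [1.0, 0.2, 0.8, 1.5, 0.3, 0.6, 0.0], 4)
        la, lb = [5, 0, 2, 1], [1, 3, 0, 4]
        assert unifrac_distance(tree, counts_from_leaves(tree, la, lb)) == \
            unifrac_distance(tree, counts_from_leaves(tree, lb, la))

    def test_k1_short_circuit(self):
        assert unifrac_distance(None, None) == 0.0

    def test_oracle_equivalence_exhaustive_small_trees(self):
        """Sweep trees with <=4 leaves and integer leaf counts <=5 against an
        independently coded evaluation of the distance equation."""
        rng = np.random.default_rng(42)
        checked = 0
        for name, (parent, k) in TOPOLOGIES.items():
            for trial in range(2):
                blen = rng.uniform(0.1, 2.0, 2 * k - 1)
                blen[-1] = 0.0
                tree = make_tree(parent, blen, k)
                if k <= 3:  # exhaustive counts in {0..5}^k per sample
                    combos = itertools.product(
                        itertools.product(range(6), repeat=k), repeat=2)
                else:       # 4 leaves: seeded random draws
                    combos = ((tuple(rng.integers(0, 6, 4)),
                               tuple(rng.integers(0, 6, 4)))
                              for _ in range(600))
                for la, lb in combos:
                    if sum(la) == 0 or sum(lb) == 0:
                        continue
                    got = unifrac_distance(tree,
                                           counts_from_leaves(tree, la, lb))
                    want = brute_force_unifrac(tree, la, lb)
                    assert got == pytest.approx(want, abs=1e-12)
                    checked += 1
        assert checked > 5000

    def test_matches_reference_weighted_unifrac(self):
        """Dual route: the implementation vs scikit-bio's normalized weighted
        UniFrac on the exported Newick tree."""
        import skbio
        from skbio.diversity.beta import weighted_unifrac
        rng = np.random.default_rng(17)
        for _ in range(20):
            k = int(rng.integers(2, 8))
            emb = make_embedding(rng.normal(size=(k, 3)))
            assign = ClusterAssignment(emb.cell_ids, np.arange(1, k + 1), k)
            from scunifrac import build_tree
            tree = build_tree(emb, assign)
            leaf_a = rng.integers(0, 20, k)
            leaf_b = rng.integers(0, 20, k)
            if leaf_a.sum() == 0 or leaf_b.sum() == 0:
                continue
            got = unifrac_distance(tree, counts_from_leaves(tree, leaf_a, leaf_b))
            sk_tree = skbio.TreeNode.read([tree.to_newick()])
            want = weighted_unifrac(leaf_a, leaf_b,
                                    taxa=[f"cluster{j + 1}" for j in range(k)],
                                    tree=sk_tree, normalized=True)
            assert got == pytest.approx(float(want), abs=1e-9)


class TestPermutationTest:
    def _fixture(self, labels, clusters, blen=(1.0, 1.0, 0.0)):
        cells = pd.Index([f"c{i}" for i in range(len(labels))])
        assign = ClusterAssignment(cells, np.asarray(clusters), 2)
        tree = make_tree([2, 2, -1], list(blen), 2)
        return tree, assign, pd.Series(list(labels), index=cells)

    def test_zero_distance_gives_p_one(self):
        tree, assign, labels = self._fixture("ABAB", [1, 1, 2, 2])
        res = permutation_test(tree, assign, labels, n_permutations=100, seed=0)
        assert res.distance == 0.0 and res.p_value == 1.0

    def test_exhaustive_null_on_four_cells(self):
        """Monte-Carlo null frequencies match exhaustive enumeration of the
        6 label arrangements of 2 A's among 4 cells, within 3 SE."""
        tree, assign, labels = self._fixture("AABB", [1, 1, 2, 2])
        # independent enumeration: choose which 2 of 4 cells are A
        exact = {}
        for apos in itertools.combinations(range(4), 2):
            la = [sum(1 for c in apos if assign.cluster_of[c] == j + 1)
                  for j in range(2)]
            lb = [sum(1 for c in range(4) if c not in apos
                      and assign.cluster_of[c] == j + 1) for j in range(2)]
            d = round(brute_force_unifrac(tree, la, lb), 12)
            exact[d] = exact.get(d, 0) + 1 / 6
        res = permutation_test(tree, assign, labels, n_permutations=10000,
                               seed=1)
        null = np.round(res.null_distances, 12)
        for value, freq in exact.items():
            got = float(np.mean(null == value))
            se = np.sqrt(freq * (1 - freq) / 10000)
            assert abs(got - freq) <= 3 * se + 1e-12
        assert set(np.unique(null)) <= set(exact)

    def test_reproducible_given_seed(self):
        tree, assign, labels = self._fixture("AABB", [1, 1, 2, 2])
        r1 = permutation_test(tree, assign, labels, 50, seed=9)
        r2 = permutation_test(tree, assign, labels, 50, seed=9)
        assert np.array_equal(r1.null_distances, r2.null_distances)

    def test_conservative_p_never_zero(self):
        tree, assign, labels = self._fixture("AABB", [1, 1, 2, 2])
        res = permutation_test(tree, assign, labels, 100, seed=2,
                               conservative_p=True)
        assert res.p_value >= 1 / 101


class TestSignificantBranches:
    def test_identical_samples_flag_nothing(self):
        cells = pd.Index([f"c{i}" for i in range(40)])
        assign = ClusterAssignment(cells, np.array([1] * 20 + [2] * 20), 2)
        tree = make_tree([2, 2, -1], [1.0, 1.0, 0.0], 2)
        labels = pd.Series(["A", "B"] * 20, index=cells)
        res = permutation_test(tree, assign, labels, 200, seed=0)
        table = significant_branches(res)
        assert not table["significant"].any()
        assert (table["ps"] <= 1e-12).all()

    def test_planted_shifted_cluster_detected(self):
        """Each sample gets a private cluster (30% of its cells) plus two
        shared, proportionally balanced clusters; the private leaves are
        flagged and the balanced leaves are not, across 20 seeded reps."""
        rng = np.random.default_rng(0)
        reps, hits, false = 20, 0, 0
        centers = np.array([[0, 0], [20, 0], [0, 20], [20, 20]], float)
        design = [(150, 0), (175, 175), (175, 175), (0, 150)]  # (A, B) cells
        for rep in range(reps):
            coords, labels = [], []
            for center, (na, nb) in zip(centers, design):
                coords.append(center + rng.normal(0, 1, (na + nb, 2)))
                labels += ["A"] * na + ["B"] * nb
            emb = make_embedding(np.vstack(coords), labels=labels)
            from scunifrac import build_tree, cluster_cells, count_branches
            assign = cluster_cells(emb, k=4)
            tree = build_tree(emb, assign)
            res = permutation_test(tree, assign, emb.sample_labels, 500,
                                   seed=rep)
            table = significant_branches(res)
            counts = count_branches(tree, assign, emb.sample_labels)
            pure = [j for j in range(4)
                    if counts.a[j] == 0 or counts.b[j] == 0]
            shared = [j for j in range(4) if j not in pure]
            assert len(pure) == 2
            hits += all(table.loc[j, "significant"] for j in pure)
            false += sum(bool(table.loc[j, "significant"]) for j in shared)
        assert hits >= 0.95 * reps
        assert false <= 0.05 * 2 * reps + 2

    def test_alpha_validated(self):
        tree = make_tree([2, 2, -1], [1.0, 1.0, 0.0], 2)
        cells = pd.Index(["c0", "c1"])
        assign = ClusterAssignment(cells, np.array([1, 2]), 2)
        labels = pd.Series(["A", "B"], index=cells)
        res = permutation_test(tree, assign, labels, 10, seed=0)
        with pytest.raises(ValueError):
            significant_branches(res, alpha=1.5)


class TestComparePair:
    def test_self_comparison_is_zero(self, two_blob_counts):
        a, _ = two_blob_counts
        twin = CountMatrix(a.values.copy(), "copy")
        cmp = compare_pair(a, twin, RunConfig(hvg_count=200, n_permutations=50,
                                              seed=1))
        assert cmp.result.distance == 0.0
        assert cmp.result.p_value == 1.0

    def test_disjoint_populations_reach_one(self, two_blob_counts):
        a, b = two_blob_counts
        cmp = compare_pair(a, b, RunConfig(hvg_count=200, n_permutations=100,
                                           seed=2))
        assert cmp.result.distance == pytest.approx(1.0, abs=1e-9)
        assert cmp.result.p_value <= 0.01

    def test_symmetry_of_roles(self, two_blob_counts):
        a, b = two_blob_counts
        cfg = RunConfig(hvg_count=200, n_permutations=50, seed=3)
        d_ab = compare_pair(a, b, cfg).result.distance
        d_ba = compare_pair(b, a, cfg).result.distance
        assert d_ab == pytest.approx(d_ba, abs=1e-12)
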