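"""Hierarchy handling, weighted label variance, split search, tree
growth, forests and Genie3 importance."""

import numpy as np
import pytest

from dysbiota.hmc_forest import (
    DEFAULT_HIERARCHY_PATHS,
    NodeWeights,
    best_split,
    build_hierarchy,
    genie3_importance,
    grow_pct,
    label_vector,
    predict,
    predict_tree,
    train_forest,
    weighted_variance,
)


@pytest.fixture(scope="module")
def hier():
    return build_hierarchy(DEFAULT_HIERARCHY_PATHS)


@pytest.fixture(scope="module")
def weights(hier):
    return NodeWeights.from_hierarchy(hier, w0=0.75)


class TestHierarchy:
    def test_default_paths_give_nine_nodes_depths_0_to_3(self, hier):
        assert len(hier.nodes) == 9
        assert hier.depth[hier.root] == 0
        assert max(hier.depth.values()) == 3
        assert hier.parent["CD"] == "IBD" and hier.parent["IBD"] == "HP"

    def test_single_path(self):
        h = build_hierarchy(["A/B"])
        assert h.nodes == ["A", "B"] and h.parent["B"] == "A"

    def test_two_roots_rejected(self):
        with pytest.raises(ValueError, match="root"):
            build_hierarchy(["A/B", "C/B"])

    def test_conflicting_parents_rejected(self):
        with pytest.raises(ValueError, match="conflicting parents"):
            build_hierarchy(["A/B/D", "A/C/D"])


class TestLabelVector:
    def test_tumor_path(self, hier):
        v = label_vector("Tumor", hier)
        on = {n for n, x in zip(hier.nodes, v) if x == 1}
        assert on == {"Subject", "HP", "Tumor"}
        assert v.sum() == 3

    def test_root_only(self, hier):
        v = label_vector("Subject", hier)
        assert v.sum() == 1 and v[hier.index("Subject")] == 1

    def test_cd_path(self, hier):
        v = label_vector("CD", hier)
        on = {n for n, x in zip(hier.nodes, v) if x == 1}
        assert on == {"Subject", "HP", "IBD", "CD"}

    def test_unknown_leaf_rejected(self, hier):
        with pytest.raises(ValueError):
            label_vector("Gout", hier)

    def test_hierarchy_consistency_of_all_leaves(self, hier):
        for leaf in ("NHC", "CD", "UC", "Tumor", "Infection", "Other"):
            v = label_vector(leaf, hier)
            for node in hier.nodes:
                par = hier.parent[node]
                if par is not None:
                    assert v[hier.index(node)] <= v[hier.index(par)]


class TestWeightedVariance:
    def test_identical_vectors_zero(self, hier, weights):
        vs = np.vstack([label_vector("CD", hier)] * 4)
        assert weighted_variance(vs, weights) == 0.0

    def test_two_point_closed_form(self, hier, weights):
        # two samples differing only at one depth-2 node:
        # Var = (1/2) * 2 * w0^2 * 0.5^2 = 0.140625 at w0 = 0.75
        i = hier.index("IBD")
        assert hier.depth["IBD"] == 2
        a = np.zeros(9)
        b = np.zeros(9)
        b[i] = 1.0
        assert weighted_variance(np.vstack([a, b]), weights) == pytest.approx(0.75**2 * 0.25)

    def test_matches_double_loop_oracle(self, hier, weights, rng):
        for _ in range(20):
            vs = rng.random((int(rng.integers(2, 8)), 9))
            mean = vs.mean(axis=0)
            oracle = np.mean([np.sum(weights.w * (v - mean) ** 2) for v in vs])
            assert weighted_variance(vs, weights) == pytest.approx(oracle, abs=1e-12)


def exhaustive_best_split(x, y, w, min_leaf=1):
    """Independent enumeration over every (feature, midpoint) pair."""
    n, p = x.shape

    def var(v):
        if len(v) == 0:
            return 0.0
        m = v.mean(axis=0)
        return float(np.mean([(w * (r - m) ** 2).sum() for r in v]))

    total = var(y)
    best = None
    for f in range(p):
        vals = np.unique(x[:, f])
        for a, b in zip(vals, vals[1:]):
            thr = (a + b) / 2
            mask = x[:, f] <= thr
            if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
                continue
            red = total - mask.mean() * var(y[mask]) - (~mask).mean() * var(y[~mask])
            if red > 1e-12 and (best is None or red > best[2] + 1e-12):
                best = (f, thr, red)
    return best


class TestBestSplit:
    def test_perfect_separator_takes_full_variance(self, hier, weights):
        y = np.vstack([label_vector("NHC", hier)] * 3 + [label_vector("Tumor", hier)] * 3)
        x = np.array([[0.0], [0.1], [0.2], [1.0], [1.1], [1.2]])
        f, thr, red = best_split(x, y, weights)
        assert f == 0 and 0.2 < thr < 1.0
        assert red == pytest.approx(weighted_variance(y, weights), abs=1e-12)

    def test_matches_exhaustive_oracle(self, hier, weights, rng):
        leaves = ["NHC", "CD", "UC", "Tumor", "Infection", "Other"]
        for _ in range(60):
            n = int(rng.integers(2, 9))
            x = np.round(rng.random((n, 3)), 2)
            y = np.vstack([label_vector(leaves[i], hier) for i in rng.integers(0, 6, n)])
            ours = best_split(x, y, weights)
            oracle = exhaustive_best_split(x, y, weights.w)
            if oracle is None:
                assert ours is None
            else:
                assert ours is not None
                assert ours[2] == pytest.approx(oracle[2], abs=1e-10)

    def test_homogeneous_labels_return_none(self, hier, weights, rng):
        y = np.vstack([label_vector("CD", hier)] * 5)
        x = rng.random((5, 3))
        assert best_split(x, y, weights) is None


class TestGrowPct:
    def test_homogeneous_labels_single_leaf(self, hier, weights):
        y = np.vstack([label_vector("UC", hier)] * 6)
        x = np.random.default_rng(0).random((6, 4))
        tree = grow_pct(x, y, weights)
        assert tree.is_leaf
        np.testing.assert_allclose(tree.prototype, y[0])

    def test_exact_xor_cannot_be_split_greedily(self, hier, weights):
        # every single split of a perfect XOR leaves the children with
        # the parent's label mix (zero variance reduction), so the root
        # becomes a leaf
        x = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.vstack(
            [label_vector(l, hier) for l in ("NHC", "Tumor", "Tumor", "NHC")]
        )
        tree = grow_pct(x, y, weights, min_leaf=1)
        assert tree.is_leaf

    def test_broken_xor_recovered_at_depth_two(self, hier, weights):
        # one duplicated corner breaks the tie and the interaction is
        # then carved out over two levels with pure leaves
        x = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        labels = ("NHC", "Tumor", "Tumor", "NHC", "NHC")
        y = np.vstack([label_vector(l, hier) for l in labels])
        tree = grow_pct(x, y, weights, min_leaf=1)
        assert not tree.is_leaf
        for i in range(5):
            np.testing.assert_allclose(predict_tree(tree, x[i]), y[i])

    def test_fully_grown_tree_memorizes_training_labels(self, hier, weights, rng):
        x = rng.random((12, 3))
        leaves = ["NHC", "CD", "UC", "Tumor"]
        y = np.vstack([label_vector(leaves[i % 4], hier) for i in range(12)])
        tree = grow_pct(x, y, weights, min_leaf=1)
        for i in range(12):
            np.testing.assert_allclose(predict_tree(tree, x[i]), y[i])


def separable_data(hier, rng, n=120):
    """Features that linearly separate every diagnosis leaf."""
    leaves = ["NHC", "CD", "UC", "Tumor", "Infection", "Other"]
    idx = rng.integers(0, 6, n)
    x = np.zeros((n, 8))
    for i, li in enumerate(idx):
        x[i, li] = 5.0 + rng.normal(0, 0.3)
        x[i, 6:] = rng.normal(0, 1.0, 2)
    y = np.vstack([label_vector(leaves[li], hier) for li in idx])
    return x, y


class TestForest:
    def test_degenerate_ensemble_equals_single_tree(self, hier, weights, rng):
        x, y = separable_data(hier, rng, 40)
        forest = train_forest(x, y, weights, hier, n_trees=1, mtry=x.shape[1], bootstrap=False, seed=0)
        tree = grow_pct(x, y, weights, min_leaf=2)
        for i in range(10):
            np.testing.assert_allclose(predict(forest, x[i])[0], predict_tree(tree, x[i]))

    def test_same_seed_identical_forests(self, hier, weights, rng):
        x, y = separable_data(hier, rng, 60)
        f1 = train_forest(x, y, weights, hier, n_trees=10, seed=7)
        f2 = train_forest(x, y, weights, hier, n_trees=10, seed=7)
        np.testing.assert_allclose(predict(f1, x), predict(f2, x))
        for a, b in zip(f1.oob_indices, f2.oob_indices):
            np.testing.assert_array_equal(a, b)

    def test_oob_misclassification_low_on_separable_data(self, hier, weights, rng):
        x, y = separable_data(hier, rng, 200)
        forest = train_forest(x, y, weights, hier, n_trees=60, seed=1)
        n = len(x)
        oob_trees = [[] for _ in range(n)]
        for t, oob in enumerate(forest.oob_indices):
            for i in oob:
                oob_trees[i].append(t)
        errs = []
        for i in range(n):
            if not oob_trees[i]:
                continue
            pred = predict(forest, x[i], tree_subset=np.array(oob_trees[i]))[0]
            errs.append(np.mean((pred >= 0.5) != (y[i] == 1)))
        assert np.mean(errs) < 0.1

    def test_predictions_hierarchy_consistent(self, hier, weights, rng):
        x, y = separable_data(hier, rng, 80)
        forest = train_forest(x, y, weights, hier, n_trees=20, seed=3)
        probe = rng.random((100, 8)) * 6
        preds = predict(forest, probe)
        for node in hier.nodes:
            par = hier.parent[node]
            if par is not None:
                assert (preds[:, hier.index(node)] <= preds[:, hier.index(par)] + 1e-12).all()

    def test_two_tree_forest_hand_average(self, hier, weights):
        x = np.array([[0.0], [1.0], [0.0], [1.0]])
        y = np.vstack([label_vector(l, hier) for l in ("NHC", "Tumor", "NHC", "Tumor")])
        forest = train_forest(x, y, weights, hier, n_trees=2, mtry=1, seed=2)
        p = predict(forest, np.array([0.0]))[0]
        expected = np.mean([predict_tree(t, np.array([0.0])) for t in forest.trees], axis=0)
        np.testing.assert_allclose(p, expected)


class TestGenie3:
    def test_unused_feature_scores_zero(self, hier, weights, rng):
        x, y = separable_data(hier, rng, 100)
        x = np.hstack([x, np.full((100, 1), 3.14)])  # constant, never splittable
        forest = train_forest(x, y, weights, hier, n_trees=20, seed=4)
        scores = genie3_importance(forest)
        assert scores[-1] == 0.0

    def test_single_split_tree_scores_n_times_reduction(self, hier, weights):
        y = np.vstack([label_vector("NHC", hier)] * 4 + [label_vector("Tumor", hier)] * 4)
        x = np.array([[0.0]] * 4 + [[1.0]] * 4)
        forest = train_forest(x, y, weights, hier, n_trees=1, mtry=1, bootstrap=False, seed=0)
        tree = forest.trees[0]
        scores = genie3_importance(forest)
        assert scores[0] == pytest.approx(tree.n * tree.reduction)

    def test_score_conservation(self, hier, weights, rng):
        x, y = separable_data(hier, rng, 80)
        forest = train_forest(x, y, weights, hier, n_trees=15, seed=5)
        scores = genie3_importance(forest)
        total = 0.0
        for tree in forest.trees:
            stack = [tree]
            while stack:
                node = stack.pop()
                if not node.is_leaf:
                    total += node.n * node.reduction
                    stack.extend([node.left, node.right])
        assert scores.sum() == pytest.approx(total / forest.n_trees, rel=1e-12)
        assert (scores >= 0).all()

    def test_informative_feature_ranks_first(self, hier, weights):
        rng = np.random.default_rng(8)
        n = 150
        idx = rng.integers(0, 2, n)
        x = rng.normal(0, 1, (n, 12))
        x[:, 5] += idx * 3.0  # single informative feature
        y = np.vstack([label_vector("NHC" if i == 0 else "Tumor", hier) for i in idx])
        forest = train_forest(x, y, weights, hier, n_trees=40, seed=9)
        scores = genie3_importance(forest)
        assert np.argmax(scores) == 5
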