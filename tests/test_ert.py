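"""Extremely randomized trees: node tests, splits, growth, propagation."""

import math

import numpy as np
import pytest

from zfscreen.ert import (
    DIFFNEIGHBOR,
    NEIGHBOR_TABLE,
    SIMPLETHRES,
    Ensemble,
    ErtParams,
    NodeTest,
    build_ensemble,
    build_tree,
    draw_random_test,
    iter_leaves,
    propagate,
    propagate_many,
    split_score,
)
from zfscreen.subwindow import N_ATTRIBUTES, PATCH_SIDE, trgb_normalize


def replay_path(vec, tree):
    """Independent descent oracle: re-evaluates each node test from scratch."""
    node = tree
    while node.test is not None:
        t = node.test
        if t.kind == SIMPLETHRES:
            q = vec[t.attr]
        else:
            q = vec[t.attr] - vec[t.neighbor_attr]
        node = node.left if q < t.threshold else node.right
    return node


class TestNeighborTable:
    def test_corner_center_edge_neighbor_counts(self):
        plane = PATCH_SIDE * PATCH_SIDE
        corner = 0
        center = 5 * PATCH_SIDE + 5
        edge = 7  # top row, interior column
        assert (NEIGHBOR_TABLE[corner] >= 0).sum() == 3
        assert (NEIGHBOR_TABLE[edge] >= 0).sum() == 5
        assert (NEIGHBOR_TABLE[center] >= 0).sum() == 8
        # neighbors stay within the same channel plane
        for ch in range(3):
            a = ch * plane + center
            nbrs = NEIGHBOR_TABLE[a]
            assert all(ch * plane <= b < (ch + 1) * plane for b in nbrs[nbrs >= 0])


class TestDrawRandomTest:
    def test_only_varying_attribute_is_chosen(self, rng):
        X = np.zeros((10, N_ATTRIBUTES))
        X[:, 5] = np.linspace(-1, 1, 10)
        t = draw_random_test(X, SIMPLETHRES, rng)
        assert t.attr == 5 and -1 < t.threshold < 1

    def test_degenerate_node_signals_no_test(self, rng):
        X = np.ones((4, N_ATTRIBUTES))
        assert draw_random_test(X, SIMPLETHRES, rng) is None
        assert draw_random_test(X, DIFFNEIGHBOR, rng) is None

    def test_constant_offset_is_degenerate_for_diffneighbor(self, rng):
        # rows differ by a constant shift: every pixel difference is constant
        X = np.outer(np.arange(6.0), np.ones(N_ATTRIBUTES))
        assert draw_random_test(X, DIFFNEIGHBOR, rng) is None
        assert draw_random_test(X, SIMPLETHRES, rng) is not None

    def test_attribute_choice_uniform(self, rng):
        X = np.zeros((8, N_ATTRIBUTES))
        X[:, 0] = np.arange(8)
        X[:, 1] = np.arange(8)[::-1]
        hits = sum(draw_random_test(X, SIMPLETHRES, rng).attr == 0 for _ in range(10_000))
        sigma = math.sqrt(10_000 * 0.25)
        assert abs(hits - 5000) <= 3 * sigma

    def test_threshold_splits_are_nondegenerate(self, rng):
        X = np.zeros((20, N_ATTRIBUTES))
        X[:, 3] = np.repeat([0.0, 1.0], 10)
        for _ in range(50):
            t = draw_random_test(X, SIMPLETHRES, rng)
            v = t.evaluate(X)
            assert (v < t.threshold).any() and (v >= t.threshold).any()


class TestSplitScore:
    def test_pure_balanced_split_is_maximal(self):
        assert split_score(["A", "A"], ["B", "B"]) == pytest.approx(1.0)

    def test_proportional_split_scores_zero(self):
        assert split_score(["A", "B"], ["A", "B"]) == pytest.approx(0.0)

    def test_hand_computed_entropy_gain(self):
        # left {A,A,B}, right {B}: H_C = 1, H_S = H(3/4), H(C|S) = 3/4 * H(2/3)
        h = lambda p: -p * math.log2(p) - (1 - p) * math.log2(1 - p)
        expected = 2 * (1.0 - 0.75 * h(2 / 3)) / (1.0 + h(0.75))
        assert split_score(["A", "A", "B"], ["B"]) == pytest.approx(expected, abs=1e-12)

    def test_empty_side_invalid(self):
        with pytest.raises(ValueError):
            split_score(["A"], [])


class TestBuildTree:
    def test_single_class_gives_single_leaf(self, rng):
        X = rng.normal(size=(10, N_ATTRIBUTES))
        tree = build_tree(X, np.zeros(10, dtype=int), ErtParams(seed=0), rng)
        assert tree.is_leaf and tree.class_counts[0] == 10

    def test_separable_data_fit_perfectly(self, rng):
        X = np.zeros((4, N_ATTRIBUTES))
        X[:, 10] = [0.0, 0.1, 0.9, 1.0]
        y = np.array([0, 0, 1, 1])
        tree = build_tree(X, y, ErtParams(n_min=1, K=28), rng)
        for i in range(4):
            leaf = propagate(X[i], tree)
            assert np.argmax(leaf.class_counts) == y[i]

    def test_nmin_larger_than_sample_gives_leaf_with_counts(self, rng):
        X = rng.normal(size=(6, N_ATTRIBUTES))
        y = np.array([0, 0, 1, 1, 1, 1])
        tree = build_tree(X, y, ErtParams(n_min=100), rng)
        assert tree.is_leaf
        np.testing.assert_array_equal(tree.class_counts, [2, 4])

    def test_pure_leaves_with_nmin_one(self, rng):
        X = rng.normal(size=(60, N_ATTRIBUTES))
        y = (rng.random(60) < 0.5).astype(int)
        tree = build_tree(X, y, ErtParams(n_min=1), rng)
        for leaf in iter_leaves(tree):
            assert np.count_nonzero(leaf.class_counts) == 1


class TestEnsemble:
    def _toy(self, rng, n=40):
        X = rng.normal(size=(n, N_ATTRIBUTES))
        y = (X[:, 0] > 0).astype(int)
        return X, y

    def test_single_tree_ensemble(self, rng):
        X, y = self._toy(rng)
        ens = build_ensemble(X, y, ErtParams(T=1, seed=4))
        assert len(ens.trees) == 1 and ens.n_leaves > 0

    def test_same_seed_identical_serialization(self, rng):
        X, y = self._toy(rng)
        a = build_ensemble(X, y, ErtParams(T=3, seed=9)).to_json()
        b = build_ensemble(X, y, ErtParams(T=3, seed=9)).to_json()
        assert a == b
        c = build_ensemble(X, y, ErtParams(T=3, seed=10)).to_json()
        assert a != c

    def test_leaf_ids_contiguous_and_all_reachable(self, rng):
        X, y = self._toy(rng, n=80)
        ens = build_ensemble(X, y, ErtParams(T=10, n_min=5, seed=2))
        seen = set()
        for tree in ens.trees:
            seen.update(propagate_many(X, tree).tolist())
        assert seen == set(range(ens.n_leaves))

    def test_training_samples_reach_leaves_of_their_class(self, rng):
        X, y = self._toy(rng, n=50)
        ens = build_ensemble(X, y, ErtParams(T=5, n_min=1, seed=3))
        for tree in ens.trees:
            for i in range(50):
                leaf = propagate(X[i], tree)
                assert leaf.class_counts[y[i]] > 0

    def test_json_roundtrip_preserves_predictions(self, rng):
        X, y = self._toy(rng)
        ens = build_ensemble(X, y, ErtParams(T=4, n_min=5, seed=8))
        back = Ensemble.from_json(ens.to_json())
        assert back.to_json() == ens.to_json()
        Q = rng.normal(size=(20, N_ATTRIBUTES))
        for t1, t2 in zip(ens.trees, back.trees):
            np.testing.assert_array_equal(propagate_many(Q, t1), propagate_many(Q, t2))


class TestPropagate:
    def test_single_leaf_tree(self, rng):
        X = rng.normal(size=(5, N_ATTRIBUTES))
        tree = build_tree(X, np.zeros(5, dtype=int), ErtParams(), rng)
        assert propagate(rng.normal(size=N_ATTRIBUTES), tree) is tree

    def test_depth_one_semantics(self):
        from zfscreen.ert import TreeNode

        left = TreeNode(class_counts=np.array([1, 0]), leaf_id=0)
        right = TreeNode(class_counts=np.array([0, 1]), leaf_id=1)
        tree = TreeNode(test=NodeTest(SIMPLETHRES, 0, 0.5), left=left, right=right)
        v = np.zeros(N_ATTRIBUTES)
        v[0] = 0.2
        assert propagate(v, tree) is left
        v[0] = 0.9
        assert propagate(v, tree) is right

    @pytest.mark.parametrize("kind", [SIMPLETHRES, DIFFNEIGHBOR])
    def test_agrees_with_path_replay_oracle(self, rng, kind):
        X = rng.normal(size=(100, N_ATTRIBUTES))
        y = (X[:, :10].mean(axis=1) > 0).astype(int)
        ens = build_ensemble(X, y, ErtParams(T=10, n_min=1, test_kind=kind, seed=6))
        Q = rng.normal(size=(100, N_ATTRIBUTES))
        for tree in ens.trees:
            ids = propagate_many(Q, tree)
            for i in range(100):
                assert replay_path(Q[i], tree).leaf_id == ids[i]

    def test_diffneighbor_invariant_to_channel_offset(self, rng):
        patch = rng.uniform(0, 200, size=(16, 16, 3))
        shifted = patch.copy()
        shifted[:, :, 1] += 30.0  # constant offset on the green channel, pre-TRGB
        plane = PATCH_SIDE * PATCH_SIDE
        raw = patch.transpose(2, 0, 1).ravel()
        raw_shifted = shifted.transpose(2, 0, 1).ravel()
        for _ in range(20):
            a = int(rng.integers(plane, 2 * plane))  # green-plane attribute
            nbrs = NEIGHBOR_TABLE[a]
            b = int(rng.choice(nbrs[nbrs >= 0]))
            t = NodeTest(DIFFNEIGHBOR, a, 0.0, b)
            assert t.evaluate(raw[None])[0] == pytest.approx(t.evaluate(raw_shifted[None])[0])
        # and TRGB removes the shift entirely
        np.testing.assert_allclose(trgb_normalize(shifted), trgb_normalize(patch), atol=1e-9)

    def test_neighbor_must_be_adjacent(self):
        with pytest.raises(ValueError):
            NodeTest(DIFFNEIGHBOR, 0, 0.0, 100)
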