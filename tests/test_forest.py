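"""Weighted-information-gain forest: weights, entropy, splits, trees,
ensemble voting."""

import numpy as np
import pandas as pd
import pytest

from sleepforest.errors import DegenerateInputError, SleepForestError
from sleepforest.forest import (
    TreeParams,
    WeightedForest,
    build_forest,
    build_tree,
    class_entropy,
    ensemble_error,
    feature_weights,
    information_gain,
    weighted_information_gain,
    weights_from_std,
)

# printed per-feature standard deviations of the two reference gender
# subsets, and the weight coefficients they normalize to
FEMALE_STD = (0.373142, 0.198726, 0.265727, 0.305066,
              0.171219, 0.352091, 0.252303, 0.144717)
FEMALE_WEIGHTS = (0.180874, 0.096328, 0.128807, 0.147876,
                  0.082996, 0.170670, 0.122300, 0.070149)
MALE_STD = (0.378916, 0.335212, 0.254561, 0.183792,
            0.381092, 0.314814, 0.242165)
MALE_WEIGHTS = (0.181252, 0.160346, 0.121767, 0.087915,
                0.182293, 0.150589, 0.115838)


class TestWeights:
    @pytest.mark.parametrize(
        "std,expected", [(FEMALE_STD, FEMALE_WEIGHTS), (MALE_STD, MALE_WEIGHTS)]
    )
    def test_printed_standard_deviations_reproduce_weights(self, std, expected):
        w = weights_from_std(std)
        assert np.allclose(w.weights, expected, atol=1e-6)
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_spread_gives_equal_weights(self):
        w = weights_from_std([0.3, 0.3])
        assert w.weights.tolist() == [0.5, 0.5]

    def test_scale_free(self):
        a = weights_from_std(np.array(FEMALE_STD))
        b = weights_from_std(2.0 * np.array(FEMALE_STD))
        assert np.allclose(a.weights, b.weights, atol=1e-15)

    def test_population_denominator_on_matrix(self, rng):
        m = pd.DataFrame(rng.uniform(size=(50, 3)), columns=list("abc"))
        w = feature_weights(m, ["a", "b", "c"])
        expected = m.to_numpy().std(axis=0, ddof=0)
        assert np.allclose(w.std, expected)

    def test_all_constant_subset_rejected(self):
        m = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(DegenerateInputError):
            feature_weights(m, ["a", "b"])


class TestEntropy:
    @pytest.mark.parametrize(
        "labels,expected",
        [([0, 0, 1, 1], 1.0), ([0, 0, 0], 0.0), ([0, 0, 1, 2], 1.5)],
    )
    def test_hand_values(self, labels, expected):
        assert class_entropy(labels) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_log2_classes(self, rng):
        labels = rng.integers(0, 5, 100)
        assert class_entropy(labels) <= np.log2(5) + 1e-12


def brute_force_best_split(x, y):
    """Enumerate every threshold position; direct entropy arithmetic."""
    best = None
    xs = np.sort(np.unique(x))
    for lo, hi in zip(xs[:-1], xs[1:]):
        thr = 0.5 * (lo + hi)
        left, right = y[x <= thr], y[x > thr]
        ig = information_gain(y, left, right)
        if best is None or ig > best[1] + 1e-12:
            best = (thr, ig)
    return best


class TestInformationGain:
    def test_pure_split_gains_full_bit(self):
        parent = np.array([0, 0, 1, 1])
        assert information_gain(parent, parent[:2], parent[2:]) == pytest.approx(1.0)

    def test_distribution_copy_gains_nothing(self):
        parent = np.array([0, 1, 0, 1])
        assert information_gain(parent, parent[:2], parent[2:]) == pytest.approx(0.0)

    def test_exhaustive_enumeration_oracle(self, rng):
        """Vectorized split search agrees with brute-force enumeration on
        random small datasets."""
        from sleepforest.forest import _best_split_for_feature

        for _ in range(300):
            n = rng.integers(4, 13)
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 3, n)
            expected = brute_force_best_split(x, y)
            found = _best_split_for_feature(x, y, 3)
            if expected is None:
                assert found is None
            else:
                assert found is not None
                assert found[1] == pytest.approx(max(expected[1], 0.0), abs=1e-9)

    def test_weighted_gain_is_product(self):
        w = weights_from_std([0.7, 0.3], features=("a", "b"))
        parent = np.array([0, 0, 1, 1])
        base = information_gain(parent, parent[:2], parent[2:])
        assert weighted_information_gain(parent, parent[:2], parent[2:], "a", w) \
            == pytest.approx(0.7 * base)
        with pytest.raises(SleepForestError):
            weighted_information_gain(parent, parent[:2], parent[2:], "zz", w)


class TestBuildTree:
    def test_linearly_separable_depth_one(self):
        X = np.array([[0.1], [0.2], [0.8], [0.9]])
        y = np.array([0, 0, 1, 1])
        tree = build_tree(X, y)
        assert tree.root.left.is_leaf and tree.root.right.is_leaf
        assert (tree.predict(X) == y).all()

    def test_pure_labels_single_leaf(self):
        tree = build_tree(np.zeros((5, 2)), np.ones(5, dtype=int))
        assert tree.root.is_leaf

    def test_xor_needs_depth_two(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 1, 1, 0])
        tree = build_tree(X, y, params=TreeParams(mtry=2))
        assert (tree.predict(X) == y).all()
        assert not tree.root.is_leaf
        assert not (tree.root.left.is_leaf and tree.root.right.is_leaf)

    def test_single_row_single_leaf(self):
        tree = build_tree(np.array([[1.0]]), np.array([2]))
        assert tree.root.is_leaf and tree.root.label == 2


class TestForest:
    def _data(self, rng, n=200):
        X = rng.uniform(size=(n, 4))
        y = (X[:, 0] + 0.3 * X[:, 1] > 0.7).astype(int)
        return X, y

    def test_degenerate_forest_equals_single_tree(self, rng):
        X, y = self._data(rng)
        f = build_forest(X, y, n_trees=1, bootstrap=False,
                         params=TreeParams(mtry=4), seed=5)
        t = build_tree(X, y, params=TreeParams(mtry=4),
                       rng=np.random.default_rng(
                           np.random.default_rng(5).integers(2 ** 31)))
        assert (f.predict(X) == t.predict(X)).all()

    def test_same_seed_byte_identical_serialization(self, rng):
        X, y = self._data(rng)
        a = build_forest(X, y, n_trees=5, seed=9).to_json()
        b = build_forest(X, y, n_trees=5, seed=9).to_json()
        assert a == b

    def test_json_round_trip_preserves_predictions(self, rng):
        X, y = self._data(rng)
        f = build_forest(X, y, n_trees=5, seed=2)
        g = WeightedForest.from_json(f.to_json())
        assert (f.predict(X) == g.predict(X)).all()

    def test_votes_sum_to_n_trees_and_majority_wins(self, rng):
        X, y = self._data(rng)
        f = build_forest(X, y, n_trees=7, seed=0)
        votes = f.predict_votes(X)
        assert (votes.sum(axis=1) == 7).all()
        assert (f.predict(X) == np.argmax(votes, axis=1)).all()

    def test_equal_weights_equals_unweighted_exactly(self, rng):
        """Uniform weight vector and no weights produce identical forests."""
        X, y = self._data(rng)
        w = weights_from_std(np.ones(4), features=tuple(f"f{i}" for i in range(4)))
        a = build_forest(X, y, w=w, n_trees=10, seed=3).to_json()
        b = build_forest(X, y, w=None, n_trees=10, seed=3).to_json()
        # serialized trees differ only in the recorded weight metadata
        import json

        da, db = json.loads(a), json.loads(b)
        assert da["trees"] == db["trees"]

    def test_unequal_weights_can_change_the_split(self):
        # two features with identical unweighted gains: weight decides
        X = np.array([[0.0, 1.0], [0.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        w = weights_from_std([0.3, 0.7], features=("f0", "f1"))
        tree = build_tree(X, y, w=w, params=TreeParams(mtry=2))
        assert tree.root.feature == 1
        w2 = weights_from_std([0.7, 0.3], features=("f0", "f1"))
        tree2 = build_tree(X, y, w=w2, params=TreeParams(mtry=2))
        assert tree2.root.feature == 0

    def test_out_of_sample_accuracy_on_separable_data(self, rng):
        X, y = self._data(rng, n=600)
        f = build_forest(X[:400], y[:400], n_trees=15, seed=1)
        assert (f.predict(X[400:]) == y[400:]).mean() > 0.9

    def test_rebalanced_bootstrap_equalizes_class_draws(self, rng):
        # 9:1 imbalance; with rebalancing the minority class appears in
        # roughly half of every bootstrap, improving its recall
        X = np.vstack([rng.normal(0, 1, (450, 2)), rng.normal(1.2, 1, (50, 2))])
        y = np.array([0] * 450 + [1] * 50)
        plain = build_forest(X, y, n_trees=11, seed=4)
        balanced = build_forest(X, y, n_trees=11, seed=4, rebalance=True)
        minority_recall = lambda f: (f.predict(X[450:]) == 1).mean()
        assert minority_recall(balanced) >= minority_recall(plain)

    def test_missing_feature_rejected(self, rng):
        X, y = self._data(rng)
        f = build_forest(X, y, n_trees=3, seed=0,
                         features=("a", "b", "c", "d"))
        with pytest.raises(SleepForestError, match="lacks"):
            f.predict_frame(pd.DataFrame({"a": [0.1], "b": [0.1], "c": [0.1]}))


class TestEnsembleError:
    def test_three_trees_at_40_percent(self):
        assert ensemble_error(0.4, 3) == pytest.approx(0.352, abs=1e-12)

    @pytest.mark.parametrize("n", [1, 3, 11, 51])
    def test_coin_flip_stays_half(self, n):
        assert ensemble_error(0.5, n) == pytest.approx(0.5, abs=1e-9)

    def test_monotone_decreasing_in_n_for_good_trees(self):
        values = [ensemble_error(0.4, n) for n in range(3, 102, 2)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[0] == pytest.approx(0.352, abs=1e-12)

    def test_binomial_tail_oracle(self):
        from math import comb

        n, p = 31, 0.4
        exact = sum(comb(n, j) * p ** j * (1 - p) ** (n - j)
                    for j in range(n // 2 + 1, n + 1))
        assert ensemble_error(p, n) == pytest.approx(exact, abs=1e-12)
        assert ensemble_error(p, n) < 0.352

    def test_even_n_rejected(self):
        with pytest.raises(SleepForestError):
            ensemble_error(0.4, 4)
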