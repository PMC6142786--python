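"""Random forest with a standard-deviation-weighted information-gain
split criterion.

The split rule differs from a textbook random forest in one place: each
candidate feature i carries a fixed weight w_i = s_i / sum_j s_j, where
s_i is the population standard deviation (1/n denominator) of feature i
over the normalized training matrix.  A node picks the (feature,
threshold) pair maximizing w_i * IG instead of IG, where IG is the usual
parent-entropy-minus-weighted-child-entropy information gain in bits.
Features with large spread over [0,1]-normalized values therefore win
ties and borderline comparisons, reducing tree depth; with all weights
equal the criterion reduces to plain information gain and the forest is
identical tree for tree.

Trees are grown on bootstrap samples with per-node feature subsampling
(mtry = ceil(sqrt(d)) by default) and midpoint thresholds between
consecutive distinct sorted values; everything is reproducible from one
seed.  The ensemble predicts by majority vote; the classical
majority-vote error bound for k independent trees of equal error rate is
available as :func:`ensemble_error`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, SleepForestError


# ---------------------------------------------------------------------------
# feature weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightVector:
    features: tuple
    std: np.ndarray      # population standard deviations s_i
    weights: np.ndarray  # w_i = s_i / sum(s), sum to 1

    def weight_of(self, feature: str) -> float:
        try:
            return float(self.weights[self.features.index(feature)])
        except ValueError:
            raise SleepForestError(f"no weight for feature {feature!r}")


def weights_from_std(std, features=None) -> WeightVector:
    """Normalize per-feature standard deviations to weights summing to 1."""
    std = np.asarray(std, dtype=float)
    total = std.sum()
    if total <= 0:
        raise DegenerateInputError("all feature standard deviations are zero")
    if features is None:
        features = tuple(f"f{i}" for i in range(len(std)))
    return WeightVector(features=tuple(features), std=std, weights=std / total)


def feature_weights(matrix: pd.DataFrame, subset) -> WeightVector:
    """Standard-deviation weights of the selected features, computed on a
    normalized feature matrix (population 1/n denominator)."""
    names = list(subset.features) if hasattr(subset, "features") else list(subset)
    if not names:
        raise DegenerateInputError("empty feature subset")
    std = matrix[names].to_numpy(dtype=float).std(axis=0, ddof=0)
    return weights_from_std(std, features=names)


# ---------------------------------------------------------------------------
# split criterion
# ---------------------------------------------------------------------------

def class_entropy(labels) -> float:
    """Base-2 entropy of the empirical class distribution."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise DegenerateInputError("empty label set")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(parent_labels, left_labels, right_labels) -> float:
    """IG = E(parent) - sum(|child|/|parent| * E(child)), in bits."""
    n = len(parent_labels)
    nl, nr = len(left_labels), len(right_labels)
    if nl + nr != n:
        raise SleepForestError("children do not partition the parent")
    if nl == 0 or nr == 0:
        return 0.0
    return class_entropy(parent_labels) - (
        nl / n * class_entropy(left_labels) + nr / n * class_entropy(right_labels)
    )


def weighted_information_gain(
    parent_labels, left_labels, right_labels, feature: str, w: WeightVector
) -> float:
    """w_feature * IG — the node-splitting criterion."""
    return w.weight_of(feature) * information_gain(
        parent_labels, left_labels, right_labels
    )


def _best_split_for_feature(x: np.ndarray, y: np.ndarray, n_classes: int):
    """Best (threshold, IG) along one feature column, vectorized.

    Thresholds are midpoints between consecutive distinct sorted values;
    IG for every threshold position comes from cumulative class counts.
    Ties in IG break toward the lower threshold.
    """
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    onehot = np.zeros((len(ys), n_classes))
    onehot[np.arange(len(ys)), ys] = 1.0
    left_counts = np.cumsum(onehot, axis=0)[:-1]  # split after position i
    total = left_counts[-1] + onehot[-1]
    right_counts = total - left_counts
    valid = xs[1:] != xs[:-1]  # only between distinct values
    if not valid.any():
        return None
    nl = left_counts.sum(axis=1)
    nr = right_counts.sum(axis=1)
    n = len(ys)

    def side_entropy(counts, sizes):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / sizes[:, None]
            term = np.where(p > 0, p * np.log2(p), 0.0)
        return -term.sum(axis=1)

    parent_entropy = class_entropy(ys)
    ig = parent_entropy - (nl / n) * side_entropy(left_counts, nl) \
        - (nr / n) * side_entropy(right_counts, nr)
    ig = np.where(valid, ig, -np.inf)
    best = int(np.argmax(ig))  # argmax takes the first (lowest threshold) tie
    if not np.isfinite(ig[best]):
        return None
    threshold = 0.5 * (xs[best] + xs[best + 1])
    return threshold, float(max(ig[best], 0.0))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    feature: int | None = None
    threshold: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: int | None = None          # set on leaves
    counts: np.ndarray | None = None  # class counts of training rows

    @property
    def is_leaf(self) -> bool:
        return self.label is not None


@dataclass(frozen=True)
class TreeParams:
    mtry: int | None = None        # None -> ceil(sqrt(d))
    max_depth: int | None = None
    min_samples_leaf: int = 1
    min_samples_split: int = 2


@dataclass
class DecisionTree:
    root: TreeNode
    features: tuple  # column names, prediction input order

    def predict_one(self, x: np.ndarray) -> int:
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.label

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([self.predict_one(row) for row in X])


def _grow(X, y, w_arr, params, rng, n_classes, depth) -> TreeNode:
    counts = np.bincount(y, minlength=n_classes)
    majority = int(np.argmax(counts))  # ties -> lowest class index
    node = TreeNode(counts=counts)
    if (
        len(y) < params.min_samples_split
        or (params.max_depth is not None and depth >= params.max_depth)
        or counts.max() == len(y)
    ):
        node.label = majority
        return node
    d = X.shape[1]
    mtry = params.mtry or int(np.ceil(np.sqrt(d)))
    candidates = rng.choice(d, size=min(mtry, d), replace=False)
    best = None  # (weighted gain, feature, threshold)
    for f in sorted(candidates):
        found = _best_split_for_feature(X[:, f], y, n_classes)
        if found is None:
            continue
        threshold, ig = found
        wg = w_arr[f] * ig
        # strictly-better comparison keeps the lowest feature index on
        # ties; zero-gain splits are allowed on impure nodes so that
        # interaction patterns (XOR-like) can still be separated deeper down
        if best is None or wg > best[0] + 1e-15:
            best = (wg, f, threshold)
    if best is None:
        node.label = majority
        return node
    _, f, threshold = best
    mask = X[:, f] <= threshold
    if mask.sum() < params.min_samples_leaf or (~mask).sum() < params.min_samples_leaf:
        node.label = majority
        return node
    node.feature = int(f)
    node.threshold = float(threshold)
    node.left = _grow(X[mask], y[mask], w_arr, params, rng, n_classes, depth + 1)
    node.right = _grow(X[~mask], y[~mask], w_arr, params, rng, n_classes, depth + 1)
    return node


def build_tree(
    X,
    y,
    w: WeightVector | None = None,
    params: TreeParams = TreeParams(),
    rng=None,
    n_classes: int | None = None,
    features: tuple | None = None,
) -> DecisionTree:
    """Grow one decision tree maximizing weighted information gain.

    ``w=None`` means uniform weights (plain information gain)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if rng is None:
        rng = np.random.default_rng(0)
    if n_classes is None:
        n_classes = int(y.max()) + 1
    if features is None:
        features = tuple(f"f{i}" for i in range(X.shape[1]))
    if w is None:
        w_arr = np.full(X.shape[1], 1.0 / X.shape[1])
    else:
        w_arr = np.array([w.weight_of(f) for f in features])
    root = _grow(X, y, w_arr, params, rng, n_classes, 0)
    return DecisionTree(root=root, features=features)


# ---------------------------------------------------------------------------
# forest
# ---------------------------------------------------------------------------

@dataclass
class WeightedForest:
    trees: list
    features: tuple
    n_classes: int
    weights: WeightVector | None
    seed: int = 0

    def predict_votes(self, X) -> np.ndarray:
        """(n_samples, n_classes) vote counts; rows sum to len(trees)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        votes = np.zeros((len(X), self.n_classes), dtype=int)
        for tree in self.trees:
            pred = tree.predict(X)
            votes[np.arange(len(X)), pred] += 1
        return votes

    def predict(self, X) -> np.ndarray:
        """Majority vote; ties break to the lowest class index."""
        return np.argmax(self.predict_votes(X), axis=1)

    def predict_frame(self, matrix: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in matrix.columns]
        if missing:
            raise SleepForestError(f"matrix lacks forest features {missing}")
        return self.predict(matrix[list(self.features)].to_numpy(dtype=float))

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        def encode(node):
            if node.is_leaf:
                return {"label": node.label, "counts": node.counts.tolist()}
            return {
                "feature": node.feature, "threshold": node.threshold,
                "left": encode(node.left), "right": encode(node.right),
                "counts": node.counts.tolist(),
            }

        doc = json.dumps(
            {
                "features": list(self.features),
                "n_classes": self.n_classes,
                "seed": self.seed,
                "weights": None if self.weights is None
                else {"features": list(self.weights.features),
                      "std": self.weights.std.tolist()},
                "trees": [encode(t.root) for t in self.trees],
            }
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str) -> "WeightedForest":
        raw = json.loads(doc)

        def decode(d):
            node = TreeNode(counts=np.array(d["counts"]))
            if "label" in d:
                node.label = d["label"]
            else:
                node.feature = d["feature"]
                node.threshold = d["threshold"]
                node.left = decode(d["left"])
                node.right = decode(d["right"])
            return node

        features = tuple(raw["features"])
        weights = None
        if raw["weights"] is not None:
            weights = weights_from_std(
                raw["weights"]["std"], features=tuple(raw["weights"]["features"])
            )
        return cls(
            trees=[DecisionTree(root=decode(t), features=features)
                   for t in raw["trees"]],
            features=features, n_classes=raw["n_classes"],
            weights=weights, seed=raw["seed"],
        )


def build_forest(
    X,
    y,
    w: WeightVector | None = None,
    n_trees: int = 30,
    params: TreeParams = TreeParams(),
    seed: int = 0,
    bootstrap: bool = True,
    rebalance: bool = False,
    n_classes: int | None = None,
    features: tuple | None = None,
) -> WeightedForest:
    """Train ``n_trees`` trees on bootstrap samples (size n, with
    replacement) with per-node feature subsampling; reproducible from
    ``seed``.

    ``rebalance=True`` draws each bootstrap with equal per-class
    probability instead of the empirical class priors (off by default:
    the standard protocol leaves the NREM2-heavy priors untouched)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if n_trees < 1:
        raise SleepForestError("n_trees must be >= 1")
    if n_classes is None:
        n_classes = int(y.max()) + 1
    if features is None:
        features = tuple(f"f{i}" for i in range(X.shape[1]))
    root_rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        tree_rng = np.random.default_rng(root_rng.integers(2 ** 31))
        if bootstrap:
            if rebalance:
                p = np.zeros(len(y))
                for cls, count in zip(*np.unique(y, return_counts=True)):
                    p[y == cls] = 1.0 / count
                p /= p.sum()
                idx = tree_rng.choice(len(y), size=len(y), replace=True, p=p)
            else:
                idx = tree_rng.integers(len(y), size=len(y))
            Xb, yb = X[idx], y[idx]
        else:
            Xb, yb = X, y
        trees.append(
            build_tree(Xb, yb, w=w, params=params, rng=tree_rng,
                       n_classes=n_classes, features=features)
        )
    return WeightedForest(
        trees=trees, features=features, n_classes=n_classes, weights=w, seed=seed
    )


def train_forest_frame(
    matrix: pd.DataFrame,
    labels,
    feature_names,
    w: WeightVector | None = None,
    n_trees: int = 30,
    params: TreeParams = TreeParams(),
    seed: int = 0,
) -> WeightedForest:
    """Convenience wrapper training on a feature table."""
    X = matrix[list(feature_names)].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    return build_forest(
        X, y, w=w, n_trees=n_trees, params=params, seed=seed,
        features=tuple(feature_names),
    )


def ensemble_error(p_err: float, n_trees: int) -> float:
    """Probability that a majority of ``n_trees`` independent classifiers,
    each wrong with probability ``p_err``, out-votes the truth:
    sum_{j > n/2} C(n, j) p^j (1-p)^(n-j).  Requires odd ``n_trees`` (no
    ties)."""
    if not 0 <= p_err <= 1:
        raise SleepForestError("p_err must be in [0, 1]")
    if n_trees % 2 == 0:
        raise SleepForestError("n_trees must be odd (majority ties undefined)")
    j = np.arange(n_trees // 2 + 1, n_trees + 1)
    return float(stats.binom.pmf(j, n_trees, p_err).sum())
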