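"""Predictive clustering trees (PCTs) for hierarchical classification,
bagged into Random Forests, with Genie3 attribute importance.

A class hierarchy (a tree of diagnosis groups rooted at "Subject") turns
each sample's leaf diagnosis into a binary label vector over all
hierarchy nodes: 1 on the root-to-leaf path, 0 elsewhere.  A PCT is a
decision tree grown to minimize the weighted variance of these label
vectors, where node c carries weight w0^depth(c) so that mistakes near
the root cost more than mistakes deep in the hierarchy.  Leaves store
the mean label vector (a prototype of per-node probabilities); averaging
prototypes over a bagged ensemble yields per-node probability
predictions that are hierarchy-consistent by construction (a mean of
consistent vectors is consistent).

Genie3 importance of a feature is the per-tree sum of
(samples at node x variance reduction) over the nodes split on that
feature, averaged over the forest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabelHierarchy",
    "NodeWeights",
    "build_hierarchy",
    "label_vector",
    "weighted_variance",
    "best_split",
    "grow_pct",
    "predict_tree",
    "train_forest",
    "predict",
    "genie3_importance",
    "PCTForest",
]

DEFAULT_HIERARCHY_PATHS = [
    "Subject/NHC",
    "Subject/HP/IBD/CD",
    "Subject/HP/IBD/UC",
    "Subject/HP/Tumor",
    "Subject/HP/Infection",
    "Subject/HP/Other",
]


@dataclass
class LabelHierarchy:
    nodes: list[str]
    parent: dict[str, str | None]
    depth: dict[str, int]

    @property
    def root(self) -> str:
        return self.nodes[0]

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    def path_to_root(self, node: str) -> list[str]:
        path = [node]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])  # type: ignore[arg-type]
        return path


@dataclass
class NodeWeights:
    """Per-node weights w(c) = w0^depth(c); the root has weight 1."""

    w: np.ndarray
    w0: float

    @classmethod
    def from_hierarchy(cls, h: LabelHierarchy, w0: float = 0.75) -> "NodeWeights":
        if not w0 > 0:
            raise ValueError("w0 must be positive")
        return cls(w=np.array([w0 ** h.depth[n] for n in h.nodes]), w0=w0)


def build_hierarchy(paths: list[str]) -> LabelHierarchy:
    """Build a label hierarchy from slash-delimited root-to-leaf paths."""
    nodes: list[str] = []
    parent: dict[str, str | None] = {}
    depth: dict[str, int] = {}
    root = None
    for path in paths:
        parts = [p for p in path.split("/") if p]
        if not parts:
            raise ValueError("empty path")
        if root is None:
            root = parts[0]
        elif parts[0] != root:
            raise ValueError(f"conflicting roots {root!r} and {parts[0]!r}")
        for i, name in enumerate(parts):
            par = parts[i - 1] if i > 0 else None
            if name in parent:
                if parent[name] != par:
                    raise ValueError(f"conflicting parents for node {name!r}")
            else:
                nodes.append(name)
                parent[name] = par
                depth[name] = i
    return LabelHierarchy(nodes=nodes, parent=parent, depth=depth)


def label_vector(leaf: str, h: LabelHierarchy) -> np.ndarray:
    """Binary vector over hierarchy nodes: 1 on the root-to-leaf path."""
    if leaf not in h.parent:
        raise ValueError(f"unknown hierarchy node {leaf!r}")
    on = set(h.path_to_root(leaf))
    return np.array([1.0 if n in on else 0.0 for n in h.nodes])


def weighted_variance(vectors: np.ndarray, weights: NodeWeights) -> float:
    """Mean weighted squared distance of label vectors to their mean:
    Var(S) = (1/|S|) sum_s sum_c w(c) (v_sc - mean_c)^2."""
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    if v.shape[0] == 0:
        raise ValueError("empty set")
    centered = v - v.mean(axis=0)
    return float((weights.w * centered**2).sum() / v.shape[0])


def _weighted_ss(prefix_sum: np.ndarray, prefix_sq: np.ndarray, n: int, w: np.ndarray) -> np.ndarray:
    """Weighted within-group sum of squares from prefix sums (vectorized
    over split positions)."""
    # prefix arrays have shape (n_positions, C)
    with np.errstate(invalid="ignore", divide="ignore"):
        ss = prefix_sq - prefix_sum**2 / np.maximum(n, 1)[..., None]
    return (ss * w).sum(axis=-1)


def best_split(
    features: np.ndarray,
    vectors: np.ndarray,
    weights: NodeWeights,
    candidate_features: np.ndarray | None = None,
    min_leaf: int = 1,
) -> tuple[int, float, float] | None:
    """Exhaustive best threshold split maximizing variance reduction.

    Numeric thresholds are midpoints between consecutive distinct sorted
    feature values (a 0/1 feature therefore gets the one-vs-rest split
    at 0.5).  Returns (feature index, threshold, reduction) or None when
    no split has positive reduction; ties break toward the lowest
    feature index, then the lowest threshold.
    """
    x = np.asarray(features, dtype=float)
    y = np.atleast_2d(np.asarray(vectors, dtype=float))
    n, p = x.shape
    if n < 2:
        return None
    cand = np.arange(p) if candidate_features is None else np.sort(np.asarray(candidate_features))
    w = weights.w
    total_ss = _weighted_ss(y.sum(axis=0)[None, :], (y**2).sum(axis=0)[None, :], np.array([n]), w)[0]

    best: tuple[int, float, float] | None = None
    for f in cand:
        order = np.argsort(x[:, f], kind="stable")
        xs = x[order, f]
        ys = y[order]
        distinct = np.flatnonzero(np.diff(xs) > 0)  # split after position i
        if len(distinct) == 0:
            continue
        csum = np.cumsum(ys, axis=0)
        csq = np.cumsum(ys**2, axis=0)
        nl = distinct + 1
        nr = n - nl
        ok = (nl >= min_leaf) & (nr >= min_leaf)
        if not ok.any():
            continue
        nl, nr, pos = nl[ok], nr[ok], distinct[ok]
        ss_left = _weighted_ss(csum[pos], csq[pos], nl, w)
        ss_right = _weighted_ss(csum[-1] - csum[pos], csq[-1] - csq[pos], nr, w)
        reduction = (total_ss - ss_left - ss_right) / n
        j = int(np.argmax(reduction))
        if reduction[j] > 1e-12:
            thr = float((xs[pos[j]] + xs[pos[j] + 1]) / 2.0)
            red = float(reduction[j])
            if best is None or red > best[2] + 1e-12:
                best = (int(f), thr, red)
            # ties handled implicitly: features scanned in ascending
            # index order and argmax takes the lowest threshold position
    return best


@dataclass
class _Node:
    n: int
    prototype: np.ndarray | None = None
    feature: int | None = None
    threshold: float | None = None
    reduction: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"n": self.n, "prototype": list(map(float, self.prototype))}
        return {
            "n": self.n,
            "feature": self.feature,
            "threshold": self.threshold,
            "reduction": self.reduction,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


def grow_pct(
    features: np.ndarray,
    vectors: np.ndarray,
    weights: NodeWeights,
    min_leaf: int = 2,
    max_depth: int | None = None,
    mtry: int | None = None,
    rng: np.random.Generator | None = None,
) -> _Node:
    """Grow one predictive clustering tree top-down.

    A node becomes a leaf when its labels are homogeneous, it holds
    fewer than 2*min_leaf samples, the depth limit is reached, or no
    candidate split achieves a positive variance reduction.  With
    ``mtry`` below the feature count, each node considers a uniform
    random subset of features (drawn from ``rng``).
    """
    x = np.asarray(features, dtype=float)
    y = np.atleast_2d(np.asarray(vectors, dtype=float))
    p = x.shape[1]

    def build(idx: np.ndarray, depth: int) -> _Node:
        ysub = y[idx]
        node = _Node(n=len(idx))
        homogeneous = bool((ysub == ysub[0]).all())
        if (
            homogeneous
            or len(idx) < 2 * min_leaf
            or (max_depth is not None and depth >= max_depth)
        ):
            node.prototype = ysub.mean(axis=0)
            return node
        if mtry is not None and mtry < p and rng is not None:
            cand = rng.choice(p, size=mtry, replace=False)
        else:
            cand = None
        split = best_split(x[idx], ysub, weights, candidate_features=cand, min_leaf=min_leaf)
        if split is None:
            node.prototype = ysub.mean(axis=0)
            return node
        f, thr, red = split
        node.feature, node.threshold, node.reduction = f, thr, red
        mask = x[idx, f] <= thr
        node.left = build(idx[mask], depth + 1)
        node.right = build(idx[~mask], depth + 1)
        return node

    return build(np.arange(x.shape[0]), 0)


def predict_tree(tree: _Node, row: np.ndarray) -> np.ndarray:
    node = tree
    while not node.is_leaf:
        node = node.left if row[node.feature] <= node.threshold else node.right
    return node.prototype


@dataclass
class PCTForest:
    trees: list[_Node]
    oob_indices: list[np.ndarray]
    hierarchy: LabelHierarchy
    weights: NodeWeights
    mtry: int
    seed: int
    n_features: int
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def train_forest(
    features: np.ndarray,
    vectors: np.ndarray,
    weights: NodeWeights,
    hierarchy: LabelHierarchy,
    n_trees: int = 100,
    mtry: int | None = None,
    min_leaf: int = 2,
    seed: int = 0,
    bootstrap: bool = True,
    feature_names: list[str] | None = None,
) -> PCTForest:
    """Bag ``n_trees`` PCTs: each is grown on a bootstrap sample (with
    replacement, original size) with per-node random feature subsets of
    size ``mtry`` (default ceil(sqrt(p))).  Out-of-bag indices are
    recorded per tree.  Deterministic under ``seed``."""
    x = np.asarray(features, dtype=float)
    y = np.atleast_2d(np.asarray(vectors, dtype=float))
    n, p = x.shape
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(p)))
    mtry = min(max(mtry, 1), p)

    trees, oob = [], []
    for t in range(n_trees):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(t,)))
        if bootstrap:
            idx = rng.integers(0, n, n)
            oob_t = np.setdiff1d(np.arange(n), idx)
        else:
            idx = np.arange(n)
            oob_t = np.array([], dtype=int)
        tree = grow_pct(x[idx], y[idx], weights, min_leaf=min_leaf, mtry=mtry, rng=rng)
        trees.append(tree)
        oob.append(oob_t)
    return PCTForest(
        trees=trees, oob_indices=oob, hierarchy=hierarchy, weights=weights,
        mtry=mtry, seed=seed, n_features=p, feature_names=feature_names or [],
    )


def predict(forest: PCTForest, features: np.ndarray, tree_subset: np.ndarray | None = None) -> np.ndarray:
    """Per-node probability predictions: the arithmetic mean of leaf
    prototypes over the (optionally restricted) ensemble."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    trees = forest.trees if tree_subset is None else [forest.trees[t] for t in tree_subset]
    if not trees:
        raise ValueError("no trees to predict with")
    out = np.zeros((x.shape[0], len(forest.hierarchy.nodes)))
    for tree in trees:
        for i in range(x.shape[0]):
            out[i] += predict_tree(tree, x[i])
    return out / len(trees)


def genie3_importance(forest: PCTForest) -> np.ndarray:
    """Genie3 scores: per feature, the mean over trees of the summed
    (node size x variance reduction) of every node split on it."""
    scores = np.zeros(forest.n_features)

    def walk(node: _Node) -> None:
        if node.is_leaf:
            return
        scores[node.feature] += node.n * node.reduction
        walk(node.left)
        walk(node.right)

    for tree in forest.trees:
        walk(tree)
    return scores / forest.n_trees
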