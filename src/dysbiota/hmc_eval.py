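"""Evaluation of hierarchical classifiers.

Per-node precision-recall curves and AUPRC, a micro-averaged pooled
curve over all non-root hierarchy nodes (AUPRC-bar, the overall model
performance), out-of-bag or stratified k-fold estimation, and
delta-AUPRC contrasts of microbial feature sets against a host-only
baseline.  A positive delta at a node is read as information about that
diagnosis group carried by the microbial community beyond the host
factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hmc_forest as hf

__all__ = ["PRCurve", "EvalReport", "pr_curve", "auprc", "pooled_pr", "evaluate", "delta_auprc"]

FEATURE_SETS = ("HostOnly", "HostBacteria", "HostFungi", "HostBoth")


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray


@dataclass
class EvalReport:
    feature_set: str
    protocol: str
    seed: int
    auprc_per_node: dict[str, float]
    auprc_bar: float
    delta_auprc_per_node: dict[str, float] | None = None
    n_samples: int = 0
    dropped_samples: list[str] = field(default_factory=list)


def pr_curve(scores, truth) -> PRCurve:
    """Precision-recall curve with one point per distinct score
    threshold (predict positive iff score >= t), highest threshold
    first."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    if truth.sum() == 0:
        raise ValueError("no positive samples")
    thresholds = np.unique(scores)[::-1]
    npos = truth.sum()
    rec, prec = [], []
    for t in thresholds:
        pred = scores >= t
        tp = int((pred & (truth == 1)).sum())
        fp = int((pred & (truth == 0)).sum())
        if tp + fp == 0:
            continue
        rec.append(tp / npos)
        prec.append(tp / (tp + fp))
    return PRCurve(recall=np.array(rec), precision=np.array(prec), thresholds=thresholds)


def auprc(curve: PRCurve) -> float:
    """Area under the PR curve by linear interpolation between
    achievable points, left-anchored at (0, precision of the first
    point)."""
    r = np.concatenate([[0.0], curve.recall])
    p = np.concatenate([[curve.precision[0]], curve.precision])
    area = float(np.trapezoid(p, r))
    return min(max(area, 0.0), 1.0)


def pooled_pr(
    scores_by_node: dict[str, np.ndarray],
    truth_by_node: dict[str, np.ndarray],
    root: str | None = None,
) -> tuple[PRCurve, float]:
    """Micro-averaged pooled PR curve across hierarchy nodes: TP/FP
    counts are summed over nodes at each threshold.  The root node (if
    named) is excluded; nodes without positives are skipped."""
    nodes = [
        n for n in scores_by_node
        if n != root and np.asarray(truth_by_node[n]).sum() > 0
    ]
    if not nodes:
        raise ValueError("no non-root nodes with positives")
    scores = np.concatenate([np.asarray(scores_by_node[n], dtype=float) for n in nodes])
    truth = np.concatenate([np.asarray(truth_by_node[n]).astype(int) for n in nodes])
    curve = pr_curve(scores, truth)
    return curve, auprc(curve)


def _host_columns(metadata: pd.DataFrame) -> pd.DataFrame:
    """Encode host factors: age numeric, gender/antibiotic as 0/1."""
    out = pd.DataFrame(index=metadata.index)
    out["age"] = metadata["age"].astype(float)
    out["gender_F"] = (metadata["gender"] == "F").astype(float)
    out["antibiotic"] = metadata["antibiotic"].astype(float)
    return out


def assemble_features(
    metadata: pd.DataFrame,
    feature_set: str,
    bacteria: pd.DataFrame | None = None,
    fungi: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the feature matrix for one of the four study feature sets,
    restricted to samples present in every required block."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    blocks = [_host_columns(metadata)]
    if feature_set in ("HostBacteria", "HostBoth"):
        if bacteria is None:
            raise ValueError("bacterial features required")
        blocks.append(bacteria)
    if feature_set in ("HostFungi", "HostBoth"):
        if fungi is None:
            raise ValueError("fungal features required")
        blocks.append(fungi)
    idx = blocks[0].index
    for b in blocks[1:]:
        idx = idx.intersection(b.index)
    x = pd.concat([b.loc[idx] for b in blocks], axis=1)
    # training-mean imputation of any missing feature values
    return x.fillna(x.mean())


def _stratified_folds(leaves: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    pos = 0
    for leaf in pd.unique(leaves):
        idx = np.flatnonzero(leaves == leaf)
        rng.shuffle(idx)
        for i in idx:
            folds[pos % k].append(int(i))
            pos += 1
    return [np.array(sorted(f), dtype=int) for f in folds]


def evaluate(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    hierarchy: hf.LabelHierarchy,
    feature_set: str,
    protocol: str = "OOB",
    n_trees: int = 100,
    mtry: int | None = None,
    min_leaf: int = 2,
    w0: float = 0.75,
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Estimate per-node AUPRC and pooled AUPRC-bar for one feature set.

    ``protocol="OOB"``: one forest on all samples; each sample is scored
    only by trees whose bootstrap excluded it (samples never out-of-bag
    are dropped and logged).  ``protocol="kfold"``: scores come from the
    model that held the sample's fold out, stratified by diagnosis leaf.
    Nodes with zero positives are omitted from the report.
    """
    if protocol not in ("OOB", "kfold"):
        raise ValueError("protocol must be 'OOB' or 'kfold'")
    meta = metadata.loc[features.index]
    leaves = meta["diagnosis_leaf"].to_numpy()
    y = np.vstack([hf.label_vector(leaf, hierarchy) for leaf in leaves])
    x = features.to_numpy(dtype=float)
    weights = hf.NodeWeights.from_hierarchy(hierarchy, w0=w0)
    n = x.shape[0]

    scores = np.full((n, len(hierarchy.nodes)), np.nan)
    dropped: list[str] = []
    if protocol == "OOB":
        forest = hf.train_forest(
            x, y, weights, hierarchy, n_trees=n_trees, mtry=mtry,
            min_leaf=min_leaf, seed=seed,
        )
        oob_trees: list[list[int]] = [[] for _ in range(n)]
        for t, oob in enumerate(forest.oob_indices):
            for i in oob:
                oob_trees[i].append(t)
        for i in range(n):
            if not oob_trees[i]:
                dropped.append(str(features.index[i]))
                continue
            scores[i] = hf.predict(forest, x[i], tree_subset=np.array(oob_trees[i]))[0]
    else:
        rng = np.random.default_rng(seed)
        k_eff = min(k, n)
        for fold in _stratified_folds(leaves, k_eff, rng):
            train = np.setdiff1d(np.arange(n), fold)
            forest = hf.train_forest(
                x[train], y[train], weights, hierarchy, n_trees=n_trees,
                mtry=mtry, min_leaf=min_leaf, seed=seed,
            )
            scores[fold] = hf.predict(forest, x[fold])

    ok = ~np.isnan(scores).any(axis=1)
    scores, y = scores[ok], y[ok]

    auprc_per_node: dict[str, float] = {}
    scores_by_node: dict[str, np.ndarray] = {}
    truth_by_node: dict[str, np.ndarray] = {}
    for ci, node in enumerate(hierarchy.nodes):
        if node == hierarchy.root:
            continue
        truth = y[:, ci].astype(int)
        if truth.sum() == 0:
            continue
        scores_by_node[node] = scores[:, ci]
        truth_by_node[node] = truth
        auprc_per_node[node] = auprc(pr_curve(scores[:, ci], truth))
    _, bar = pooled_pr(scores_by_node, truth_by_node, root=hierarchy.root)

    return EvalReport(
        feature_set=feature_set, protocol=protocol, seed=seed,
        auprc_per_node=auprc_per_node, auprc_bar=bar,
        n_samples=int(ok.sum()), dropped_samples=dropped,
    )


def delta_auprc(report: EvalReport, baseline: EvalReport) -> dict[str, float]:
    """Node-wise AUPRC difference report - baseline; the two reports
    must come from the same protocol and sample set."""
    if report.protocol != baseline.protocol:
        raise ValueError("protocol mismatch between reports")
    if report.n_samples != baseline.n_samples:
        raise ValueError("reports cover different sample sets")
    return {
        node: report.auprc_per_node[node] - baseline.auprc_per_node[node]
        for node in report.auprc_per_node
        if node in baseline.auprc_per_node
    }
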