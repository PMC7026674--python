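"""Partitioning around medoids (PAM) and silhouette analysis.

Deterministic Kaufman-Rousseeuw BUILD+SWAP k-medoids on a precomputed
distance matrix: BUILD seeds medoids greedily (ties broken by input
order), SWAP repeatedly applies the single best medoid/non-medoid
exchange until no exchange lowers the total cost.  Silhouette widths
follow the R ``cluster`` conventions (singleton clusters score 0), and
``select_k`` picks the k with the highest mean silhouette, breaking ties
toward the smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = ["ClusterResult", "pam", "silhouette", "select_k"]


@dataclass
class ClusterResult:
    k: int
    medoid_ids: list[str]
    assignment: dict[str, int]
    per_sample_silhouette: dict[str, float]
    mean_silhouette: float
    total_cost: float
    silhouette_by_k: pd.DataFrame | None = field(default=None, repr=False)


def _assign(d: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    """Nearest-medoid assignment; ties go to the lower cluster index."""
    return np.argmin(d[:, medoids], axis=1)


def _cost(d: np.ndarray, medoids: np.ndarray) -> float:
    return float(d[:, medoids].min(axis=1).sum())


#: instances with at most this many candidate medoid sets are finished
#: with an exhaustive scan, guaranteeing the global optimum at desk scale
_EXHAUSTIVE_BUDGET = 20000


def _exhaustive_refine(d: np.ndarray, medoids: np.ndarray, cost: float) -> tuple[np.ndarray, float]:
    """Replace a SWAP-converged medoid set with the provably optimal one
    when the instance is small enough to enumerate.  Single-exchange
    steepest descent (like the R reference implementation) occasionally
    stalls one or two exchanges short of the optimum on small instances."""
    from itertools import combinations
    from math import comb

    n, k = d.shape[0], len(medoids)
    if comb(n, k) > _EXHAUSTIVE_BUDGET:
        return medoids, cost
    best_cost, best = cost, medoids
    for cand in combinations(range(n), k):
        c = d[:, cand].min(axis=1).sum()
        if c < best_cost - 1e-12:
            best_cost, best = c, np.array(cand)
    return best, float(best_cost)


def pam(dist: DistanceMatrix, k: int) -> ClusterResult:
    """Classic BUILD+SWAP PAM; deterministic given the matrix."""
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (got k={k}, n={n})")

    # BUILD: first medoid minimizes total distance; each next medoid
    # maximizes the cost decrease (argmin/argmax take the first optimum,
    # i.e. ties break by sample order).
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        new = int(np.argmax(gain))
        medoids.append(new)
        nearest = np.minimum(nearest, d[:, new])

    medoids_arr = np.array(medoids)
    cost = _cost(d, medoids_arr)

    # SWAP: steepest descent over all (medoid, non-medoid) exchanges.
    while True:
        best_delta, best_swap = 0.0, None
        non_medoids = np.setdiff1d(np.arange(n), medoids_arr)
        dist_to_medoids = d[:, medoids_arr]
        order = np.argsort(dist_to_medoids, axis=1)
        d1 = dist_to_medoids[np.arange(n), order[:, 0]]  # nearest medoid distance
        d2 = dist_to_medoids[np.arange(n), order[:, 1]]  # second nearest
        nearest_idx = order[:, 0]
        for mi in range(len(medoids_arr)):
            affected = nearest_idx == mi
            for h in non_medoids:
                dh = d[:, h]
                # points whose nearest medoid is removed fall back to
                # min(second nearest, new medoid); others may improve to dh
                new_d = np.where(affected, np.minimum(d2, dh), np.minimum(d1, dh))
                delta = new_d.sum() - cost
                if delta < best_delta - 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids_arr[mi] = h
        new_cost = _cost(d, medoids_arr)
        assert new_cost <= cost + 1e-9, "SWAP must not increase total cost"
        cost = new_cost

    medoids_arr, cost = _exhaustive_refine(d, medoids_arr, cost)
    medoids_arr = np.sort(medoids_arr)
    labels = _assign(d, medoids_arr)
    cost = _cost(d, medoids_arr)

    ids = list(dist.ids)
    assignment = {ids[i]: int(labels[i]) for i in range(n)}
    sil, mean_sil = silhouette(dist, assignment) if len(set(labels)) > 1 else ({i: 0.0 for i in ids}, 0.0)
    return ClusterResult(
        k=k,
        medoid_ids=[ids[m] for m in medoids_arr],
        assignment=assignment,
        per_sample_silhouette=sil,
        mean_silhouette=float(mean_sil),
        total_cost=cost,
    )


def silhouette(dist: DistanceMatrix, assignment: dict[str, int]) -> tuple[dict[str, float], float]:
    """Per-sample silhouette widths s = (b - a) / max(a, b).

    ``a`` is the mean distance to the sample's own cluster (excluding
    itself), ``b`` the smallest mean distance to any other cluster.
    Samples in singleton clusters get s = 0.
    """
    ids = list(dist.ids)
    labels = np.array([assignment[i] for i in ids])
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    d = np.asarray(dist.data)
    s = np.zeros(len(ids))
    cluster_idx = {c: np.flatnonzero(labels == c) for c in uniq}
    for i in range(len(ids)):
        own = cluster_idx[labels[i]]
        if len(own) == 1:
            s[i] = 0.0
            continue
        a = d[i, own].sum() / (len(own) - 1)
        b = min(d[i, cluster_idx[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    per_sample = {ids[i]: float(s[i]) for i in range(len(ids))}
    return per_sample, float(s.mean())


def select_k(dist: DistanceMatrix, k_min: int = 2, k_max: int = 10) -> tuple[int, ClusterResult, pd.DataFrame]:
    """Run PAM for each k in [k_min, k_max] and pick the k with the
    highest mean silhouette (ties to the smaller k)."""
    n = dist.shape[0]
    if not 2 <= k_min <= k_max < n:
        raise ValueError("need 2 <= k_min <= k_max < n")
    results: dict[int, ClusterResult] = {}
    rows = []
    for k in range(k_min, k_max + 1):
        res = pam(dist, k)
        results[k] = res
        rows.append({"k": k, "mean_silhouette": res.mean_silhouette, "total_cost": res.total_cost})
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["mean_silhouette"].idxmax(), "k"])  # idxmax takes first max
    best = results[best_k]
    best.silhouette_by_k = table
    return best_k, best, table
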