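"""Diversity, distance and permutation statistics.

Implements the beta-diversity toolkit used to characterize the cohort:
Shannon alpha diversity (natural log), Bray-Curtis distances, a
distance-based AMOVA (mothur-style, pairwise squared distances),
sequential (Type-I, adonis-style) PERMANOVA for ordered covariates, a
medoid-based multivariate dispersion test, and Pearson correlation with
pairwise-complete handling of missing values.

All permutation p-values use the (hits + 1) / (n_perm + 1) correction,
so a p-value of exactly zero is never reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .datatypes import DegenerateInputError

__all__ = [
    "PermutationTestResult",
    "shannon_index",
    "bray_curtis",
    "amova",
    "permanova",
    "dispersion_test",
    "pearson_corr",
]


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    r_squared: float | None = None
    term: str | None = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


def shannon_index(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i in nats."""
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total == 0:
        raise DegenerateInputError("all-zero count vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(abund, sample_ids=None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix, d = 1 - 2*sum(min)/(sum x + sum y)."""
    if isinstance(abund, pd.DataFrame):
        sample_ids = list(abund.index) if sample_ids is None else sample_ids
        abund = abund.to_numpy(dtype=float)
    else:
        abund = np.asarray(abund, dtype=float)
    if (abund < 0).any():
        raise ValueError("negative abundances")
    if (abund.sum(axis=1) == 0).any():
        raise DegenerateInputError("zero-sum sample row")
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(abund, metric="braycurtis"))
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(abund.shape[0])]
    return DistanceMatrix(d, ids=ids)


def _group_masks(groups) -> tuple[np.ndarray, list]:
    groups = np.asarray(groups)
    uniq = list(pd.unique(groups))
    return groups, uniq


def _amova_f(d2: np.ndarray, groups: np.ndarray, uniq: list) -> float:
    n = d2.shape[0]
    k = len(uniq)
    ss_total = d2.sum() / 2.0 / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(groups == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / 2.0 / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def amova(dist: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> PermutationTestResult:
    """Distance-based analysis of molecular variance.

    Partitions pairwise squared distances among vs within groups and
    tests the pseudo-F by permuting group labels.
    """
    groups, uniq = _group_masks(groups)
    if len(groups) != dist.shape[0]:
        raise ValueError("groups length does not match distance matrix")
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    for g in uniq:
        if (groups == g).sum() < 2:
            raise ValueError(f"singleton group {g!r}")
    d2 = np.asarray(dist.data) ** 2
    f_obs = _amova_f(d2, groups, uniq)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(groups))
        if _amova_f(d2, groups[perm], uniq) >= f_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermutationTestResult(statistic=float(f_obs), p_value=p, n_permutations=n_perm, seed=seed)


def _design_columns(values: pd.Series) -> np.ndarray:
    if values.dtype.kind in "ifub":
        return values.to_numpy(dtype=float).reshape(-1, 1)
    dummies = pd.get_dummies(values.astype(str), drop_first=True)
    return dummies.to_numpy(dtype=float)


def permanova(
    dist: DistanceMatrix,
    covariates: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> list[PermutationTestResult]:
    """Sequential (Type-I) PERMANOVA over ordered covariates.

    Covariate columns enter the model in the order given; each term's R²
    is its sequential share of the Gower-centered total sum of squares.
    Significance is assessed by freely permuting the distance matrix
    rows/columns (raw observations) and recomputing every term's
    pseudo-F.
    """
    ids = list(dist.ids)
    if isinstance(covariates, pd.DataFrame) and not covariates.index.equals(pd.Index(range(len(ids)))):
        covariates = covariates.loc[ids] if set(ids).issubset(covariates.index) else covariates
    if len(covariates) != len(ids):
        raise ValueError("covariate rows do not align with distance matrix samples")

    n = len(ids)
    d = np.asarray(dist.data)
    a = -0.5 * d**2
    c = np.eye(n) - np.ones((n, n)) / n
    g = c @ a @ c
    ss_total = np.trace(g)

    # sequential hat matrices
    x = np.ones((n, 1))
    hats, dfs, names = [], [], []
    rank_prev = 1
    for col in covariates.columns:
        z = _design_columns(covariates[col])
        x = np.hstack([x, z])
        rank = np.linalg.matrix_rank(x)
        df = rank - rank_prev
        if df == 0:
            raise ValueError(f"covariate {col!r} is constant or collinear with earlier terms")
        rank_prev = rank
        q, _ = np.linalg.qr(x)
        q = q[:, :rank]
        hats.append(q @ q.T)
        dfs.append(df)
        names.append(col)

    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_stats(gm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tr = np.array([np.sum(h * gm) for h in hats])
        ss = np.diff(np.concatenate([[0.0], tr]))
        ss_res = np.trace(gm) - tr[-1]
        f = (ss / np.array(dfs)) / (ss_res / df_res)
        return ss, f

    ss_obs, f_obs = term_stats(g)
    rng = np.random.default_rng(seed)
    hits = np.zeros(len(names), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, f_perm = term_stats(g[np.ix_(perm, perm)])
        hits += f_perm >= f_obs
    pvals = (hits + 1) / (n_perm + 1)

    return [
        PermutationTestResult(
            statistic=float(f_obs[j]),
            p_value=float(pvals[j]),
            n_permutations=n_perm,
            seed=seed,
            r_squared=float(ss_obs[j] / ss_total),
            term=names[j],
        )
        for j in range(len(names))
    ]


def _dispersions(d: np.ndarray, groups: np.ndarray, uniq: list) -> tuple[np.ndarray, float]:
    """Per-sample distance to its group medoid, and the test statistic
    (|mean difference| for 2 groups, one-way F for more)."""
    disp = np.empty(len(groups))
    for g in uniq:
        idx = np.flatnonzero(groups == g)
        sub = d[np.ix_(idx, idx)]
        medoid = idx[np.argmin(sub.sum(axis=1))]
        disp[idx] = d[idx, medoid]
    means = [disp[groups == g] for g in uniq]
    if len(uniq) == 2:
        stat = abs(means[0].mean() - means[1].mean())
    else:
        stat = stats.f_oneway(*means).statistic
        if not np.isfinite(stat):
            stat = 0.0
    return disp, float(stat)


def dispersion_test(dist: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> PermutationTestResult:
    """Permutation test of homogeneity of multivariate dispersions,
    measured as distance to the group medoid (a distance-space
    approximation of the centroid-based test)."""
    groups, uniq = _group_masks(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    for g in uniq:
        if (groups == g).sum() < 2:
            raise ValueError(f"singleton group {g!r}")
    d = np.asarray(dist.data)
    _, stat_obs = _dispersions(d, groups, uniq)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(groups))
        if _dispersions(d, groups[perm], uniq)[1] >= stat_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermutationTestResult(statistic=stat_obs, p_value=p, n_permutations=n_perm, seed=seed)


def pearson_corr(x, y) -> tuple[float, float]:
    """Product-moment correlation with pairwise-complete observations;
    two-sided p from the t transform with n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
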