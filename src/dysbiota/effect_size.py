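"""LEfSe-style differential abundance.

Two-stage screen in the spirit of linear discriminant analysis effect
size (LEfSe): a Kruskal-Wallis test per feature on per-million-scaled
abundances, then a bootstrapped one-dimensional Fisher discriminant
effect size for the features that pass, reported on a log10 scale.

This is a reimplementation of the algorithm's spirit, not a
bit-compatible port of the published tool: the pairwise Wilcoxon
subclass stage is omitted (the analyses here define no subclasses), and
the score uses log10(1 + effect) so a zero effect maps to a score of
exactly 0.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EffectSizeRecord", "kruskal_wallis", "lda_effect_size", "lefse"]


@dataclass
class EffectSizeRecord:
    taxon_id: str
    enriched_class: str
    kw_p: float
    lda_score: float
    passes: bool


def kruskal_wallis(values, classes) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    When every observation is identical the statistic is defined as 0
    (p = 1) rather than the 0/0 of the tie-corrected formula.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    uniq = pd.unique(classes)
    if len(uniq) < 2:
        raise ValueError("need at least 2 classes")
    groups = [values[classes == c] for c in uniq]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty class")
    if np.all(values == values[0]):
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def _fisher_direction(x: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Unit-norm Fisher discriminant direction with a variance ridge."""
    m0 = x[y01 == 0].mean(axis=0)
    m1 = x[y01 == 1].mean(axis=0)
    xc = np.vstack([x[y01 == 0] - m0, x[y01 == 1] - m1])
    sw = xc.T @ xc / max(len(x) - 2, 1)
    mean_var = np.trace(sw) / sw.shape[0]
    ridge = 1e-6 * mean_var if mean_var > 0 else 1e-12
    sw = sw + ridge * np.eye(sw.shape[0])
    w = np.linalg.solve(sw, m1 - m0)
    norm = np.linalg.norm(w)
    if norm == 0:
        return np.zeros_like(w)
    return w / norm


def lda_effect_size(
    abund_per_million: pd.DataFrame,
    classes,
    n_boot: int = 30,
    boot_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> pd.Series:
    """Bootstrapped linear-discriminant effect size for two classes.

    Per bootstrap round a ``boot_fraction`` subsample of each class is
    drawn, a ridged Fisher discriminant is fitted, and each feature's
    effect is the mean of (a) its share of the projected class-mean
    difference mapped back to abundance units and (b) its raw class-mean
    abundance difference.  The returned signed score is
    ``sign * log10(1 + mean |effect| over rounds)``, positive when the
    feature is enriched in the second class (sorted label order).
    """
    x = abund_per_million.to_numpy(dtype=float)
    classes = np.asarray(classes)
    uniq = sorted(pd.unique(classes).tolist())
    if len(uniq) != 2:
        raise ValueError("lda_effect_size requires exactly 2 classes")
    y01 = (classes == uniq[1]).astype(int)
    n0, n1 = int((y01 == 0).sum()), int((y01 == 1).sum())
    if min(n0, n1) < 2:
        raise ValueError("each class needs at least 2 samples")

    idx0 = np.flatnonzero(y01 == 0)
    idx1 = np.flatnonzero(y01 == 1)
    k0 = max(2, int(round(boot_fraction * n0)))
    k1 = max(2, int(round(boot_fraction * n1)))

    def class_stream(b: int, idx: np.ndarray) -> np.random.Generator:
        # keyed by the class's membership, not its label, so swapping
        # class names reproduces the identical subsamples (score then
        # flips sign only)
        key = zlib.crc32(np.sort(idx).astype(np.int64).tobytes())
        return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(b, key)))

    effects = np.zeros((n_boot, x.shape[1]))
    for b in range(n_boot):
        sub0 = class_stream(b, idx0).choice(idx0, k0, replace=False)
        sub1 = class_stream(b, idx1).choice(idx1, k1, replace=False)
        sub = np.concatenate([sub0, sub1])
        ysub = y01[sub]
        xs = x[sub]
        w = _fisher_direction(xs, ysub)
        m0 = xs[ysub == 0].mean(axis=0)
        m1 = xs[ysub == 1].mean(axis=0)
        diff = m1 - m0
        proj_component = w * float(w @ diff)  # projected difference in abundance units
        effects[b] = 0.5 * (proj_component + diff)

    mean_abs = np.abs(effects).mean(axis=0)
    direction = np.sign(effects.mean(axis=0))
    score = direction * np.log10(1.0 + mean_abs)
    return pd.Series(score, index=abund_per_million.columns)


def lefse(
    table_relabund: pd.DataFrame,
    classes,
    alpha: float = 0.05,
    lda_cutoff: float = 2.0,
    n_boot: int = 30,
    seed: int = 0,
) -> list[EffectSizeRecord]:
    """Full screen: per-feature Kruskal-Wallis at ``alpha``, survivors
    scored by the bootstrapped discriminant (one-vs-rest per class when
    there are more than two classes).  Records sorted by score
    descending."""
    classes = np.asarray(classes)
    uniq = sorted(pd.unique(classes).tolist())
    if len(uniq) < 2:
        raise ValueError("need at least 2 classes")
    per_million = table_relabund * 1e6

    records: list[EffectSizeRecord] = []
    kw = {}
    survivors = []
    for col in per_million.columns:
        _, p = kruskal_wallis(per_million[col].to_numpy(), classes)
        kw[col] = p
        if p < alpha:
            survivors.append(col)

    if survivors:
        sub = per_million[survivors]
        if len(uniq) == 2:
            scores = {uniq[1]: lda_effect_size(sub, classes, n_boot=n_boot, seed=seed)}
        else:
            scores = {}
            for ci, c in enumerate(uniq):
                ovr = np.where(classes == c, "b_" + str(c), "a_rest")
                scores[c] = lda_effect_size(sub, ovr, n_boot=n_boot, seed=seed + ci)
        class_means = {c: per_million.loc[classes == c, survivors].mean(axis=0) for c in uniq}
        for col in survivors:
            best_score = max(abs(float(s[col])) for s in scores.values())
            enriched = max(uniq, key=lambda c: float(class_means[c][col]))
            passes = (kw[col] < alpha) and (best_score >= lda_cutoff)
            records.append(
                EffectSizeRecord(
                    taxon_id=str(col), enriched_class=str(enriched),
                    kw_p=float(kw[col]), lda_score=float(best_score), passes=bool(passes),
                )
            )
    for col in per_million.columns:
        if col not in survivors:
            records.append(
                EffectSizeRecord(taxon_id=str(col), enriched_class="", kw_p=float(kw[col]), lda_score=0.0, passes=False)
            )
    records.sort(key=lambda r: r.lda_score, reverse=True)
    return records
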