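"""Preprocessing of OTU count tables and subject rosters.

Order of operations in the pipeline is fixed: subject exclusion, then
rare-OTU filtering (dataset-wide relative abundance strictly below the
threshold), then rarefaction to a common depth (uniform subsampling
without replacement; samples below the target depth are dropped).
"""

from __future__ import annotations

import operator
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DegenerateInputError, OtuTable, as_mapping, rank_index

__all__ = [
    "ExclusionRule",
    "exclude_subjects",
    "filter_rare_otus",
    "rarefy",
    "relative_abundance",
    "aggregate_taxa",
]

_COMPARATORS = {
    ">": operator.gt,
    ">=": operator.ge,
    "<": operator.lt,
    "<=": operator.le,
    "==": operator.eq,
    "!=": operator.ne,
}


@dataclass(frozen=True)
class ExclusionRule:
    """One exclusion criterion: ``field comparator value``, restricted to
    hospitalized patients (``HP``), controls (``NHC``) or ``both``."""

    name: str
    field: str
    comparator: str
    value: object
    applies_to: str = "both"  # HP | NHC | both

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS and self.comparator != "is_true":
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.applies_to not in ("HP", "NHC", "both"):
            raise ValueError("applies_to must be 'HP', 'NHC' or 'both'")

    def matches(self, record) -> bool:
        rec = as_mapping(record)
        if self.field not in rec:
            raise KeyError(f"exclusion rule {self.name!r}: unknown field {self.field!r}")
        hospitalized = bool(rec.get("hospitalized", False))
        if self.applies_to == "HP" and not hospitalized:
            return False
        if self.applies_to == "NHC" and hospitalized:
            return False
        val = rec[self.field]
        if self.comparator == "is_true":
            return bool(val)
        if val is None or (isinstance(val, float) and val != val):
            return False
        return bool(_COMPARATORS[self.comparator](val, self.value))


def exclude_subjects(metadata, rules: list[ExclusionRule]):
    """Apply exclusion rules with first-match accounting.

    Each subject is excluded by (and counted under) the FIRST rule it
    matches, so the per-rule counts in the log are disjoint and sum to
    the number excluded.

    Parameters
    ----------
    metadata
        Sequence of metadata records (dataclasses, dicts or DataFrame rows).
    rules
        Rules tried in list order per subject.

    Returns
    -------
    (retained, log)
        Retained records in input order, and an ordered
        ``{rule name: count}`` log covering every rule.
    """
    if isinstance(metadata, pd.DataFrame):
        records = [row for _, row in metadata.iterrows()]
    else:
        records = list(metadata)
    log = {rule.name: 0 for rule in rules}
    retained = []
    for rec in records:
        for rule in rules:
            if rule.matches(rec):
                log[rule.name] += 1
                break
        else:
            retained.append(rec)
    return retained, log


def filter_rare_otus(table: OtuTable, threshold: float = 1e-4) -> OtuTable:
    """Drop OTUs whose dataset-wide relative abundance is strictly below
    ``threshold`` (default 0.01%).  An OTU at exactly the threshold is
    retained."""
    grand = int(table.counts.to_numpy().sum())
    if grand == 0:
        raise DegenerateInputError("table grand total is zero")
    totals = table.counts.sum(axis=0)
    keep = totals / grand >= threshold
    return OtuTable(
        table.counts.loc[:, keep.index[keep]],
        {o: table.taxonomy[o] for o in keep.index[keep] if o in table.taxonomy},
    )


def rarefy(table: OtuTable, depth: int, seed: int = 0) -> tuple[OtuTable, list[str]]:
    """Rarefy every sample to ``depth`` reads by uniform subsampling
    without replacement; samples with fewer than ``depth`` reads are
    dropped and returned in ``dropped_sample_ids``."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy()
    rowsums = counts.sum(axis=1)
    kept_rows, kept_ids, dropped = [], [], []
    for i, sid in enumerate(table.sample_ids):
        if rowsums[i] < depth:
            dropped.append(sid)
            continue
        if rowsums[i] == depth:
            kept_rows.append(counts[i].copy())
        else:
            kept_rows.append(rng.multivariate_hypergeometric(counts[i], depth))
        kept_ids.append(sid)
    new = pd.DataFrame(
        np.array(kept_rows, dtype=np.int64).reshape(len(kept_ids), counts.shape[1]),
        index=kept_ids,
        columns=table.otu_ids,
    )
    return OtuTable(new, dict(table.taxonomy)), dropped


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Counts divided by their row sums; raises on any all-zero sample."""
    counts = table.counts
    rowsums = counts.sum(axis=1)
    if (rowsums == 0).any():
        bad = list(rowsums.index[rowsums == 0])
        raise DegenerateInputError(f"zero-count samples: {bad}")
    return counts.div(rowsums, axis=0)


def aggregate_taxa(table: OtuTable, rank: str) -> OtuTable:
    """Sum OTU counts over shared labels at a taxonomic rank.

    OTUs lacking a label at that rank (short lineage or literal
    "unclassified") are pooled into an "unclassified" column.
    """
    idx = rank_index(rank)
    labels = []
    for otu in table.otu_ids:
        lin = table.lineage(otu)
        lab = lin[idx] if len(lin) > idx else "unclassified"
        labels.append(lab if lab else "unclassified")
    grouped = table.counts.T.groupby(pd.Index(labels, name=rank), sort=False).sum().T
    taxonomy = {}
    for lab in grouped.columns:
        if lab == "unclassified":
            taxonomy[lab] = ("unclassified",) * (idx + 1)
        else:
            for otu, l in zip(table.otu_ids, labels):
                if l == lab:
                    taxonomy[lab] = table.lineage(otu)[: idx + 1]
                    break
    return OtuTable(grouped, taxonomy)
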