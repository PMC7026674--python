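"""Core in-memory containers shared across the pipeline.

The central community object is :class:`OtuTable`, an integer count matrix
(samples x OTUs) with a taxonomy lineage per OTU, stored as a pandas
DataFrame.  Subject-level host factors live in :class:`SampleMetadata`
records; a cohort is usually handled as a pandas DataFrame built with
:func:`metadata_frame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DIAGNOSIS_LEAVES = ("NHC", "CD", "UC", "Infection", "Tumor", "Other")
CLUSTER_NAMES = ("C1", "C2", "C3")

#: taxonomic ranks used in lineage strings, kingdom..genus
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but analytically empty
    (all-zero counts, zero-variance vectors, ...)."""


@dataclass
class OtuTable:
    """Integer OTU count matrix with per-OTU taxonomy.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, columns are OTU ids, values are
        non-negative integers.
    taxonomy
        Mapping from OTU id to an ordered lineage tuple
        (kingdom, ..., genus).  Missing ranks may be "unclassified".
    """

    counts: pd.DataFrame
    taxonomy: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate OTU ids")
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("negative counts")
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        return OtuTable(self.counts.loc[list(sample_ids)], dict(self.taxonomy))

    def lineage(self, otu_id: str) -> tuple[str, ...]:
        return self.taxonomy.get(otu_id, ())


@dataclass
class SampleMetadata:
    """Host factors for one subject.

    ``true_cluster`` is generator ground truth and is ``None`` for real
    data.  Inflammation markers are ``nan`` where unavailable (the study
    collected them for hospitalized subjects only).
    """

    subject_id: str
    diagnosis_leaf: str
    hospitalized: bool
    age: float
    gender: str
    antibiotic: bool
    true_cluster: str | None = None
    crp: float = float("nan")
    leukocytes: float = float("nan")
    neutrophils: float = float("nan")

    def __post_init__(self) -> None:
        if self.diagnosis_leaf not in DIAGNOSIS_LEAVES:
            raise ValueError(f"unknown diagnosis leaf {self.diagnosis_leaf!r}")
        if self.hospitalized != (self.diagnosis_leaf != "NHC"):
            raise ValueError("hospitalized flag must equal (diagnosis_leaf != 'NHC')")
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.gender not in ("F", "M"):
            raise ValueError("gender must be 'F' or 'M'")
        for name in ("crp", "leukocytes", "neutrophils"):
            v = getattr(self, name)
            if v == v and v < 0:  # nan-safe
                raise ValueError(f"{name} must be >= 0 when present")


def metadata_frame(records: Sequence[SampleMetadata]) -> pd.DataFrame:
    """Collect metadata records into a DataFrame indexed by subject id."""
    df = pd.DataFrame([asdict(r) for r in records])
    return df.set_index("subject_id")


def lineage_string(lineage: Sequence[str]) -> str:
    """Render a lineage tuple as a mothur-style semicolon string with
    rank prefixes, e.g. ``k__Bacteria;p__Firmicutes;...``."""
    prefixes = ("k__", "p__", "c__", "o__", "f__", "g__")
    return ";".join(p + name for p, name in zip(prefixes, lineage)) + ";"


def parse_lineage(s: str) -> tuple[str, ...]:
    parts = [p for p in s.strip().strip(";").split(";") if p]
    out = []
    for p in parts:
        out.append(p.split("__", 1)[1] if "__" in p else p)
    return tuple(out)


def rank_index(rank: str) -> int:
    try:
        return RANKS.index(rank)
    except ValueError:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}") from None


def as_mapping(record) -> Mapping:
    """View a metadata record (dataclass, mapping, or pandas row) as a mapping."""
    if isinstance(record, Mapping):
        return record
    if isinstance(record, pd.Series):
        return record.to_dict()
    if hasattr(record, "__dataclass_fields__"):
        return asdict(record)
    return vars(record)
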