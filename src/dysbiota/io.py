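"""Reading and writing the study's flat-file formats.

OTU counts travel as mothur-style "shared" TSV (columns ``label``,
``Group``, ``numOtus`` then one column per OTU), taxonomy as a two-column
TSV (OTU id, semicolon lineage with rank prefixes), metadata as a plain
TSV with an index column of subject ids and ``NA`` for missing numerics.
Distance matrices use scikit-bio's lsmat writer (square TSV).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .datatypes import OtuTable, lineage_string, parse_lineage


def write_shared(table: OtuTable, path: str | Path, label: str = "0.03") -> None:
    df = table.counts.copy()
    out = pd.DataFrame(
        {
            "label": label,
            "Group": df.index,
            "numOtus": df.shape[1],
        }
    )
    out = pd.concat([out.reset_index(drop=True), df.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_shared(path: str | Path) -> pd.DataFrame:
    """Read a mothur shared file, returning the counts DataFrame
    (samples x OTUs); combine with :func:`read_taxonomy` to build an
    :class:`~dysbiota.datatypes.OtuTable`."""
    df = pd.read_csv(path, sep="\t")
    for col in ("label", "Group", "numOtus"):
        if col not in df.columns:
            raise ValueError(f"not a shared file: missing column {col!r}")
    counts = df.drop(columns=["label", "numOtus"]).set_index("Group")
    counts.index.name = "subject_id"
    return counts.astype(np.int64)


def write_taxonomy(table: OtuTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("OTU\tTaxonomy\n")
        for otu in table.otu_ids:
            fh.write(f"{otu}\t{lineage_string(table.lineage(otu))}\n")


def read_taxonomy(path: str | Path) -> dict[str, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.iloc[0]): parse_lineage(str(r.iloc[1])) for _, r in df.iterrows()}


def read_otu_table(shared_path: str | Path, taxonomy_path: str | Path | None = None) -> OtuTable:
    counts = read_shared(shared_path)
    tax = read_taxonomy(taxonomy_path) if taxonomy_path else {}
    return OtuTable(counts, tax)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", na_rep="NA")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], index_col=0)
    for col in ("hospitalized", "antibiotic"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    return df


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.write(str(path))


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    return DistanceMatrix.read(str(path))
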