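#!/usr/bin/env python
"""LEfSe-style differential abundance screens.

Contrasts hospitalized patients vs controls (bacteria and fungi) and
the four cluster-derived groups (bacteria), reporting Kruskal-Wallis
p-values and bootstrapped LDA effect sizes on the log10 scale.

Run 03_cluster_dysbiosis.py first.
"""

import dataclasses
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dysbiota import io as dio
from dysbiota import otu_preprocess as prep
from dysbiota.effect_size import lefse

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "lefse"


def frame(records) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def main() -> None:
    bact = dio.read_otu_table(ROOT / "preprocessed" / "bacteria.rarefied.shared",
                              ROOT / "preprocessed" / "bacteria.rarefied.taxonomy")
    fungi = dio.read_otu_table(ROOT / "preprocessed" / "fungi.rarefied.shared",
                               ROOT / "preprocessed" / "fungi.rarefied.taxonomy")
    md = dio.read_metadata(ROOT / "preprocessed" / "metadata.tsv")
    groups = pd.read_csv(ROOT / "clusters" / "assignments.tsv", sep="\t").set_index("subject_id")["group"]

    rel_b = prep.relative_abundance(bact)
    rel_f = prep.relative_abundance(fungi)

    OUT.mkdir(parents=True, exist_ok=True)
    contrasts = {
        "bacteria_HP_vs_NHC": (rel_b, np.where(md.loc[rel_b.index, "hospitalized"], "HP", "NHC")),
        "fungi_HP_vs_NHC": (rel_f, np.where(md.loc[rel_f.index, "hospitalized"], "HP", "NHC")),
        "bacteria_cluster_groups": (rel_b, groups.loc[rel_b.index].to_numpy()),
    }
    for name, (rel, classes) in contrasts.items():
        tab = frame(lefse(rel, classes, seed=SEED))
        tab.to_csv(OUT / f"{name}.tsv", sep="\t", index=False)
        passed = tab[tab["passes"]]
        print(f"{name}: {len(passed)} taxa pass (KW < 0.05 and LDA >= 2)")
        top = passed.head(5)
        for _, row in top.iterrows():
            lineage = bact.lineage(row.taxon_id) or fungi.lineage(row.taxon_id)
            genus = lineage[-1] if lineage else row.taxon_id
            print(f"   {row.taxon_id} ({genus}) enriched in {row.enriched_class}: LDA = {row.lda_score:.2f}")
    print(f"wrote effect-size tables to {OUT}")


if __name__ == "__main__":
    main()
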