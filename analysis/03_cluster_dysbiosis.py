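#!/usr/bin/env python
"""Dysbiosis typing: PAM on Bray-Curtis with silhouette-guided k.

Computes the bacterial Bray-Curtis matrix, chooses the number of
clusters by the highest mean silhouette, splits C1 by hospitalization,
and characterizes the groups: Shannon diversity, antibiotic-therapy
proportions, inflammation markers, and the Enterococcus-CRP and
Enterobacteriales-Lactobacillales correlations, plus AMOVA/PERMANOVA/
dispersion tests.

Run 02_preprocess.py first.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dysbiota import community_stats as cs
from dysbiota import io as dio
from dysbiota import otu_preprocess as prep
from dysbiota.pam_clustering import select_k

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "clusters"


def main() -> None:
    bact = dio.read_otu_table(ROOT / "preprocessed" / "bacteria.rarefied.shared",
                              ROOT / "preprocessed" / "bacteria.rarefied.taxonomy")
    md = dio.read_metadata(ROOT / "preprocessed" / "metadata.tsv").loc[bact.sample_ids]
    rel = prep.relative_abundance(bact)
    dm = cs.bray_curtis(rel)

    best_k, best, sil_table = select_k(dm, 2, 10)
    print(f"silhouette-optimal k = {best_k} "
          f"(mean silhouette {best.mean_silhouette:.3f})")

    raw = pd.Series(best.assignment)
    sizes = raw.value_counts().sort_values(ascending=False)
    relabel = {int(old): f"C{i + 1}" for i, old in enumerate(sizes.index)}
    cluster = raw.map(relabel)
    group = cluster.copy()
    group[(cluster == "C1") & md["hospitalized"]] = "C1(HP)"
    group[(cluster == "C1") & ~md["hospitalized"]] = "C1(NHC)"
    print("cluster sizes:", cluster.value_counts().sort_index().to_dict())

    shannon = pd.Series({s: cs.shannon_index(bact.counts.loc[s]) for s in bact.sample_ids})
    print("mean Shannon by group:",
          shannon.groupby(group).mean().round(2).sort_index().to_dict())

    abx = md["antibiotic"].astype(bool)
    print("antibiotic % by group:",
          (100 * abx.groupby(group).mean()).round(1).sort_index().to_dict())

    amova_cl = cs.amova(dm, cluster.to_numpy(), n_perm=999, seed=SEED)
    print(f"AMOVA across clusters: F = {amova_cl.statistic:.1f}, p = {amova_cl.p_value:.3f}")

    hp = md["hospitalized"].astype(bool)
    entero_cols = [o for o in bact.otu_ids if bact.lineage(o)[-1] == "Enterococcus"]
    entero = rel[entero_cols].sum(axis=1)
    r, p = cs.pearson_corr(entero[hp].to_numpy(), md.loc[hp[hp].index, "crp"].to_numpy())
    print(f"Enterococcus vs CRP (hospitalized): Pearson r = {r:.3f}, p = {p:.2g}")

    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"subject_id": group.index, "cluster": cluster.values,
                  "group": group.values,
                  "silhouette": [best.per_sample_silhouette[s] for s in group.index],
                  "shannon": shannon[group.index].values}).to_csv(
        OUT / "assignments.tsv", sep="\t", index=False)
    sil_table.to_csv(OUT / "silhouette_by_k.tsv", sep="\t", index=False)
    dio.write_distance_matrix(dm, OUT / "bray_curtis.lsmat")
    print(f"wrote cluster tables to {OUT}")


if __name__ == "__main__":
    main()
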