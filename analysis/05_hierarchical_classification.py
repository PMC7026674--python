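#!/usr/bin/env python
"""Hierarchical classification of diagnosis-based groups.

Trains Random Forests of 100 predictive clustering trees on four
feature sets — host factors alone and combined with the bacterial
and/or fungal community — evaluates per-node AUPRC out-of-bag, reports
delta-AUPRC over the host-only baseline (the information carried by each
microbial community), and ranks attributes by Genie3 score.

Run 02_preprocess.py first.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dysbiota import hmc_eval as he
from dysbiota import hmc_forest as hf
from dysbiota import io as dio
from dysbiota import otu_preprocess as prep

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "hmc"


def main() -> None:
    bact = dio.read_otu_table(ROOT / "preprocessed" / "bacteria.rarefied.shared")
    fungi = dio.read_otu_table(ROOT / "preprocessed" / "fungi.rarefied.shared")
    md = dio.read_metadata(ROOT / "preprocessed" / "metadata.tsv")
    rel_b = prep.relative_abundance(bact)
    rel_f = prep.relative_abundance(fungi)
    common = rel_b.index.intersection(rel_f.index)
    hierarchy = hf.build_hierarchy(hf.DEFAULT_HIERARCHY_PATHS)

    reports = {}
    for fs in he.FEATURE_SETS:
        feats = he.assemble_features(md.loc[common], fs, bacteria=rel_b.loc[common], fungi=rel_f.loc[common])
        reports[fs] = he.evaluate(feats, md, hierarchy, fs, protocol="OOB", n_trees=100, seed=SEED)
        print(f"{fs}: AUPRC-bar = {reports[fs].auprc_bar:.3f} "
              f"({reports[fs].n_samples} samples scored out-of-bag)")

    base = reports["HostOnly"]
    rows = []
    for fs in ("HostBacteria", "HostFungi", "HostBoth"):
        for node, d in he.delta_auprc(reports[fs], base).items():
            rows.append({"feature_set": fs, "node": node,
                         "auprc": reports[fs].auprc_per_node[node],
                         "auprc_host_only": base.auprc_per_node[node],
                         "delta_auprc": d})
    delta = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    delta.to_csv(OUT / "delta_auprc.tsv", sep="\t", index=False)

    for fs in ("HostBacteria", "HostFungi"):
        sub = delta[delta["feature_set"] == fs].set_index("node")
        print(f"delta-AUPRC ({fs}) at HP: {sub.loc['HP', 'delta_auprc']:+.3f}, "
              f"NHC: {sub.loc['NHC', 'delta_auprc']:+.3f}, "
              f"IBD: {sub.loc['IBD', 'delta_auprc']:+.3f}")

    # Genie3 attribute importance from the all-features forest
    feats = he.assemble_features(md.loc[common], "HostBoth", bacteria=rel_b.loc[common], fungi=rel_f.loc[common])
    y = np.vstack([hf.label_vector(l, hierarchy) for l in md.loc[feats.index, "diagnosis_leaf"]])
    w = hf.NodeWeights.from_hierarchy(hierarchy)
    forest = hf.train_forest(feats.to_numpy(float), y, w, hierarchy, n_trees=100, seed=SEED)
    scores = hf.genie3_importance(forest)
    order = np.argsort(scores)[::-1][:15]
    top = pd.DataFrame({"attribute": [feats.columns[i] for i in order],
                        "genie3_score": scores[order]})
    top.to_csv(OUT / "genie3_top_attributes.tsv", sep="\t", index=False)
    print("top 5 Genie3 attributes:", ", ".join(top["attribute"].head(5)))
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
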