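#!/usr/bin/env python
"""Preprocess the raw OTU tables to analysis-ready form.

Applies the fixed stage order — subject exclusion (age > 80), removal of
OTUs below 0.01% dataset-wide abundance, rarefaction to 3,000 (16S) /
1,000 (ITS2) reads — and writes the processed tables plus an exclusion
and preprocessing log under results/preprocessed/.

Run 01_simulate_cohort.py first.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dysbiota import io as dio
from dysbiota import otu_preprocess as prep

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "preprocessed"


def main() -> None:
    bact = dio.read_otu_table(ROOT / "cohort" / "bacteria.shared", ROOT / "cohort" / "bacteria.taxonomy")
    fungi = dio.read_otu_table(ROOT / "cohort" / "fungi.shared", ROOT / "cohort" / "fungi.taxonomy")
    md = dio.read_metadata(ROOT / "cohort" / "metadata.tsv")

    rules = [prep.ExclusionRule("age_over_80", "age", ">", 80, "both")]
    retained, log = prep.exclude_subjects(md, rules)
    keep = [r.name for r in retained]
    md = md.loc[keep]
    print(f"exclusion: retained {len(keep)} subjects; log = {log}")

    n_b0, n_f0 = bact.shape[1], fungi.shape[1]
    bact = prep.filter_rare_otus(bact.subset_samples(keep), 1e-4)
    fungi = prep.filter_rare_otus(fungi.subset_samples(keep), 1e-4)
    print(f"rare-OTU filter (<0.01% dataset-wide): bacteria {n_b0}->{bact.shape[1]}, fungi {n_f0}->{fungi.shape[1]}")

    bact, dropped_b = prep.rarefy(bact, 3000, seed=SEED * 1009 + 1)
    fungi, dropped_f = prep.rarefy(fungi, 1000, seed=SEED * 1009 + 2)
    print(f"rarefaction: bacteria kept {bact.shape[0]} (dropped {len(dropped_b)}); "
          f"fungi kept {fungi.shape[0]} (dropped {len(dropped_f)})")

    OUT.mkdir(parents=True, exist_ok=True)
    dio.write_shared(bact, OUT / "bacteria.rarefied.shared")
    dio.write_taxonomy(bact, OUT / "bacteria.rarefied.taxonomy")
    dio.write_shared(fungi, OUT / "fungi.rarefied.shared")
    dio.write_taxonomy(fungi, OUT / "fungi.rarefied.taxonomy")
    dio.write_metadata(md, OUT / "metadata.tsv")
    pd.DataFrame({"rule": list(log), "count": list(log.values())}).to_csv(
        OUT / "exclusion_log.tsv", sep="\t", index=False)
    print(f"wrote preprocessed tables to {OUT}")


if __name__ == "__main__":
    main()
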