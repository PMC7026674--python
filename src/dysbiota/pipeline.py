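"""End-to-end study pipeline.

Fixed stage order: subject exclusion -> rare-OTU filter -> rarefaction
-> (a) Bray-Curtis -> silhouette-guided PAM -> cluster characterization
(diversity, antibiotic proportions, inflammation markers, correlations,
LEfSe contrasts) and (b) the four-feature-set hierarchical
classification experiment (host factors alone and combined with the
bacterial and/or fungal community) with delta-AUPRC contrasts and
Genie3 attribute rankings.

Every stage draws its seed from the global seed by a fixed offset
(stage_seed = (global_seed * 1009 + stage_index) mod 2^31), so a rerun
with the same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import community_stats as cs
from . import hmc_eval as he
from . import hmc_forest as hf
from . import otu_preprocess as prep
from .datatypes import OtuTable, metadata_frame
from .effect_size import kruskal_wallis, lefse
from .pam_clustering import select_k
from .synthetic_cohort import CohortConfig, generate_cohort, taxon_otu_map

__all__ = ["AnalysisConfig", "ReportBundle", "run_full_analysis", "proportion_test"]


@dataclass
class AnalysisConfig:
    simulate: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    shared_bact: str | None = None
    taxonomy_bact: str | None = None
    shared_fungi: str | None = None
    taxonomy_fungi: str | None = None
    metadata_path: str | None = None
    exclusion_max_age: float = 80.0
    rare_threshold: float = 1e-4
    depth_bact: int = 3000
    depth_fungi: int = 1000
    k_min: int = 2
    k_max: int = 10
    lefse_alpha: float = 0.05
    lefse_cutoff: float = 2.0
    lefse_n_boot: int = 30
    n_trees: int = 100
    w0: float = 0.75
    min_leaf: int = 2
    protocol: str = "OOB"
    n_perm: int = 999
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        has_paths = self.shared_bact is not None
        if self.simulate == has_paths:
            raise ValueError("exactly one of simulate or input paths must be active")
        if self.simulate:
            self.cohort.validate()

    def config_hash(self) -> str:
        blob = repr(self).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class ReportBundle:
    seed: int
    config_hash: str
    preprocessing_log: pd.DataFrame
    cluster_assignments: pd.DataFrame
    silhouette_by_k: pd.DataFrame
    best_k: int
    cluster_summary: pd.DataFrame
    antibiotic_table: pd.DataFrame
    inflammation_table: pd.DataFrame
    correlation_table: pd.DataFrame
    beta_tests: pd.DataFrame
    lefse_tables: dict[str, pd.DataFrame]
    eval_reports: dict[str, he.EvalReport]
    delta_table: pd.DataFrame
    genie3_table: pd.DataFrame
    mwu_shannon: pd.DataFrame | None = field(default=None, repr=False)
    metadata: pd.DataFrame = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "preprocessing_log": self.preprocessing_log,
            "cluster_assignments": self.cluster_assignments,
            "silhouette_by_k": self.silhouette_by_k,
            "cluster_summary": self.cluster_summary,
            "antibiotic_table": self.antibiotic_table,
            "inflammation_table": self.inflammation_table,
            "correlation_table": self.correlation_table,
            "beta_tests": self.beta_tests,
            "delta_auprc": self.delta_table,
            "genie3_top_attributes": self.genie3_table,
        }
        if self.mwu_shannon is not None and len(self.mwu_shannon):
            tables["shannon_pairwise_mwu"] = self.mwu_shannon
        for name, df in self.lefse_tables.items():
            tables[f"lefse_{name}"] = df
        header = f"# seed={self.seed} config_hash={self.config_hash}\n"
        for name, df in tables.items():
            path = outdir / f"{name}.tsv"
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False)
        evals = {
            name: {
                "feature_set": r.feature_set,
                "protocol": r.protocol,
                "seed": r.seed,
                "auprc_per_node": r.auprc_per_node,
                "auprc_bar": r.auprc_bar,
                "delta_auprc_per_node": r.delta_auprc_per_node,
                "n_samples": r.n_samples,
                "dropped_samples": r.dropped_samples,
            }
            for name, r in self.eval_reports.items()
        }
        with open(outdir / "eval_reports.json", "w") as fh:
            json.dump({"seed": self.seed, "config_hash": self.config_hash, "reports": evals}, fh, indent=2)


def _round_half_away(x: float, ndigits: int = 1) -> float:
    factor = 10**ndigits
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


def proportion_test(counts) -> dict:
    """Chi-square homogeneity test on a 2 x k table of (yes, no) counts
    per column, with continuity correction for 2 x 2 tables; returns the
    statistic, p, per-column percentages (rounded half-away-from-zero to
    one decimal) and a small-sample warning flag when any expected cell
    is below 1."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    colsums = table.sum(axis=0)
    if (colsums == 0).any():
        raise ValueError("empty column")
    pct = [_round_half_away(100.0 * table[0, j] / colsums[j]) for j in range(table.shape[1])]
    if table.shape[1] == 1:
        return {"statistic": float("nan"), "p_value": float("nan"), "percentages": pct, "small_sample_warning": False}
    if np.allclose(table, table[:, [0]] * colsums / colsums[0]):
        # identical column compositions: no heterogeneity
        return {"statistic": 0.0, "p_value": 1.0, "percentages": pct, "small_sample_warning": False}
    correction = table.shape == (2, 2)
    chi2, p, _, expected = stats.chi2_contingency(table, correction=correction)
    return {
        "statistic": float(chi2),
        "p_value": float(p),
        "percentages": pct,
        "small_sample_warning": bool((expected < 1).any()),
    }


def _stage_seed(seed: int, stage: int) -> int:
    return (seed * 1009 + stage) % (2**31)


def _pairwise_mwu(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """All pairwise Mann-Whitney tests with Benjamini-Hochberg
    correction."""
    names = list(pd.unique(groups))
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = values[groups == names[i]].dropna()
            b = values[groups == names[j]].dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append({"group_a": names[i], "group_b": names[j], "u": float(stat), "p_raw": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    return df


def _genus_column(relabund: pd.DataFrame, table: OtuTable, genus: str) -> pd.Series:
    cols = [o for o in table.otu_ids if len(table.lineage(o)) >= 6 and table.lineage(o)[5] == genus]
    if not cols:
        return pd.Series(0.0, index=relabund.index)
    return relabund[cols].sum(axis=1)


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    config.validate()
    seed = config.seed
    log_rows: list[dict] = []

    # ---------------------------------------------------------- load/simulate
    if config.simulate:
        cohort = config.cohort
        cohort.seed = seed
        bact, fungi, records = generate_cohort(cohort)
        metadata = metadata_frame(records)
    else:
        from . import io as dio

        bact = dio.read_otu_table(config.shared_bact, config.taxonomy_bact)
        fungi = dio.read_otu_table(config.shared_fungi, config.taxonomy_fungi)
        metadata = dio.read_metadata(config.metadata_path)
    log_rows.append({"stage": "input", "detail": "n_subjects", "value": len(metadata)})

    # ---------------------------------------------------------- exclusion
    rules = [prep.ExclusionRule("age_over_80", "age", ">", config.exclusion_max_age, "both")]
    retained, excl_log = prep.exclude_subjects(metadata, rules)
    keep_ids = [r.name for r in retained]
    metadata = metadata.loc[keep_ids]
    bact = bact.subset_samples([s for s in bact.sample_ids if s in set(keep_ids)])
    fungi = fungi.subset_samples([s for s in fungi.sample_ids if s in set(keep_ids)])
    for rule, n in excl_log.items():
        log_rows.append({"stage": "exclusion", "detail": rule, "value": n})

    # ---------------------------------------------------------- filter + rarefy
    bact = prep.filter_rare_otus(bact, config.rare_threshold)
    fungi = prep.filter_rare_otus(fungi, config.rare_threshold)
    bact, dropped_b = prep.rarefy(bact, config.depth_bact, seed=_stage_seed(seed, 1))
    fungi, dropped_f = prep.rarefy(fungi, config.depth_fungi, seed=_stage_seed(seed, 2))
    log_rows.append({"stage": "rarefy_bacteria", "detail": "samples_dropped", "value": len(dropped_b)})
    log_rows.append({"stage": "rarefy_fungi", "detail": "samples_dropped", "value": len(dropped_f)})
    log_rows.append({"stage": "filter", "detail": "bacterial_otus", "value": bact.shape[1]})
    log_rows.append({"stage": "filter", "detail": "fungal_otus", "value": fungi.shape[1]})

    rel_b = prep.relative_abundance(bact)
    rel_f = prep.relative_abundance(fungi)
    meta_b = metadata.loc[bact.sample_ids]

    # ---------------------------------------------------------- clustering
    dm = cs.bray_curtis(rel_b)
    best_k, best, sil_table = select_k(dm, config.k_min, config.k_max)
    raw = pd.Series(best.assignment)
    sizes = raw.value_counts().sort_values(ascending=False)
    relabel = {int(old): f"C{rank + 1}" for rank, old in enumerate(sizes.index)}
    cluster = raw.map(relabel)
    group4 = cluster.copy()
    c1_mask = cluster == "C1"
    group4[c1_mask & meta_b["hospitalized"]] = "C1(HP)"
    group4[c1_mask & ~meta_b["hospitalized"]] = "C1(NHC)"

    assignments = pd.DataFrame(
        {
            "subject_id": cluster.index,
            "cluster": cluster.values,
            "group": group4.values,
            "silhouette": [best.per_sample_silhouette[s] for s in cluster.index],
        }
    )

    # ---------------------------------------------------------- cluster stats
    shannon = rel_b.apply(lambda row: cs.shannon_index(bact.counts.loc[row.name]), axis=1)
    _, kw_shannon = kruskal_wallis(shannon.to_numpy(), group4.to_numpy())
    mwu_shannon = _pairwise_mwu(shannon, group4)

    group_order = sorted(pd.unique(group4), key=lambda g: (g != "C1(NHC)", g != "C1(HP)", g))
    summary_rows = []
    for g in group_order:
        idx = group4[group4 == g].index
        summary_rows.append(
            {
                "group": g,
                "n": len(idx),
                "shannon_mean": float(shannon[idx].mean()),
                "shannon_sd": float(shannon[idx].std(ddof=1)) if len(idx) > 1 else float("nan"),
            }
        )
    cluster_summary = pd.DataFrame(summary_rows)

    abx = metadata.loc[group4.index, "antibiotic"].astype(bool)
    counts = np.array(
        [
            [int(abx[group4 == g].sum()) for g in group_order],
            [int((~abx[group4 == g]).sum()) for g in group_order],
        ]
    )
    prop = proportion_test(counts)
    antibiotic_table = pd.DataFrame(
        {
            "group": group_order,
            "n_on_antibiotics": counts[0],
            "n_total": counts.sum(axis=0),
            "percent": prop["percentages"],
        }
    )
    antibiotic_table["chi2"] = prop["statistic"]
    antibiotic_table["p_value"] = prop["p_value"]

    hp_mask = meta_b["hospitalized"].astype(bool)
    hp_groups = group4[hp_mask]
    inflammation_rows = []
    for marker in ("crp", "leukocytes", "neutrophils"):
        vals = metadata.loc[hp_groups.index, marker]
        if vals.notna().sum() >= 6 and hp_groups.nunique() >= 2:
            _, kw_p = kruskal_wallis(vals.fillna(vals.median()).to_numpy(), hp_groups.to_numpy())
        else:
            kw_p = float("nan")
        for g in sorted(pd.unique(hp_groups)):
            sub = vals[hp_groups == g].dropna()
            inflammation_rows.append(
                {"marker": marker, "group": g, "n": len(sub), "mean": float(sub.mean()) if len(sub) else float("nan"),
                 "kw_p": kw_p}
            )
    inflammation_table = pd.DataFrame(inflammation_rows)

    entero = _genus_column(rel_b, bact, "Enterococcus")
    crp = metadata.loc[entero.index, "crp"]
    corr_rows = []
    try:
        r, p = cs.pearson_corr(entero[hp_mask].to_numpy(), crp[hp_mask].to_numpy())
        corr_rows.append({"pair": "Enterococcus_vs_CRP", "r": r, "p_value": p, "n": int(hp_mask.sum())})
    except (ValueError, cs.DegenerateInputError):
        corr_rows.append({"pair": "Enterococcus_vs_CRP", "r": float("nan"), "p_value": float("nan"), "n": 0})
    order_b = prep.aggregate_taxa(bact, "order")
    rel_order = prep.relative_abundance(order_b)
    if {"Enterobacteriales", "Lactobacillales"}.issubset(rel_order.columns):
        hp_ids = meta_b.index[hp_mask]
        r2, p2 = cs.pearson_corr(
            rel_order.loc[hp_ids, "Enterobacteriales"].to_numpy(),
            rel_order.loc[hp_ids, "Lactobacillales"].to_numpy(),
        )
        corr_rows.append({"pair": "Enterobacteriales_vs_Lactobacillales", "r": r2, "p_value": p2, "n": len(hp_ids)})
    correlation_table = pd.DataFrame(corr_rows)

    # ---------------------------------------------------------- beta tests
    beta_rows = []
    amova_hp = cs.amova(dm, np.where(hp_mask, "HP", "NHC"), n_perm=config.n_perm, seed=_stage_seed(seed, 3))
    beta_rows.append({"test": "AMOVA_HP_vs_NHC", "statistic": amova_hp.statistic, "r_squared": float("nan"),
                      "p_value": amova_hp.p_value})
    amova_cl = cs.amova(dm, cluster.to_numpy(), n_perm=config.n_perm, seed=_stage_seed(seed, 4))
    beta_rows.append({"test": "AMOVA_clusters", "statistic": amova_cl.statistic, "r_squared": float("nan"),
                      "p_value": amova_cl.p_value})
    covars = meta_b[["age", "antibiotic"]].copy()
    covars["antibiotic"] = covars["antibiotic"].astype(float)
    for res in cs.permanova(dm, covars, n_perm=config.n_perm, seed=_stage_seed(seed, 5)):
        beta_rows.append({"test": f"PERMANOVA_bacteria_{res.term}", "statistic": res.statistic,
                          "r_squared": res.r_squared, "p_value": res.p_value})
    dm_f = cs.bray_curtis(rel_f)
    covars_f = metadata.loc[fungi.sample_ids, ["antibiotic"]].astype(float)
    for res in cs.permanova(dm_f, covars_f, n_perm=config.n_perm, seed=_stage_seed(seed, 6)):
        beta_rows.append({"test": f"PERMANOVA_fungi_{res.term}", "statistic": res.statistic,
                          "r_squared": res.r_squared, "p_value": res.p_value})
    disp = cs.dispersion_test(dm, np.where(hp_mask, "HP", "NHC"), n_perm=config.n_perm, seed=_stage_seed(seed, 7))
    beta_rows.append({"test": "dispersion_HP_vs_NHC", "statistic": disp.statistic, "r_squared": float("nan"),
                      "p_value": disp.p_value})
    beta_tests = pd.DataFrame(beta_rows)

    # ---------------------------------------------------------- LEfSe
    def lefse_frame(rel: pd.DataFrame, classes: np.ndarray, seed_: int) -> pd.DataFrame:
        recs = lefse(rel, classes, alpha=config.lefse_alpha, lda_cutoff=config.lefse_cutoff,
                     n_boot=config.lefse_n_boot, seed=seed_)
        return pd.DataFrame(
            [
                {"taxon": r.taxon_id, "enriched_class": r.enriched_class, "kw_p": r.kw_p,
                 "lda_score": r.lda_score, "passes": r.passes}
                for r in recs
            ]
        )

    lefse_tables = {
        "bacteria_HP_vs_NHC": lefse_frame(rel_b, np.where(hp_mask, "HP", "NHC"), _stage_seed(seed, 8)),
        "fungi_HP_vs_NHC": lefse_frame(
            rel_f, np.where(metadata.loc[fungi.sample_ids, "hospitalized"].astype(bool), "HP", "NHC"),
            _stage_seed(seed, 9)),
        "bacteria_cluster_groups": lefse_frame(rel_b, group4.to_numpy(), _stage_seed(seed, 10)),
    }

    # ---------------------------------------------------------- HMC experiment
    hierarchy = hf.build_hierarchy(hf.DEFAULT_HIERARCHY_PATHS)
    eval_reports: dict[str, he.EvalReport] = {}
    common = rel_b.index.intersection(rel_f.index)
    for fs in he.FEATURE_SETS:
        feats = he.assemble_features(metadata.loc[common], fs, bacteria=rel_b.loc[common], fungi=rel_f.loc[common])
        eval_reports[fs] = he.evaluate(
            feats, metadata, hierarchy, fs, protocol=config.protocol,
            n_trees=config.n_trees, min_leaf=config.min_leaf, w0=config.w0,
            seed=_stage_seed(seed, 11),
        )
    base = eval_reports["HostOnly"]
    delta_rows = []
    for fs in ("HostBacteria", "HostFungi", "HostBoth"):
        deltas = he.delta_auprc(eval_reports[fs], base)
        eval_reports[fs].delta_auprc_per_node = deltas
        for node, d in deltas.items():
            delta_rows.append({"feature_set": fs, "node": node,
                               "auprc": eval_reports[fs].auprc_per_node[node],
                               "auprc_host_only": base.auprc_per_node[node], "delta_auprc": d})
    delta_table = pd.DataFrame(delta_rows)

    feats_both = he.assemble_features(metadata.loc[common], "HostBoth", bacteria=rel_b.loc[common], fungi=rel_f.loc[common])
    y = np.vstack([hf.label_vector(l, hierarchy) for l in metadata.loc[feats_both.index, "diagnosis_leaf"]])
    weights = hf.NodeWeights.from_hierarchy(hierarchy, w0=config.w0)
    forest = hf.train_forest(feats_both.to_numpy(float), y, weights, hierarchy,
                             n_trees=config.n_trees, min_leaf=config.min_leaf,
                             seed=_stage_seed(seed, 12), feature_names=list(feats_both.columns))
    scores = hf.genie3_importance(forest)
    order = np.argsort(scores)[::-1][:20]
    genie3_table = pd.DataFrame(
        {"attribute": [feats_both.columns[i] for i in order], "genie3_score": scores[order]}
    )

    bundle = ReportBundle(
        seed=seed,
        config_hash=config.config_hash(),
        preprocessing_log=pd.DataFrame(log_rows),
        cluster_assignments=assignments,
        silhouette_by_k=sil_table,
        best_k=best_k,
        cluster_summary=cluster_summary.assign(shannon_kw_p=kw_shannon),
        antibiotic_table=antibiotic_table,
        inflammation_table=inflammation_table,
        correlation_table=correlation_table,
        beta_tests=beta_tests,
        lefse_tables=lefse_tables,
        eval_reports=eval_reports,
        delta_table=delta_table,
        genie3_table=genie3_table,
        mwu_shannon=mwu_shannon,
        metadata=metadata,
    )
    if config.outdir:
        bundle.write(config.outdir)
    return bundle
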