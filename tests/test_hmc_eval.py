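"""PR curves, AUPRC (vs a dense-threshold oracle), pooled micro-average
and the evaluation protocols."""

import numpy as np
import pandas as pd
import pytest

from dysbiota.hmc_eval import (
    EvalReport,
    assemble_features,
    auprc,
    delta_auprc,
    evaluate,
    pooled_pr,
    pr_curve,
)
from dysbiota.hmc_forest import DEFAULT_HIERARCHY_PATHS, build_hierarchy


def dense_auprc(scores, truth, n_grid=2000):
    """Numeric oracle: evaluate precision/recall on a dense threshold
    grid plus every achieved score, then trapezoid in recall order."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    thresholds = np.unique(np.concatenate([scores, np.linspace(scores.min(), scores.max(), n_grid)]))[::-1]
    pts = []
    npos = truth.sum()
    for t in thresholds:
        pred = scores >= t
        if pred.sum() == 0:
            continue
        pts.append((pred[truth == 1].sum() / npos, pred[truth == 1].sum() / pred.sum()))
    rec = np.array([p[0] for p in pts])
    prec = np.array([p[1] for p in pts])
    rec = np.concatenate([[0.0], rec])
    prec = np.concatenate([[prec[0]], prec])
    return float(np.trapezoid(prec, rec))


class TestPrCurve:
    def test_hand_enumerated_example(self):
        c = pr_curve([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        np.testing.assert_allclose(c.recall, [0.5, 0.5, 1.0, 1.0])
        np.testing.assert_allclose(c.precision, [1.0, 0.5, 2 / 3, 0.5])

    def test_perfect_separation_reaches_1_1(self):
        c = pr_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert (1.0, 1.0) in set(zip(c.recall, c.precision))

    def test_constant_scores_single_point_at_prevalence(self):
        c = pr_curve([0.5, 0.5, 0.5, 0.5], [1, 0, 0, 0])
        np.testing.assert_allclose(c.recall, [1.0])
        np.testing.assert_allclose(c.precision, [0.25])

    def test_recall_never_decreases(self, rng):
        for _ in range(10):
            scores = rng.random(30)
            truth = rng.integers(0, 2, 30)
            if truth.sum() == 0:
                truth[0] = 1
            c = pr_curve(scores, truth)
            assert (np.diff(c.recall) >= -1e-12).all()

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_curve([0.4, 0.6], [0, 0])


class TestAuprc:
    def test_perfect_classifier_scores_one(self):
        assert auprc(pr_curve([0.9, 0.8, 0.2], [1, 1, 0])) == pytest.approx(1.0)

    def test_constant_scores_equal_prevalence(self):
        assert auprc(pr_curve([0.3] * 8, [1, 1, 0, 0, 0, 0, 0, 0])) == pytest.approx(0.25)

    def test_hand_example_matches_dense_oracle(self):
        scores = [0.9, 0.8, 0.7, 0.6]
        truth = [1, 0, 1, 0]
        assert auprc(pr_curve(scores, truth)) == pytest.approx(dense_auprc(scores, truth), abs=1e-9)

    def test_random_instances_match_dense_oracle(self, rng):
        for _ in range(20):
            scores = rng.random(25)
            truth = rng.integers(0, 2, 25)
            if truth.sum() == 0:
                truth[0] = 1
            assert auprc(pr_curve(scores, truth)) == pytest.approx(dense_auprc(scores, truth), abs=1e-9)


class TestPooledPr:
    def test_single_node_equals_per_node_curve(self, rng):
        scores = rng.random(20)
        truth = rng.integers(0, 2, 20)
        truth[0] = 1
        _, bar = pooled_pr({"A": scores}, {"A": truth})
        assert bar == pytest.approx(auprc(pr_curve(scores, truth)))

    def test_duplicated_nodes_leave_curve_unchanged(self, rng):
        scores = rng.random(15)
        truth = rng.integers(0, 2, 15)
        truth[0] = 1
        _, bar1 = pooled_pr({"A": scores}, {"A": truth})
        _, bar2 = pooled_pr({"A": scores, "B": scores}, {"A": truth, "B": truth})
        assert bar1 == pytest.approx(bar2)

    def test_two_node_hand_counting(self):
        # node A: scores .9/.1 truth 1/0; node B: scores .5/.9 truth 1/0
        scores = {"A": np.array([0.9, 0.1]), "B": np.array([0.5, 0.9])}
        truth = {"A": np.array([1, 0]), "B": np.array([1, 0])}
        curve, bar = pooled_pr(scores, truth)
        # thresholds .9: predictions A1,B2 -> TP=1 FP=1; .5: +B1 -> TP=2 FP=1; .1: all -> TP=2 FP=2
        np.testing.assert_allclose(curve.recall, [0.5, 1.0, 1.0])
        np.testing.assert_allclose(curve.precision, [0.5, 2 / 3, 0.5])

    def test_invariant_to_node_order(self, rng):
        s1, s2 = rng.random(10), rng.random(10)
        t1 = rng.integers(0, 2, 10)
        t2 = rng.integers(0, 2, 10)
        t1[0] = t2[0] = 1
        _, a = pooled_pr({"A": s1, "B": s2}, {"A": t1, "B": t2})
        _, b = pooled_pr({"B": s2, "A": s1}, {"B": t2, "A": t1})
        assert a == pytest.approx(b)


def make_cohort_features(rng, n=60, informative=True):
    hierarchy = build_hierarchy(DEFAULT_HIERARCHY_PATHS)
    leaves = np.array(["NHC", "CD", "UC", "Tumor", "Infection", "Other"])
    leaf = leaves[rng.integers(0, 6, n)]
    meta = pd.DataFrame(
        {
            "diagnosis_leaf": leaf,
            "age": rng.normal(50, 10, n),
            "gender": np.where(rng.random(n) < 0.5, "F", "M"),
            "antibiotic": rng.random(n) < 0.3,
        },
        index=[f"S{i}" for i in range(n)],
    )
    x = pd.DataFrame(rng.normal(0, 1, (n, 5)), index=meta.index, columns=[f"f{j}" for j in range(5)])
    if informative:
        for j, l in enumerate(["NHC", "CD", "UC", "Tumor", "Infection"]):
            x.loc[leaf == l, f"f{j}"] += 4.0
    return x, meta, hierarchy


class TestEvaluate:
    def test_loo_scores_every_sample_exactly_once(self, rng):
        x, meta, hierarchy = make_cohort_features(rng, n=12)
        feats = pd.concat([assemble_features(meta, "HostOnly"), x], axis=1)
        rep = evaluate(feats, meta, hierarchy, "HostOnly", protocol="kfold", k=12, n_trees=5, seed=0)
        assert rep.n_samples == 12

    def test_oob_beats_null_on_separable_data(self):
        rng = np.random.default_rng(0)
        x, meta, hierarchy = make_cohort_features(rng, n=120)
        feats = pd.concat([assemble_features(meta, "HostOnly"), x], axis=1)
        rep = evaluate(feats, meta, hierarchy, "HostOnly", protocol="OOB", n_trees=40, seed=0)
        prevalence = (meta["diagnosis_leaf"] != "NHC").mean()
        assert rep.auprc_per_node["HP"] > prevalence
        assert 0 <= rep.auprc_bar <= 1

    def test_shuffled_labels_track_prevalence(self):
        rng = np.random.default_rng(1)
        x, meta, hierarchy = make_cohort_features(rng, n=100, informative=False)
        feats = pd.concat([assemble_features(meta, "HostOnly"), x], axis=1)
        meta = meta.copy()
        meta["diagnosis_leaf"] = rng.permutation(meta["diagnosis_leaf"].to_numpy())
        rep = evaluate(feats, meta, hierarchy, "HostOnly", protocol="OOB", n_trees=40, seed=1)
        prev_hp = (meta["diagnosis_leaf"] != "NHC").mean()
        assert abs(rep.auprc_per_node["HP"] - prev_hp) < 0.15

    def test_nodes_without_positives_absent(self, rng):
        x, meta, hierarchy = make_cohort_features(rng, n=40)
        meta = meta.copy()
        meta.loc[meta["diagnosis_leaf"] == "UC", "diagnosis_leaf"] = "CD"
        feats = assemble_features(meta, "HostOnly")
        rep = evaluate(feats, meta, hierarchy, "HostOnly", protocol="kfold", k=5, n_trees=5, seed=0)
        assert "UC" not in rep.auprc_per_node

    def test_oob_and_kfold_agree_on_clean_signal(self):
        rng = np.random.default_rng(3)
        x, meta, hierarchy = make_cohort_features(rng, n=150)
        feats = pd.concat([assemble_features(meta, "HostOnly"), x], axis=1)
        oob = evaluate(feats, meta, hierarchy, "HostOnly", protocol="OOB", n_trees=50, seed=3)
        kf = evaluate(feats, meta, hierarchy, "HostOnly", protocol="kfold", k=10, n_trees=50, seed=3)
        assert abs(oob.auprc_bar - kf.auprc_bar) < 0.1


class TestDeltaAuprc:
    def make_report(self, values, protocol="OOB", n=50):
        return EvalReport(
            feature_set="HostBacteria", protocol=protocol, seed=0,
            auprc_per_node=values, auprc_bar=float(np.mean(list(values.values()))), n_samples=n,
        )

    def test_identical_reports_give_zeros(self):
        r = self.make_report({"HP": 0.7, "NHC": 0.8})
        assert delta_auprc(r, r) == {"HP": 0.0, "NHC": 0.0}

    def test_ibd_node_contrast_arithmetic(self):
        rep = self.make_report({"IBD": 0.80})
        base = self.make_report({"IBD": 0.48})
        assert delta_auprc(rep, base)["IBD"] == pytest.approx(0.32)

    def test_negative_delta_allowed(self):
        rep = self.make_report({"UC": 0.10})
        base = self.make_report({"UC": 0.14})
        assert delta_auprc(rep, base)["UC"] == pytest.approx(-0.04)

    def test_protocol_mismatch_rejected(self):
        a = self.make_report({"HP": 0.5})
        b = self.make_report({"HP": 0.5}, protocol="kfold")
        with pytest.raises(ValueError, match="protocol"):
            delta_auprc(a, b)

    def test_nodes_absent_in_either_report_are_absent(self):
        a = self.make_report({"HP": 0.5, "CD": 0.4})
        b = self.make_report({"HP": 0.45})
        assert set(delta_auprc(a, b)) == {"HP"}
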