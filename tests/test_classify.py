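"""Feature assembly and SVM model evaluation."""

import numpy as np
import pandas as pd
import pytest

from peakspec import classify
from peakspec.classify import (
    FEATURE_GROUPS,
    FEATURE_NAMES,
    SUPERGROUPS,
    ModelSpec,
    cross_celltype_evaluation,
    feature_group_elimination,
    height_percentiles,
    high_clustered_subset,
    label_by_overlap,
    train_and_crossvalidate,
)
from peakspec.intervals import GenomicInterval, Peak, PeakSet

from conftest import random_peaks


def feature_frame(rng, n, informative=None):
    """Random feature table; `informative` columns get a label-linked shift."""
    X = pd.DataFrame(
        rng.normal(size=(n, len(FEATURE_NAMES))), columns=FEATURE_NAMES,
        index=[f"p{i}" for i in range(n)],
    )
    y = rng.integers(0, 2, size=n)
    for col in informative or []:
        X[col] += 1.5 * y
    labels = ["common" if v else "specific" for v in y]
    return X, labels


class TestLabelByOverlap:
    def test_identical_sets_all_common(self, rng):
        ps = PeakSet(random_peaks(rng, 10))
        comp = PeakSet(
            [Peak(p.interval, p.height, p.tf, "cellB", p.peak_id) for p in ps]
        )
        labels = label_by_overlap(ps, comp)
        assert set(labels.values()) == {"common"}

    def test_empty_comparison_all_specific(self, rng):
        ps = PeakSet(random_peaks(rng, 10))
        labels = label_by_overlap(ps, PeakSet([]))
        assert set(labels.values()) == {"specific"}

    def test_matches_pairwise_scan(self, rng):
        a = random_peaks(rng, 60)
        b = random_peaks(rng, 60, cell="cellB")
        labels = label_by_overlap(PeakSet(a), PeakSet(b))
        for p in a:
            expected = any(
                q.chrom == p.chrom and max(q.start, p.start) < min(q.end, p.end)
                for q in b
            )
            assert (labels[p.peak_id] == "common") == expected


class TestHeightPercentiles:
    def test_single_peak_is_100(self):
        ps = PeakSet([Peak(GenomicInterval("chr1", 0, 10), 5, "t", "c", "p0")])
        assert height_percentiles(ps) == {"p0": 100.0}

    def test_strictly_increasing_heights(self):
        ps = PeakSet(
            [Peak(GenomicInterval("chr1", i * 100, i * 100 + 10), i + 1, "t", "c", f"p{i}")
             for i in range(10)]
        )
        pct = height_percentiles(ps)
        assert [pct[f"p{i}"] for i in range(10)] == pytest.approx(
            [10.0 * (i + 1) for i in range(10)]
        )

    def test_ties_share_average_rank(self):
        ps = PeakSet(
            [Peak(GenomicInterval("chr1", i * 100, i * 100 + 10), 7, "t", "c", f"p{i}")
             for i in range(4)]
        )
        pct = height_percentiles(ps)
        assert list(pct.values()) == pytest.approx([62.5] * 4)  # mean rank 2.5 of 4


class TestTrainAndCrossvalidate:
    def test_separable_by_height(self, rng):
        X, _ = feature_frame(rng, 200)
        y = ["common" if v > 0 else "specific" for v in X["height_pct"]]
        res = train_and_crossvalidate(X, y, ModelSpec.height(), k=10, seed=0)
        assert res.mean_roc == pytest.approx(1.0)

    def test_random_labels_near_half(self):
        scores = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X, labels = feature_frame(rng, 400)
            res = train_and_crossvalidate(X, labels, ModelSpec.svm(), k=5, seed=seed)
            scores.append(res.mean_roc)
        assert abs(np.mean(scores) - 0.5) < 0.05

    def test_same_seed_reproducible(self, rng):
        X, labels = feature_frame(rng, 150, informative=["height_pct"])
        r1 = train_and_crossvalidate(X, labels, ModelSpec.svm(), k=5, seed=3)
        r2 = train_and_crossvalidate(X, labels, ModelSpec.svm(), k=5, seed=3)
        assert r1.fold_scores == r2.fold_scores

    def test_stratified_folds_preserve_proportions(self, rng):
        from sklearn.model_selection import StratifiedKFold

        y = np.array([1] * 30 + [0] * 70)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        for _, test_idx in skf.split(np.zeros((100, 1)), y):
            assert abs(int(y[test_idx].sum()) - 3) <= 1

    def test_single_class_rejected(self, rng):
        X, _ = feature_frame(rng, 50)
        with pytest.raises(ValueError):
            train_and_crossvalidate(X, ["common"] * 50, ModelSpec.svm(), k=5, seed=0)

    def test_model_feature_sets(self):
        assert ModelSpec.height().features == ("height_pct",)
        assert set(ModelSpec.hpp().features) == {"height_pct", "phylop", "pwm_score"}
        assert set(ModelSpec.svm().features) == set(FEATURE_NAMES)


class TestFeatureGroupElimination:
    def test_groups_cover_all_features_once(self):
        members = [f for g in FEATURE_GROUPS.values() for f in g]
        assert sorted(members) == sorted(FEATURE_NAMES)

    def test_generative_group_detected(self, rng):
        X, labels = feature_frame(rng, 600, informative=["height_pct"])
        deltas = feature_group_elimination(X, labels, k=5, seed=1)
        assert deltas["Height"] < -0.05
        others = [v for g, v in deltas.items() if g != "Height"]
        assert max(abs(v) for v in others) < 0.05

    def test_constant_group_is_neutral(self, rng):
        X, labels = feature_frame(rng, 400, informative=["height_pct"])
        X["phylop"] = 0.0
        deltas = feature_group_elimination(X, labels, k=5, seed=2)
        assert abs(deltas["PhyloP"]) < 0.02

    def test_supergroups_partition_reduced_features(self):
        removed = set(FEATURE_GROUPS["Height"]) | set(FEATURE_GROUPS["Cluster"])
        members = [f for g in SUPERGROUPS.values() for f in g]
        remaining = [f for f in FEATURE_NAMES if f not in removed]
        # every supergroup member is a remaining feature, none repeated;
        # peak length stays outside the three blocks
        assert len(members) == len(set(members))
        assert set(members) == set(remaining) - {"length"}

    def test_reduced_elimination_flags_context_block(self, rng):
        X, labels = feature_frame(rng, 600, informative=["chromatin_diff"])
        deltas = classify.grouped_elimination_reduced(X, labels, k=5, seed=4)
        assert deltas["cell_type_specific"] == min(deltas.values())
        assert deltas["cell_type_specific"] < -0.05


class TestHighClusteredSubset:
    def test_filter_matches_brute_force(self, rng):
        X, _ = feature_frame(rng, 300)
        X["height_pct"] = rng.uniform(0, 100, size=300)
        X["cluster_tfs"] = rng.integers(1, 9, size=300).astype(float)
        sub = high_clustered_subset(X)
        thr = X["cluster_tfs"].quantile(0.8)
        expected = set(
            X.index[(X["height_pct"] >= 90) & (X["cluster_tfs"] >= thr)]
        )
        assert set(sub.peak_ids) == expected
        assert sub.cluster_threshold == thr

    def test_degenerate_singleton_clusters(self, rng):
        X, _ = feature_frame(rng, 50)
        X["height_pct"] = rng.uniform(0, 100, size=50)
        X["cluster_tfs"] = 1.0
        sub = high_clustered_subset(X)
        assert sub.cluster_threshold == 1.0
        assert set(sub.peak_ids) == set(X.index[X["height_pct"] >= 90])


class TestCrossCelltypeEvaluation:
    def test_identical_test_context_matches_cv(self, rng):
        X, labels = feature_frame(rng, 500, informative=["height_pct"])
        lab = dict(zip(X.index, labels))
        res = cross_celltype_evaluation(X, lab, X, lab, ModelSpec.height(), k=5, seed=0)
        cv = train_and_crossvalidate(X, labels, ModelSpec.height(), k=5, seed=0)
        assert abs(res.mean_roc - cv.mean_roc) < 0.05

    def test_decoupled_context_hurts_full_model_more(self, rng):
        X, labels = feature_frame(
            rng, 800, informative=["height_pct", "chromatin_diff", "h3k4me3_diff"]
        )
        lab = dict(zip(X.index, labels))
        X_test = X.copy()
        # context features re-drawn independently of the labels in the third cell
        for col in ("chromatin_diff", "h3k4me3_diff"):
            X_test[col] = rng.normal(size=len(X))
        full_in = train_and_crossvalidate(X, labels, ModelSpec.svm(), k=5, seed=1).mean_roc
        h_in = train_and_crossvalidate(X, labels, ModelSpec.height(), k=5, seed=1).mean_roc
        full_x = cross_celltype_evaluation(X, lab, X_test, lab, ModelSpec.svm(), k=5, seed=1).mean_roc
        h_x = cross_celltype_evaluation(X, lab, X_test, lab, ModelSpec.height(), k=5, seed=1).mean_roc
        assert (full_in - full_x) > (h_in - h_x) + 0.03

    def test_mismatched_indices_rejected(self, rng):
        X, labels = feature_frame(rng, 60, informative=["height_pct"])
        lab = dict(zip(X.index, labels))
        X2 = X.iloc[:-5]
        with pytest.raises(ValueError):
            cross_celltype_evaluation(X, lab, X2, lab, ModelSpec.height(), k=5, seed=0)


class TestAssembleFeatures:
    def test_full_vector_matches_per_field_oracles(self, small_study):
        from peakspec import pipeline

        study = small_study
        ref, comp = study.config.cell_types[:2]
        contexts = pipeline.build_contexts(study, ref, comp)
        tf, (ps, ctx, labels) = sorted(contexts.items())[1]
        table = classify.assemble_feature_table(ps, ctx)
        assert list(table.columns)[:16] == FEATURE_NAMES
        pct = height_percentiles(ps)
        for p in list(ps)[:10]:
            row = table.loc[p.peak_id]
            assert row["length"] == p.length()
            assert row["height_pct"] == pytest.approx(pct[p.peak_id])
            own, other = ctx.dnase[p.peak_id]
            assert row["chromatin_avg"] == pytest.approx((own + other) / 2)
            assert row["chromatin_diff"] == pytest.approx(own - other)
            assert row["high_cpg"] + row["low_cpg"] <= 1
            assert 0 <= row["tss_dist"] <= 20_000

    def test_singleton_cluster_features(self):
        p = Peak(GenomicInterval("chr1", 1000, 1100), 42, "t", "c", "solo")
        ctx = classify.FeatureContext(
            promoters=__import__("peakspec.annotation", fromlist=["RegionSet"]).RegionSet("prom", []),
            genes=[],
            clusters=[],
            sequences={"solo": "ACGT" * 25},
            dnase={"solo": (0.1, 0.2)},
            h3k4me3={"solo": (0.0, 0.0)},
            h3k27me3={"solo": (0.0, 0.0)},
            phylop={"solo": 0.5},
        )
        row = classify.assemble_features(p, ctx, height_pct=100.0)
        assert row["cluster_tfs"] == 1.0
        assert row["cluster_avg_height"] == 42.0
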