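"""Cell-type-specificity classifiers: feature assembly, SVM models, CV.

Three models predict whether a reference-cell-type peak is also found in a
comparison cell type: the full SVM over 16 peak/region features, the
single-feature Height baseline, and the HPP baseline (height percentile,
conservation, motif score).  All are soft-margin linear SVMs evaluated by
stratified 10-fold cross-validation with per-fold standardization, scored
by area under the ROC curve on decision values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from . import annotation, signal
from .annotation import RegionSet, classify_cpg, cpg_observed_expected, region_overlap_flags
from .intervals import Peak, PeakSet, PeakCluster, cluster_lookup, overlap_flags

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_GROUPS",
    "SUPERGROUPS",
    "PWM_SCORE",
    "ModelSpec",
    "CvResult",
    "label_by_overlap",
    "height_percentiles",
    "FeatureContext",
    "assemble_features",
    "assemble_feature_table",
    "train_and_crossvalidate",
    "feature_group_elimination",
    "grouped_elimination_reduced",
    "high_clustered_subset",
    "cross_celltype_evaluation",
]

FEATURE_NAMES = [
    "height_pct",
    "length",
    "promoter",
    "tss_dist",
    "cluster_tfs",
    "cluster_avg_height",
    "chromatin_avg",
    "chromatin_diff",
    "h3k4me3_avg",
    "h3k4me3_diff",
    "h3k27me3_avg",
    "h3k27me3_diff",
    "cpg_freq",
    "high_cpg",
    "low_cpg",
    "phylop",
]

FEATURE_GROUPS: dict[str, list[str]] = {
    "Height": ["height_pct"],
    "Length": ["length"],
    "Promoter": ["promoter"],
    "TSS dist": ["tss_dist"],
    "Cluster": ["cluster_tfs", "cluster_avg_height"],
    "Chromatin": ["chromatin_avg", "chromatin_diff"],
    "H3K4me3": ["h3k4me3_avg", "h3k4me3_diff"],
    "H3K27me3": ["h3k27me3_avg", "h3k27me3_diff"],
    "CpG": ["cpg_freq", "high_cpg", "low_cpg"],
    "PhyloP": ["phylop"],
}

# After removing Height and Cluster features, the remaining features are
# grouped into three blocks (peak length belongs to none of them and stays
# in the base set throughout).
SUPERGROUPS: dict[str, list[str]] = {
    "cell_type_specific": [
        "chromatin_avg",
        "chromatin_diff",
        "h3k4me3_avg",
        "h3k4me3_diff",
        "h3k27me3_avg",
        "h3k27me3_diff",
    ],
    "promoter_sequence": ["promoter", "tss_dist", "cpg_freq", "high_cpg", "low_cpg"],
    "conservation": ["phylop"],
}

PWM_SCORE = "pwm_score"  # extra column used only by the HPP model

LABEL_COMMON = "common"
LABEL_SPECIFIC = "specific"


@dataclass(frozen=True)
class ModelSpec:
    """Named feature subset defining a classifier."""

    name: str
    features: tuple[str, ...]

    @staticmethod
    def svm() -> "ModelSpec":
        return ModelSpec("SVM", tuple(FEATURE_NAMES))

    @staticmethod
    def height() -> "ModelSpec":
        return ModelSpec("Height", ("height_pct",))

    @staticmethod
    def hpp() -> "ModelSpec":
        return ModelSpec("HPP", ("height_pct", "phylop", PWM_SCORE))


def label_by_overlap(reference: PeakSet, comparison: PeakSet) -> dict[str, str]:
    """'common' for reference peaks overlapping the comparison set, else 'specific'."""
    flags = overlap_flags(reference, comparison)
    return {
        p.peak_id: (LABEL_COMMON if f else LABEL_SPECIFIC)
        for p, f in zip(reference, flags)
    }


def height_percentiles(peaks: PeakSet | Sequence[Peak]) -> dict[str, float]:
    """Average-rank percentile of each peak's height within its set.

    percentile = average rank / n * 100, so a single peak scores 100 and
    tied heights share a percentile.
    """
    peaks = list(peaks)
    if not peaks:
        raise ValueError("empty peak set")
    heights = np.array([p.height for p in peaks], dtype=float)
    ranks = stats.rankdata(heights, method="average")
    pct = ranks / len(peaks) * 100.0
    return {p.peak_id: float(v) for p, v in zip(peaks, pct)}


@dataclass
class FeatureContext:
    """Everything feature assembly needs besides the peaks themselves.

    Signals are pre-computed per peak per cell type (reference first) for
    DNase, H3K4me3 and H3K27me3; `sequences` maps peak_id to the peak-region
    DNA; `clusters` come from pooled per-cell-type clustering.
    """

    promoters: RegionSet
    genes: Sequence[annotation.GeneModel]
    clusters: Sequence[PeakCluster]
    sequences: Mapping[str, str]
    dnase: Mapping[str, tuple[float, float]]  # peak_id -> (own, other)
    h3k4me3: Mapping[str, tuple[float, float]]
    h3k27me3: Mapping[str, tuple[float, float]]
    phylop: Mapping[str, float]
    pwm_scores: Mapping[str, float] | None = None  # peak_id -> best motif score


def assemble_features(peak: Peak, context: FeatureContext, height_pct: float) -> dict[str, float]:
    """The 16-feature vector for one peak (plus pwm_score when available)."""
    lookup = cluster_lookup(context.clusters)
    return _features_one(peak, context, height_pct,
                         region_overlap_flags([peak], context.promoters)[0], lookup)


def _features_one(
    peak: Peak,
    ctx: FeatureContext,
    height_pct: float,
    in_promoter: bool,
    lookup: Mapping[str, PeakCluster],
) -> dict[str, float]:
    key = f"{peak.tf}\t{peak.cell_type}\t{peak.peak_id}"
    cluster = lookup.get(key)
    if cluster is None:  # peak absent from pooled clustering: its own singleton
        n_tfs, avg_h = 1, float(peak.height)
    else:
        n_tfs, avg_h = cluster.n_tfs, cluster.avg_height
    seq = ctx.sequences[peak.peak_id]
    cpg_class = classify_cpg(seq)
    dn = ctx.dnase[peak.peak_id]
    k4 = ctx.h3k4me3[peak.peak_id]
    k27 = ctx.h3k27me3[peak.peak_id]
    row = {
        "height_pct": height_pct,
        "length": float(peak.length()),
        "promoter": float(in_promoter),
        "tss_dist": float(annotation.tss_distance(peak, ctx.genes)),
        "cluster_tfs": float(n_tfs),
        "cluster_avg_height": float(avg_h),
        "chromatin_avg": signal.signal_avg_diff(*dn)[0],
        "chromatin_diff": signal.signal_avg_diff(*dn)[1],
        "h3k4me3_avg": signal.signal_avg_diff(*k4)[0],
        "h3k4me3_diff": signal.signal_avg_diff(*k4)[1],
        "h3k27me3_avg": signal.signal_avg_diff(*k27)[0],
        "h3k27me3_diff": signal.signal_avg_diff(*k27)[1],
        "cpg_freq": cpg_observed_expected(seq),
        "high_cpg": float(cpg_class is annotation.CpGClass.RICH),
        "low_cpg": float(cpg_class is annotation.CpGClass.POOR),
        "phylop": float(ctx.phylop[peak.peak_id]),
    }
    if ctx.pwm_scores is not None:
        row[PWM_SCORE] = float(ctx.pwm_scores.get(peak.peak_id, 0.0))
    return row


def assemble_feature_table(peaks: PeakSet, context: FeatureContext) -> pd.DataFrame:
    """Feature matrix (rows = peaks, columns = Table features) for a peak set."""
    pct = height_percentiles(peaks)
    in_prom = region_overlap_flags(list(peaks), context.promoters)
    lookup = cluster_lookup(context.clusters)
    rows = {
        p.peak_id: _features_one(p, context, pct[p.peak_id], f, lookup)
        for p, f in zip(peaks, in_prom)
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    cols = FEATURE_NAMES + ([PWM_SCORE] if context.pwm_scores is not None else [])
    return df[cols]


@dataclass
class CvResult:
    model: str
    fold_scores: list[float]
    seed: int
    roc_points: tuple[list[float], list[float]] | None = None

    @property
    def mean_roc(self) -> float:
        return float(np.mean(self.fold_scores))


def _make_classifier(c: float = 1.0) -> LinearSVC:
    # soft-margin linear SVM; liblinear is deterministic for fixed data
    return LinearSVC(C=c, dual=True, max_iter=20000, random_state=0)


def _binary_labels(labels: Sequence[str]) -> np.ndarray:
    return np.array([1 if l == LABEL_COMMON else 0 for l in labels])


def train_and_crossvalidate(
    features: pd.DataFrame,
    labels: Sequence[str],
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    c: float = 1.0,
    keep_curve: bool = False,
) -> CvResult:
    """Stratified k-fold CV of a linear SVM on the spec's feature subset.

    Features are z-scored on each training fold; ROC AUC is computed per
    fold from the decision function on the held-out fold.
    """
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    cols = [f for f in spec.features if f in features.columns]
    if not cols:
        raise ValueError(f"no requested features present: {spec.features}")
    X = features[cols].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    all_scores = np.zeros(len(y))
    for train_idx, test_idx in skf.split(X, y):
        scaler = StandardScaler().fit(X[train_idx])
        clf = _make_classifier(c).fit(scaler.transform(X[train_idx]), y[train_idx])
        dec = clf.decision_function(scaler.transform(X[test_idx]))
        scores.append(float(roc_auc_score(y[test_idx], dec)))
        all_scores[test_idx] = dec
    curve = None
    if keep_curve:
        fpr, tpr, _ = roc_curve(y, all_scores)
        curve = (fpr.tolist(), tpr.tolist())
    return CvResult(spec.name, scores, seed, curve)


def feature_group_elimination(
    features: pd.DataFrame,
    labels: Sequence[str],
    groups: Mapping[str, Sequence[str]] = FEATURE_GROUPS,
    base_features: Sequence[str] = tuple(FEATURE_NAMES),
    k: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Mean ROC change after removing each feature group.

    Negative values mean the group carried information the remaining
    features could not replace.
    """
    base = tuple(base_features)
    full = train_and_crossvalidate(features, labels, ModelSpec("full", base), k, seed)
    deltas = {}
    for gname, members in groups.items():
        kept = tuple(f for f in base if f not in set(members))
        res = train_and_crossvalidate(features, labels, ModelSpec(gname, kept), k, seed)
        deltas[gname] = res.mean_roc - full.mean_roc
    return deltas


def grouped_elimination_reduced(
    features: pd.DataFrame,
    labels: Sequence[str],
    k: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Supergroup elimination after dropping Height and Cluster features."""
    removed = set(FEATURE_GROUPS["Height"]) | set(FEATURE_GROUPS["Cluster"])
    base = tuple(f for f in FEATURE_NAMES if f not in removed)
    return feature_group_elimination(
        features, labels, groups=SUPERGROUPS, base_features=base, k=k, seed=seed
    )


@dataclass
class HighClusteredSubset:
    peak_ids: list[str]
    height_threshold: float  # percentile cut (>= 90)
    cluster_threshold: float  # minimum cluster_tfs retained


def high_clustered_subset(
    features: pd.DataFrame, height_pct_min: float = 90.0, cluster_quantile: float = 0.8
) -> HighClusteredSubset:
    """Peaks among the 10% highest and the top 20% largest clusters.

    The cluster-size threshold is the `cluster_quantile` quantile of the
    cluster_tfs feature over all peaks; both thresholds are reported.
    """
    thr = float(features["cluster_tfs"].quantile(cluster_quantile))
    mask = (features["height_pct"] >= height_pct_min) & (features["cluster_tfs"] >= thr)
    return HighClusteredSubset(list(features.index[mask]), height_pct_min, thr)


def cross_celltype_evaluation(
    features_train: pd.DataFrame,
    labels_train: Mapping[str, str],
    features_test: pd.DataFrame,
    labels_test: Mapping[str, str],
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    c: float = 1.0,
) -> CvResult:
    """Train against one comparison cell type, test against another.

    Both tables index the same reference peaks; train rows use labels and
    cell-type-dependent features derived against the training comparison
    cell type, held-out rows use those derived against the test cell type.
    Fold assignment stratifies on the training labels; train and test peak
    subsets are disjoint by construction of the folds.
    """
    ids = list(features_train.index)
    if set(ids) != set(features_test.index):
        raise ValueError("train and test tables must index the same reference peaks")
    features_test = features_test.loc[ids]
    y_train = _binary_labels([labels_train[i] for i in ids])
    y_test = _binary_labels([labels_test[i] for i in ids])
    cols = [f for f in spec.features if f in features_train.columns]
    Xtr = features_train[cols].to_numpy(dtype=float)
    Xte = features_test[cols].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in skf.split(Xtr, y_train):
        if set(train_idx) & set(test_idx):
            raise RuntimeError("train/test fold overlap")
        scaler = StandardScaler().fit(Xtr[train_idx])
        clf = _make_classifier(c).fit(scaler.transform(Xtr[train_idx]), y_train[train_idx])
        dec = clf.decision_function(scaler.transform(Xte[test_idx]))
        if len(np.unique(y_test[test_idx])) < 2:
            continue  # degenerate fold under the test labeling
        scores.append(float(roc_auc_score(y_test[test_idx], dec)))
    if not scores:
        raise ValueError("no evaluable folds (single-class test labelings)")
    return CvResult(spec.name, scores, seed)
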