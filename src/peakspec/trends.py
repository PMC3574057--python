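"""Height-binned trend analyses.

Peaks are binned into ten approximately equal-sized groups by tag-count
height; per-bin feature means are regressed on bin index to test whether a
genomic characteristic (overlap rate, promoter membership, chromatin
accessibility, conservation, motif score, clustering) rises or falls with
peak height.  Also provides GC-balanced subsampling, top/bottom-height
chromatin comparisons (KS tests), and the expression/peak-count correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import Peak, PeakSet
from .signal import normalized_difference

__all__ = [
    "HeightBinning",
    "TrendResult",
    "bin_by_height",
    "bin_trend",
    "gc_balanced_subset",
    "extreme_height_comparison",
    "median_diff_by_height",
    "cofactor_pwm_ks",
    "expression_peakcount_correlation",
]

DEFAULT_N_BINS = 10
DEFAULT_ALPHA = 0.05


@dataclass
class HeightBinning:
    """Assignment of peaks to contiguous height bins (0 = lowest heights)."""

    n_bins: int
    assignments: dict[str, int]  # peak_id -> bin index

    def bin_members(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_bins)]
        for pid, b in self.assignments.items():
            out[b].append(pid)
        return out


def bin_by_height(peaks: PeakSet | Sequence[Peak], n_bins: int = DEFAULT_N_BINS) -> HeightBinning:
    """Sort peaks by height and split into n_bins nearly equal groups.

    Ties are broken by peak_id for determinism.  When the count is not
    divisible, the larger bins are the highest ones.
    """
    peaks = list(peaks)
    if len(peaks) < n_bins:
        raise ValueError(f"need at least {n_bins} peaks, got {len(peaks)}")
    order = sorted(peaks, key=lambda p: (p.height, p.peak_id))
    n = len(order)
    base, rem = divmod(n, n_bins)
    sizes = [base] * (n_bins - rem) + [base + 1] * rem
    assignments: dict[str, int] = {}
    i = 0
    for b, size in enumerate(sizes):
        for p in order[i : i + size]:
            assignments[p.peak_id] = b
        i += size
    return HeightBinning(n_bins, assignments)


@dataclass
class TrendResult:
    feature: str
    bin_means: list[float]
    slope: float
    stderr: float
    p_value: float
    significant: bool
    degenerate: bool = False


def bin_trend(
    binning: HeightBinning,
    feature_values: Mapping[str, float],
    feature: str = "",
    alpha: float = DEFAULT_ALPHA,
) -> TrendResult:
    """OLS regression of per-bin feature means on bin index 1..n.

    The fit is on the bin means (one point per bin), matching a per-bin
    presentation of the trend.  Zero variance of the means yields slope 0
    with p = 1 and a degenerate flag.
    """
    members = binning.bin_members()
    means = []
    for pids in members:
        vals = [feature_values[pid] for pid in pids]
        if not vals:
            raise ValueError("empty height bin")
        means.append(float(np.mean(vals)))
    x = np.arange(1, binning.n_bins + 1, dtype=float)
    y = np.array(means)
    if np.allclose(y, y[0]):
        return TrendResult(feature, means, 0.0, 0.0, 1.0, False, degenerate=True)
    fit = stats.linregress(x, y)
    return TrendResult(
        feature,
        means,
        float(fit.slope),
        float(fit.stderr),
        float(fit.pvalue),
        bool(fit.pvalue <= alpha),
    )


def gc_balanced_subset(
    peaks: PeakSet | Sequence[Peak],
    gc_fractions: Mapping[str, float],
    binning: HeightBinning,
    n_gc_bins: int = 10,
    trim: float = 0.05,
    seed: int = 0,
) -> list[Peak]:
    """Equalize the GC composition of every height bin by subsampling.

    GC outliers (the top and bottom `trim` quantiles) are removed, the
    remaining GC range is cut into `n_gc_bins` equal-interval bins, and
    within each height bin the same number of peaks (the minimum available
    across occupied GC bins) is sampled from each occupied GC bin.
    """
    rng = np.random.default_rng(seed)
    peaks = list(peaks)
    gc = np.array([gc_fractions[p.peak_id] for p in peaks])
    lo, hi = np.quantile(gc, [trim, 1 - trim])
    kept = [p for p, g in zip(peaks, gc) if lo <= g <= hi]
    if not kept:
        return []
    edges = np.linspace(lo, hi, n_gc_bins + 1)

    def gc_bin(g: float) -> int:
        b = int(np.searchsorted(edges, g, side="right")) - 1
        return min(max(b, 0), n_gc_bins - 1)

    selected: list[Peak] = []
    for pids in binning.bin_members():
        in_bin = [p for p in kept if p.peak_id in set(pids)]
        groups: dict[int, list[Peak]] = {}
        for p in in_bin:
            groups.setdefault(gc_bin(gc_fractions[p.peak_id]), []).append(p)
        if not groups:
            continue
        take = min(len(g) for g in groups.values())
        for b in sorted(groups):
            members = sorted(groups[b], key=lambda p: p.peak_id)
            idx = rng.choice(len(members), size=take, replace=False)
            selected.extend(members[i] for i in sorted(idx))
    return selected


@dataclass
class KsComparison:
    group: str
    side: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    skipped: bool = False


def _ks(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    # exact small-sample p-values below 30 per group, asymptotic otherwise
    method = "exact" if min(len(a), len(b)) < 30 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def extreme_height_comparison(
    peaks: Sequence[Peak],
    labels: Mapping[str, str],
    signal_own: Mapping[str, float],
    signal_other: Mapping[str, float],
    top_fraction: float = 0.3,
    side: str = "highest",
) -> list[KsComparison]:
    """KS tests of own- vs other-cell-type chromatin signal by height stratum.

    Selects the `top_fraction` highest (or lowest) peaks by height rank over
    the full set, then compares, at the cell-type-specific peaks of that
    stratum, the distribution of the signal in the peak's own cell type
    against the signal at the same regions in the other cell type; the
    common peaks' own/other comparison is included for reference.
    """
    if side not in ("highest", "lowest"):
        raise ValueError("side must be 'highest' or 'lowest'")
    order = sorted(peaks, key=lambda p: (p.height, p.peak_id))
    k = max(1, int(round(top_fraction * len(order))))
    stratum = order[-k:] if side == "highest" else order[:k]

    results = []
    for group in ("specific", "common"):
        pids = [p.peak_id for p in stratum if labels[p.peak_id] == group]
        a = np.array([signal_own[pid] for pid in pids])
        b = np.array([signal_other[pid] for pid in pids])
        if len(a) < 2:
            results.append(KsComparison(group, side, len(a), len(b), float("nan"),
                                        float("nan"), skipped=True))
            continue
        d, p = _ks(a, b)
        results.append(KsComparison(group, side, len(a), len(b), d, p))
    return results


def median_diff_by_height(
    binning: HeightBinning,
    signal_own: Mapping[str, float],
    signal_other: Mapping[str, float],
    peak_ids: Sequence[str] | None = None,
) -> list[float | None]:
    """Per height bin, median(own-cell signal) - median(other-cell signal).

    Restricted to `peak_ids` when given (e.g. the cell-type-specific peaks).
    Empty bins yield None.
    """
    allowed = set(peak_ids) if peak_ids is not None else None
    out: list[float | None] = []
    for pids in binning.bin_members():
        use = [pid for pid in pids if allowed is None or pid in allowed]
        if not use:
            out.append(None)
            continue
        own = np.median([signal_own[pid] for pid in use])
        other = np.median([signal_other[pid] for pid in use])
        out.append(float(own - other))
    return out


def cofactor_pwm_ks(
    scores_specific_a: Sequence[float], scores_specific_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample KS test between PWM-score samples from two peak groups."""
    if len(scores_specific_a) < 2 or len(scores_specific_b) < 2:
        raise ValueError("need at least 2 scores per sample")
    return _ks(np.asarray(scores_specific_a, float), np.asarray(scores_specific_b, float))


@dataclass
class ExpressionCountCorrelation:
    r: float
    p_value: float
    n: int
    r_excluded: float | None = None
    p_excluded: float | None = None
    n_excluded: int | None = None


def expression_peakcount_correlation(
    expr_a: Mapping[str, float],
    expr_b: Mapping[str, float],
    count_a: Mapping[str, int],
    count_b: Mapping[str, int],
    exclude: set[str] | frozenset[str] = frozenset(),
) -> ExpressionCountCorrelation:
    """Correlate normalized expression vs peak-count differences across TFs.

    Each TF contributes (expr_a-expr_b)/(expr_a+expr_b) on one axis and the
    same normalized difference of peak counts on the other.  Reported with
    all TFs and, when `exclude` is non-empty, with the excluded TFs removed.
    """
    tfs = sorted(set(expr_a) & set(expr_b) & set(count_a) & set(count_b))
    if len(tfs) < 3:
        raise ValueError("need at least 3 TFs")

    def corr(names: list[str]) -> tuple[float, float]:
        x = [normalized_difference(expr_a[t], expr_b[t]) for t in names]
        y = [normalized_difference(float(count_a[t]), float(count_b[t])) for t in names]
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)

    r, p = corr(tfs)
    result = ExpressionCountCorrelation(r, p, len(tfs))
    if exclude:
        kept = [t for t in tfs if t not in exclude]
        if len(kept) >= 3:
            r2, p2 = corr(kept)
            result.r_excluded, result.p_excluded, result.n_excluded = r2, p2, len(kept)
    return result
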