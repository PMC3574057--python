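"""Genomic-interval primitives: peaks, overlap counting and cross-TF clustering.

All coordinates are 0-based, half-open (BED convention).  "Overlap" always
means a non-empty intersection, i.e. at least one shared base pair.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "PeakCluster",
    "intervals_overlap",
    "count_overlapping",
    "overlap_flags",
    "relative_overlap",
    "windowed_overlap_counts",
    "extend_to_length",
    "cluster_peaks",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")

    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def widened(self, left: int, right: int) -> "GenomicInterval":
        """A copy extended by `left`/`right` bp, clamped at coordinate 0."""
        return GenomicInterval(self.chrom, max(0, self.start - left), self.end + right)


@dataclass(frozen=True)
class Peak:
    """A called ChIP-seq region with its tag-count height.

    The height is the number of sequenced tags mapping to the peak region and
    is the central covariate of every downstream analysis.
    """

    interval: GenomicInterval
    height: int
    tf: str
    cell_type: str
    peak_id: str

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError(f"peak height must be non-negative, got {self.height}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def length(self) -> int:
        return self.interval.length()


class PeakSet:
    """An ordered collection of peaks for one (tf, cell_type) pair."""

    def __init__(self, peaks: Iterable[Peak]):
        self.peaks: list[Peak] = list(peaks)
        tfs = {p.tf for p in self.peaks}
        cts = {p.cell_type for p in self.peaks}
        if len(tfs) > 1 or len(cts) > 1:
            raise ValueError(
                f"PeakSet must hold one (tf, cell_type); got tfs={sorted(tfs)}, "
                f"cell_types={sorted(cts)}"
            )
        ids = [p.peak_id for p in self.peaks]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate peak_id within PeakSet")
        self.tf = next(iter(tfs)) if tfs else None
        self.cell_type = next(iter(cts)) if cts else None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def heights(self) -> list[int]:
        return [p.height for p in self.peaks]


@dataclass
class PeakCluster:
    """A maximal group of peaks connected by extended-interval overlaps.

    Holds peaks from any number of TFs within one cell type; `n_tfs` and
    `avg_height` are the cluster features attached to every member peak.
    """

    members: list[Peak] = field(default_factory=list)

    @property
    def n_tfs(self) -> int:
        return len({p.tf for p in self.members})

    @property
    def avg_height(self) -> float:
        return sum(p.height for p in self.members) / len(self.members)


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share at least one base pair."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def _build_tree(peaks: Iterable[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for p in peaks:
        trees[p.chrom].addi(p.start, p.end, p)
    return trees


def overlap_flags(query: PeakSet | Sequence[Peak], target: PeakSet | Sequence[Peak]) -> list[bool]:
    """For each query peak, whether it overlaps >=1 target peak by >=1 bp."""
    trees = _build_tree(target)
    flags = []
    for p in query:
        tree = trees.get(p.chrom)
        flags.append(bool(tree is not None and tree.overlap(p.start, p.end)))
    return flags


def count_overlapping(query: PeakSet | Sequence[Peak], target: PeakSet | Sequence[Peak]) -> int:
    """Number of query peaks with at least one overlapping target peak.

    Each query peak counts at most once regardless of how many target peaks
    it touches.
    """
    return sum(overlap_flags(query, target))


def relative_overlap(set_a: PeakSet, set_b: PeakSet) -> float:
    """Overlap count of A against B divided by the smaller set size.

    Note the ratio can exceed 1 when several A peaks overlap a single B peak;
    the value is reported unclipped.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("relative_overlap requires two non-empty peak sets")
    return count_overlapping(set_a, set_b) / min(len(set_a), len(set_b))


def windowed_overlap_counts(
    set_a: PeakSet, set_b: PeakSet, extensions: Sequence[int]
) -> list[int]:
    """Overlap counts after widening each A peak by e/2 bp per side.

    `extensions` are total added lengths (half added to each side, clamped at
    coordinate 0).  Counts are non-decreasing in the extension.
    """
    for e in extensions:
        if e < 0:
            raise ValueError(f"extension must be non-negative, got {e}")
    trees = _build_tree(set_b)
    counts = []
    for e in extensions:
        left = e // 2
        right = e - left
        n = 0
        for p in set_a:
            tree = trees.get(p.chrom)
            if tree is not None and tree.overlap(max(0, p.start - left), p.end + right):
                n += 1
        counts.append(n)
    return counts


def extend_to_length(interval: GenomicInterval, target_length: int) -> GenomicInterval:
    """Symmetrically extend an interval to `target_length` bp total.

    Intervals already at or above the target are returned unchanged.  An odd
    deficit puts the extra base on the right; the left end is clamped at 0
    (no compensating shift).
    """
    deficit = target_length - interval.length()
    if deficit <= 0:
        return interval
    left = deficit // 2
    right = deficit - left
    return interval.widened(left, right)


def cluster_peaks(
    all_peaks: Sequence[Peak], target_length: int = 2000
) -> list[PeakCluster]:
    """Partition pooled peaks (all TFs, one cell type) into overlap clusters.

    Each peak is first extended to a total footprint of `target_length` bp;
    peaks whose extended footprints overlap, directly or through a chain of
    neighbours, form one cluster.  Computed by a sorted sweep per chromosome.
    """
    cell_types = {p.cell_type for p in all_peaks}
    if len(cell_types) > 1:
        raise ValueError(f"cluster_peaks expects one cell type, got {sorted(cell_types)}")

    by_chrom: dict[str, list[tuple[GenomicInterval, Peak]]] = defaultdict(list)
    for p in all_peaks:
        by_chrom[p.chrom].append((extend_to_length(p.interval, target_length), p))

    clusters: list[PeakCluster] = []
    for chrom in sorted(by_chrom):
        pairs = sorted(by_chrom[chrom], key=lambda ip: (ip[0].start, ip[0].end))
        current: list[Peak] = []
        reach = -1
        for iv, p in pairs:
            if current and iv.start < reach:
                current.append(p)
                reach = max(reach, iv.end)
            else:
                if current:
                    clusters.append(PeakCluster(current))
                current = [p]
                reach = iv.end
        if current:
            clusters.append(PeakCluster(current))
    return clusters


def cluster_lookup(clusters: Iterable[PeakCluster]) -> dict[str, PeakCluster]:
    """Map (tf, cell_type, peak_id) key of every member to its cluster."""
    lookup: dict[str, PeakCluster] = {}
    for c in clusters:
        for p in c.members:
            lookup[_peak_key(p)] = c
    return lookup


def _peak_key(p: Peak) -> str:
    return f"{p.tf}\t{p.cell_type}\t{p.peak_id}"
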