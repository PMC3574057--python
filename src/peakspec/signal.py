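"""Per-region quantification of tag tracks, conservation scores and expression.

Tag-based signals (DNase accessibility, histone-mark ChIP) are normalized as
tags overlapping the region, divided by region length and by the
experiment's total tag count in millions.  Conservation tracks (phyloP
semantics) are summarized as a length-weighted average over the overlapping
scored segments.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np

from .intervals import GenomicInterval

__all__ = [
    "TagSet",
    "SignalTrack",
    "DensityTags",
    "region_signal",
    "signal_avg_diff",
    "phylop_region_score",
    "RegionScore",
    "gc_fraction",
    "gene_expression",
    "expression_table",
    "normalized_difference",
]


class TagSet:
    """Aligned-read footprints plus the experiment's total tag count.

    Storage may be restricted to a region of interest, so `total_tags` can
    exceed the number of stored tags; it is the normalization denominator.
    Overlap counting uses sorted start/end arrays: a tag misses a region
    exactly when it starts at/after the region end or ends at/before the
    region start, and those two conditions are mutually exclusive.
    """

    def __init__(self, tags: Iterable[GenomicInterval], total_tags: int):
        self.tags = list(tags)
        if total_tags < len(self.tags):
            raise ValueError("total_tags smaller than the stored tag count")
        self.total_tags = total_tags
        self._sorted: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for t in self.tags:
            by_chrom[t.chrom].append((t.start, t.end))
        for chrom, pairs in by_chrom.items():
            starts = np.sort(np.array([s for s, _ in pairs]))
            ends = np.sort(np.array([e for _, e in pairs]))
            self._sorted[chrom] = (starts, ends)

    def count_overlapping(self, region: GenomicInterval) -> int:
        if region.chrom not in self._sorted:
            return 0
        starts, ends = self._sorted[region.chrom]
        n = len(starts)
        n_right = n - int(np.searchsorted(starts, region.end, side="left"))
        n_left = int(np.searchsorted(ends, region.start, side="right"))
        return n - n_right - n_left


class SignalTrack:
    """Sorted, non-overlapping scored segments (bedGraph semantics)."""

    def __init__(self, segments: Iterable[tuple[GenomicInterval, float]]):
        by_chrom: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
        for iv, v in segments:
            by_chrom[iv.chrom].append((iv.start, iv.end, float(v)))
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, segs in by_chrom.items():
            segs.sort()
            starts = np.array([s for s, _, _ in segs])
            ends = np.array([e for _, e, _ in segs])
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping segments on {chrom}")
            self._chroms[chrom] = (starts, ends, np.array([v for _, _, v in segs]))

    def overlapping(self, region: GenomicInterval) -> list[tuple[int, int, float]]:
        """(overlap_start, overlap_end, value) for segments touching region."""
        if region.chrom not in self._chroms:
            return []
        starts, ends, values = self._chroms[region.chrom]
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        out = []
        for i in range(lo, hi):
            s = max(int(starts[i]), region.start)
            e = min(int(ends[i]), region.end)
            if s < e:
                out.append((s, e, float(values[i])))
        return out


class DensityTags:
    """Coverage track treated as tag counts (per-base tag density mode).

    For inputs delivered as bedGraph coverage rather than individual read
    intervals: the overlap "count" over a region is the integral of segment
    value times overlap length, rounded to the nearest whole tag.
    """

    def __init__(self, track: SignalTrack, total_tags: int):
        self.track = track
        self.total_tags = total_tags

    def count_overlapping(self, region: GenomicInterval) -> int:
        mass = sum((e - s) * v for s, e, v in self.track.overlapping(region))
        return int(round(mass))


def region_signal(tags: "TagSet | DensityTags", region: GenomicInterval) -> float:
    """Tags per bp per million total tags over a region."""
    if tags.total_tags <= 0:
        raise ValueError("total_tags must be positive")
    n = tags.count_overlapping(region)
    return n / region.length() / (tags.total_tags / 1e6)


def signal_avg_diff(value_a: float, value_b: float) -> tuple[float, float]:
    """Average and difference (reference minus comparison) of two signals."""
    return (value_a + value_b) / 2.0, value_a - value_b


class RegionScore(NamedTuple):
    value: float
    covered: bool


def phylop_region_score(track: SignalTrack, region: GenomicInterval) -> RegionScore:
    """Length-weighted average of segment values overlapping the region.

    Regions with no scored coverage return 0.0 with `covered=False` so
    consumers can distinguish true zero conservation from missing data.
    """
    segs = track.overlapping(region)
    if not segs:
        return RegionScore(0.0, False)
    total = sum(e - s for s, e, _ in segs)
    weighted = sum((e - s) * v for s, e, v in segs)
    return RegionScore(weighted / total, True)


def gc_fraction(sequence: str) -> float:
    """G+C fraction; N counts in the denominator but not the numerator."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    return (s.count("G") + s.count("C")) / len(s)


def gene_expression(
    read_counts_per_exon: Mapping[str, list[int]],
    genes: Mapping[str, "object"],
    total_reads: int,
) -> dict[str, float]:
    """Per-symbol expression from exon-level read counts.

    For each transcript: mean over exons of count/exon_length, divided by
    total reads in millions.  Transcripts with no exonic read are excluded;
    remaining transcript values are averaged per gene symbol.

    `genes` maps transcript name to a GeneModel; `read_counts_per_exon` maps
    transcript name to per-exon counts in genomic exon order.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    per_symbol: dict[str, list[float]] = defaultdict(list)
    for tx_name, counts in read_counts_per_exon.items():
        gene = genes[tx_name]
        exons = gene.exons
        if len(counts) != len(exons):
            raise ValueError(f"exon count mismatch for {tx_name}")
        if sum(counts) < 1:
            continue
        density = float(np.mean([c / ex.length() for c, ex in zip(counts, exons)]))
        per_symbol[gene.symbol].append(density / (total_reads / 1e6))
    return {sym: float(np.mean(vals)) for sym, vals in per_symbol.items()}


@dataclass
class ExpressionTable:
    """Per-gene-symbol expression values (length- and depth-normalized)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        for sym, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative expression for {sym}")

    def __getitem__(self, symbol: str) -> float:
        return self.values[symbol]


def expression_table(values: Mapping[str, float]) -> ExpressionTable:
    return ExpressionTable(dict(values))


def normalized_difference(a: float, b: float) -> float:
    """Relative difference (a-b)/(a+b), bounded in [-1, 1] for a,b >= 0."""
    if a < 0 or b < 0:
        raise ValueError("inputs must be non-negative")
    if a + b == 0:
        raise ValueError("a + b must be positive")
    return (a - b) / (a + b)
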