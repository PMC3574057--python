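"""SNP genotype analysis downstream of genotype calling.

Selects SNPs that are homozygous for different alleles in two cell lines,
rescored the binding motif under each genotype, and runs the paired
statistics that ask whether a cell line's own genotype scores better than
the other line's genotype in its cell-type-specific peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .motifs import max_pwm_score

__all__ = [
    "Genotype",
    "SnpRecord",
    "GenotypeMotifPair",
    "select_homozygous_different",
    "snp_in_best_motif",
    "genotype_alleles",
    "genotype_motif_scores",
    "genotype_motif_test",
    "height_motifscore_correlation",
    "snp_peak_summary",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_QUALITY = 20.0


class Genotype(Enum):
    HOM_REF = "0"
    HOM_ALT = "1"
    HET = "het"
    MISSING = "."


@dataclass(frozen=True)
class SnpRecord:
    """A genotyped single-nucleotide variant with per-cell-type calls.

    `genotypes` maps cell-type name to a Genotype; quality (Q), alternate
    allele frequency (AF) and read depth (DP) follow the genotype caller's
    conventions.
    """

    snp_id: str
    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    genotypes: Mapping[str, Genotype]
    quality: float = 0.0
    alt_freq: float = 0.0
    depth: int = 0

    def __post_init__(self) -> None:
        for a in (self.ref_allele, self.alt_allele):
            if a not in "ACGT" or len(a) != 1:
                raise ValueError(f"alleles must be single A/C/G/T bases, got {a!r}")
        if not 0.0 <= self.alt_freq <= 1.0:
            raise ValueError(f"AF must be in [0,1], got {self.alt_freq}")
        if self.depth < 0:
            raise ValueError("DP must be non-negative")

    def allele_for(self, cell_type: str) -> str | None:
        gt = self.genotypes.get(cell_type, Genotype.MISSING)
        if gt == Genotype.HOM_REF:
            return self.ref_allele
        if gt == Genotype.HOM_ALT:
            return self.alt_allele
        return None


def select_homozygous_different(
    snps: Iterable[SnpRecord],
    cell_a: str,
    cell_b: str,
    min_quality: float = DEFAULT_MIN_QUALITY,
) -> list[SnpRecord]:
    """SNPs homozygous in both cell types but for different alleles.

    Heterozygous, missing, or low-quality calls are excluded (quality stands
    in for external variant-panel filtering).
    """
    selected = []
    for snp in snps:
        ga = snp.genotypes.get(cell_a, Genotype.MISSING)
        gb = snp.genotypes.get(cell_b, Genotype.MISSING)
        if Genotype.MISSING in (ga, gb):
            logger.warning("SNP %s missing a genotype call; skipped", snp.snp_id)
            continue
        if snp.quality < min_quality:
            continue
        if ga in (Genotype.HOM_REF, Genotype.HOM_ALT) and gb in (
            Genotype.HOM_REF,
            Genotype.HOM_ALT,
        ) and ga != gb:
            selected.append(snp)
    return selected


def snp_in_best_motif(
    peak_sequence: str, matrix: np.ndarray, snp_offset: int
) -> bool:
    """Whether a SNP falls inside the best-scoring motif window of a peak.

    The hit footprint is [offset, offset + W) in forward coordinates for
    either strand.  Returns False when no valid motif window exists.
    """
    if not 0 <= snp_offset < len(peak_sequence):
        raise ValueError("snp_offset outside sequence")
    hit = max_pwm_score(matrix, peak_sequence)
    if hit is None:
        return False
    w = matrix.shape[1]
    return hit.offset <= snp_offset < hit.offset + w


@dataclass(frozen=True)
class GenotypeMotifPair:
    """Best motif scores of one peak under two genotypes."""

    peak_id: str
    score_own: float  # genotype of the cell type bearing the peak
    score_other: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.score_own) and np.isfinite(self.score_other)):
            raise ValueError("scores must be finite")


def genotype_alleles(
    snps: Sequence[SnpRecord], cell_type: str
) -> list[tuple[int, str]]:
    """(position, allele) pairs for a cell type's homozygous calls."""
    out = []
    for snp in snps:
        allele = snp.allele_for(cell_type)
        if allele is not None:
            out.append((snp.pos, allele))
    return out


def genotype_motif_scores(
    peak_sequence: str,
    seq_start: int,
    matrix: np.ndarray,
    snps: Sequence[SnpRecord],
    cell_own: str,
    cell_other: str,
    peak_id: str = "",
) -> GenotypeMotifPair | None:
    """Rescan a peak sequence under each cell type's genotype.

    All homozygous SNP alleles of a genotype are substituted before scanning
    (positions are genomic; `seq_start` anchors the sequence).  Returns None
    when either scan finds no valid window.
    """
    hits = []
    for cell in (cell_own, cell_other):
        seq = peak_sequence
        for pos, allele in genotype_alleles(snps, cell):
            off = pos - seq_start
            if 0 <= off < len(seq):
                seq = seq[:off] + allele + seq[off + 1 :]
        hits.append(max_pwm_score(matrix, seq))
    if hits[0] is None or hits[1] is None:
        return None
    return GenotypeMotifPair(peak_id, hits[0].score, hits[1].score)


@dataclass
class PairedTestResult:
    t_statistic: float
    p_value: float
    n_higher_own: int
    n_higher_other: int
    degenerate: bool = False


def genotype_motif_test(pairs: Sequence[GenotypeMotifPair]) -> PairedTestResult:
    """One-sided paired t-test of own-genotype score > other-genotype score.

    Also tallies how many peaks score higher under each genotype.  When every
    difference is zero the test is undefined and p is reported as 1.0.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    own = np.array([p.score_own for p in pairs])
    other = np.array([p.score_other for p in pairs])
    diffs = own - other
    n_hi = int(np.sum(diffs > 0))
    n_lo = int(np.sum(diffs < 0))
    if np.allclose(diffs, 0.0):
        return PairedTestResult(0.0, 1.0, n_hi, n_lo, degenerate=True)
    t, p = stats.ttest_rel(own, other, alternative="greater")
    return PairedTestResult(float(t), float(p), n_hi, n_lo)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    degenerate: bool = False


def height_motifscore_correlation(
    pairs: Sequence[tuple[float, float]]
) -> CorrelationResult:
    """Pearson correlation of (height difference, motif-score difference).

    Used on common peaks to ask whether genotype-driven motif-score
    differences track peak-height differences between the cell lines.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.array([a for a, _ in pairs])
    y = np.array([b for _, b in pairs])
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), len(pairs), degenerate=True)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(pairs))


@dataclass
class SnpCategorySummary:
    n_peaks: int
    n_with_snp: int
    n_snps: int
    n_hom_diff_snps: int

    @property
    def frac_with_snp(self) -> float:
        return self.n_with_snp / self.n_peaks if self.n_peaks else 0.0

    @property
    def frac_hom_diff(self) -> float:
        return self.n_hom_diff_snps / self.n_snps if self.n_snps else 0.0


def snp_peak_summary(
    peak_categories: Mapping[str, str],
    snps_per_peak: Mapping[str, Sequence[SnpRecord]],
    cell_a: str,
    cell_b: str,
    min_quality: float = DEFAULT_MIN_QUALITY,
) -> dict[str, SnpCategorySummary]:
    """Per overlap category: SNP-bearing peak fraction and hom-diff SNP share.

    `peak_categories` maps peak_id to a category label (e.g. 'common',
    'specific_<cell>'); `snps_per_peak` maps peak_id to its SNP records.
    """
    out: dict[str, SnpCategorySummary] = {}
    by_cat: dict[str, list[str]] = {}
    for pid, cat in peak_categories.items():
        by_cat.setdefault(cat, []).append(pid)
    for cat, pids in sorted(by_cat.items()):
        n_with = 0
        n_snps = 0
        n_hd = 0
        for pid in pids:
            snps = list(snps_per_peak.get(pid, ()))
            if snps:
                n_with += 1
            n_snps += len(snps)
            n_hd += len(
                select_homozygous_different(snps, cell_a, cell_b, min_quality)
            )
        out[cat] = SnpCategorySummary(len(pids), n_with, n_snps, n_hd)
    return out
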