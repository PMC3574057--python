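"""PWM construction and log-odds motif scanning.

A PWM is a 4 x W base-count matrix (rows A, C, G, T).  Scoring converts the
counts to log2-odds against a genome background with a pseudocount of 1 per
cell, then takes the maximum-scoring window over every offset on both
strands.  Allele rescoring substitutes a base and rescans, which is how the
genotype analysis quantifies motif disruption by SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BASES",
    "PWM",
    "Background",
    "MotifHit",
    "genome_background",
    "logodds_matrix",
    "max_pwm_score",
    "rescore_with_allele",
    "information_content",
    "select_pwm",
    "reverse_complement",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BACKGROUND_FLOOR = 1e-6


@dataclass(frozen=True)
class PWM:
    """A named 4 x W count matrix over (A, C, G, T)."""

    name: str
    counts: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"counts must be 4 x W with W >= 1, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=0))


@dataclass(frozen=True)
class Background:
    """Genome-wide base frequencies (A, C, G, T)."""

    freq: np.ndarray

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        if freq.shape != (4,):
            raise ValueError("background must have 4 frequencies")
        if abs(freq.sum() - 1.0) > 1e-9 or np.any(freq <= 0):
            raise ValueError("background frequencies must be positive and sum to 1")
        object.__setattr__(self, "freq", freq)


@dataclass(frozen=True)
class MotifHit:
    """Best-scoring motif window: forward-coordinate offset, strand, score."""

    offset: int
    strand: str
    score: float


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def genome_background(sequences: Iterable[str]) -> Background:
    """Base frequencies counted over sequences; N ignored.

    Frequencies are floored at a tiny positive value and renormalized so the
    log-odds transform stays finite even for degenerate genomes.
    """
    counts = np.zeros(4)
    for seq in sequences:
        s = seq.upper()
        for i, b in enumerate(BASES):
            counts[i] += s.count(b)
    if counts.sum() == 0:
        raise ValueError("no A/C/G/T bases in input")
    freq = counts / counts.sum()
    freq = np.maximum(freq, BACKGROUND_FLOOR)
    return Background(freq / freq.sum())


def logodds_matrix(pwm: PWM, background: Background) -> np.ndarray:
    """log2 of (pseudocounted column probability / background probability)."""
    c = pwm.counts + pwm.pseudocount
    probs = c / c.sum(axis=0, keepdims=True)
    return np.log2(probs / background.freq[:, None])


def _encode(sequence: str) -> np.ndarray:
    """Sequence as base indices; non-ACGT becomes -1."""
    s = sequence.upper()
    out = np.full(len(s), -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(s.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def _strand_scores(matrix: np.ndarray, encoded: np.ndarray) -> np.ndarray:
    """Window scores at every forward offset; NaN where a window contains N."""
    w = matrix.shape[1]
    n = len(encoded) - w + 1
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(w):
        idx = encoded[j : j + n]
        ok = idx >= 0
        valid &= ok
        scores[ok] += matrix[idx[ok], j]
    scores[~valid] = np.nan
    return scores


def max_pwm_score(matrix: np.ndarray, sequence: str) -> MotifHit | None:
    """Best log-odds window over all offsets and both strands.

    The minus strand is scored by scanning the reverse-complemented matrix
    along the forward sequence, so the reported offset is always in forward
    coordinates and the hit footprint is [offset, offset + W).  Ties prefer
    the smaller offset, then '+' over '-'.  Windows containing non-ACGT
    bases are skipped; returns None when no valid window exists.
    """
    w = matrix.shape[1]
    if len(sequence) < w:
        raise ValueError(f"sequence shorter than matrix width {w}")
    encoded = _encode(sequence)
    fwd = _strand_scores(matrix, encoded)
    rc_matrix = matrix[::-1, ::-1]  # complement rows (T,G,C,A order), reverse columns
    rev = _strand_scores(rc_matrix, encoded)

    stacked = np.stack([fwd, rev], axis=1)  # (offset, strand) with '+' first
    if np.all(np.isnan(stacked)):
        return None
    best_score = np.nanmax(stacked)
    flat = np.where(stacked.ravel() == best_score)[0][0]  # offset-major: ties
    offset, strand_i = divmod(int(flat), 2)  # prefer smaller offset, then '+'
    return MotifHit(offset, "+-"[strand_i], float(best_score))


def rescore_with_allele(
    matrix: np.ndarray, sequence: str, pos: int, allele: str
) -> MotifHit | None:
    """Best score after substituting `allele` at `pos` (forward coordinates).

    The minus strand sees the complementary base automatically since both
    strands are scanned from the forward sequence.
    """
    if not 0 <= pos < len(sequence):
        raise ValueError(f"position {pos} outside sequence of length {len(sequence)}")
    if allele.upper() not in _BASE_INDEX:
        raise ValueError(f"allele must be one of A/C/G/T, got {allele!r}")
    edited = sequence[:pos] + allele.upper() + sequence[pos + 1 :]
    return max_pwm_score(matrix, edited)


def information_content(pwm: PWM, background: Background | None = None) -> float:
    """Mean per-column information content (bits) of a PWM.

    Relative entropy of each pseudocounted column against the background
    (uniform if not given), averaged over columns — used to pick one matrix
    when several are available for a TF.
    """
    bg = background.freq if background is not None else np.full(4, 0.25)
    c = pwm.counts + pwm.pseudocount
    probs = c / c.sum(axis=0, keepdims=True)
    ic_per_col = np.sum(probs * np.log2(probs / bg[:, None]), axis=0)
    return float(np.mean(ic_per_col))


def select_pwm(pwms: Sequence[PWM], background: Background | None = None) -> PWM:
    """The matrix with the highest mean per-column information content."""
    if not pwms:
        raise ValueError("no PWMs to select from")
    return max(pwms, key=lambda p: information_content(p, background))
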