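"""Synthetic two- (or three-) cell-type ChIP-seq study generator.

Emits, from explicit parameters and a seed, everything the analysis
consumes: a genome, gene models, PWMs, per-TF peak sets in each cell type,
chromatin tag tracks, a conservation track, genotyped SNPs — together with
the ground truth that produced them.

The generative structure mirrors the relationships the analysis is built to
detect: the probability that a reference peak is common to the other cell
type follows a logistic model in height percentile and cluster size; the
own cell type's DNase and H3K4me3 tag counts are elevated at a cell's
peaks (so cell-type-specific peaks show a chromatin asymmetry); common
peaks sit in more conserved sequence; and a configurable fraction of
cell-type-specific peaks carry a homozygous-different SNP that converts the
planted binding motif into a low-scoring variant in the other cell line's
genotype.

Peaks are laid out on a 2.5 kb grid (one peak per transcription factor per
cell per grid cell) so that same-TF peaks never overlap accidentally:
the true common/specific labels coincide exactly with observed overlap.
Grid cells shared by several TFs produce bona fide peak clusters, and the
3 kb spacing keeps separate cells from chaining after the 2 kb cluster
extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .annotation import GeneModel
from .intervals import GenomicInterval, Peak, PeakSet, cluster_peaks, cluster_lookup
from .genotype import Genotype, SnpRecord
from .motifs import BASES, PWM, Background, genome_background
from .signal import SignalTrack, TagSet

__all__ = ["SimConfig", "SimulatedStudy", "generate", "truth_report"]

GRID = 2500  # grid-cell size
# Peak starts fall in [1050, 1250) of a cell; with lengths up to 400 bp the
# worst-case gap between peaks of adjacent cells is 2500-600-... >= 1900 bp,
# which the 2 kb cluster extension cannot bridge.
PEAK_ZONE = (1050, 1250)
TAG_LENGTH = 36
CONS_SEGMENT = 50


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are sized for a desk-scale study: a 2 x 5 Mb genome, 5 TFs
    with ~2,000 peaks per TF per cell type, and effect sizes strong enough
    that each planted relationship is recoverable at those sample sizes.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 200
    n_tfs: int = 5
    n_tfs_without_pwm: int = 1
    peaks_per_tf: int = 2000
    peak_count_sigma: float = 0.3  # lognormal spread of per-TF peak counts
    # peak heights: tag counts ~ lognormal(meanlog, sdlog)
    height_meanlog: float = 3.0
    height_sdlog: float = 1.0
    # commonness: P(common) = logistic(b0 + bh * height_pct + bc * cluster_tfs)
    beta0: float = -4.7
    beta_height: float = 0.04
    beta_cluster: float = 0.5
    partner_jitter: int = 50
    # cluster hotspots: grid cells carry shared gamma(shape) attractiveness
    # weights, so TFs co-localize and cluster sizes vary as in real
    # cis-regulatory modules; smaller shape = stronger concentration
    cluster_hotspot_shape: float = 0.7
    # chromatin tag model (per peak region): Poisson(base + elevation * scale)
    tag_base_rate: float = 1.0
    dnase_elevation: float = 15.0
    h3k4me3_elevation: float = 15.0
    elevation_scales_with_height: bool = True
    nominal_total_tags: int = 1_000_000
    # conservation: N(0, sd) background, +elevation over common peaks
    conservation_noise_sd: float = 0.3
    conservation_elevation: float = 0.5
    # sequence composition
    cpg_depletion: float = 0.8  # fraction of background CpG dinucleotides removed
    cpg_island_gene_fraction: float = 0.3
    gc_height_confound: float = 0.0  # >0 plants GC-rich islands at high peaks
    # SNPs
    snp_rate: float = 0.12  # background P(peak carries some SNP)
    motif_disruption_prob: float = 0.1  # P(specific peak gets a hom-diff motif SNP)
    # motif model
    motif_width: int = 10
    motif_consensus_count: int = 18
    # cell types
    cell_types: tuple[str, ...] = ("cellA", "cellB")
    decouple_third_context: bool = False

    def __post_init__(self) -> None:
        if not 2 <= len(self.cell_types) <= 3:
            raise ValueError("need two or three cell types")
        for p in (self.snp_rate, self.motif_disruption_prob, self.cpg_depletion):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        n_cells = self.n_chroms * (self.chrom_length // GRID)
        if self.peaks_per_tf * 2 > n_cells:
            raise ValueError(
                f"infeasible: {self.peaks_per_tf} peaks/TF need more than the "
                f"{n_cells} available grid cells"
            )


@dataclass
class SimulatedStudy:
    """All emitted data plus ground truth for one simulated study."""

    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    pwms: dict[str, PWM | None]
    background: Background
    peak_sets: dict[tuple[str, str], PeakSet]  # (tf, cell_type) -> peaks
    tags: dict[tuple[str, str], TagSet]  # (mark, cell_type) -> tags
    conservation: SignalTrack
    snps: dict[str, list[SnpRecord]]  # peak_id -> SNP records
    expression: dict[str, dict[str, float]]  # cell_type -> tf -> expression
    truth: pd.DataFrame

    def peak_sequence(self, peak: Peak) -> str:
        return self.genome[peak.chrom][peak.start : peak.end]

    def all_peaks(self, cell_type: str) -> list[Peak]:
        out: list[Peak] = []
        for (tf, ct), ps in sorted(self.peak_sets.items()):
            if ct == cell_type:
                out.extend(ps)
        return out


def _mutate_cpg(seq: np.ndarray, rng: np.random.Generator, depletion: float) -> None:
    """Deplete CpG dinucleotides in place (C=1, G=2 in base codes)."""
    cg = np.where((seq[:-1] == 1) & (seq[1:] == 2))[0]
    hit = cg[rng.random(len(cg)) < depletion]
    seq[hit + 1] = rng.choice([0, 3], size=len(hit))  # G -> A or T


def _random_genome(cfg: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    genome = {}
    for i in range(cfg.n_chroms):
        seq = rng.integers(0, 4, size=cfg.chrom_length).astype(np.int8)
        _mutate_cpg(seq, rng, cfg.cpg_depletion)
        genome[f"chr{i + 1}"] = seq
    return genome


_BASE_LUT = np.frombuffer("ACGT".encode(), dtype=np.uint8)


def _decode(seq: np.ndarray) -> str:
    return _BASE_LUT[seq].tobytes().decode()


def _island(rng: np.random.Generator, length: int) -> np.ndarray:
    """GC- and CpG-rich sequence (observed/expected CpG ratio near 1)."""
    return rng.choice(4, size=length, p=[0.15, 0.35, 0.35, 0.15]).astype(np.int8)


def _make_pwm(name: str, rng: np.random.Generator, cfg: SimConfig) -> PWM:
    consensus = rng.integers(0, 4, size=cfg.motif_width)
    counts = np.ones((4, cfg.motif_width))
    counts[consensus, np.arange(cfg.motif_width)] = cfg.motif_consensus_count
    return PWM(name, counts)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate(config: SimConfig) -> SimulatedStudy:
    """Generate a complete synthetic study; all randomness flows from the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genome = _random_genome(cfg, rng)
    chroms = sorted(genome)
    ref_cell = cfg.cell_types[0]
    other_cells = list(cfg.cell_types[1:])

    # ---- grid cells ------------------------------------------------------
    cells_per_chrom = cfg.chrom_length // GRID
    cell_index = [(c, i) for c in chroms for i in range(cells_per_chrom)]
    n_cells = len(cell_index)
    # shared hotspot weights concentrate peaks of different TFs in the
    # same cells, producing dispersed cluster sizes
    cell_weight = rng.gamma(cfg.cluster_hotspot_shape, 1.0, size=n_cells) + 1e-9

    tfs = [f"TF{i + 1}" for i in range(cfg.n_tfs)]
    pwms: dict[str, PWM | None] = {}
    for i, tf in enumerate(tfs):
        has_pwm = i >= cfg.n_tfs_without_pwm
        pwms[tf] = _make_pwm(tf, rng, cfg) if has_pwm else None

    # per-TF, per-cell-type peak budgets
    def _n_peaks() -> int:
        if cfg.peak_count_sigma <= 0:
            return cfg.peaks_per_tf
        return max(10, int(round(cfg.peaks_per_tf * rng.lognormal(0, cfg.peak_count_sigma))))

    n_ref = {tf: _n_peaks() for tf in tfs}

    # ---- reference-cell peaks -------------------------------------------
    peaks_by_key: dict[tuple[str, str], list[Peak]] = {
        (tf, ct): [] for tf in tfs for ct in cfg.cell_types
    }
    used_cells: dict[tuple[str, str], set[int]] = {
        (tf, ct): set() for tf in tfs for ct in cfg.cell_types
    }
    peak_cell_of: dict[str, int] = {}  # peak_id -> grid-cell index
    serial = 0

    def _place_peak(tf: str, ct: str, cell: int, height: int) -> Peak:
        nonlocal serial
        chrom, ci = cell_index[cell]
        start = ci * GRID + int(rng.integers(PEAK_ZONE[0], PEAK_ZONE[1]))
        length = int(rng.integers(100, 401))
        serial += 1
        pid = f"{ct}_{tf}_pk{serial}"
        p = Peak(GenomicInterval(chrom, start, start + length), height, tf, ct, pid)
        peaks_by_key[(tf, ct)].append(p)
        used_cells[(tf, ct)].add(cell)
        peak_cell_of[pid] = cell
        return p

    for tf in tfs:
        chosen = _weighted_sample(rng, cell_weight, n_ref[tf])
        heights = np.maximum(
            1, np.round(rng.lognormal(cfg.height_meanlog, cfg.height_sdlog, n_ref[tf]))
        ).astype(int)
        for cell, h in zip(chosen, heights):
            _place_peak(tf, ref_cell, int(cell), int(h))

    # ---- covariates and common/specific labels --------------------------
    ref_peaks_all = [p for tf in tfs for p in peaks_by_key[(tf, ref_cell)]]
    clusters = cluster_peaks(ref_peaks_all)
    lookup = cluster_lookup(clusters)
    cluster_tfs = {
        p.peak_id: lookup[f"{p.tf}\t{ref_cell}\t{p.peak_id}"].n_tfs for p in ref_peaks_all
    }
    height_pct: dict[str, float] = {}
    for tf in tfs:
        ps = peaks_by_key[(tf, ref_cell)]
        ranks = rankdata([p.height for p in ps], method="average")
        for p, r in zip(ps, ranks):
            height_pct[p.peak_id] = float(r / len(ps) * 100.0)

    p_common = {
        p.peak_id: float(
            _logistic(
                np.array(
                    cfg.beta0
                    + cfg.beta_height * height_pct[p.peak_id]
                    + cfg.beta_cluster * cluster_tfs[p.peak_id]
                )
            )
        )
        for p in ref_peaks_all
    }
    common_with: dict[str, dict[str, bool]] = {
        p.peak_id: {ct: bool(rng.random() < p_common[p.peak_id]) for ct in other_cells}
        for p in ref_peaks_all
    }

    # ---- partner and cell-specific peaks in the other cell types --------
    partner_of: dict[tuple[str, str], str] = {}  # (ref peak_id, cell) -> partner id
    for ct in other_cells:
        for tf in tfs:
            commons = [
                p for p in peaks_by_key[(tf, ref_cell)] if common_with[p.peak_id][ct]
            ]
            for p in commons:
                jitter = int(rng.integers(-cfg.partner_jitter, cfg.partner_jitter + 1))
                length = int(rng.integers(100, 401))
                start = max(0, p.start + jitter)
                height = max(1, int(round(p.height * rng.lognormal(0, 0.3))))
                partner = _place_partner(
                    peaks_by_key, used_cells, peak_cell_of, tf, ct,
                    peak_cell_of[p.peak_id], GenomicInterval(p.chrom, start, start + length),
                    height,
                )
                partner_of[(p.peak_id, ct)] = partner.peak_id
            # cell-type-specific peaks of this cell type
            n_specific = max(0, _n_peaks() - len(commons))
            forbidden = used_cells[(tf, ref_cell)] | used_cells[(tf, ct)]
            free = np.setdiff1d(np.arange(n_cells), np.fromiter(forbidden, int))
            chosen = _weighted_sample(
                rng, cell_weight[free], min(n_specific, len(free))
            )
            heights = np.maximum(
                1, np.round(rng.lognormal(cfg.height_meanlog, cfg.height_sdlog, len(chosen)))
            ).astype(int)
            for idx, h in zip(chosen, heights):
                _place_peak(tf, ct, int(free[idx]), int(h))

    # ---- gene models (and their CpG islands) ----------------------------
    all_peaks = [p for key in sorted(peaks_by_key) for p in peaks_by_key[key]]
    partner_ids = set(partner_of.values())
    island_genes = rng.random(cfg.n_genes) < cfg.cpg_island_gene_fraction
    genes: list[GeneModel] = []
    # avoid the first two cells of each chromosome so upstream exons fit
    eligible = np.array(
        [i for i, (_, ci) in enumerate(cell_index) if ci >= 2], dtype=int
    )
    gene_cells = eligible[rng.choice(len(eligible), size=cfg.n_genes, replace=False)]
    for gi, cell in enumerate(gene_cells):
        chrom, ci = cell_index[int(cell)]
        strand = "+" if rng.random() < 0.5 else "-"
        tss = ci * GRID + 1500
        exon1_len = int(rng.integers(100, 301))
        intron_len = int(rng.integers(500, 2001))
        exon2_len = int(rng.integers(100, 301))
        if strand == "+":
            e1 = GenomicInterval(chrom, tss, tss + exon1_len)
            e2_start = e1.end + intron_len
            e2 = GenomicInterval(chrom, e2_start, e2_start + exon2_len)
            tx_start, tx_end = e1.start, e2.end
            exons = (e1, e2)
        else:
            e1 = GenomicInterval(chrom, tss - exon1_len, tss)
            e2_end = e1.start - intron_len
            e2 = GenomicInterval(chrom, max(0, e2_end - exon2_len), e2_end)
            tx_start, tx_end = e2.start, e1.end
            exons = (e2, e1)
        symbol = f"GENE{gi + 1}"
        genes.append(GeneModel(f"tx{gi + 1}", symbol, chrom, strand, tx_start, tx_end, exons))
        if island_genes[gi]:
            lo = max(0, tss - 300)
            genome[chrom][lo : tss + 300] = _island(rng, tss + 300 - lo)

    # ---- GC-height confound islands (optional) --------------------------
    if cfg.gc_height_confound > 0:
        for p in ref_peaks_all:
            if rng.random() < cfg.gc_height_confound * height_pct[p.peak_id] / 100.0:
                genome[p.chrom][p.start : p.end] = _island(rng, p.length())

    # ---- plant motifs (last, so nothing overwrites them) ----------------
    motif_start: dict[str, int] = {}
    occupied: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for p in all_peaks:
        pwm = pwms[p.tf]
        if pwm is None:
            continue
        if p.cell_type != ref_cell and p.peak_id in partner_ids:
            continue  # partner shares the reference peak's planted motif
        start = _free_motif_slot(p, pwm.width, occupied, cfg.partner_jitter)
        if start is None:
            continue
        consensus = np.argmax(pwm.counts, axis=0).astype(np.int8)
        genome[p.chrom][start : start + pwm.width] = consensus
        occupied.setdefault((p.chrom, start // GRID), []).append((start, start + pwm.width))
        motif_start[p.peak_id] = start
    for ct in other_cells:  # partners reuse the reference peak's motif
        for (ref_pid, c), partner_pid in partner_of.items():
            if c == ct and ref_pid in motif_start:
                motif_start[partner_pid] = motif_start[ref_pid]

    # ---- chromatin tag tracks -------------------------------------------
    tags: dict[tuple[str, str], TagSet] = {}
    peaks_of_cell = {ct: [p for p in all_peaks if p.cell_type == ct] for ct in cfg.cell_types}
    decoupled = (
        {cfg.cell_types[2]} if (len(cfg.cell_types) == 3 and cfg.decouple_third_context)
        else set()
    )
    for mark, elev in (
        ("dnase", cfg.dnase_elevation),
        ("h3k4me3", cfg.h3k4me3_elevation),
        ("h3k27me3", 0.0),
    ):
        for ct in cfg.cell_types:
            tag_list: list[GenomicInterval] = []
            for p in all_peaks:
                own = p.cell_type == ct
                if ct in decoupled:
                    # context decoupled from this cell's peak occupancy
                    elevated = rng.random() < 0.5
                else:
                    elevated = own
                scale = (
                    0.5 + (height_pct.get(p.peak_id, 50.0) / 100.0)
                    if cfg.elevation_scales_with_height
                    else 1.0
                )
                rate = cfg.tag_base_rate + (elev * scale if elevated else 0.0)
                n = int(rng.poisson(rate))
                if n == 0:
                    continue
                starts = rng.integers(p.start, max(p.start + 1, p.end - TAG_LENGTH), size=n)
                tag_list.extend(
                    GenomicInterval(p.chrom, int(s), int(s) + TAG_LENGTH) for s in starts
                )
            total = max(cfg.nominal_total_tags, len(tag_list))
            tags[(mark, ct)] = TagSet(tag_list, total)

    # ---- conservation track ---------------------------------------------
    conservation = _conservation_track(cfg, rng, all_peaks, common_with, partner_of, ref_cell)

    # ---- SNPs ------------------------------------------------------------
    genome_str = {c: _decode(genome[c]) for c in chroms}
    background = genome_background(genome_str.values())
    from .motifs import logodds_matrix, max_pwm_score

    matrices = {
        tf: (logodds_matrix(pwm, background) if pwm is not None else None)
        for tf, pwm in pwms.items()
    }
    snps: dict[str, list[SnpRecord]] = {}
    disruption_flag: dict[str, bool] = {}
    snp_serial = 0
    hi_col = cfg.motif_width // 2  # disruption column of the planted motif
    for p in all_peaks:
        records: list[SnpRecord] = []
        own_ct = p.cell_type
        others = [c for c in cfg.cell_types if c != own_ct]
        if own_ct == ref_cell:
            is_specific = not any(common_with[p.peak_id].values())
        else:
            is_specific = p.peak_id not in partner_ids
        disrupt = (
            is_specific
            and pwms[p.tf] is not None
            and p.peak_id in motif_start
            and rng.random() < cfg.motif_disruption_prob
        )
        if disrupt:
            pwm = pwms[p.tf]
            pos = motif_start[p.peak_id] + hi_col
            ref_base = BASES[int(genome[p.chrom][pos])]
            lo = np.argsort(pwm.counts[:, hi_col])  # worst-scoring base first
            alt_base = BASES[int(lo[0] if BASES[int(lo[0])] != ref_base else lo[1])]
            # emit only if the substitution really lowers the peak's best
            # score (a chance second consensus occurrence can otherwise
            # mask the planted disruption)
            seq = genome_str[p.chrom][p.start : p.end]
            off = pos - p.start
            own_hit = max_pwm_score(matrices[p.tf], seq)
            alt_hit = max_pwm_score(
                matrices[p.tf], seq[:off] + alt_base + seq[off + 1 :]
            )
            if own_hit is None or alt_hit is None or own_hit.score <= alt_hit.score:
                disrupt = False
            else:
                snp_serial += 1
                gts = {own_ct: Genotype.HOM_REF}
                for c in others:
                    gts[c] = Genotype.HOM_ALT
                records.append(
                    SnpRecord(
                        f"snp{snp_serial}", p.chrom, pos, ref_base, alt_base,
                        gts, quality=99.0, alt_freq=0.5, depth=30,
                    )
                )
        disruption_flag[p.peak_id] = bool(disrupt)
        if rng.random() < cfg.snp_rate:
            pos = int(rng.integers(p.start, p.end))
            ref_base = BASES[int(genome[p.chrom][pos])]
            alt_base = BASES[int((int(genome[p.chrom][pos]) + int(rng.integers(1, 4))) % 4)]
            gt_choices = [Genotype.HOM_REF, Genotype.HOM_ALT, Genotype.HET]
            gts = {c: gt_choices[int(rng.integers(0, 3))] for c in cfg.cell_types}
            snp_serial += 1
            records.append(
                SnpRecord(
                    f"snp{snp_serial}", p.chrom, pos, ref_base, alt_base,
                    gts, quality=float(rng.integers(10, 100)), alt_freq=0.5,
                    depth=int(rng.integers(5, 60)),
                )
            )
        if records:
            snps[p.peak_id] = records

    # ---- expression ------------------------------------------------------
    expression: dict[str, dict[str, float]] = {}
    for ct in cfg.cell_types:
        expr = {}
        for tf in tfs:
            n_ct = len(peaks_by_key[(tf, ct)])
            expr[tf] = float(n_ct * rng.lognormal(0, 0.2) / 100.0)
        expression[ct] = expr

    # ---- ground truth ----------------------------------------------------
    rows = []
    partner_ids = set(partner_of.values())
    for p in all_peaks:
        if p.cell_type == ref_cell:
            per_cell = common_with[p.peak_id]
            label = "common" if any(per_cell.values()) else "specific"
            overlap_cols = {f"common_with_{c}": per_cell[c] for c in other_cells}
        else:
            is_partner = p.peak_id in partner_ids
            label = "common" if is_partner else "specific"
            overlap_cols = {f"common_with_{c}": (c == ref_cell and is_partner)
                            for c in [ref_cell]}
        rows.append(
            {
                "peak_id": p.peak_id,
                "tf": p.tf,
                "cell_type": p.cell_type,
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "height": p.height,
                "height_pct": height_pct.get(p.peak_id, float("nan")),
                "cluster_tfs": cluster_tfs.get(p.peak_id, np.nan),
                "p_common": p_common.get(p.peak_id, float("nan")),
                "label": label,
                "has_disruption_snp": disruption_flag.get(p.peak_id, False),
                **overlap_cols,
            }
        )
    truth = pd.DataFrame(rows).set_index("peak_id")

    peak_sets = {key: PeakSet(ps) for key, ps in peaks_by_key.items()}
    return SimulatedStudy(
        cfg, genome_str, genes, pwms, background, peak_sets, tags,
        conservation, snps, expression, truth,
    )


def _weighted_sample(rng: np.random.Generator, weights: np.ndarray, k: int) -> np.ndarray:
    """k indices sampled without replacement with probability ∝ weights.

    Exponential-race formulation of weighted reservoir sampling: the k
    smallest Exp(w) arrival times are the sample.
    """
    keys = rng.exponential(1.0, size=len(weights)) / weights
    return np.argpartition(keys, k - 1)[:k] if k < len(weights) else np.arange(len(weights))


def _free_motif_slot(p, width, occupied, jitter):
    """A motif start inside the peak (with jitter margin for partner peaks)
    that does not collide with an already-planted motif.

    Peaks of different TFs can overlap within a cluster; shifting on
    collision keeps every planted motif intact.
    """
    lo = p.start + jitter + 2
    hi = p.end - jitter - 2 - width
    if hi < lo:
        lo, hi = p.start, p.end - width
    candidates = [p.interval.midpoint - width // 2]
    step = width + 2
    for k in range(1, 20):
        candidates.extend([candidates[0] + k * step, candidates[0] - k * step])
    for s in candidates:
        if s < lo or s > hi:
            continue
        cell = s // GRID
        taken = [
            iv
            for c in (cell - 1, cell, cell + 1)
            for iv in occupied.get((p.chrom, c), ())
        ]
        if all(e <= s or b >= s + width for b, e in taken):
            return s
    return None


def _place_partner(peaks_by_key, used_cells, peak_cell_of, tf, ct, cell, interval, height):
    pid = f"{ct}_{tf}_pt{len(peak_cell_of) + 1}"
    p = Peak(interval, height, tf, ct, pid)
    peaks_by_key[(tf, ct)].append(p)
    used_cells[(tf, ct)].add(cell)
    peak_cell_of[pid] = cell
    return p


def _conservation_track(cfg, rng, all_peaks, common_with, partner_of, ref_cell):
    """Segmented conservation over the union of peak neighbourhoods."""
    partner_ids = set(partner_of.values())

    def is_common(p: Peak) -> bool:
        if p.cell_type == ref_cell:
            return any(common_with[p.peak_id].values())
        return p.peak_id in partner_ids

    by_chrom: dict[str, list[tuple[int, int, bool]]] = {}
    for p in all_peaks:
        by_chrom.setdefault(p.chrom, []).append(
            (max(0, p.start - 100), p.end + 100, is_common(p))
        )
    segments: list[tuple[GenomicInterval, float]] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        merged: list[list] = []
        for s, e, c in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2] = merged[-1][2] or c
            else:
                merged.append([s, e, c])
        for s, e, c in merged:
            for seg_start in range(s, e, CONS_SEGMENT):
                seg_end = min(seg_start + CONS_SEGMENT, e)
                val = rng.normal(0.0, cfg.conservation_noise_sd)
                if c:
                    val += cfg.conservation_elevation
                segments.append((GenomicInterval(chrom, seg_start, seg_end), val))
    return SignalTrack(segments)


def truth_report(
    truth: pd.DataFrame, predictions: dict[str, float], labels: dict[str, str]
) -> dict[str, float]:
    """Recovery metrics of pipeline outputs against ground truth.

    `predictions` maps peak_id to a continuous commonness score and
    `labels` to the pipeline's overlap-derived labels; reports the ROC of
    the scores against true labels and the label agreement rate.
    """
    from sklearn.metrics import roc_auc_score

    ids = [i for i in predictions if i in truth.index]
    if not ids:
        raise ValueError("no matching peak identifiers")
    y = (truth.loc[ids, "label"] == "common").astype(int).to_numpy()
    scores = np.array([predictions[i] for i in ids])
    out = {"n": float(len(ids))}
    if len(np.unique(y)) == 2:
        out["score_roc"] = float(roc_auc_score(y, scores))
    agree = np.mean([labels.get(i) == truth.loc[i, "label"] for i in ids if i in labels])
    out["label_agreement"] = float(agree)
    return out
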