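"""Readers and writers for the text formats the analysis consumes.

Coordinates are normalized to 0-based half-open on read.  Formats: BED6
peaks, BED12 gene models, bedGraph signal tracks, tag BED files with a
``#total_tags=N`` sidecar header, FASTA, JASPAR-style PFMs (plus a minimal
TRANSFAC-like tabular dialect), a minimal VCF subset, and the combined
peak+SNP table dialect in which each peak row carries its SNPs as a
dash-delimited list of semicolon-delimited attribute tuples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .annotation import GeneModel
from .genotype import Genotype, SnpRecord
from .intervals import GenomicInterval, Peak, PeakSet
from .motifs import BASES, PWM, Background
from .signal import SignalTrack, TagSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_bed_peaks",
    "write_bed_peaks",
    "read_bed12_genes",
    "write_bed12_genes",
    "read_bedgraph",
    "write_bedgraph",
    "read_tags_bed",
    "write_tags_bed",
    "read_fasta",
    "write_fasta",
    "read_pfm",
    "write_pfm",
    "read_background",
    "write_background",
    "read_symbol_list",
    "read_vcf_snps",
    "PeakSnpRecord",
    "read_peak_snp_file",
    "write_peak_snp_file",
]


class FormatError(ValueError):
    """Malformed input file."""


def _check_coords(start: int, end: int, path: str, lineno: int) -> None:
    if start < 0 or end <= start:
        raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")


# ---------------------------------------------------------------- BED6 peaks

def read_bed_peaks(path: str | Path, tf: str, cell_type: str) -> PeakSet:
    """BED6 peaks: chrom, start, end, name(peak_id), score(height), strand."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 BED fields")
            start, end = int(f[1]), int(f[2])
            _check_coords(start, end, str(path), lineno)
            peaks.append(
                Peak(GenomicInterval(f[0], start, end), int(float(f[4])), tf, cell_type, f[3])
            )
    return PeakSet(peaks)


def write_bed_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{p.height}\t.\n")


# --------------------------------------------------------------- BED12 genes

def read_bed12_genes(path: str | Path) -> list[GeneModel]:
    """BED12 gene models; blocks are exons, thickStart/thickEnd ignored.

    The gene symbol is taken as the part of the name before the first '|',
    allowing "symbol|transcript" names; otherwise symbol == name.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED fields")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            _check_coords(start, end, str(path), lineno)
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                GenomicInterval(chrom, start + o, start + o + s)
                for o, s in zip(offsets, sizes)
            )
            symbol, _, tx = name.partition("|")
            genes.append(
                GeneModel(tx or name, symbol, chrom, strand, start, end, exons)
            )
    return genes


def write_bed12_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e.length()) for e in g.exons)
            offsets = ",".join(str(e.start - g.tx_start) for e in g.exons)
            name = f"{g.symbol}|{g.name}"
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{name}\t0\t{g.strand}\t"
                f"{g.tx_start}\t{g.tx_start}\t0\t{len(g.exons)}\t{sizes}\t{offsets}\n"
            )


# ----------------------------------------------------------------- bedGraph

def read_bedgraph(path: str | Path) -> SignalTrack:
    """bedGraph to a SignalTrack; out-of-order lines are sorted with a warning."""
    segments = []
    prev = None
    out_of_order = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            start, end = int(f[1]), int(f[2])
            _check_coords(start, end, str(path), lineno)
            key = (f[0], start)
            if prev is not None and key < prev:
                out_of_order = True
            prev = key
            segments.append((GenomicInterval(f[0], start, end), float(f[3])))
    if out_of_order:
        logger.warning("%s: bedGraph lines out of order; sorted on read", path)
    try:
        return SignalTrack(segments)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track._chroms):
            starts, ends, values = track._chroms[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")


# ----------------------------------------------------------------- tag BED

def read_tags_bed(path: str | Path) -> TagSet:
    """One tag interval per BED line; '#total_tags=N' header gives the depth."""
    tags = []
    total = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#total_tags="):
                total = int(line.split("=", 1)[1])
                continue
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            start, end = int(f[1]), int(f[2])
            _check_coords(start, end, str(path), lineno)
            tags.append(GenomicInterval(f[0], start, end))
    if total is None:
        total = len(tags)
    return TagSet(tags, total)


def write_tags_bed(tags: TagSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#total_tags={tags.total_tags}\n")
        for t in sorted(tags.tags):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\n")


# -------------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Chromosome name -> upper-cased sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------- PFM

def read_pfm(path: str | Path) -> list[PWM]:
    """JASPAR-style PFMs (with or without 'A [ .. ]' row labels) or a
    TRANSFAC-like table (one row per position, columns A C G T)."""
    text = Path(path).read_text()
    if any(line.startswith(("P0", "PO")) for line in text.splitlines()):
        return [_parse_transfac(text, Path(path).stem)]
    return _parse_jaspar(text, Path(path).stem)


def _parse_jaspar(text: str, default_name: str) -> list[PWM]:
    pwms = []
    name = default_name
    rows: list[list[float]] = []
    for line in text.splitlines() + [">"]:
        line = line.strip()
        if line.startswith(">"):
            if rows:
                if len(rows) != 4:
                    raise FormatError(f"PFM {name}: expected 4 rows, got {len(rows)}")
                pwms.append(PWM(name, np.array(rows)))
                rows = []
            name = line[1:].split()[0] if len(line) > 1 else default_name
            continue
        if not line:
            continue
        body = line
        if body[0] in "ACGT" and (len(body) == 1 or not body[1].isdigit()):
            body = body[1:]
        body = body.replace("[", " ").replace("]", " ")
        rows.append([float(x) for x in body.split()])
    return pwms


def _parse_transfac(text: str, default_name: str) -> PWM:
    name = default_name
    rows = []
    for line in text.splitlines():
        f = line.split()
        if not f:
            continue
        if f[0] in ("ID", "NA"):
            name = f[1] if len(f) > 1 else name
        elif f[0][0].isdigit() and len(f) >= 5:
            rows.append([float(x) for x in f[1:5]])
    if not rows:
        raise FormatError("no matrix rows in TRANSFAC input")
    return PWM(name, np.array(rows).T)


def write_pfm(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for i, base in enumerate(BASES):
                row = " ".join(f"{v:g}" for v in pwm.counts[i])
                fh.write(f"{base} [ {row} ]\n")


# --------------------------------------------------------------- background

def read_background(path: str | Path) -> Background:
    vals = [float(x) for x in Path(path).read_text().split()]
    return Background(np.array(vals))


def write_background(bg: Background, path: str | Path) -> None:
    Path(path).write_text("\t".join(f"{v:.8f}" for v in bg.freq) + "\n")


def read_symbol_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s)
    return out


# ------------------------------------------------------------ VCF (subset)

def read_vcf_snps(path: str | Path) -> list[SnpRecord]:
    """Minimal VCF: CHROM, POS, ID, REF, ALT and per-sample GT.

    Sample names are the cell types.  Only biallelic SNVs are accepted.
    Genotypes map 0/0 -> reference-homozygous, 1/1 -> alternate, anything
    mixed -> heterozygous, missing -> missing.  QUAL and INFO AF/DP are
    carried when present.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(f"{path}: multi-allelic record at {rec.chrom}:{rec.pos}")
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                raise FormatError(f"{path}: non-SNV record at {rec.chrom}:{rec.pos}")
            gts = {}
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    gts[s] = Genotype.MISSING
                elif all(a == 0 for a in gt):
                    gts[s] = Genotype.HOM_REF
                elif all(a == 1 for a in gt):
                    gts[s] = Genotype.HOM_ALT
                else:
                    gts[s] = Genotype.HET
            info = dict(rec.info)
            af = info.get("AF", 0.0)
            if isinstance(af, tuple):
                af = af[0]
            out.append(
                SnpRecord(
                    rec.id or f"{rec.chrom}:{rec.pos}",
                    rec.chrom,
                    rec.pos - 1,  # VCF is 1-based
                    rec.ref,
                    rec.alts[0],
                    gts,
                    quality=float(rec.qual or 0.0),
                    alt_freq=float(af),
                    depth=int(info.get("DP", 0)),
                )
            )
    return out


# ----------------------------------------------- combined peak + SNP dialect

@dataclass
class PeakSnpRecord:
    """One row of the combined peak+SNP table.

    The SNP field packs, per SNP, `pos;ref;alt;gt;Q;AF;DP` (semicolons
    within a SNP, dashes between SNPs); `gt` is 0 for reference-homozygous,
    1 for alternate-homozygous, 'het' for heterozygous.  A legacy 5-field
    form `pos;gt;Q;AF;DP` (no alleles) is accepted on read.
    """

    peak: Peak
    overlaps: dict[str, bool] = field(default_factory=dict)  # cell type -> flag
    in_promoter: bool = False
    snps: list[tuple] = field(default_factory=list)  # (pos, ref, alt, gt, Q, AF, DP)


_HYPHENS = str.maketrans({"−": "-", "–": "-"})


def _format_snp(s: tuple) -> str:
    pos, ref, alt, gt, q, af, dp = s
    return f"{pos};{ref};{alt};{gt};{q:g};{af:g};{dp}"


def _parse_snp(text: str, path: str, lineno: int) -> tuple:
    f = text.split(";")
    try:
        if len(f) == 7:
            return (int(f[0]), f[1], f[2], f[3], float(f[4]), float(f[5]), int(f[6]))
        if len(f) == 5:
            return (int(f[0]), "N", "N", f[1], float(f[2]), float(f[3]), int(f[4]))
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: bad SNP field {text!r}") from exc
    raise FormatError(f"{path}:{lineno}: SNP field must have 5 or 7 attributes")


def read_peak_snp_file(path: str | Path) -> list[PeakSnpRecord]:
    """Parse the combined peak+SNP table; malformed lines are collected and
    reported in one error rather than silently dropped."""
    records = []
    errors = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["peakID", "cellType", "TF"]:
            raise FormatError(f"{path}: unrecognized header {header[:3]}")
        overlap_cols = [
            (i, h[len("overlap") :])
            for i, h in enumerate(header)
            if h.startswith("overlap") and h != "overlapPromoter"
        ]
        prom_col = header.index("overlapPromoter") if "overlapPromoter" in header else None
        snp_col = header.index("SNPs") if "SNPs" in header else None
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n").translate(_HYPHENS)
            if not line:
                continue
            f = line.split("\t")
            try:
                start, end = int(f[4]), int(f[5])
                _check_coords(start, end, str(path), lineno)
                peak = Peak(
                    GenomicInterval(f[3], start, end), int(float(f[6])), f[2], f[1], f[0]
                )
                snps = []
                if snp_col is not None and f[snp_col]:
                    snps = [
                        _parse_snp(s, str(path), lineno)
                        for s in f[snp_col].split("-")
                    ]
                records.append(
                    PeakSnpRecord(
                        peak,
                        {name: f[i] == "1" for i, name in overlap_cols},
                        f[prom_col] == "1" if prom_col is not None else False,
                        snps,
                    )
                )
            except (FormatError, ValueError, IndexError) as exc:
                errors.append(f"{path}:{lineno}: {exc}")
    if errors:
        raise FormatError("malformed lines:\n" + "\n".join(errors))
    return records


def write_peak_snp_file(
    records: Sequence[PeakSnpRecord], path: str | Path, cell_types: Sequence[str]
) -> None:
    with open(path, "w") as fh:
        overlap_headers = "\t".join(f"overlap{c}" for c in cell_types)
        fh.write(
            "peakID\tcellType\tTF\tchromosome\tpeakStart\tpeakStop\theight\t"
            f"{overlap_headers}\toverlapPromoter\tSNPs\n"
        )
        for r in records:
            p = r.peak
            flags = "\t".join(
                "1" if r.overlaps.get(c, False) else "0" for c in cell_types
            )
            snps = "-".join(_format_snp(s) for s in r.snps)
            fh.write(
                f"{p.peak_id}\t{p.cell_type}\t{p.tf}\t{p.chrom}\t{p.start}\t{p.end}\t"
                f"{p.height}\t{flags}\t{'1' if r.in_promoter else '0'}\t{snps}\n"
            )
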