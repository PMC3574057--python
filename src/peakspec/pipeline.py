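"""End-to-end orchestration: study persistence and the full analysis run.

A "study" bundles everything one two- or three-cell-type comparison needs
(peaks, genome, tracks, PWMs, SNPs).  `write_study`/`load_study` round-trip
a study through plain-text files; `run_pipeline` executes the analysis
stages — overlap, features, trends, chromatin comparisons, genotype
analysis, classification — and writes deterministic TSV/JSON results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, io, trends
from .annotation import promoter_regions
from .classify import FeatureContext, ModelSpec
from .genotype import (
    genotype_motif_scores,
    genotype_motif_test,
    height_motifscore_correlation,
    select_homozygous_different,
    snp_in_best_motif,
    snp_peak_summary,
)
from .intervals import (
    PeakSet,
    cluster_peaks,
    relative_overlap,
    windowed_overlap_counts,
)
from .motifs import logodds_matrix, max_pwm_score
from .signal import phylop_region_score, region_signal
from .simulate import SimConfig, SimulatedStudy, truth_report

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

WINDOW_EXTENSIONS = (0, 500, 1000, 4000, 10000)

TREND_FEATURES = (
    "overlap",
    "promoter",
    "cpg_rich",
    "dnase_own",
    "h3k4me3_own",
    "phylop",
    "pwm_score",
    "cluster_tfs",
)


# ------------------------------------------------------------- persistence

def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write a study to a directory of plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(study.config), sort_keys=True)
    )
    io.write_fasta(study.genome, out / "genome.fa")
    io.write_bed12_genes(study.genes, out / "genes.bed12")
    (out / "peaks").mkdir(exist_ok=True)
    for (tf, ct), ps in sorted(study.peak_sets.items()):
        io.write_bed_peaks(ps, out / "peaks" / f"{ct}_{tf}.bed")
    (out / "tags").mkdir(exist_ok=True)
    for (mark, ct), ts in sorted(study.tags.items()):
        io.write_tags_bed(ts, out / "tags" / f"{mark}_{ct}.bed")
    io.write_bedgraph(study.conservation, out / "conservation.bedgraph")
    io.write_pfm(
        [p for p in (study.pwms[tf] for tf in sorted(study.pwms)) if p is not None],
        out / "pwms.pfm",
    )
    io.write_background(study.background, out / "background.tsv")
    _write_snp_vcf(study, out / "snps.vcf")
    for ct in study.config.cell_types:
        _write_peaksnp_dialect(study, ct, out / f"peaksnps_{ct}.tsv")
        expr = study.expression.get(ct, {})
        with open(out / f"expression_{ct}.tsv", "w") as fh:
            for tf in sorted(expr):
                fh.write(f"{tf}\t{expr[tf]:.6g}\n")
    study.truth.sort_index().to_csv(out / "truth.tsv", sep="\t")


def _write_snp_vcf(study: SimulatedStudy, path: Path) -> None:
    cells = list(study.config.cell_types)
    rows = []
    seen = set()  # a SNP inside several overlapping peaks is written once
    for pid in sorted(study.snps):
        for s in study.snps[pid]:
            if (s.snp_id, s.chrom, s.pos) in seen:
                continue
            seen.add((s.snp_id, s.chrom, s.pos))
            gts = []
            for c in cells:
                gt = s.genotypes.get(c)
                gts.append(
                    {"0": "0/0", "1": "1/1", "het": "0/1"}.get(
                        gt.value if gt else ".", "./."
                    )
                )
            rows.append(
                (s.chrom, s.pos + 1, s.snp_id, s.ref_allele, s.alt_allele,
                 f"{s.quality:g}", f"AF={s.alt_freq:g};DP={s.depth}", gts)
            )
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(study.genome):
            fh.write(f"##contig=<ID={chrom},length={len(study.genome[chrom])}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele frequency">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cells) + "\n")
        for chrom, pos, sid, ref, alt, qual, info, gts in rows:
            fh.write(
                f"{chrom}\t{pos}\t{sid}\t{ref}\t{alt}\t{qual}\tPASS\t{info}\tGT\t"
                + "\t".join(gts) + "\n"
            )


def _write_peaksnp_dialect(study: SimulatedStudy, cell_type: str, path: Path) -> None:
    cells = list(study.config.cell_types)
    records = []
    for (tf, ct), ps in sorted(study.peak_sets.items()):
        if ct != cell_type:
            continue
        other_sets = {
            c: study.peak_sets.get((tf, c), PeakSet([])) for c in cells if c != ct
        }
        flags_by_cell = {
            c: dict(zip((p.peak_id for p in ps),
                        _overlap_flags_list(ps, other_sets[c])))
            for c in other_sets
        }
        promoters = promoter_regions(study.genes)
        from .annotation import region_overlap_flags

        prom_flags = region_overlap_flags(list(ps), promoters)
        for p, in_prom in zip(ps, prom_flags):
            snps = []
            for s in study.snps.get(p.peak_id, []):
                gt = s.genotypes.get(ct)
                snps.append(
                    (s.pos, s.ref_allele, s.alt_allele,
                     gt.value if gt else ".", s.quality, s.alt_freq, s.depth)
                )
            overlaps = {c: flags_by_cell[c][p.peak_id] for c in other_sets}
            overlaps[ct] = True
            records.append(io.PeakSnpRecord(p, overlaps, in_prom, snps))
    io.write_peak_snp_file(records, path, cells)


def _overlap_flags_list(query: PeakSet, target: PeakSet) -> list[bool]:
    from .intervals import overlap_flags

    return overlap_flags(query, target)


def load_study(path: str | Path) -> SimulatedStudy:
    """Load a study directory written by `write_study`."""
    d = Path(path)
    raw = yaml.safe_load((d / "config.yaml").read_text())
    raw["cell_types"] = tuple(raw["cell_types"])
    cfg = SimConfig(**raw)
    genome = io.read_fasta(d / "genome.fa")
    genes = io.read_bed12_genes(d / "genes.bed12")
    pwm_list = io.read_pfm(d / "pwms.pfm") if (d / "pwms.pfm").exists() else []
    background = io.read_background(d / "background.tsv")
    peak_sets = {}
    for bed in sorted((d / "peaks").glob("*.bed")):
        ct, _, tf = bed.stem.partition("_")
        peak_sets[(tf, ct)] = io.read_bed_peaks(bed, tf, ct)
    pwms = {tf: None for (tf, _) in peak_sets}
    for p in pwm_list:
        pwms[p.name] = p
    tags = {}
    for bed in sorted((d / "tags").glob("*.bed")):
        mark, _, ct = bed.stem.partition("_")
        tags[(mark, ct)] = io.read_tags_bed(bed)
    conservation = io.read_bedgraph(d / "conservation.bedgraph")
    snp_records = io.read_vcf_snps(d / "snps.vcf") if (d / "snps.vcf").exists() else []
    snps = _assign_snps_to_peaks(snp_records, peak_sets)
    expression = {}
    for ct in cfg.cell_types:
        f = d / f"expression_{ct}.tsv"
        if f.exists():
            expression[ct] = {
                line.split("\t")[0]: float(line.split("\t")[1])
                for line in f.read_text().splitlines()
                if line
            }
    truth_path = d / "truth.tsv"
    truth = (
        pd.read_csv(truth_path, sep="\t", index_col=0)
        if truth_path.exists()
        else pd.DataFrame()
    )
    return SimulatedStudy(
        cfg, genome, genes, pwms, background, peak_sets, tags, conservation,
        snps, expression, truth,
    )


def _assign_snps_to_peaks(snp_records, peak_sets) -> dict[str, list]:
    from collections import defaultdict

    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for ps in peak_sets.values():
        for p in ps:
            trees[p.chrom].addi(p.start, p.end, p.peak_id)
    snps: dict[str, list] = defaultdict(list)
    for s in snp_records:
        for iv in trees[s.chrom].overlap(s.pos, s.pos + 1):
            snps[iv.data].append(s)
    return {pid: sorted(v, key=lambda s: (s.pos, s.snp_id)) for pid, v in snps.items()}


# --------------------------------------------------------- feature assembly

def build_contexts(
    study: SimulatedStudy, reference: str, comparison: str
) -> dict[str, tuple[PeakSet, FeatureContext, dict[str, str]]]:
    """Per TF: reference peaks, their feature context against `comparison`,
    and the overlap-derived common/specific labels."""
    promoters = promoter_regions(study.genes)
    ref_peaks_all = study.all_peaks(reference)
    clusters = cluster_peaks(ref_peaks_all)
    out = {}
    tfs = sorted({tf for (tf, ct) in study.peak_sets if ct == reference})
    for tf in tfs:
        ps = study.peak_sets[(tf, reference)]
        comp = study.peak_sets.get((tf, comparison), PeakSet([]))
        sequences = {p.peak_id: study.peak_sequence(p) for p in ps}
        signals = {}
        for mark in ("dnase", "h3k4me3", "h3k27me3"):
            own_tags = study.tags[(mark, reference)]
            other_tags = study.tags[(mark, comparison)]
            signals[mark] = {
                p.peak_id: (
                    region_signal(own_tags, p.interval),
                    region_signal(other_tags, p.interval),
                )
                for p in ps
            }
        phylop = {
            p.peak_id: phylop_region_score(study.conservation, p.interval).value
            for p in ps
        }
        pwm = study.pwms.get(tf)
        pwm_scores = None
        if pwm is not None:
            matrix = logodds_matrix(pwm, study.background)
            pwm_scores = {}
            for p in ps:
                hit = max_pwm_score(matrix, sequences[p.peak_id])
                pwm_scores[p.peak_id] = hit.score if hit else 0.0
        ctx = FeatureContext(
            promoters=promoters,
            genes=study.genes,
            clusters=clusters,
            sequences=sequences,
            dnase=signals["dnase"],
            h3k4me3=signals["h3k4me3"],
            h3k27me3=signals["h3k27me3"],
            phylop=phylop,
            pwm_scores=pwm_scores,
        )
        labels = classify.label_by_overlap(ps, comp) if len(comp) else {
            p.peak_id: classify.LABEL_SPECIFIC for p in ps
        }
        out[tf] = (ps, ctx, labels)
    return out


# ------------------------------------------------------------------ stages

def overlap_stage(study: SimulatedStudy, reference: str, comparison: str) -> pd.DataFrame:
    rows = []
    tfs = sorted({tf for (tf, ct) in study.peak_sets if ct == reference})
    for tf in tfs:
        a = study.peak_sets[(tf, reference)]
        b = study.peak_sets.get((tf, comparison), PeakSet([]))
        if len(a) == 0 or len(b) == 0:
            continue
        win = windowed_overlap_counts(a, b, WINDOW_EXTENSIONS)
        rows.append(
            {
                "tf": tf,
                "n_reference": len(a),
                "n_comparison": len(b),
                "n_overlapping": win[0],
                "relative_overlap": relative_overlap(a, b),
                **{f"overlap_ext{e}": c for e, c in zip(WINDOW_EXTENSIONS, win)},
            }
        )
    return pd.DataFrame(rows)


def trend_stage(
    contexts, alpha: float = 0.05, n_bins: int = 10
) -> pd.DataFrame:
    """Height-binned trend regressions per TF and genomic characteristic."""
    rows = []
    for tf, (ps, ctx, labels) in sorted(contexts.items()):
        if len(ps) < n_bins:
            continue
        binning = trends.bin_by_height(ps, n_bins)
        table = classify.assemble_feature_table(ps, ctx)
        feature_values: dict[str, dict[str, float]] = {
            "overlap": {
                p.peak_id: float(labels[p.peak_id] == classify.LABEL_COMMON) for p in ps
            },
            "promoter": table["promoter"].to_dict(),
            "cpg_rich": table["high_cpg"].to_dict(),
            "dnase_own": {pid: v[0] for pid, v in ctx.dnase.items()},
            "h3k4me3_own": {pid: v[0] for pid, v in ctx.h3k4me3.items()},
            "phylop": table["phylop"].to_dict(),
            "cluster_tfs": table["cluster_tfs"].to_dict(),
        }
        if ctx.pwm_scores is not None:
            feature_values["pwm_score"] = dict(ctx.pwm_scores)
        for feature, values in feature_values.items():
            res = trends.bin_trend(binning, values, feature, alpha)
            for b, m in enumerate(res.bin_means):
                rows.append(
                    {
                        "tf": tf,
                        "feature": feature,
                        "bin": b + 1,
                        "mean": m,
                        "slope": res.slope,
                        "p": res.p_value,
                        "significant": res.significant,
                    }
                )
    return pd.DataFrame(rows)


def chromatin_stage(contexts) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top/bottom-30% KS comparisons and per-bin median signal differences."""
    ks_rows = []
    md_rows = []
    for tf, (ps, ctx, labels) in sorted(contexts.items()):
        for mark, signals in (("dnase", ctx.dnase), ("h3k4me3", ctx.h3k4me3)):
            own = {pid: v[0] for pid, v in signals.items()}
            other = {pid: v[1] for pid, v in signals.items()}
            for side in ("highest", "lowest"):
                for r in trends.extreme_height_comparison(
                    list(ps), labels, own, other, side=side
                ):
                    ks_rows.append(
                        {"tf": tf, "mark": mark, "side": side, "group": r.group,
                         "n": r.n_a, "D": r.statistic, "p": r.p_value,
                         "skipped": r.skipped}
                    )
            if len(ps) >= 10:
                binning = trends.bin_by_height(ps)
                specific_ids = [
                    p.peak_id for p in ps if labels[p.peak_id] == classify.LABEL_SPECIFIC
                ]
                diffs = trends.median_diff_by_height(binning, own, other, specific_ids)
                for b, dval in enumerate(diffs):
                    md_rows.append(
                        {"tf": tf, "mark": mark, "bin": b + 1,
                         "median_diff": np.nan if dval is None else dval}
                    )
    return pd.DataFrame(ks_rows), pd.DataFrame(md_rows)


def genotype_stage(
    study: SimulatedStudy, reference: str, comparison: str, min_quality: float = 20.0
) -> dict:
    """Motif rescoring of homozygous-different SNPs in specific peaks.

    For each cell type of the pair: take its cell-type-specific peaks whose
    homozygous-different SNPs fall in the best-scoring motif window, rescore
    under both genotypes, and run the one-sided paired t-test.
    """
    results: dict = {}
    pair = (reference, comparison)
    categories: dict[str, str] = {}
    snps_per_peak = {}
    for own, other in (pair, pair[::-1]):
        pairs = []
        tfs = sorted({tf for (tf, ct) in study.peak_sets if ct == own})
        for tf in tfs:
            pwm = study.pwms.get(tf)
            if pwm is None:
                continue
            matrix = logodds_matrix(pwm, study.background)
            ps = study.peak_sets[(tf, own)]
            comp = study.peak_sets.get((tf, other), PeakSet([]))
            labels = classify.label_by_overlap(ps, comp)
            for p in ps:
                cat = (
                    "common" if labels[p.peak_id] == classify.LABEL_COMMON
                    else f"specific_{own}"
                )
                if own == reference or labels[p.peak_id] == classify.LABEL_SPECIFIC:
                    categories[p.peak_id] = cat
                    snps_per_peak[p.peak_id] = study.snps.get(p.peak_id, [])
                if labels[p.peak_id] != classify.LABEL_SPECIFIC:
                    continue
                snps = select_homozygous_different(
                    study.snps.get(p.peak_id, []), own, other, min_quality
                )
                if not snps:
                    continue
                seq = study.peak_sequence(p)
                in_motif = [
                    s for s in snps
                    if snp_in_best_motif(seq, matrix, s.pos - p.start)
                ]
                if not in_motif:
                    continue
                gp = genotype_motif_scores(
                    seq, p.start, matrix, in_motif, own, other, p.peak_id
                )
                if gp is not None:
                    pairs.append(gp)
        entry: dict = {"n_pairs": len(pairs)}
        if len(pairs) >= 2:
            t = genotype_motif_test(pairs)
            entry.update(
                t_statistic=t.t_statistic, p_one_sided=t.p_value,
                n_higher_own=t.n_higher_own, n_higher_other=t.n_higher_other,
            )
        results[f"specific_{own}"] = entry
    # common peaks: does the genotype motif-score gap track the height gap?
    corr_pairs = []
    corr_pairs_top = []
    for tf in sorted({tf for (tf, ct) in study.peak_sets if ct == reference}):
        pwm = study.pwms.get(tf)
        if pwm is None:
            continue
        matrix = logodds_matrix(pwm, study.background)
        ps = study.peak_sets[(tf, reference)]
        comp = study.peak_sets.get((tf, comparison), PeakSet([]))
        if not len(comp):
            continue
        labels = classify.label_by_overlap(ps, comp)
        heights = sorted(p.height for p in ps)
        top_cut = heights[int(0.9 * len(heights))] if len(heights) >= 10 else None
        comp_by_overlap = _partner_heights(ps, comp)
        for p in ps:
            if labels[p.peak_id] != classify.LABEL_COMMON:
                continue
            snps = select_homozygous_different(
                study.snps.get(p.peak_id, []), reference, comparison, min_quality
            )
            if not snps:
                continue
            gp = genotype_motif_scores(
                study.peak_sequence(p), p.start, matrix, snps,
                reference, comparison, p.peak_id,
            )
            partner_h = comp_by_overlap.get(p.peak_id)
            if gp is None or partner_h is None:
                continue
            pair = (float(p.height - partner_h), gp.score_own - gp.score_other)
            corr_pairs.append(pair)
            if top_cut is not None and p.height >= top_cut:
                corr_pairs_top.append(pair)
    for name, pairs_ in (("all_common", corr_pairs), ("top10pct", corr_pairs_top)):
        if len(pairs_) >= 3:
            c = height_motifscore_correlation(pairs_)
            results[f"height_motifscore_corr_{name}"] = {
                "r": c.r, "p": c.p_value, "n": c.n, "degenerate": c.degenerate,
            }

    summary = snp_peak_summary(categories, snps_per_peak, reference, comparison, min_quality)
    results["snp_summary"] = {
        cat: {
            "n_peaks": s.n_peaks,
            "frac_with_snp": s.frac_with_snp,
            "frac_hom_diff": s.frac_hom_diff,
        }
        for cat, s in summary.items()
    }
    return results


def _partner_heights(reference: PeakSet, comparison: PeakSet) -> dict[str, float]:
    """Height of an overlapping comparison peak per common reference peak
    (the highest one when several overlap)."""
    from collections import defaultdict

    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for q in comparison:
        trees[q.chrom].addi(q.start, q.end, q.height)
    out = {}
    for p in reference:
        hits = trees[p.chrom].overlap(p.start, p.end) if p.chrom in trees else ()
        if hits:
            out[p.peak_id] = float(max(iv.data for iv in hits))
    return out


def expression_stage(study: SimulatedStudy, reference: str, comparison: str) -> dict:
    """Correlate per-TF expression differences with peak-count differences."""
    expr_a = study.expression.get(reference, {})
    expr_b = study.expression.get(comparison, {})
    count_a = {tf: len(ps) for (tf, ct), ps in study.peak_sets.items() if ct == reference}
    count_b = {tf: len(ps) for (tf, ct), ps in study.peak_sets.items() if ct == comparison}
    try:
        res = trends.expression_peakcount_correlation(expr_a, expr_b, count_a, count_b)
    except ValueError:
        return {"skipped": "fewer than 3 TFs with expression"}
    return {"r": res.r, "p": res.p_value, "n": res.n}


def classify_stage(
    contexts, seed: int, k: int = 10, third_contexts=None
) -> dict:
    """CV of the SVM/Height/HPP models per TF, plus feature elimination."""
    out: dict = {}
    for tf, (ps, ctx, labels) in sorted(contexts.items()):
        table = classify.assemble_feature_table(ps, ctx)
        y = [labels[pid] for pid in table.index]
        n_common = sum(1 for v in y if v == classify.LABEL_COMMON)
        entry: dict = {"n": len(y), "n_common": n_common}
        if min(n_common, len(y) - n_common) < k:
            entry["skipped"] = "fewer than k examples in a class"
            out[tf] = entry
            continue
        models = [ModelSpec.svm(), ModelSpec.height()]
        if ctx.pwm_scores is not None:
            models.append(ModelSpec.hpp())
        for spec in models:
            res = classify.train_and_crossvalidate(table, y, spec, k, seed)
            entry[f"roc_{spec.name}"] = res.mean_roc
        entry["elimination"] = classify.feature_group_elimination(table, y, k=k, seed=seed)
        hc = classify.high_clustered_subset(table)
        sub = table.loc[hc.peak_ids]
        y_sub = [labels[pid] for pid in sub.index]
        n_sub_common = y_sub.count(classify.LABEL_COMMON)
        if min(n_sub_common, len(y_sub) - n_sub_common) > 100:
            # height/cluster confounds removed; which other groups matter
            removed = set(classify.FEATURE_GROUPS["Height"]) | set(
                classify.FEATURE_GROUPS["Cluster"]
            )
            base = tuple(f for f in classify.FEATURE_NAMES if f not in removed)
            groups = {g: m for g, m in classify.FEATURE_GROUPS.items()
                      if g not in ("Height", "Cluster")}
            entry["high_clustered_elimination"] = classify.feature_group_elimination(
                sub, y_sub, groups=groups, base_features=base, k=k, seed=seed
            )
            entry["high_clustered_n"] = len(y_sub)
        if third_contexts is not None and tf in third_contexts:
            ps3, ctx3, labels3 = third_contexts[tf]
            table3 = classify.assemble_feature_table(ps3, ctx3)
            if set(table3.index) == set(table.index):
                lab_tr = {pid: labels[pid] for pid in table.index}
                lab_te = {pid: labels3[pid] for pid in table.index}
                for spec in models:
                    try:
                        res = classify.cross_celltype_evaluation(
                            table, lab_tr, table3, lab_te, spec, k, seed
                        )
                        entry[f"cross_roc_{spec.name}"] = res.mean_roc
                    except ValueError:
                        entry[f"cross_roc_{spec.name}"] = None
        out[tf] = entry
    return out


# ----------------------------------------------------------------- run all

def run_pipeline(
    study: SimulatedStudy | str | Path,
    out_dir: str | Path,
    seed: int = 0,
    k: int = 10,
) -> dict:
    """Run every stage on a study and write deterministic results files."""
    if not isinstance(study, SimulatedStudy):
        study = load_study(study)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    reference, comparison = cfg.cell_types[0], cfg.cell_types[1]
    third = cfg.cell_types[2] if len(cfg.cell_types) > 2 else None

    contexts = build_contexts(study, reference, comparison)
    third_contexts = build_contexts(study, reference, third) if third else None

    overlap = overlap_stage(study, reference, comparison)
    overlap.to_csv(out / "overlap.tsv", sep="\t", index=False, float_format="%.6g")

    trend = trend_stage(contexts)
    trend.to_csv(out / "trends.tsv", sep="\t", index=False, float_format="%.6g")

    ks, md = chromatin_stage(contexts)
    ks.to_csv(out / "chromatin_ks.tsv", sep="\t", index=False, float_format="%.6g")
    md.to_csv(out / "median_diff.tsv", sep="\t", index=False, float_format="%.6g")

    geno = genotype_stage(study, reference, comparison)
    cls = classify_stage(contexts, seed=seed, k=k, third_contexts=third_contexts)
    expr = expression_stage(study, reference, comparison)

    results = {
        "overlap": overlap.to_dict(orient="records"),
        "genotype": geno,
        "classification": cls,
        "expression_peakcount": expr,
    }
    if len(study.truth):
        pct = {}
        labels_all = {}
        for tf, (ps, ctx, labels) in contexts.items():
            pct.update(classify.height_percentiles(ps))
            labels_all.update(labels)
        results["truth_report"] = truth_report(study.truth, pct, labels_all)

    meta = {
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "version": __version__,
        "reference": reference,
        "comparison": comparison,
        "third": third,
    }
    (out / "run_meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1))
    (out / "results.json").write_text(
        json.dumps(results, sort_keys=True, indent=1, default=_jsonable)
    )
    return results


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.bool_):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
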