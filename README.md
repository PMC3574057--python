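# peakspec

Analysis of the **cell-type specificity of transcription-factor ChIP-seq
peaks**: given called peak sets for the same TFs in two (or three) cell
lines, the package quantifies how much binding is shared, which genomic and
chromatin properties track that sharing, and how well a peak's fate in a
second cell type can be predicted from features measured in the first.

It is written for computational biologists working with BED-like peak
calls, bedGraph/tag-interval signal tracks, FASTA genomes, JASPAR-style
PWMs and genotype calls. The package is a library first (`import
peakspec`), with narrative scripts under `examples/` and a thin
`peakspec` CLI for the simulate/run workflow.

## What it computes

* **Overlap analysis** — two peaks are shared ("common") when they overlap
  by ≥ 1 bp (0-based half-open coordinates). *Relative overlap* for a TF is
  the overlap count divided by the smaller of the two peak-set sizes.
  Windowed variants widen each peak by 0–10 kb to test for nearby
  alternative sites.
* **Peak clustering** — peaks from all TFs in one cell type are extended to
  a 2 kb footprint; chains of overlapping extended peaks form clusters.
  A peak's cluster contributes the *Cluster TFs* and *cluster average
  height* features.
* **Annotation features** — promoters ([TSS−2000, TSS+200) plus the first
  intron), Pol III promoters around tRNA genes, distance to the nearest
  TSS (capped at 20 kb), CpG class from GC fraction and the
  observed/expected CpG ratio in 500 bp windows, housekeeping-promoter
  membership.
* **Signal features** — per-region tag counts normalized by region length
  and sequencing depth (tags/bp per million tags) for DNase accessibility
  and the H3K4me3/H3K27me3 histone marks; length-weighted phyloP
  conservation averages; per-TF expression from exon read counts.
* **Motif scoring** — PWMs (pseudocount 1) are converted to log2-odds
  against the genome base composition; a peak's score is the maximal
  window score over both strands. Allele substitution plus rescanning
  quantifies motif disruption by SNPs that are homozygous for different
  alleles in the two cell lines (one-sided paired t-test of
  own-genotype vs other-genotype scores).
* **Height-binned trends** — peaks are split into 10 near-equal height
  bins; each characteristic's bin means are regressed on the bin index
  (slope, p-value at α = 0.05). A GC-balanced subsample controls for GC
  bias; top/bottom-30% height strata are compared by two-sample KS tests
  on own- vs other-cell chromatin signal.
* **Classifiers** — three soft-margin linear SVMs predict common vs
  specific peaks under stratified 10-fold cross-validation (ROC score):
  **SVM** (all 16 features of the table below), **Height** (height
  percentile only), **HPP** (height percentile, phyloP, PWM score).
  Feature-group elimination reports the ROC change after removing each
  group; a cross-cell-type protocol trains against one comparison cell
  line and tests against another.

Feature groups: Height, Length, Promoter, TSS dist, Cluster (2 features),
Chromatin (2), H3K4me3 (2), H3K27me3 (2), CpG (3), PhyloP.

A first-class **synthetic study generator** (`peakspec.simulate`) emits a
genome, genes, PWMs, peaks, tracks and SNPs in which P(common) =
logistic(β₀ + β_h·height percentile + β_c·cluster TFs), chromatin is
elevated at a cell's own peaks, conservation is elevated at common peaks,
and a configurable fraction of specific peaks carry a motif-disrupting
homozygous-different SNP — with the ground truth returned alongside.

## Worked example

`python examples/04_specificity_classifier.py` builds a synthetic study,
assembles the 16-feature vectors for one TF and evaluates the models:

```
TF3: 537 peaks, 193 common / 344 specific
  SVM     mean ROC score = 0.878
  Height  mean ROC score = 0.761
  HPP     mean ROC score = 0.870

ROC change after removing each feature group (negative = group matters):
  Height     -0.074
  PhyloP     -0.048
  Chromatin  -0.002
  ...
```

The full SVM beats the single-feature Height baseline (0.878 vs 0.761)
because conservation, chromatin and clustering add information beyond
height; the elimination table shows which groups the model could not do
without. The other examples cover overlap counting
(`01_overlap_between_cell_types.py`), height-binned trends (`02`), SNP
motif disruption (`03`) and the full simulate→run pipeline (`05`).

From the shell:

```bash
peakspec simulate --out study/ --seed 7
peakspec run study/ --out results/ --seed 7
```

`results/` then holds `overlap.tsv`, `trends.tsv`, `chromatin_ks.tsv`,
`median_diff.tsv`, `results.json` and `run_meta.json` (config hash, seed,
version); reruns with the same seed are byte-identical.

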