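# Methods

This note documents the models, conventions and design choices behind
peakspec, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates, overlap and clustering

All coordinates are 0-based, half-open (BED convention). Two intervals
overlap iff `max(start) < min(end)` on the same chromosome — "at least one
shared base pair". Overlap counts are query-sided: a query peak counts
once however many target peaks it touches. Relative overlap divides the
count by the smaller of the two set sizes; because several query peaks can
pile onto one target peak the ratio can exceed 1, and it is reported
unclipped rather than capped.

For clustering, every peak is extended symmetrically to a total footprint
of 2,000 bp (floor division per side, remainder to the right, clamped at
coordinate 0; peaks already ≥ 2 kb are left alone). Clusters are the
connected components of extended-interval overlap, computed by a sorted
sweep per chromosome and verified in tests against an all-pairs
transitive-closure oracle. Clustering pools the peaks of **all** TFs
within one cell type; a peak outside any multi-peak cluster is treated as
its own singleton (Cluster TFs = 1, cluster average height = its own
height) so that missingness is never encoded as zero.

## Annotation

Promoters are [TSS−2000, TSS+200) (strand-reflected) plus the first
intron in transcription order; single-exon genes contribute no intron.
Pol III promoters use the same window around tRNA gene starts. TSS
distance is measured from the peak midpoint (the anchor is a package
choice; midpoints make the feature symmetric in peak length) and capped
at 20,000 bp; the cap reading limits the feature's range, and peaks on
chromosomes without an annotated TSS receive the cap.

CpG classes follow the observed/expected-ratio convention: for a window,
expected CpG = count(C)·count(G)/length, and the ratio is observed/expected
(0 when the expectation is 0). A sequence is **rich** if any 500 bp window
has GC > 0.55 and ratio > 0.75, **poor** if it is not rich and the whole
sequence's ratio is < 0.48, else **intermediate** (so the High-CpG and
Low-CpG booleans can both be 0). The poor test deliberately uses the whole
region — the windowed alternative is noted in the code. The window scan
strides 10 bp by default; tests check agreement with a 1 bp-stride oracle
on island-and-background mixtures, where window statistics change slowly
relative to the stride. Sequences shorter than the window are one window.

## Signal quantification

Tag-based signal over a region is `tags overlapping / region length /
(total tags ⁄ 10⁶)` — insensitive to peak length and sequencing depth.
Counting uses sorted start/end arrays (a tag misses a region exactly when
it starts at/after the region end or ends at/before the region start), so
per-region queries are O(log n). Conservation (phyloP semantics) is the
length-weighted average of overlapping bedGraph segment values; a region
with no scored segment returns 0.0 **plus** an explicit no-coverage flag,
leaving the drop-or-default decision to the consumer. Cross-cell-type
comparisons use the average and the difference (reference minus
comparison) of the two cell types' values; expression/peak-count
comparisons use the bounded relative difference (a−b)/(a+b), chosen as the
standard parameter-free normalization onto [−1, 1].

Per-gene expression is the exon-length-normalized read count averaged over
exons, scaled per million total reads; transcripts with zero exonic reads
are excluded before averaging per gene symbol.

## Motif model

A PWM is a 4×W count matrix. Scoring adds a pseudocount of 1 to every
cell, normalizes columns, and takes log base 2 against the genome
background (base frequencies counted over the genome, N ignored, floored
at 10⁻⁶ and renormalized so degenerate synthetic genomes cannot produce
infinite log-odds). Only score *order* matters downstream, which is
invariant to the log base. A peak's PWM score is the maximum window score
over all offsets on both strands; the minus strand is scanned by sliding
the reverse-complemented matrix along the forward sequence, so hits always
report a forward-coordinate footprint [offset, offset+W). Ties prefer the
smaller offset, then '+'. Windows containing non-ACGT bases are skipped;
all-N scans return no hit. When several PWMs exist for a TF, the one with
the highest mean per-column information content is used; TFs without a PWM
carry an explicit "PWM unavailable" marker and the HPP model simply drops
that feature for them.

Genotype rescoring substitutes a cell line's homozygous alleles at all its
SNP positions and rescans — the best window may move, which is the point:
the comparison is between best attainable scores per genotype.

## Genotype analysis

SNPs are usable when both cell lines have homozygous calls for different
alleles; heterozygous, missing and low-quality calls (Q < 20 by default)
are excluded — the quality filter stands in for external variant-panel
membership, which is out of scope. The motif test is a one-sided paired
t-test of own-genotype score > other-genotype score across peaks, with the
higher-own vs higher-other counts reported alongside; all-zero differences
yield a degenerate flag with p = 1. The common-peak analysis correlates
the between-genotype motif-score difference with the between-cell-line
height difference (Pearson, t-based p).

## Trends and comparisons

Peaks are sorted by height (ties broken by peak id for determinism) and
cut into 10 contiguous bins whose sizes differ by at most one; remainder
peaks go to the highest bins. The trend statistic is an ordinary
least-squares fit of the 10 bin means on the bin index 1..10 — the fit is
on bin means, matching the per-bin presentation of the analysis — with a
two-sided slope test at α = 0.05 and no multiple-testing correction
(significance is flagged per panel). Constant bin means short-circuit to
slope 0, p 1, with a degenerate flag.

GC balancing removes the top and bottom 5 % GC tails, cuts the remaining
range into 10 equal-interval GC bins, and samples, within each height bin,
the minimum available count from every occupied GC bin (seeded RNG;
GC bins unoccupied in a height bin are excluded for that bin).

The chromatin comparison selects the 30 % highest (or lowest) peaks by
height rank over the full set and, at the cell-type-specific peaks of
that stratum, applies a two-sample KS test between the own-cell and
other-cell signal distributions, with the common-peak comparison reported
for reference. KS p-values are asymptotic, switching to the exact
small-sample distribution below 30 per group.

## Classifiers

The 16 features are: height percentile (average rank / n × 100, so ties
and singletons are well defined), peak length, promoter overlap (0/1),
capped TSS distance, cluster TF count, cluster average height,
DNase average and difference, H3K4me3 average and difference, H3K27me3
average and difference, CpG observed/expected ratio, High-CpG, Low-CpG,
and phyloP. The models are soft-margin linear SVMs (C = 1, liblinear)
with per-fold z-score standardization under stratified 10-fold CV; the
ROC score is the area under the curve of the decision values. A linear
kernel is the deliberate default: with 16 features, thousands of
examples and an attribution-centred analysis, linearity keeps the
elimination results interpretable; C and the kernel implementation are
config-exposed. Fold assignment is seeded and reproducible.

Feature-group elimination removes one group at a time and reports the
mean-ROC change against the full model at the same seed. The reduced
grouped analysis first drops the Height and Cluster features and then
eliminates three blocks — cell-type-specific (chromatin + both histone
marks), promoter/sequence (promoter, TSS distance, CpG), and conservation
(phyloP); peak length belongs to none of the blocks and stays in the base
set. The high-and-clustered subset keeps peaks at height percentile ≥ 90
whose cluster TF count reaches the 80th percentile (both thresholds
reported); downstream reruns require > 100 peaks per class per TF.

The cross-cell-type protocol stratifies folds on the training labels;
training folds use labels and cell-type-dependent features derived against
one comparison cell line, held-out folds those derived against another,
and the train/test peak subsets are disjoint by construction. Held-out
folds that end up single-class under the test labeling are skipped.

## Synthetic studies

The generator emulates the statistical structure the analysis is designed
to detect, not raw reads. Peaks are laid out on a 2.5 kb grid — one peak
per TF per cell type per grid cell, peak starts confined to a 200 bp zone —
so same-TF peaks never overlap by accident and the emitted common/specific
labels coincide exactly with observed overlap; the worst-case gap between
peaks of adjacent cells (1,900 bp) is exactly what the 2 kb cluster
extension cannot bridge, while peaks sharing a cell always cluster.
Grid cells carry shared gamma-distributed attractiveness weights (shape
0.7), so the TFs co-localize in hotspot cells the way binding concentrates
in cis-regulatory modules; cluster sizes are correspondingly dispersed
rather than binomial.

Reference-cell peaks get log-normal tag-count heights (meanlog 3, sdlog 1,
i.e. median ≈ 20 tags with a heavy tail, resembling trimmed 100–400 bp
peak calls). Commonness is drawn per peak as P(common) = logistic(β₀ +
0.04·height percentile + 0.5·cluster TFs) with β₀ = −4.7, set once so that
roughly one third of reference peaks are common — the headline sharing
level of desk-scale two-line comparisons. Common peaks receive an
overlapping partner jittered ±50 bp (exercising the half-open overlap
logic); the comparison cell type is topped up with specific peaks placed
away from same-TF reference peaks.

Chromatin tracks drop Poisson tags per peak region: base rate 1 tag,
plus an elevation of 15 tags in the cell type owning the peak (DNase and
H3K4me3; H3K27me3 is background-only), scaled by 0.5 + height/100 when
elevation tracks height. Bound regions in accessible chromatin are
enriched well above background, hence the strong default contrast; because
tracks are additive over overlapping peaks, local chromatin signal partly
mirrors cluster size — a realistic confound worth remembering when
interpreting elimination results on generator data. Conservation is a
50 bp-segment track over peak neighbourhoods, N(0, 0.3) noise with +0.5
at common peaks. Genomes are uniform-random sequence with 80 % of CpG
dinucleotides mutated away (mimicking vertebrate CpG depletion, making
background sequence CpG-poor), GC/CpG-rich islands at 30 % of promoters,
and TF consensus motifs (one 10-column matrix per TF, consensus count 18
against 1) planted inside every peak, collision-checked so overlapping
peaks of different TFs keep distinct intact motifs.

A configurable fraction of specific peaks carries a homozygous-different
SNP at the central motif column: the peak-bearing line keeps the consensus
(reference) allele, the other line is homozygous for the worst-scoring
base. Each such SNP is verified at generation time — it is emitted only if
the alternate allele strictly lowers the peak's best motif score, since a
chance second consensus occurrence in flanking sequence could otherwise
mask the disruption. Background SNPs (12 % of peaks by default) get
random genotypes and qualities. The default disruption fraction is 0.1;
analyses that need the extremes (all or none of the specific peaks
disrupted) set it explicitly.

What the generator does **not** emulate: read-level noise, mappability
and GC amplification bias, fragment-size effects, replicate structure,
inter-TF motif similarity, or genuine enhancer biology. Passing tests on
generator data show that the pipeline recovers relationships of the
planted kind at the planted effect sizes — not that those effect sizes
hold in any particular real data set.

## Determinism and numerics

Every stochastic step takes an explicit seed (numpy `default_rng`);
pipeline outputs embed the config hash, seed and package version, and
reruns are byte-identical. Sizes used by the test suite and acceptance
script — 2,000 peaks per TF per cell type on a 2×5 Mb genome for the
default study, 10 seeds for seed-fraction checks, 500 replicates for null
calibrations — were chosen to make each planted effect statistically
decisive on one CPU. Degenerate inputs (empty peak sets, zero-variance
features, all-N windows, missing conservation coverage) return flagged
results or raise typed validation errors rather than silently propagating
zeros.

## Known limitations

* The grid layout caps peaks per TF at the number of 2.5 kb cells per
  genome; infeasible configurations are rejected at construction.
* `relative_overlap` > 1 is possible by design; consumers that need a
  bounded quantity should use the overlap fraction instead.
* The CpG fast path (10 bp stride) can in principle miss a rich window
  that exists only at intermediate offsets of an adversarial sequence;
  the 1 bp stride is available via `step=1`.
* The exchangeability-based null for the genotype test assumes allele
  orientation is symmetric between cell lines, which holds for the
  generator's background SNPs but not necessarily for real ascertainment
  schemes.
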