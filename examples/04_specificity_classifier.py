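"""Predict which peaks are cell-type specific, and which features matter.

Assembles the 16-feature vectors for one TF's reference-cell peaks, runs
10-fold stratified cross-validation of the full SVM and the Height and HPP
baselines, then removes one feature group at a time to see which groups
carry the signal.
"""

from peakspec import classify, pipeline
from peakspec.classify import ModelSpec
from peakspec.simulate import SimConfig, generate

study = generate(SimConfig(seed=3, peaks_per_tf=800, chrom_length=3_000_000))
ref, comp = study.config.cell_types[:2]
tf = "TF3"

ps, ctx, labels = pipeline.build_contexts(study, ref, comp)[tf]
table = classify.assemble_feature_table(ps, ctx)
y = [labels[pid] for pid in table.index]

print(f"{tf}: {len(y)} peaks, {y.count('common')} common / {y.count('specific')} specific")
for spec in (ModelSpec.svm(), ModelSpec.height(), ModelSpec.hpp()):
    res = classify.train_and_crossvalidate(table, y, spec, k=10, seed=0)
    print(f"  {spec.name:<7} mean ROC score = {res.mean_roc:.3f}")

print("\nROC change after removing each feature group (negative = group matters):")
deltas = classify.feature_group_elimination(table, y, k=10, seed=0)
for group, d in sorted(deltas.items(), key=lambda kv: kv[1]):
    print(f"  {group:<10} {d:+.3f}")
print(
    "\nGroups with strongly negative values carried information the other "
    "features could not replace.  In this simulated study conservation and "
    "height dominate; a near-zero value means the group was redundant "
    "(e.g. cluster size is partly mirrored by local chromatin signal), "
    "not that it was unrelated to specificity."
)
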