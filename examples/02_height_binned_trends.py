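"""Do higher peaks overlap more and sit in more active chromatin?

Bins one TF's peaks into ten height groups and regresses each genomic
characteristic's per-bin mean on the bin index.  A significant positive
slope reproduces the hallmark pattern: tall peaks are less cell-type
specific and live in accessible, conserved, motif-bearing sequence.
"""

from peakspec import pipeline
from peakspec.simulate import SimConfig, generate

study = generate(SimConfig(seed=2, peaks_per_tf=600, chrom_length=2_500_000))
ref, comp = study.config.cell_types[:2]
contexts = pipeline.build_contexts(study, ref, comp)

df = pipeline.trend_stage(contexts)
summary = df.drop_duplicates(["tf", "feature"])[
    ["tf", "feature", "slope", "p", "significant"]
]
print(summary.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(
    "\nEach row is one ordinary least-squares fit of 10 bin means on the "
    "bin index; 'significant' marks slope p <= 0.05.  'overlap' rising "
    "with height means tall peaks are more often found in both cell types."
)
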