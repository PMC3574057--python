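"""How many TF peaks are shared between two cell types?

Generates a small synthetic two-cell-type study, counts per-TF peak
overlaps, and prints the relative overlap (overlap count divided by the
smaller peak set) together with windowed overlap counts that ask whether
"missing" overlap hides at nearby alternative sites.
"""

from peakspec import pipeline
from peakspec.simulate import SimConfig, generate

study = generate(SimConfig(seed=1, peaks_per_tf=400, chrom_length=2_000_000))
ref, comp = study.config.cell_types[:2]

df = pipeline.overlap_stage(study, ref, comp)
print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

frac = df["n_overlapping"].sum() / df["n_reference"].sum()
print(f"\n{100 * frac:.1f}% of {ref} peaks overlap a same-TF peak in {comp}.")
print(
    "The overlap_ext columns widen each reference peak by 0..10 kb; a flat "
    "profile means cell-type-specific peaks sit at different loci, not at "
    "shifted nearby sites."
)
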