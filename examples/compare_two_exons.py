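"""Align one sample exon against the reference exon and name the variant.

Builds the bundled synthetic TP53-like model, spikes the c.404G>T hotspot
substitution into exon 5, aligns sample vs reference, and prints the
juxtaposition, the identity score and the called variant.
"""

from exoncompare import (
    apply_variant,
    call_variants,
    fixture_gene_model,
    format_alignment,
    global_align,
    identity_score,
    parse_name,
)

model = fixture_gene_model(seed=1)
ref_exon5 = model.exon_sequence(5)
sample = apply_variant(ref_exon5, parse_name("c.404G>T", model), model)

aln = global_align(ref_exon5, sample)
print(format_alignment(aln))
# identity = identical columns / total columns; one mismatch in a 185-nt
# exon leaves it just below 1
print(f"identity score: {identity_score(aln):.4f}")
for v in call_variants(aln, model, exon_id=5):
    print(f"called variant: {v.name} (exon {v.exon_id})")
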