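"""Score a single deep intronic variant.

Builds a small in-memory locus and a synthetic hexamer table, then
computes the three per-variant statistics of the framework: the
splice-site delta score (DS, from a precomputed annotation), ΔESRseq
(change in total hexamer SRE score over the 11-nt window around the
variant) and the flank absolute difference (SRE-balance asymmetry of the
100-nt windows either side of the variant).
"""

import numpy as np

from spliceland import (
    DictGenome,
    GenomicVariant,
    SpliceAIAnnotation,
    score_variant,
)
from spliceland.simulate import TableSpec, gen_hexamer_table

rng = np.random.default_rng(0)
synth = gen_hexamer_table(TableSpec(seed=0))

# a 400-nt intronic locus with the variant in the middle
seq = "".join(rng.choice(list("ACGT"), size=400))
genome = DictGenome({"chr17": seq})
ref = seq[199]
alt = "A" if ref != "A" else "G"
variant = GenomicVariant(chrom="chr17", pos=200, ref=ref, alt=alt, gene_id="GENE")

# precomputed splice-site delta scores (as parsed from an annotated VCF)
ann = SpliceAIAnnotation(ds_ag=0.41, ds_al=0.0, ds_dg=0.05, ds_dl=0.0, dp_ag=-4)

scores = score_variant(variant, ann, genome, synth.table, region_class="deep_intronic")
print(f"variant          {variant.chrom}:{variant.pos} {variant.ref}>{variant.alt}")
print(f"DS               {scores.ds:.2f}   (max of acceptor/donor gain: intronic)")
print(f"delta_ESRseq     {scores.delta_esrseq:+.3f}  (>= +0.63 suggests SRE gain)")
print(f"flank_abs_diff   {scores.abs_diff:.3f}  (>= 0.51 marks asymmetric SRE balance)")
# DS >= 0.05 already flags this variant as a cryptic-splice-site candidate;
# the SRE statistics are consulted only when DS falls below that cut-off.
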