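"""Filtering and scoring individual exome variants.

Each variant's score is frequency_score x pathogenicity_score: rarity maps
minor allele frequency (MAF) linearly from 1 at 0% to 0 at 2%, and predicted
damage is the most deleterious of SIFT (as 1 - sift), PolyPhen-2 and
MutationTaster, with fixed defaults for loss-of-function classes and 0.6 for
missense variants no tool has scored.
"""

import exomewalker as ew
from exomewalker.variants import Effect, Genotype

variants = [
    ew.AnnotatedVariant("1", 1000, "C", "T", Genotype.HET, gene="GENE1",
                        effect=Effect.MISSENSE, maf=None, polyphen=0.97),
    ew.AnnotatedVariant("1", 2000, "G", "A", Genotype.HET, gene="GENE2",
                        effect=Effect.MISSENSE, maf=0.01, sift=0.02),
    ew.AnnotatedVariant("2", 3000, "A", "G", Genotype.HOM_ALT, gene="GENE3",
                        effect=Effect.NONSENSE, maf=0.001),
    ew.AnnotatedVariant("2", 4000, "T", "C", Genotype.HET, gene="GENE4",
                        effect=Effect.MISSENSE, maf=0.05, polyphen=0.99),
    ew.AnnotatedVariant("3", 5000, "G", "C", Genotype.HET, gene="GENE5",
                        effect=Effect.SYNONYMOUS),
]

kept, removed = ew.filter_variants(variants, max_maf=0.01)
print(f"kept {len(kept)} of {len(variants)} variants")
for r in removed:
    print(f"  removed {r.variant.key} ({r.variant.gene}): {r.reason.value}")

print("\ngene    freq   pathog  variant_score")
for v in kept:
    s = ew.score_variant(v)
    print(f"{v.gene:6s}  {s.frequency_score:.2f}   {s.pathogenicity_score:.2f}"
          f"    {s.variant_score:.3f}")

# GENE4 falls to the 1% MAF filter despite a damaging prediction; GENE5 is
# synonymous (off-target) and removed; the novel damaging missense in GENE1
# scores highest.
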