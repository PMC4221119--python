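"""Gene-level assembly: grouping variants, mode-of-inheritance models and the
per-gene variant score.

Under no inheritance model the gene score is the best single variant score.
An autosomal dominant (AD) gene needs at least one alternate-genotype
variant.  An autosomal recessive (AR) gene needs two alleles: either one
homozygous-alternate variant, or at least two distinct heterozygous variants
assumed in trans (compound heterozygote); in the compound-het case the gene
score is the mean of the two best variant scores.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .variants import AnnotatedVariant, Genotype, VariantScore


class InheritanceModel(enum.Enum):
    NONE = "NONE"
    AD = "AD"
    AR = "AR"


@dataclass
class ScoredVariant:
    variant: AnnotatedVariant
    score: VariantScore


@dataclass
class GeneCandidate:
    """A gene with qualifying variants and its component + fused scores."""

    gene: str
    variants: list[ScoredVariant]
    gene_variant_score: float
    walk_score: float = 0.0
    walk_percentile: float = 0.0
    exome_walker_score: float = 0.0
    rank: int = 0
    off_network: bool = False
    seed_paths: list = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def group_by_gene(
    variants: list[AnnotatedVariant],
) -> tuple[dict[str, list[AnnotatedVariant]], int]:
    """Group variants by annotated gene, preserving per-gene input order.

    Returns (mapping, n_dropped) where n_dropped counts variants lacking a
    gene assignment.
    """
    grouped: dict[str, list[AnnotatedVariant]] = {}
    dropped = 0
    for v in variants:
        if v.gene is None:
            dropped += 1
            continue
        grouped.setdefault(v.gene, []).append(v)
    return grouped, dropped


def apply_inheritance(
    gene_variants: list[AnnotatedVariant], model: InheritanceModel
) -> list[AnnotatedVariant]:
    """Variants of one gene that qualify under the inheritance model; an
    empty list means the gene is excluded from candidacy.

    AD admits HET and HOM_ALT (a homozygous dominant allele is still causal).
    AR requires >=1 HOM_ALT or >=2 distinct HET variants (compound-het
    assumption; phase is unknowable from a single sample).
    """
    alt = [v for v in gene_variants if v.genotype in (Genotype.HET, Genotype.HOM_ALT)]
    if model is InheritanceModel.NONE or model is InheritanceModel.AD:
        return alt
    if model is InheritanceModel.AR:
        homs = [v for v in alt if v.genotype is Genotype.HOM_ALT]
        hets = [v for v in alt if v.genotype is Genotype.HET]
        if homs or len(hets) >= 2:
            return homs + hets if len(hets) >= 2 else homs
        return []
    raise ValueError(f"unknown inheritance model {model}")


def gene_variant_score(
    qualifying: list[ScoredVariant], model: InheritanceModel
) -> float:
    """Per-gene variant score from the qualifying scored variants.

    Default: best single variant score.  AR satisfied only through a
    compound-het pair: mean of the two best scores.  AR with both a HOM_ALT
    variant and a het pair: the larger of the two mechanisms' scores.
    """
    if not qualifying:
        raise ValueError("gene_variant_score called with no qualifying variants")
    scores = [sv.score.variant_score for sv in qualifying]
    if model is not InheritanceModel.AR:
        return max(scores)
    hom_scores = [
        sv.score.variant_score
        for sv in qualifying
        if sv.variant.genotype is Genotype.HOM_ALT
    ]
    het_scores = sorted(
        (
            sv.score.variant_score
            for sv in qualifying
            if sv.variant.genotype is Genotype.HET
        ),
        reverse=True,
    )
    mechanisms = []
    if hom_scores:
        mechanisms.append(max(hom_scores))
    if len(het_scores) >= 2:
        mechanisms.append((het_scores[0] + het_scores[1]) / 2.0)
    if not mechanisms:
        raise ValueError("variants do not satisfy the AR model")
    return max(mechanisms)
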