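"""End-to-end candidate ranking: filter -> score variants -> assemble genes
-> random walk -> fuse -> rank.

Ranking is ordinal: candidates are sorted by the chosen score descending,
ties are broken by ascending alphabetical gene identifier, and unique
consecutive ranks 1..K are assigned — mirroring the real-use situation where
a researcher works through equally scored candidates one by one.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

from .combine import CombinerModel, WalkTransform, combine
from .genes import (
    GeneCandidate,
    InheritanceModel,
    ScoredVariant,
    apply_inheritance,
    gene_variant_score,
    group_by_gene,
)
from .network import PPANetwork, build_transition_matrix, make_seed_set, neighbor_paths
from .variants import AnnotatedVariant, filter_variants, read_vcf, score_variant
from .walk import (
    RWRParams,
    WalkMatrix,
    precompute_walk_matrix,
    rwr_closed_form,
    walk_percentiles,
    walk_scores,
)


class RankKey(enum.Enum):
    EXOMEWALKER = "exomewalker"
    VARIANT = "variant"
    WALK = "walk"


_KEY_ATTR = {
    RankKey.EXOMEWALKER: "exome_walker_score",
    RankKey.VARIANT: "gene_variant_score",
    RankKey.WALK: "walk_score",
}


@dataclass
class RankedResult:
    """Ordered candidate list plus run metadata."""

    candidates: list[GeneCandidate]
    n_postfilter_genes: int
    rank_by: RankKey
    metadata: dict = field(default_factory=dict)

    def rank_of(self, gene: str) -> int | None:
        for c in self.candidates:
            if c.gene == gene:
                return c.rank
        return None

    def write_tsv(self, path: str | Path) -> None:
        """TSV report (6 significant digits) plus a JSON metadata sidecar."""
        cols = (
            "rank\tgene\texome_walker_score\tgene_variant_score\twalk_score\t"
            "n_variants\toff_network\tdirect_seed_neighbors\tsecond_degree_paths\n"
        )
        with open(path, "w") as fh:
            fh.write(cols)
            for c in self.candidates:
                direct = sum(1 for p in c.seed_paths if len(p) == 1)
                second = sum(1 for p in c.seed_paths if len(p) == 2)
                fh.write(
                    f"{c.rank}\t{c.gene}\t{c.exome_walker_score:.6g}\t"
                    f"{c.gene_variant_score:.6g}\t{c.walk_score:.6g}\t"
                    f"{c.n_variants}\t{int(c.off_network)}\t{direct}\t{second}\n"
                )
        Path(str(path) + ".meta.json").write_text(
            json.dumps(
                {"n_postfilter_genes": self.n_postfilter_genes, **self.metadata},
                indent=2,
                sort_keys=True,
            )
        )


def rank_candidates(
    candidates: list[GeneCandidate],
    key: RankKey = RankKey.EXOMEWALKER,
    n_postfilter_genes: int | None = None,
    metadata: dict | None = None,
) -> RankedResult:
    """Assign unique consecutive ranks: descending score, alphabetical
    tie-break."""
    attr = _KEY_ATTR[key]
    ordered = sorted(candidates, key=lambda c: (-getattr(c, attr), c.gene))
    for i, c in enumerate(ordered, start=1):
        c.rank = i
    return RankedResult(
        candidates=ordered,
        n_postfilter_genes=len(candidates) if n_postfilter_genes is None else n_postfilter_genes,
        rank_by=key,
        metadata=metadata or {},
    )


def prioritize_variants(
    variants: list[AnnotatedVariant],
    network: PPANetwork,
    seeds: list[str],
    model: CombinerModel,
    moi: InheritanceModel = InheritanceModel.NONE,
    params: RWRParams | None = None,
    max_maf: float = 0.01,
    rank_by: RankKey = RankKey.EXOMEWALKER,
    walk_matrix: WalkMatrix | None = None,
    collect_paths: bool = True,
) -> RankedResult:
    """Rank candidate genes of one exome's variants (in-memory entry point).

    A precomputed ``walk_matrix`` (shared across many runs on the same
    network and restart probability) skips the per-call factorization.
    Returns a structured empty result when no gene survives filtering and
    the inheritance model.
    """
    params = params or RWRParams()
    kept, removed = filter_variants(variants, max_maf=max_maf)
    grouped, n_unassigned = group_by_gene(kept)

    candidates: list[GeneCandidate] = []
    for gene in sorted(grouped):
        qualifying = apply_inheritance(grouped[gene], moi)
        if not qualifying:
            continue
        scored = [ScoredVariant(v, score_variant(v)) for v in qualifying]
        gvs = gene_variant_score(scored, moi)
        candidates.append(
            GeneCandidate(gene=gene, variants=scored, gene_variant_score=gvs)
        )

    metadata = {
        "r": params.r,
        "moi": moi.value,
        "seeds": sorted(seeds),
        "max_maf": max_maf,
        "rank_by": rank_by.value,
        "n_input_variants": len(variants),
        "n_kept_variants": len(kept),
        "n_removed_variants": len(removed),
        "n_unassigned_variants": n_unassigned,
        "model_provenance": model.provenance,
    }
    if not candidates:
        return RankedResult([], 0, rank_by, metadata)

    seed_set = make_seed_set(network, seeds)
    if walk_matrix is None:
        walk_matrix = precompute_walk_matrix(
            build_transition_matrix(network), params
        )
    profile = rwr_closed_form(walk_matrix, seed_set)
    genes = [c.gene for c in candidates]
    scores, off_network = walk_scores(profile, genes)
    percentiles = walk_percentiles(profile, scores)
    for c in candidates:
        c.walk_score = scores[c.gene]
        c.walk_percentile = percentiles[c.gene]
        c.off_network = c.gene in off_network
        feature = (
            c.walk_percentile
            if model.walk_transform is WalkTransform.PERCENTILE
            else c.walk_score
        )
        c.exome_walker_score = combine(c.gene_variant_score, feature, model)
        if collect_paths:
            c.seed_paths = neighbor_paths(network, c.gene, seed_set, max_len=2)
    metadata["seed_members"] = list(seed_set.members)
    metadata["seeds_missing_from_network"] = list(seed_set.missing)
    return rank_candidates(
        candidates, rank_by, n_postfilter_genes=len(candidates), metadata=metadata
    )


def prioritize(
    vcf: str | Path,
    network: PPANetwork,
    seeds: list[str],
    model: CombinerModel,
    annotations: str | Path | None = None,
    moi: InheritanceModel = InheritanceModel.NONE,
    params: RWRParams | None = None,
    max_maf: float = 0.01,
    rank_by: RankKey = RankKey.EXOMEWALKER,
) -> RankedResult:
    """Rank candidate genes from a VCF file (with optional sidecar
    annotations); see `prioritize_variants` for the pipeline itself."""
    variants = read_vcf(vcf, sidecar=annotations)
    result = prioritize_variants(
        variants,
        network,
        seeds,
        model,
        moi=moi,
        params=params,
        max_maf=max_maf,
        rank_by=rank_by,
    )
    result.metadata["vcf"] = str(vcf)
    return result
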