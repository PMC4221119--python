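"""Deterministic synthetic data: planted-module networks, background exomes
and labeled variant examples.

The generators encode the working assumption of network-based prioritization:
genes of one disease-gene family interact in a dense subnetwork of the larger
interactome.  `generate_network` plants such modules in a sparse random
background graph; `generate_exome` draws background variants with realistic
mixtures of effect classes, allele frequencies (including absent) and
pathogenicity predictions; `generate_labeled_variants` draws
(variant score, walk feature) pairs for training the score fusion.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .combine import Label, LabeledExample
from .network import PPANetwork, network_from_edges
from .variants import (
    AnnotatedVariant,
    Effect,
    Genotype,
    OFF_TARGET_EFFECTS,
)

#: default mixture over effect classes for background exome variants;
#: roughly half the calls fall outside coding sequence / splice sites, and
#: ~10% are loss-of-function — echoing the ~100 genuine LOF variants found
#: per genome, scaled to the 1000-variant fixture exome
DEFAULT_EFFECT_PROPORTIONS: dict[Effect, float] = {
    Effect.MISSENSE: 0.35,
    Effect.NONSENSE: 0.05,
    Effect.FRAMESHIFT: 0.05,
    Effect.SPLICE_SITE: 0.02,
    Effect.INFRAME_INDEL: 0.02,
    Effect.SYNONYMOUS: 0.16,
    Effect.INTRONIC: 0.15,
    Effect.UTR: 0.10,
    Effect.INTERGENIC: 0.06,
    Effect.NONCODING: 0.04,
}

DEFAULT_GENOTYPE_PROPORTIONS: dict[Genotype, float] = {
    Genotype.HET: 0.60,
    Genotype.HOM_ALT: 0.25,
    Genotype.HOM_REF: 0.10,
    Genotype.MISSING: 0.05,
}


@dataclass
class FixtureConfig:
    """Scale and distribution parameters of the synthetic study.

    Defaults give a 300-gene network with 20 planted 5-gene disease-gene
    families and 1000-variant background exomes — small enough for fast
    exhaustive testing, large enough that ranking is non-trivial.
    """

    n_genes: int = 300
    n_modules: int = 20
    module_size: int = 5
    intra_module_edge_prob: float = 0.8
    background_edge_prob: float = 0.01
    n_background_variants: int = 1000
    # MAF mixture: absent (novel), common in (0.01, 0.5], rare in (0, 0.01]
    p_maf_absent: float = 0.30
    p_maf_common: float = 0.20
    # per-tool probability that a missense prediction is available
    p_prediction_present: float = 0.80
    effect_proportions: dict[Effect, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_PROPORTIONS)
    )
    genotype_proportions: dict[Genotype, float] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_PROPORTIONS)
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError(
                f"{self.n_modules} modules of size {self.module_size} do not fit "
                f"in {self.n_genes} genes"
            )
        for p in (
            self.intra_module_edge_prob,
            self.background_edge_prob,
            self.p_maf_absent,
            self.p_maf_common,
            self.p_prediction_present,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.p_maf_absent + self.p_maf_common > 1.0:
            raise ValueError("MAF mixture weights exceed 1")


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def gene_locus(gene_index: int, offset: int = 0) -> tuple[str, int]:
    """Deterministic (chrom, pos) layout: each gene owns a 1 Mb window on one
    of 22 autosomes; ``offset`` addresses positions inside the window."""
    chrom = str(gene_index % 22 + 1)
    base = (gene_index // 22 + 1) * 1_000_000
    return chrom, base + offset


def generate_network(cfg: FixtureConfig) -> tuple[PPANetwork, dict[str, list[str]]]:
    """Random PPA network with planted dense modules (disease-gene families).

    Intra-module edges appear with ``intra_module_edge_prob`` and carry
    confidences in [0.75, 1.0); background edges appear with
    ``background_edge_prob`` and carry confidences in [0.4, 1.0), so a part
    of the background is removed by the 0.7 confidence filter.  Components
    are stitched to the largest one with high-confidence edges so the final
    network is connected; isolated genes are dropped by construction of the
    filter.  Deterministic per seed.

    Returns (network, families) with families mapping family name ->
    member gene list.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    genes = [_gene_name(i) for i in range(cfg.n_genes)]
    order = rng.permutation(cfg.n_genes)
    families: dict[str, list[str]] = {}
    edges: list[tuple[str, str, float]] = []
    for k in range(cfg.n_modules):
        members = sorted(
            genes[i] for i in order[k * cfg.module_size : (k + 1) * cfg.module_size]
        )
        families[f"FAM{k:02d}"] = members
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < cfg.intra_module_edge_prob:
                    edges.append((members[i], members[j], rng.uniform(0.75, 1.0)))
    # sparse background over all genes
    for i in range(cfg.n_genes):
        for j in range(i + 1, cfg.n_genes):
            if rng.random() < cfg.background_edge_prob:
                edges.append((genes[i], genes[j], rng.uniform(0.4, 1.0)))
    g = nx.Graph()
    for a, b, c in edges:
        if c >= 0.7:
            if g.has_edge(a, b):
                c = max(c, g.edges[a, b]["confidence"])
            g.add_edge(a, b, confidence=c)
    # stitch components so the walk can reach every retained gene
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    giant = sorted(components[0])
    for comp in components[1:]:
        member = sorted(comp)[rng.integers(len(comp))]
        anchor = giant[rng.integers(len(giant))]
        g.add_edge(anchor, member, confidence=float(rng.uniform(0.7, 0.9)))
    net = network_from_edges(
        (a, b, d["confidence"]) for a, b, d in g.edges(data=True)
    )
    # families restricted to genes that survived filtering
    families = {
        fam: [m for m in members if m in net.index] for fam, members in families.items()
    }
    return net, families


def generate_exome(
    cfg: FixtureConfig,
    genes: list[str] | None = None,
    seed: int | None = None,
) -> list[AnnotatedVariant]:
    """Background exome: ``n_background_variants`` annotated variants.

    Genes are drawn uniformly from the network gene list (regenerated from
    the config when not supplied).  MAF is a mixture of absent, common
    (uniform in (0.01, 0.5]) and rare (uniform in (0, 0.01]) components.
    Missense predictions are correlated with a latent per-variant
    deleteriousness drawn from Beta(0.7, 2.2), each tool reporting
    independently with probability ``p_prediction_present``.
    """
    if genes is None:
        net, _ = generate_network(cfg)
        genes = list(net.genes)
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    gene_index = {g: int(g[1:]) for g in genes}
    effects = list(cfg.effect_proportions)
    effect_w = np.array([cfg.effect_proportions[e] for e in effects], dtype=float)
    effect_w /= effect_w.sum()
    gts = list(cfg.genotype_proportions)
    gt_w = np.array([cfg.genotype_proportions[g] for g in gts], dtype=float)
    gt_w /= gt_w.sum()
    bases = np.array(list("ACGT"))

    used_offsets: dict[str, int] = {}
    out: list[AnnotatedVariant] = []
    for _ in range(cfg.n_background_variants):
        gene = genes[rng.integers(len(genes))]
        offset = used_offsets.get(gene, 0) + 1 + int(rng.integers(50))
        used_offsets[gene] = offset
        chrom, pos = gene_locus(gene_index[gene], offset)
        effect = effects[rng.choice(len(effects), p=effect_w)]
        genotype = gts[rng.choice(len(gts), p=gt_w)]
        u = rng.random()
        if u < cfg.p_maf_absent:
            maf = None
        elif u < cfg.p_maf_absent + cfg.p_maf_common:
            maf = float(rng.uniform(0.01, 0.5))
        else:
            maf = float(rng.uniform(0.0, 0.01))
        sift = polyphen = mt = None
        if effect is Effect.MISSENSE:
            latent = float(rng.beta(0.7, 2.2))
            if rng.random() < cfg.p_prediction_present:
                sift = float(np.clip(1.0 - latent + rng.normal(0, 0.08), 0, 1))
            if rng.random() < cfg.p_prediction_present:
                polyphen = float(np.clip(latent + rng.normal(0, 0.08), 0, 1))
            if rng.random() < cfg.p_prediction_present:
                mt = float(np.clip(latent + rng.normal(0, 0.08), 0, 1))
        ref = str(bases[rng.integers(4)])
        alt = str(rng.choice(bases[bases != ref]))
        out.append(
            AnnotatedVariant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                genotype=genotype,
                gene=gene,
                effect=effect,
                maf=maf,
                sift=sift,
                polyphen=polyphen,
                mutation_taster=mt,
            )
        )
    out.sort(key=lambda v: (int(v.chrom), v.pos, v.ref, v.alt))
    return out


def expected_retention(cfg: FixtureConfig, max_maf: float = 0.01) -> float:
    """Closed-form probability that a generated background variant survives
    the filter (alternate genotype, on-target effect, MAF not known-common).

    The common MAF component is uniform on (0.01, 0.5], entirely above the
    default 1% cutoff; the rare component lies at or below it.
    """
    gt_w = np.array(list(cfg.genotype_proportions.values()), dtype=float)
    gt_w /= gt_w.sum()
    p_alt = sum(
        w
        for g, w in zip(cfg.genotype_proportions, gt_w)
        if g in (Genotype.HET, Genotype.HOM_ALT)
    )
    eff_w = np.array(list(cfg.effect_proportions.values()), dtype=float)
    eff_w /= eff_w.sum()
    p_on_target = sum(
        w
        for e, w in zip(cfg.effect_proportions, eff_w)
        if e not in OFF_TARGET_EFFECTS
    )
    lo, hi = 0.01, 0.5
    p_common_removed = cfg.p_maf_common * max(0.0, (hi - max(max_maf, lo)) / (hi - lo))
    return p_alt * p_on_target * (1.0 - p_common_removed)


def make_pathogenic_variant(
    gene: str,
    genotype: Genotype = Genotype.HET,
    polyphen: float = 0.95,
    mutation_taster: float = 0.90,
) -> AnnotatedVariant:
    """A rare damaging missense template for spike-in experiments: no
    population frequency (novel), strong damage predictions, placed in the
    gene's locus window above the offsets used by background variants."""
    chrom, pos = gene_locus(int(gene[1:]), offset=900_000)
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref="C",
        alt="T",
        genotype=genotype,
        gene=gene,
        effect=Effect.MISSENSE,
        maf=None,
        sift=None,
        polyphen=polyphen,
        mutation_taster=mutation_taster,
    )


def generate_labeled_variants(
    n_pos: int, n_neg: int, effect_size: float, seed: int
) -> list[LabeledExample]:
    """Labeled (variant score, walk feature) pairs for combiner training.

    Disease examples draw each feature from Beta(a + 3e, a); benign from
    Beta(a, a + 3e) with a = 1.2 and e = ``effect_size``: e = 0 makes the
    classes indistinguishable, large e separates them.  The two features are
    drawn independently, so each carries its own signal.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    rng = np.random.default_rng(seed)
    a = 1.2
    shift = 3.0 * effect_size
    out: list[LabeledExample] = []
    for _ in range(n_pos):
        out.append(
            LabeledExample(
                variant_score=float(rng.beta(a + shift, a)),
                walk_score=float(rng.beta(a + shift, a)),
                label=Label.DISEASE,
            )
        )
    for _ in range(n_neg):
        out.append(
            LabeledExample(
                variant_score=float(rng.beta(a, a + shift)),
                walk_score=float(rng.beta(a, a + shift)),
                label=Label.BENIGN,
            )
        )
    return out
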