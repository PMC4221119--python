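"""End-to-end ranking pipeline and ordinal ranking semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import exomewalker as ew
from exomewalker.genes import GeneCandidate
from exomewalker.prioritize import RankKey
from exomewalker.variants import Effect, Genotype

from test_variants import mkvar


def candidate(gene, score=0.5, walk=0.0):
    return GeneCandidate(
        gene=gene,
        variants=[],
        gene_variant_score=score,
        walk_score=walk,
        exome_walker_score=score,
    )


class TestRankCandidates:
    def test_alphabetical_tie_break(self):
        cands = [candidate("G_B", 0.5), candidate("G_A", 0.5), candidate("G_C", 0.9)]
        result = ew.rank_candidates(cands, RankKey.EXOMEWALKER)
        assert [(c.gene, c.rank) for c in result.candidates] == [
            ("G_C", 1),
            ("G_A", 2),
            ("G_B", 3),
        ]

    def test_all_equal_scores_pure_alphabetical(self):
        cands = [candidate(g, 0.4) for g in ("Z", "M", "A", "Q")]
        result = ew.rank_candidates(cands)
        assert [c.gene for c in result.candidates] == ["A", "M", "Q", "Z"]

    def test_single_candidate_rank_one(self):
        result = ew.rank_candidates([candidate("ONLY")])
        assert result.candidates[0].rank == 1

    @given(st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=40)
    def test_rank_permutation_matches_stable_sort_oracle(self, scores):
        genes = [f"G{i:03d}" for i in range(len(scores))]
        rng = np.random.default_rng(0)
        rng.shuffle(genes)
        cands = [candidate(g, s) for g, s in zip(genes, scores)]
        result = ew.rank_candidates(cands, RankKey.EXOMEWALKER)
        ranks = [c.rank for c in result.candidates]
        assert ranks == list(range(1, len(scores) + 1))
        oracle = sorted(zip(genes, scores), key=lambda t: (-t[1], t[0]))
        assert [c.gene for c in result.candidates] == [g for g, _ in oracle]
        # key consistency
        for a, b in zip(result.candidates, result.candidates[1:]):
            assert a.exome_walker_score > b.exome_walker_score or (
                a.exome_walker_score == b.exome_walker_score and a.gene < b.gene
            )


def toy_study():
    """12-gene network with a 4-gene disease module; spiked damaging variant
    in the module's 4th gene; a decoy background gene carries a higher
    variant score than the spiked gene."""
    module = ["M01", "M02", "M03", "M04"]
    others = [f"B{i:02d}" for i in range(8)]
    edges = []
    for i in range(4):
        for j in range(i + 1, 4):
            edges.append((module[i], module[j], 0.9))
    # background chain, loosely attached to one module gene
    chain = others + [module[0]]
    for a, b in zip(chain, chain[1:]):
        edges.append((a, b, 0.8))
    net = ew.network_from_edges(edges)

    variants = [
        # spiked: rare damaging missense in M04 (variant score 0.9)
        mkvar(pos=10, gene="M04", maf=None, polyphen=0.9),
        # decoy: novel nonsense in a background gene (variant score 0.95)
        mkvar(pos=20, gene="B03", effect=Effect.NONSENSE, maf=None),
    ]
    rng = np.random.default_rng(4)
    for i, g in enumerate(others):
        variants.append(
            mkvar(
                pos=100 + i,
                gene=g,
                maf=float(rng.uniform(0.001, 0.009)),
                polyphen=float(rng.uniform(0.1, 0.6)),
            )
        )
    # a few off-target / common variants exercising the filter
    variants += [
        mkvar(pos=300, gene="B00", effect=Effect.SYNONYMOUS),
        mkvar(pos=301, gene="B01", maf=0.2),
        mkvar(pos=302, gene="B02", genotype=Genotype.HOM_REF),
    ]
    return net, module, variants


class TestPrioritizePipeline:
    def test_spiked_module_gene_ranks_first_by_fused_score(self, trained_model):
        net, module, variants = toy_study()
        result = ew.prioritize_variants(
            variants, net, seeds=module[:3], model=trained_model
        )
        assert result.candidates[0].gene == "M04"
        assert result.rank_of("M04") == 1

    def test_variant_only_ranking_prefers_decoy(self, trained_model):
        net, module, variants = toy_study()
        result = ew.prioritize_variants(
            variants, net, seeds=module[:3], model=trained_model,
            rank_by=RankKey.VARIANT,
        )
        assert result.rank_of("M04") > 1
        assert result.rank_of("B03") < result.rank_of("M04")

    def test_candidates_carry_component_scores_and_paths(self, trained_model):
        net, module, variants = toy_study()
        result = ew.prioritize_variants(
            variants, net, seeds=module[:3], model=trained_model
        )
        top = result.candidates[0]
        assert top.walk_score > 0
        assert 0 < top.exome_walker_score < 1
        direct = [p for p in top.seed_paths if len(p) == 1]
        assert len(direct) == 3  # M04 adjacent to all three seeds

    def test_empty_input_gives_structured_empty_result(self, trained_model):
        net, module, _ = toy_study()
        result = ew.prioritize_variants([], net, seeds=module[:3], model=trained_model)
        assert result.candidates == []
        assert result.n_postfilter_genes == 0

    def test_off_network_gene_still_ranked_via_variant_score(self, trained_model):
        net, module, variants = toy_study()
        variants = variants + [mkvar(pos=999, gene="OFFNET", maf=None, polyphen=0.99)]
        result = ew.prioritize_variants(
            variants, net, seeds=module[:3], model=trained_model
        )
        cand = {c.gene: c for c in result.candidates}["OFFNET"]
        assert cand.off_network
        assert cand.walk_score == 0.0
        assert cand.exome_walker_score > 0

    def test_pipeline_determinism(self, trained_model):
        net, module, variants = toy_study()
        r1 = ew.prioritize_variants(variants, net, seeds=module[:3], model=trained_model)
        r2 = ew.prioritize_variants(variants, net, seeds=module[:3], model=trained_model)
        assert [(c.gene, c.rank, c.exome_walker_score) for c in r1.candidates] == [
            (c.gene, c.rank, c.exome_walker_score) for c in r2.candidates
        ]

    def test_vcf_entry_point_and_tsv_output(self, tmp_path, trained_model):
        net, module, variants = toy_study()
        vcf = tmp_path / "toy.vcf"
        ew.write_vcf(variants, vcf)
        result = ew.prioritize(vcf, net, seeds=module[:3], model=trained_model)
        assert result.rank_of("M04") == 1
        out = tmp_path / "ranked.tsv"
        result.write_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("rank\tgene")
        assert lines[1].split("\t")[1] == "M04"
        assert (tmp_path / "ranked.tsv.meta.json").exists()
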