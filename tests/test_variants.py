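"""Variant filtering/scoring rules and VCF/sidecar IO."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import exomewalker as ew
from exomewalker.variants import (
    Effect,
    Genotype,
    RemovalReason,
    frequency_score,
    pathogenicity_score,
)


def mkvar(**kw):
    base = dict(
        chrom="1",
        pos=100,
        ref="A",
        alt="T",
        genotype=Genotype.HET,
        gene="G1",
        effect=Effect.MISSENSE,
    )
    base.update(kw)
    return ew.AnnotatedVariant(**base)


class TestFrequencyScore:
    @pytest.mark.parametrize(
        "maf, expected",
        [
            (None, 1.0),  # novel variant: rarest-case ceiling
            (0.0, 1.0),
            (0.02, 0.0),  # 2% boundary scores zero
            (0.05, 0.0),
            (0.01, 0.5),  # linear midpoint
            (0.005, 0.75),
        ],
    )
    def test_endpoints_and_linear_map(self, maf, expected):
        assert frequency_score(maf) == pytest.approx(expected)

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError):
            frequency_score(1.5)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_nonincreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert frequency_score(lo) >= frequency_score(hi)


class TestPathogenicityScore:
    def test_most_deleterious_prediction_wins(self):
        v = mkvar(sift=0.01, polyphen=0.2, mutation_taster=None)
        assert pathogenicity_score(v) == pytest.approx(0.99)  # 1 - SIFT

    def test_missing_all_predictions_default(self):
        assert pathogenicity_score(mkvar()) == pytest.approx(0.6)

    @pytest.mark.parametrize(
        "effect", [Effect.SYNONYMOUS, Effect.INTRONIC, Effect.INTERGENIC, Effect.UTR, Effect.NONCODING]
    )
    def test_off_target_scores_zero(self, effect):
        assert pathogenicity_score(mkvar(effect=effect, polyphen=1.0)) == 0.0

    @pytest.mark.parametrize(
        "effect, expected",
        [
            (Effect.NONSENSE, 0.95),
            (Effect.FRAMESHIFT, 0.95),
            (Effect.SPLICE_SITE, 0.90),
            (Effect.INFRAME_INDEL, 0.85),
        ],
    )
    def test_class_defaults(self, effect, expected):
        assert pathogenicity_score(mkvar(effect=effect)) == pytest.approx(expected)

    def test_class_defaults_configurable(self):
        table = {Effect.NONSENSE: 0.5}
        assert pathogenicity_score(mkvar(effect=Effect.NONSENSE), table) == 0.5


class TestScoreVariant:
    def test_product_composition(self):
        s = ew.score_variant(mkvar(maf=None))  # novel missense, no predictions
        assert s.variant_score == pytest.approx(1.0 * 0.6)
        s = ew.score_variant(mkvar(maf=0.02, polyphen=1.0))
        assert s.variant_score == 0.0
        s = ew.score_variant(mkvar(maf=0.0, mutation_taster=1.0))
        assert s.variant_score == pytest.approx(1.0)

    @given(
        st.floats(0, 0.02),
        st.floats(0, 0.02),
        st.floats(0, 1),
        st.floats(0, 1),
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_rarity_and_damage(self, maf_a, maf_b, pph_a, pph_b):
        maf_lo, maf_hi = sorted((maf_a, maf_b))
        pph_lo, pph_hi = sorted((pph_a, pph_b))
        rarer = ew.score_variant(mkvar(maf=maf_lo, polyphen=pph_lo))
        commoner = ew.score_variant(mkvar(maf=maf_hi, polyphen=pph_lo))
        assert rarer.variant_score >= commoner.variant_score
        damaging = ew.score_variant(mkvar(maf=maf_lo, polyphen=pph_hi))
        assert damaging.variant_score >= rarer.variant_score


class TestFilterVariants:
    def toy_table(self):
        return [
            mkvar(pos=1, effect=Effect.INTERGENIC),
            mkvar(pos=2, maf=0.05),
            mkvar(pos=3, maf=0.001),
            mkvar(pos=4, maf=None),
            mkvar(pos=5, maf=0.004),
        ]

    def test_printed_toy_table_counts(self):
        kept, removed = ew.filter_variants(self.toy_table())
        assert len(kept) == 3
        reasons = [r.reason for r in removed]
        assert reasons.count(RemovalReason.OFF_TARGET) == 1
        assert reasons.count(RemovalReason.COMMON) == 1

    def test_absent_maf_is_kept(self):
        kept, _ = ew.filter_variants([mkvar(maf=None)])
        assert len(kept) == 1

    def test_no_alt_genotype_removed(self):
        kept, removed = ew.filter_variants(
            [mkvar(genotype=Genotype.HOM_REF), mkvar(pos=200, genotype=Genotype.MISSING)]
        )
        assert kept == []
        assert all(r.reason is RemovalReason.NO_ALT_GENOTYPE for r in removed)

    def test_partition_and_order(self):
        table = self.toy_table()
        kept, removed = ew.filter_variants(table)
        assert len(kept) + len(removed) == len(table)
        assert set(id(v) for v in kept).isdisjoint(id(r.variant) for r in removed)
        assert [v.pos for v in kept] == sorted(v.pos for v in kept)

    def test_empty_input(self):
        assert ew.filter_variants([]) == ([], [])

    def test_kept_variants_never_off_target(self):
        kept, _ = ew.filter_variants(self.toy_table())
        for v in kept:
            assert ew.score_variant(v).pathogenicity_score >= 0
            assert v.effect not in ew.variants.OFF_TARGET_EFFECTS


class TestVariantValidation:
    def test_position_must_be_one_based(self):
        with pytest.raises(ValueError):
            mkvar(pos=0)

    @pytest.mark.parametrize("field", ["maf", "sift", "polyphen", "mutation_taster"])
    def test_scores_in_unit_interval(self, field):
        with pytest.raises(ValueError):
            mkvar(**{field: 1.2})


class TestVcfRoundTrip:
    def test_exome_round_trips_through_vcf(self, tmp_path):
        cfg = ew.FixtureConfig(n_background_variants=150, rng_seed=3)
        variants = ew.generate_exome(cfg)
        vcf = tmp_path / "exome.vcf"
        ew.write_vcf(variants, vcf)
        back = ew.read_vcf(vcf)
        assert len(back) == len(variants)
        by_key = {v.key: v for v in variants}
        for v in back:
            orig = by_key[v.key]
            assert v.gene == orig.gene
            assert v.effect == orig.effect
            assert v.genotype == orig.genotype
            for f in ("maf", "sift", "polyphen", "mutation_taster"):
                a, b = getattr(v, f), getattr(orig, f)
                assert (a is None) == (b is None)
                if a is not None:
                    assert a == pytest.approx(b, abs=1e-6)

    def test_sidecar_annotations_and_maf_mask(self, tmp_path):
        variants = [
            mkvar(pos=10, maf=0.005, polyphen=0.9),
            mkvar(pos=20, gene="G2", effect=Effect.NONSENSE, maf=None),
        ]
        vcf = tmp_path / "s.vcf"
        side = tmp_path / "s.tsv"
        # write VCF without annotations; annotations only in the sidecar
        bare = [
            ew.AnnotatedVariant(
                chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, genotype=v.genotype
            )
            for v in variants
        ]
        ew.write_vcf(bare, vcf)
        ew.write_sidecar(variants, side)
        back = ew.read_vcf(vcf, sidecar=side)
        assert {v.gene for v in back} == {"G1", "G2"}
        assert back[0].maf == pytest.approx(0.005)
        # masking the only MAF column makes every variant novel
        masked = ew.read_vcf(
            vcf, sidecar=ew.read_sidecar(side, ignore_maf_columns=["maf_max"])
        )
        assert all(v.maf is None for v in masked)

    def test_multiallelic_record_is_split(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t500\t.\tA\tT,G\t.\t.\t.\tGT\t0/1\n"
        )
        back = ew.read_vcf(vcf)
        assert [(v.pos, v.alt) for v in back] == [(500, "T"), (500, "G")]
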