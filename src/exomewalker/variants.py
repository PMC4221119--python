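"""Variant-level filtering and scoring.

Each exome variant is scored by two multiplicative components:

* a frequency score mapping population minor allele frequency (MAF) linearly
  from 1 at MAF 0 down to 0 at MAF 2% (novel variants score 1);
* a pathogenicity score: for missense variants the most deleterious of the
  available SIFT (as 1 - sift), PolyPhen-2 and MutationTaster predictions, or
  0.6 when none is available; for other protein-altering classes a
  configurable class default; 0 for off-target classes.

Variants are filtered before gene assembly: off-target classes, variants with
a known MAF above the cutoff (default 1%), and records without an alternate
genotype call are removed, each with a machine-readable reason.

Annotations (gene, effect class, MAF, predictions) are consumed, not
computed: they arrive either as VCF INFO tags (EWGENE, EWEFFECT, EWMAF,
EWSIFT, EWPPH, EWMT) or as a sidecar TSV keyed by chrom:pos:ref:alt.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class Effect(enum.Enum):
    """Transcript-level consequence class of a variant."""

    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    FRAMESHIFT = "FRAMESHIFT"
    SPLICE_SITE = "SPLICE_SITE"
    INFRAME_INDEL = "INFRAME_INDEL"
    SYNONYMOUS = "SYNONYMOUS"
    NONCODING = "NONCODING"
    INTRONIC = "INTRONIC"
    INTERGENIC = "INTERGENIC"
    UTR = "UTR"


#: classes outside protein-coding sequence / splice sites; pathogenicity 0, removed
OFF_TARGET_EFFECTS = frozenset(
    {Effect.SYNONYMOUS, Effect.NONCODING, Effect.INTRONIC, Effect.INTERGENIC, Effect.UTR}
)


class Genotype(enum.Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"


class RemovalReason(enum.Enum):
    OFF_TARGET = "OFF_TARGET"
    COMMON = "COMMON"
    NO_ALT_GENOTYPE = "NO_ALT_GENOTYPE"


#: pathogenicity defaults for protein-altering classes other than missense
DEFAULT_CLASS_PATHOGENICITY: dict[Effect, float] = {
    Effect.NONSENSE: 0.95,
    Effect.FRAMESHIFT: 0.95,
    Effect.SPLICE_SITE: 0.90,
    Effect.INFRAME_INDEL: 0.85,
}

#: pathogenicity assigned to a missense variant with no prediction from any tool
MISSING_PREDICTION_DEFAULT = 0.6

#: MAF at which the frequency score reaches 0
FREQUENCY_SCORE_CEILING = 0.02

#: variants with a known MAF above this are excluded outright
DEFAULT_MAX_MAF = 0.01


@dataclass(frozen=True)
class AnnotatedVariant:
    """One bi-allelic variant call plus its consumed annotations.

    ``maf`` is the maximal reported population frequency across sources
    (``None`` for variants unseen in any population database).  ``sift`` is a
    tolerance score (low = damaging); ``polyphen`` and ``mutation_taster``
    are damage probabilities (high = damaging).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: Genotype
    gene: str | None = None
    effect: Effect | None = None
    maf: float | None = None
    sift: float | None = None
    polyphen: float | None = None
    mutation_taster: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        for name in ("maf", "sift", "polyphen", "mutation_taster"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1] at {self.key}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class VariantScore:
    frequency_score: float
    pathogenicity_score: float

    @property
    def variant_score(self) -> float:
        return self.frequency_score * self.pathogenicity_score


@dataclass(frozen=True)
class RemovedVariant:
    variant: AnnotatedVariant
    reason: RemovalReason


def frequency_score(maf: float | None) -> float:
    """Rarity score: 1 at MAF 0 falling linearly to 0 at MAF 2%.

    A variant with no reported frequency in any source is treated as novel
    and scores 1.0.
    """
    if maf is None:
        return 1.0
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"MAF must be in [0, 1], got {maf}")
    if maf >= FREQUENCY_SCORE_CEILING:
        return 0.0
    return 1.0 - maf / FREQUENCY_SCORE_CEILING


def pathogenicity_score(
    v: AnnotatedVariant,
    class_defaults: dict[Effect, float] | None = None,
) -> float:
    """Predicted-deleteriousness score in [0, 1].

    Missense: max of (1 - sift), polyphen, mutation_taster over whichever are
    present, or 0.6 when all three are absent.  Other protein-altering
    classes take a class default (see DEFAULT_CLASS_PATHOGENICITY).
    Off-target classes score 0.
    """
    if v.effect is None or v.effect in OFF_TARGET_EFFECTS:
        return 0.0
    if v.effect is Effect.MISSENSE:
        preds = []
        if v.sift is not None:
            preds.append(1.0 - v.sift)
        if v.polyphen is not None:
            preds.append(v.polyphen)
        if v.mutation_taster is not None:
            preds.append(v.mutation_taster)
        return max(preds) if preds else MISSING_PREDICTION_DEFAULT
    table = DEFAULT_CLASS_PATHOGENICITY if class_defaults is None else class_defaults
    return table[v.effect]


def score_variant(
    v: AnnotatedVariant, class_defaults: dict[Effect, float] | None = None
) -> VariantScore:
    """Frequency score x pathogenicity score for a variant that passed the
    filter."""
    return VariantScore(
        frequency_score=frequency_score(v.maf),
        pathogenicity_score=pathogenicity_score(v, class_defaults),
    )


def filter_variants(
    variants: Iterable[AnnotatedVariant],
    max_maf: float = DEFAULT_MAX_MAF,
) -> tuple[list[AnnotatedVariant], list[RemovedVariant]]:
    """Partition variants into (kept, removed-with-reason).

    Removes off-target effect classes, variants with a known MAF above
    ``max_maf`` and records without an alternate genotype call.  A variant
    with no reported MAF cannot be excluded on frequency.  Input order of the
    kept list is preserved; kept and removed partition the input.
    """
    if not 0.0 <= max_maf <= 1.0:
        raise ValueError(f"max_maf must be in [0, 1], got {max_maf}")
    kept: list[AnnotatedVariant] = []
    removed: list[RemovedVariant] = []
    for v in variants:
        if v.genotype in (Genotype.HOM_REF, Genotype.MISSING):
            removed.append(RemovedVariant(v, RemovalReason.NO_ALT_GENOTYPE))
        elif v.effect is None or v.effect in OFF_TARGET_EFFECTS:
            removed.append(RemovedVariant(v, RemovalReason.OFF_TARGET))
        elif v.maf is not None and v.maf > max_maf:
            removed.append(RemovedVariant(v, RemovalReason.COMMON))
        else:
            kept.append(v)
    return kept, removed


# ---------------------------------------------------------------------------
# IO: VCF + annotation sidecar
# ---------------------------------------------------------------------------

_GT_FROM_CYVCF2 = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.MISSING, 3: Genotype.HOM_ALT}

SIDECAR_FIXED_COLUMNS = ("chrom", "pos", "ref", "alt", "gene", "effect")
SIDECAR_PRED_COLUMNS = ("sift", "polyphen", "mutation_taster")


def read_sidecar(
    path: str | Path, ignore_maf_columns: Sequence[str] = ()
) -> dict[str, dict]:
    """Load an annotation sidecar TSV keyed by chrom:pos:ref:alt.

    Columns: chrom pos ref alt gene effect maf_* sift polyphen
    mutation_taster, '.' for absent.  Multiple ``maf_*`` columns are
    collapsed to their maximum (maximal reported frequency in any source);
    columns named in ``ignore_maf_columns`` are masked out, which lets a
    benchmark withhold one frequency source.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    maf_cols = [
        c for c in df.columns if c.startswith("maf") and c not in set(ignore_maf_columns)
    ]
    out: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        mafs = [float(d[c]) for c in maf_cols if pd.notna(d[c])]
        ann = {
            "gene": d["gene"] if pd.notna(d["gene"]) else None,
            "effect": Effect[d["effect"]] if pd.notna(d["effect"]) else None,
            "maf": max(mafs) if mafs else None,
        }
        for c in SIDECAR_PRED_COLUMNS:
            ann[c] = float(d[c]) if c in d and pd.notna(d[c]) else None
        key = f"{d['chrom']}:{d['pos']}:{d['ref']}:{d['alt']}"
        out[key] = ann
    return out


def read_vcf(
    vcf_path: str | Path,
    sidecar: dict[str, dict] | str | Path | None = None,
    ignore_maf_columns: Sequence[str] = (),
) -> list[AnnotatedVariant]:
    """Read a single-sample VCF into AnnotatedVariants.

    Multi-allelic records are split into bi-allelic variants.  Annotations
    come from a sidecar (path or pre-loaded mapping) when given, otherwise
    from EW* INFO tags.  Records with neither stay unannotated (gene None)
    and fall out at the filter step.
    """
    from cyvcf2 import VCF

    if sidecar is not None and not isinstance(sidecar, dict):
        sidecar = read_sidecar(sidecar, ignore_maf_columns=ignore_maf_columns)

    out: list[AnnotatedVariant] = []
    vcf = VCF(str(vcf_path))
    try:
        for rec in vcf:
            if len(vcf.samples) >= 1:
                gt = _GT_FROM_CYVCF2.get(int(rec.gt_types[0]), Genotype.MISSING)
            else:
                gt = Genotype.MISSING
            for alt in rec.ALT:
                key = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
                if sidecar is not None:
                    ann = sidecar.get(key, {})
                else:
                    ann = _annotations_from_info(rec)
                out.append(
                    AnnotatedVariant(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        genotype=gt,
                        gene=ann.get("gene"),
                        effect=ann.get("effect"),
                        maf=ann.get("maf"),
                        sift=ann.get("sift"),
                        polyphen=ann.get("polyphen"),
                        mutation_taster=ann.get("mutation_taster"),
                    )
                )
    finally:
        vcf.close()
    return out


def _annotations_from_info(rec) -> dict:
    def _num(tag):
        v = rec.INFO.get(tag)
        return float(v) if v is not None else None

    eff = rec.INFO.get("EWEFFECT")
    return {
        "gene": rec.INFO.get("EWGENE"),
        "effect": Effect[eff] if eff else None,
        "maf": _num("EWMAF"),
        "sift": _num("EWSIFT"),
        "polyphen": _num("EWPPH"),
        "mutation_taster": _num("EWMT"),
    }


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=EWGENE,Number=1,Type=String,Description="Gene identifier">
##INFO=<ID=EWEFFECT,Number=1,Type=String,Description="Effect class">
##INFO=<ID=EWMAF,Number=1,Type=Float,Description="Maximal population MAF">
##INFO=<ID=EWSIFT,Number=1,Type=Float,Description="SIFT tolerance score">
##INFO=<ID=EWPPH,Number=1,Type=Float,Description="PolyPhen-2 probability">
##INFO=<ID=EWMT,Number=1,Type=Float,Description="MutationTaster probability">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE1
"""

_GT_TO_VCF = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def chrom_key_str(c: str) -> tuple:
    c = c.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def write_vcf(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    """Write variants as a single-sample VCF v4.2 with EW* INFO annotations.

    Sorted by (chrom, pos, ref, alt) with numeric-aware chromosome order.
    """
    def chrom_key(v: AnnotatedVariant):
        c = v.chrom.removeprefix("chr")
        return (0, int(c)) if c.isdigit() else (1, c)

    chroms = sorted({v.chrom for v in variants}, key=lambda c: chrom_key_str(c))
    header, columns = _VCF_HEADER.rsplit("#CHROM", 1)
    with open(path, "w") as fh:
        fh.write(header)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM" + columns)
        for v in sorted(variants, key=lambda v: (chrom_key(v), v.pos, v.ref, v.alt)):
            info = []
            if v.gene is not None:
                info.append(f"EWGENE={v.gene}")
            if v.effect is not None:
                info.append(f"EWEFFECT={v.effect.value}")
            for tag, val in (
                ("EWMAF", v.maf),
                ("EWSIFT", v.sift),
                ("EWPPH", v.polyphen),
                ("EWMT", v.mutation_taster),
            ):
                if val is not None:
                    info.append(f"{tag}={val:.6g}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                f"{';'.join(info) or '.'}\tGT\t{_GT_TO_VCF[v.genotype]}\n"
            )


def write_sidecar(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    """Write the annotation sidecar TSV mirroring the variants' annotations
    (single ``maf_max`` column)."""
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene if v.gene is not None else ".",
                "effect": v.effect.value if v.effect is not None else ".",
                "maf_max": f"{v.maf:.6g}" if v.maf is not None else ".",
                "sift": f"{v.sift:.6g}" if v.sift is not None else ".",
                "polyphen": f"{v.polyphen:.6g}" if v.polyphen is not None else ".",
                "mutation_taster": f"{v.mutation_taster:.6g}"
                if v.mutation_taster is not None
                else ".",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
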