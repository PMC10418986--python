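"""Readers and writers for the formats the pipeline touches.

Two variant sources are supported: a multi-sample VCF 4.x file whose INFO
field carries the functional annotations, and a flat annotation table in a
documented TSV dialect (tab-separated, a single ``#``-prefixed header line,
``.`` for missing values) of the kind produced by consequence annotators.
Reports are written as deterministic, sorted TSV so identical inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import ConfigurationError, ParseError
from .model import (
    AnnotatedVariant,
    Cohort,
    EffectClass,
    Genotype,
    RegionClass,
    Role,
    Sample,
    Trio,
    sort_variants,
)

logger = logging.getLogger(__name__)

# Annovar-style effect strings -> internal effect classes. Compound strings
# (e.g. "exonic;splicing") are resolved by the precedence order below:
# splice_site > stopgain > stoploss > frameshift > inframe > nonsynonymous >
# synonymous > noncoding.
_EFFECT_ALIASES: dict[str, EffectClass] = {
    "synonymous": EffectClass.SYNONYMOUS,
    "synonymous snv": EffectClass.SYNONYMOUS,
    "nonsynonymous": EffectClass.NONSYNONYMOUS,
    "nonsynonymous snv": EffectClass.NONSYNONYMOUS,
    "missense": EffectClass.NONSYNONYMOUS,
    "frameshift": EffectClass.FRAMESHIFT_INDEL,
    "frameshift_indel": EffectClass.FRAMESHIFT_INDEL,
    "frameshift insertion": EffectClass.FRAMESHIFT_INDEL,
    "frameshift deletion": EffectClass.FRAMESHIFT_INDEL,
    "frameshift substitution": EffectClass.FRAMESHIFT_INDEL,
    "indel": EffectClass.FRAMESHIFT_INDEL,
    "inframe_indel": EffectClass.INFRAME_INDEL,
    "nonframeshift insertion": EffectClass.INFRAME_INDEL,
    "nonframeshift deletion": EffectClass.INFRAME_INDEL,
    "stopgain": EffectClass.STOPGAIN,
    "stop-gain": EffectClass.STOPGAIN,
    "stoploss": EffectClass.STOPLOSS,
    "stop-loss": EffectClass.STOPLOSS,
    "splicing": EffectClass.SPLICE_SITE,
    "splice_site": EffectClass.SPLICE_SITE,
    "splice site": EffectClass.SPLICE_SITE,
    "noncoding": EffectClass.NONCODING,
    "ncrna_exonic": EffectClass.NONCODING,
    "unknown": EffectClass.UNKNOWN,
}

_EFFECT_PRECEDENCE = [
    EffectClass.SPLICE_SITE,
    EffectClass.STOPGAIN,
    EffectClass.STOPLOSS,
    EffectClass.FRAMESHIFT_INDEL,
    EffectClass.INFRAME_INDEL,
    EffectClass.NONSYNONYMOUS,
    EffectClass.SYNONYMOUS,
    EffectClass.NONCODING,
]

_REGION_ALIASES: dict[str, RegionClass] = {
    "protein_coding_exon": RegionClass.PROTEIN_CODING_EXON,
    "exonic": RegionClass.PROTEIN_CODING_EXON,
    "utr5": RegionClass.UTR5,
    "utr3": RegionClass.UTR3,
    "lncrna_exon": RegionClass.LNCRNA_EXON,
    "intron": RegionClass.INTRON,
    "intronic": RegionClass.INTRON,
    "intergenic": RegionClass.INTERGENIC,
}


def parse_effect(text: str) -> EffectClass:
    """Map an annotator effect string (possibly compound) to an effect class.

    Compound annotations separated by ``;`` or ``,`` resolve to the
    highest-precedence component; an unrecognized string maps to ``UNKNOWN``
    with a logged warning rather than aborting.
    """
    parts = [p.strip().lower() for p in re.split(r"[;,]", text) if p.strip()]
    found = [_EFFECT_ALIASES[p] for p in parts if p in _EFFECT_ALIASES]
    if not found:
        logger.warning("unknown effect string %r mapped to 'unknown'", text)
        return EffectClass.UNKNOWN
    if len(found) > 1:
        chosen = min(found, key=_EFFECT_PRECEDENCE.index)
        logger.info("compound effect %r resolved to %s by precedence", text, chosen.value)
        return chosen
    return found[0]


def parse_region(text: str) -> RegionClass:
    key = text.strip().lower()
    if key not in _REGION_ALIASES:
        logger.warning("unknown region string %r mapped to 'intergenic'", text)
        return RegionClass.INTERGENIC
    return _REGION_ALIASES[key]


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def _recode_genotype(alleles: Sequence[int], alt_index: int) -> tuple[Genotype, bool]:
    """Recode a diploid allele pair against one alternate allele.

    Returns the genotype and whether the call carried *another* alternate
    allele and was recoded to hom_ref for the allele under consideration.
    """
    if any(a < 0 for a in alleles):
        return Genotype.MISSING, False
    n_this = sum(1 for a in alleles if a == alt_index)
    other = any(a not in (0, alt_index) for a in alleles)
    if n_this == 2:
        return Genotype.HOM_ALT, False
    if n_this == 1:
        return Genotype.HET, False
    return Genotype.HOM_REF, other


def read_vcf(path: str | Path, cohort: Cohort) -> list[AnnotatedVariant]:
    """Read a multi-sample VCF into annotated variants, one per (record, alt).

    Annotations are taken from INFO keys ``GENE``, ``REGION``, ``EFFECT``,
    ``SPLICE_DIST``, ``CADD``, ``MAPPABILITY``, the flag ``DISCORDANT`` and
    frequency keys of the form ``AF_<resource>``; per-alt values may be
    comma-separated in allele order. Missing annotations stay null/unknown.
    dbSNP membership is inferred from a non-missing ID column.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad input
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    vcf_samples = list(vcf.samples)
    missing = [s for s in cohort.sample_ids if s not in vcf_samples]
    if missing:
        raise ConfigurationError(
            f"cohort samples absent from VCF {path}: {', '.join(missing)}"
        )

    def per_alt(value: object, i: int, n_alt: int) -> str | None:
        if value is None:
            return None
        if isinstance(value, (tuple, list)):
            return str(value[i]) if i < len(value) else None
        text = str(value)
        if n_alt > 1 and "," in text:
            parts = text.split(",")
            return parts[i] if i < len(parts) else None
        return text

    variants: list[AnnotatedVariant] = []
    for record in vcf:
        n_alt = len(record.ALT)
        gts = record.genotypes  # [[a1, a2, phased], ...] in vcf sample order
        depths = {}
        try:
            dp = record.format("DP")
        except KeyError:
            dp = None
        for j, sample in enumerate(vcf_samples):
            if sample not in cohort.sample_ids:
                continue
            if dp is not None and dp[j][0] >= 0:
                depths[sample] = int(dp[j][0])
        for i, alt in enumerate(record.ALT):
            freqs: dict[str, float] = {}
            for key in record.INFO:
                name = key[0] if isinstance(key, tuple) else key
                if name.startswith("AF_"):
                    raw = per_alt(record.INFO.get(name), i, n_alt)
                    if raw not in (None, "", "."):
                        freqs[name[3:]] = float(raw)
            cadd = per_alt(record.INFO.get("CADD"), i, n_alt)
            sdist = per_alt(record.INFO.get("SPLICE_DIST"), i, n_alt)
            mapp = record.INFO.get("MAPPABILITY")
            effect = per_alt(record.INFO.get("EFFECT"), i, n_alt)
            region = per_alt(record.INFO.get("REGION"), i, n_alt)
            genotypes: dict[str, Genotype] = {}
            flags: set[str] = set()
            for j, sample in enumerate(vcf_samples):
                if sample not in cohort.sample_ids:
                    continue
                gt, recoded = _recode_genotype(gts[j][:2], i + 1)
                genotypes[sample] = gt
                if recoded:
                    flags.add(f"recoded_other_alt:{sample}")
            if n_alt > 1:
                flags.add("split_multiallelic")
            variants.append(
                AnnotatedVariant(
                    chrom=record.CHROM,
                    pos=record.POS,
                    ref=record.REF,
                    alt=alt,
                    gene=record.INFO.get("GENE"),
                    region_class=parse_region(region) if region else RegionClass.INTERGENIC,
                    effect_class=parse_effect(effect) if effect else EffectClass.UNKNOWN,
                    splice_distance=int(sdist) if sdist not in (None, ".") else None,
                    cadd_phred=float(cadd) if cadd not in (None, ".") else None,
                    allele_freqs=freqs,
                    known=record.ID is not None,
                    genotypes=genotypes,
                    depths=dict(depths),
                    mappability=float(mapp) if mapp is not None else None,
                    assembly_concordant=record.INFO.get("DISCORDANT") is None,
                    flags=flags,
                )
            )
    return variants


# ---------------------------------------------------------------------------
# Annotation table (TSV dialect)
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "region",
    "effect",
    "splice_distance",
    "cadd",
    "known",
    "mappability",
    "concordant",
]

_MISSING = "."


def _fmt(value: object) -> str:
    if value is None:
        return _MISSING
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_annotation_table(
    variants: Iterable[AnnotatedVariant], path: str | Path
) -> None:
    """Write variants to the TSV annotation dialect (round-trips with the reader)."""
    variants = sort_variants(variants)
    resources = sorted({r for v in variants for r in v.allele_freqs})
    samples = sorted({s for v in variants for s in v.genotypes})
    header = (
        _FIXED_COLUMNS
        + [f"freq:{r}" for r in resources]
        + [f"gt:{s}" for s in samples]
        + [f"dp:{s}" for s in samples]
    )
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for v in variants:
            row = [
                v.chrom,
                str(v.pos),
                v.ref,
                v.alt,
                _fmt(v.gene),
                v.region_class.value,
                v.effect_class.value,
                _fmt(v.splice_distance),
                _fmt(v.cadd_phred),
                _fmt(v.known),
                _fmt(v.mappability),
                _fmt(v.assembly_concordant),
            ]
            row += [
                _fmt(v.allele_freqs.get(r)) if r in v.allele_freqs else _MISSING
                for r in resources
            ]
            row += [
                v.genotypes[s].value if v.genotypes.get(s, Genotype.MISSING) != Genotype.MISSING
                else _MISSING
                for s in samples
            ]
            row += [_fmt(v.depths.get(s)) for s in samples]
            fh.write("\t".join(row) + "\n")


def read_annotation_table(path: str | Path) -> list[AnnotatedVariant]:
    """Read the TSV annotation dialect into typed variants.

    An empty/``.`` frequency cell means the allele is absent from that
    catalog (the resource is left out of ``allele_freqs``); a variant with
    every frequency cell empty is therefore treated as novel downstream.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.startswith("#"):
            raise ParseError(f"{path}:1: annotation table must start with a '#' header")
        columns = header_line[1:].rstrip("\n").split("\t")
        for col in _FIXED_COLUMNS:
            if col not in columns:
                raise ParseError(f"{path}:1: missing required column {col!r}")
        idx = {c: k for k, c in enumerate(columns)}
        freq_cols = [(c[5:], idx[c]) for c in columns if c.startswith("freq:")]
        gt_cols = [(c[3:], idx[c]) for c in columns if c.startswith("gt:")]
        dp_cols = [(c[3:], idx[c]) for c in columns if c.startswith("dp:")]

        variants: list[AnnotatedVariant] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(columns):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(columns)} columns, got {len(cells)}"
                )

            def cell(col: str) -> str:
                return cells[idx[col]]

            def opt(col: str) -> str | None:
                value = cells[idx[col]]
                return None if value == _MISSING or value == "" else value

            try:
                sdist = opt("splice_distance")
                cadd = opt("cadd")
                mapp = opt("mappability")
                variants.append(
                    AnnotatedVariant(
                        chrom=cell("chrom"),
                        pos=int(cell("pos")),
                        ref=cell("ref"),
                        alt=cell("alt"),
                        gene=opt("gene"),
                        region_class=parse_region(cell("region")),
                        effect_class=parse_effect(cell("effect")),
                        splice_distance=int(sdist) if sdist is not None else None,
                        cadd_phred=float(cadd) if cadd is not None else None,
                        allele_freqs={
                            r: float(cells[k])
                            for r, k in freq_cols
                            if cells[k] not in (_MISSING, "")
                        },
                        known=cell("known") == "1",
                        genotypes={
                            s: Genotype(cells[k]) if cells[k] != _MISSING else Genotype.MISSING
                            for s, k in gt_cols
                        },
                        depths={
                            s: int(cells[k]) for s, k in dp_cols if cells[k] != _MISSING
                        },
                        mappability=float(mapp) if mapp is not None else None,
                        assembly_concordant=cell("concordant") == "1",
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return variants


def read_variants(path: str | Path, cohort: Cohort) -> list[AnnotatedVariant]:
    """Dispatch on extension: ``.vcf``/``.vcf.gz`` -> VCF reader, else TSV table."""
    name = str(path)
    if name.endswith(".vcf") or name.endswith(".vcf.gz"):
        return read_vcf(path, cohort)
    return read_annotation_table(path)


from .prioritize import write_candidate_report  # noqa: E402,F401  (re-export)


# ---------------------------------------------------------------------------
# Cohort configuration (YAML/JSON)
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path) -> Cohort:
    """Load a cohort from a YAML/JSON config.

    Expected shape::

        samples:
          - {id: P1, role: proband, affected: true, sex: M}
          - {id: F1, role: father, affected: false}
        trios:
          - {proband: P1, father: F1, mother: M1}
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) if str(path).endswith((".yaml", ".yml")) else json.load(fh)
    try:
        samples = [
            Sample(
                sample_id=str(s["id"]),
                role=Role(s["role"]),
                affected=bool(s["affected"]),
                sex=s.get("sex"),
            )
            for s in data["samples"]
        ]
        trios = [
            Trio(proband=t["proband"], father=t["father"], mother=t["mother"])
            for t in data.get("trios", [])
        ]
    except (KeyError, ValueError) as exc:
        raise ConfigurationError(f"bad cohort config {path}: {exc}") from exc
    return Cohort(samples=samples, trios=trios)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    data = {
        "samples": [
            {"id": s.sample_id, "role": s.role.value, "affected": s.affected, "sex": s.sex}
            for s in cohort.samples
        ],
        "trios": [
            {"proband": t.proband, "father": t.father, "mother": t.mother}
            for t in cohort.trios
        ],
    }
    with open(path, "w") as fh:
        if str(path).endswith((".yaml", ".yml")):
            yaml.safe_dump(data, fh, sort_keys=False)
        else:
            json.dump(data, fh, indent=2)
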