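"""Inheritance-model candidate filtering for rare-disease exomes.

Implements the filters used to shortlist candidate disease-causing variants
in an autosomal-recessive setting: rare homozygous candidates with parental
exclusion, the disruptive-effect ("disease-causing") subset, compound
heterozygosity (phase-checked when a trio is available, phase-unknown
otherwise), de novo detection, a looser comorbidity screen and
cross-patient gene recurrence.

Frequency clauses always use the *maximum* allele frequency across all
population catalogs: an allele common in any single catalog is not rare.
An allele absent from every catalog is treated as novel (frequency 0).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .classify import is_disruptive
from .errors import ConfigurationError
from .model import (
    AnnotatedVariant,
    Cohort,
    FilterConfig,
    Genotype,
    Trio,
    sort_variants,
)

logger = logging.getLogger(__name__)


@dataclass
class CompoundHetPair:
    """Two distinct heterozygous candidates in one gene.

    ``phase`` is ``"phase_confirmed"`` when parental genotypes show the two
    variants on opposite haplotypes (one inherited from each parent) and
    ``"phase_unknown"`` when no parental genotypes are available.
    """

    gene: str
    variant_a: AnnotatedVariant
    variant_b: AnnotatedVariant
    phase: str = "phase_unknown"


@dataclass
class CandidateReport:
    """Per-proband candidate lists plus cohort-level recurrence results."""

    rare_homozygous: dict[str, list[AnnotatedVariant]] = field(default_factory=dict)
    disease_causing: dict[str, list[AnnotatedVariant]] = field(default_factory=dict)
    compound_het: dict[str, dict[str, list[CompoundHetPair]]] = field(default_factory=dict)
    de_novo: dict[str, list[AnnotatedVariant]] = field(default_factory=dict)
    comorbidity_variants: list[AnnotatedVariant] = field(default_factory=list)
    recurrent_genes: dict[str, set[str]] = field(default_factory=dict)


def _is_rare(variant: AnnotatedVariant, maf: float) -> bool:
    return variant.max_allele_freq() <= maf


def rare_homozygous(
    variants: Iterable[AnnotatedVariant],
    proband: str,
    cohort: Cohort,
    config: FilterConfig,
) -> list[AnnotatedVariant]:
    """Rare variants homozygous in the proband and not in any healthy parent.

    Keeps variants whose maximum catalog frequency is <= ``maf_disease``,
    that are hom-alt in the proband, and that are not hom-alt in any healthy
    parent sample present in the cohort (parental exclusion applies
    cohort-wide, not only to the proband's own trio). A parent with a
    missing genotype does not veto the candidate; the variant is flagged
    ``parent_missing`` instead.
    """
    if proband not in cohort.sample_ids:
        raise ConfigurationError(f"proband {proband!r} not in cohort")
    parents = cohort.healthy_parents
    out: list[AnnotatedVariant] = []
    for v in variants:
        if not _is_rare(v, config.maf_disease):
            continue
        if v.genotype(proband) is not Genotype.HOM_ALT:
            continue
        vetoed = False
        for parent in parents:
            gt = v.genotype(parent)
            if gt is Genotype.HOM_ALT:
                vetoed = True
                break
            if gt is Genotype.MISSING:
                v.flags.add("parent_missing")
        if not vetoed:
            out.append(v)
    logger.info("rare_homozygous(%s): %d candidates", proband, len(out))
    return sort_variants(out)


def disease_causing(
    rare_homozygous_list: Sequence[AnnotatedVariant], config: FilterConfig
) -> list[AnnotatedVariant]:
    """Subset of rare homozygous candidates with a radical/deleterious effect."""
    return sort_variants(v for v in rare_homozygous_list if is_disruptive(v, config))


def compound_het(
    variants: Iterable[AnnotatedVariant],
    proband: str,
    cohort: Cohort,
    config: FilterConfig,
) -> dict[str, list[CompoundHetPair]]:
    """Candidate compound-heterozygous genes for one proband.

    Groups the proband's heterozygous, rare (max frequency <= ``maf_disease``),
    disruptive variants by gene and reports genes carrying at least two
    distinct such variants. With a fully genotyped trio, only pairs in trans
    are kept: one variant carried by exactly the father and the other by
    exactly the mother (``phase_confirmed``); pairs compatible with a single
    parental haplotype are dropped. Without parental genotypes every pair is
    reported ``phase_unknown``.
    """
    if proband not in cohort.sample_ids:
        raise ConfigurationError(f"proband {proband!r} not in cohort")
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in variants:
        if v.gene is None:
            continue
        if v.genotype(proband) is not Genotype.HET:
            continue
        if not _is_rare(v, config.maf_disease):
            continue
        if not is_disruptive(v, config):
            continue
        by_gene.setdefault(v.gene, []).append(v)

    trio = cohort.trio_for(proband)
    result: dict[str, list[CompoundHetPair]] = {}
    for gene, gene_variants in sorted(by_gene.items()):
        gene_variants = sort_variants(gene_variants)
        if len(gene_variants) < 2:
            continue
        pairs: list[CompoundHetPair] = []
        for a, b in itertools.combinations(gene_variants, 2):
            if trio is None:
                pairs.append(CompoundHetPair(gene, a, b, "phase_unknown"))
                continue
            ga_f, ga_m = a.genotype(trio.father), a.genotype(trio.mother)
            gb_f, gb_m = b.genotype(trio.father), b.genotype(trio.mother)
            if Genotype.MISSING in (ga_f, ga_m, gb_f, gb_m):
                pairs.append(CompoundHetPair(gene, a, b, "phase_unknown"))
                continue
            a_from = {p for p, gt in (("father", ga_f), ("mother", ga_m)) if gt.carries_alt}
            b_from = {p for p, gt in (("father", gb_f), ("mother", gb_m)) if gt.carries_alt}
            if (a_from, b_from) in (
                ({"father"}, {"mother"}),
                ({"mother"}, {"father"}),
            ):
                pairs.append(CompoundHetPair(gene, a, b, "phase_confirmed"))
            # otherwise: both variants on one parental haplotype (cis) or
            # inconsistent transmission -> not a compound het candidate
        if pairs:
            result[gene] = pairs
    logger.info("compound_het(%s): %d genes", proband, len(result))
    return result


def de_novo(
    variants: Iterable[AnnotatedVariant],
    trio: Trio | None,
    config: FilterConfig,
) -> list[AnnotatedVariant]:
    """Variants present in the proband and confirmed absent in both parents.

    Requires a complete trio; a proband without sequenced parents has no
    defined de novo set. A variant qualifies when the proband carries the
    alternate allele, both parents are called hom-ref (a missing parental
    genotype is conservative: not de novo), and all three samples reach
    ``min_depth``. Candidates that are additionally rare and disruptive are
    flagged ``rare_disruptive``.
    """
    if trio is None:
        raise ConfigurationError("de novo detection requires a complete trio")
    out: list[AnnotatedVariant] = []
    for v in variants:
        if not v.genotype(trio.proband).carries_alt:
            continue
        if v.genotype(trio.father) is not Genotype.HOM_REF:
            continue
        if v.genotype(trio.mother) is not Genotype.HOM_REF:
            continue
        if any(
            v.depth(s) < config.min_depth
            for s in (trio.proband, trio.father, trio.mother)
        ):
            continue
        if _is_rare(v, config.maf_disease) and is_disruptive(v, config):
            v.flags.add("rare_disruptive")
        out.append(v)
    logger.info("de_novo(%s): %d candidates", trio.proband, len(out))
    return sort_variants(out)


def comorbidity_filter(
    variants: Iterable[AnnotatedVariant],
    cohort: Cohort,
    config: FilterConfig,
) -> list[AnnotatedVariant]:
    """Looser screen for variants possibly underlying disease comorbidities.

    Keeps disruptive variants with maximum catalog frequency <=
    ``maf_comorbidity`` that are carried (het or hom-alt) by at least one
    affected proband and are not hom-alt in any healthy parent.
    """
    probands = [p for p in cohort.probands if cohort.sample(p).affected]
    parents = cohort.healthy_parents
    out = [
        v
        for v in variants
        if _is_rare(v, config.maf_comorbidity)
        and is_disruptive(v, config)
        and any(v.genotype(p).carries_alt for p in probands)
        and not any(v.genotype(parent) is Genotype.HOM_ALT for parent in parents)
    ]
    logger.info("comorbidity_filter: %d variants", len(out))
    return sort_variants(out)


def recurrent_genes(
    comorbidity_variants: Iterable[AnnotatedVariant],
    probands: Sequence[str],
    min_patients: int = 2,
) -> dict[str, set[str]]:
    """Genes whose qualifying variants are carried by >= ``min_patients`` probands.

    Recurrence counts distinct carrier probands, not alleles: one variant
    shared by two probands counts both, and a hom-alt carrier still counts
    once.
    """
    if min_patients < 1:
        raise ConfigurationError("min_patients must be >= 1")
    carriers: dict[str, set[str]] = {}
    for v in comorbidity_variants:
        if v.gene is None:
            continue
        for p in probands:
            if v.genotype(p).carries_alt:
                carriers.setdefault(v.gene, set()).add(p)
    return {g: s for g, s in sorted(carriers.items()) if len(s) >= min_patients}


def build_report(
    variants: Sequence[AnnotatedVariant],
    cohort: Cohort,
    config: FilterConfig,
) -> CandidateReport:
    """Run the full prioritization workflow over QC-passed variants."""
    report = CandidateReport()
    affected = [p for p in cohort.probands if cohort.sample(p).affected]
    for proband in affected:
        rh = rare_homozygous(variants, proband, cohort, config)
        report.rare_homozygous[proband] = rh
        report.disease_causing[proband] = disease_causing(rh, config)
        report.compound_het[proband] = compound_het(variants, proband, cohort, config)
        trio = cohort.trio_for(proband)
        if trio is not None:
            report.de_novo[proband] = de_novo(variants, trio, config)
    report.comorbidity_variants = comorbidity_filter(variants, cohort, config)
    report.recurrent_genes = recurrent_genes(report.comorbidity_variants, affected)
    return report


def write_candidate_report(report: CandidateReport, path: str | Path) -> None:
    """Write a candidate report as deterministic TSV (sorted by chrom, pos, alt).

    Identical reports produce byte-identical files; an empty report yields a
    header-only file.
    """
    rows: list[tuple] = []
    for proband, lst in report.rare_homozygous.items():
        for v in lst:
            rows.append(("rare_homozygous", proband, v))
    for proband, lst in report.disease_causing.items():
        for v in lst:
            rows.append(("disease_causing", proband, v))
    for proband, genes in report.compound_het.items():
        for gene, pairs in genes.items():
            for pair in pairs:
                for v in (pair.variant_a, pair.variant_b):
                    rows.append((f"compound_het:{pair.phase}", proband, v))
    for proband, lst in report.de_novo.items():
        for v in lst:
            rows.append(("de_novo", proband, v))
    for v in report.comorbidity_variants:
        carriers = ",".join(sorted(s for s, gt in v.genotypes.items() if gt.carries_alt))
        rows.append(("comorbidity", carriers, v))

    header = ["category", "sample", "chrom", "pos", "ref", "alt", "gene",
              "effect", "max_freq", "cadd", "flags"]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        ordered = sorted(
            rows,
            key=lambda r: (r[0], r[1], r[2].chrom, r[2].pos, r[2].alt),
        )
        for category, sample, v in ordered:
            fh.write(
                "\t".join(
                    [
                        category,
                        sample,
                        v.chrom,
                        str(v.pos),
                        v.ref,
                        v.alt,
                        v.gene or ".",
                        v.effect_class.value,
                        repr(v.max_allele_freq()),
                        "." if v.cadd_phred is None else repr(v.cadd_phred),
                        ",".join(sorted(v.flags)) or ".",
                    ]
                )
                + "\n"
            )
        for gene, probands in sorted(report.recurrent_genes.items()):
            fh.write(
                "\t".join(
                    ["recurrent_gene", ",".join(sorted(probands)), ".", "0", ".", ".",
                     gene, ".", ".", ".", "."]
                )
                + "\n"
            )
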