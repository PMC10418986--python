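"""Core data model: genotypes, annotated variants, cohorts, filter thresholds.

Coordinates are 1-based and fully closed throughout (VCF convention); every
interval routine in the package documents and assumes this.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping


class Genotype(enum.Enum):
    """Diploid genotype state relative to a single alternate allele.

    ``MISSING`` (uncalled, ``./.``) is distinct from ``HOM_REF``: an uncalled
    parent does not count as a confirmed reference-homozygote in any
    inheritance filter.
    """

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        """True for genotypes carrying at least one alternate allele."""
        return self in (Genotype.HET, Genotype.HOM_ALT)


class RegionClass(enum.Enum):
    PROTEIN_CODING_EXON = "protein_coding_exon"
    UTR5 = "utr5"
    UTR3 = "utr3"
    LNCRNA_EXON = "lncRNA_exon"
    INTRON = "intron"
    INTERGENIC = "intergenic"


class EffectClass(enum.Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    SPLICE_SITE = "splice_site"
    NONCODING = "noncoding"
    UNKNOWN = "unknown"


#: Effect classes with a radical (loss-of-function-like) impact on the gene
#: product, counted as disruptive regardless of any deleteriousness score.
RADICAL_EFFECTS = frozenset(
    {
        EffectClass.FRAMESHIFT_INDEL,
        EffectClass.SPLICE_SITE,
        EffectClass.STOPGAIN,
        EffectClass.STOPLOSS,
    }
)


@dataclass
class AnnotatedVariant:
    """A single bi-allelic variant with functional annotation and per-sample calls.

    Multi-allelic records are split upstream into one object per alternate
    allele; genotypes are recoded against the allele under consideration
    (a genotype carrying only *another* alternate allele becomes ``HOM_REF``
    here, with a ``recoded_other_alt:<sample>`` entry in :attr:`flags`).

    ``allele_freqs`` maps a population-catalog name to the allele frequency
    observed there; a catalog in which the allele was never seen is simply
    absent from the map, and an allele absent from every catalog is treated
    as novel (frequency 0) by :meth:`max_allele_freq`.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str | None = None
    region_class: RegionClass = RegionClass.INTERGENIC
    effect_class: EffectClass = EffectClass.UNKNOWN
    splice_distance: int | None = None
    cadd_phred: float | None = None
    allele_freqs: dict[str, float] = field(default_factory=dict)
    known: bool = False
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    depths: dict[str, int] = field(default_factory=dict)
    mappability: float | None = None
    assembly_concordant: bool = True
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if "," in self.alt:
            raise ValueError("AnnotatedVariant holds exactly one alt allele")
        for resource, freq in self.allele_freqs.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"frequency for {resource} outside [0,1]: {freq}")
        if self.splice_distance is not None and self.splice_distance < 0:
            raise ValueError("splice_distance must be >= 0 when set")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def max_allele_freq(self) -> float:
        """Maximum frequency across all catalogs; 0.0 for a novel allele."""
        return max(self.allele_freqs.values(), default=0.0)

    def genotype(self, sample: str) -> Genotype:
        return self.genotypes.get(sample, Genotype.MISSING)

    def depth(self, sample: str) -> int:
        return self.depths.get(sample, 0)


class Role(enum.Enum):
    PROBAND = "proband"
    FATHER = "father"
    MOTHER = "mother"
    UNRELATED_PROBAND = "unrelated_proband"


@dataclass(frozen=True)
class Sample:
    sample_id: str
    role: Role
    affected: bool
    sex: str | None = None


@dataclass(frozen=True)
class Trio:
    proband: str
    father: str
    mother: str


@dataclass
class Cohort:
    """Study samples with family structure.

    A cohort may mix a full trio (proband plus both parents) with singleton
    probands; inheritance filters that need parental genotypes apply only
    where a trio exists, while parental-exclusion clauses use every healthy
    parent present in the cohort.
    """

    samples: list[Sample]
    trios: list[Trio] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = {s.sample_id for s in self.samples}
        if len(ids) != len(self.samples):
            raise ValueError("duplicate sample ids in cohort")
        seen_probands: set[str] = set()
        for trio in self.trios:
            for member in (trio.proband, trio.father, trio.mother):
                if member not in ids:
                    raise ValueError(f"trio references unknown sample {member!r}")
            if trio.proband in seen_probands:
                raise ValueError(f"proband {trio.proband!r} appears in multiple trios")
            seen_probands.add(trio.proband)

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def probands(self) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.role in (Role.PROBAND, Role.UNRELATED_PROBAND)
        ]

    @property
    def affected_samples(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.affected]

    @property
    def healthy_parents(self) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.role in (Role.FATHER, Role.MOTHER) and not s.affected
        ]

    def trio_for(self, proband: str) -> Trio | None:
        for trio in self.trios:
            if trio.proband == proband:
                return trio
        return None


@dataclass
class FilterConfig:
    """Thresholds driving QC and prioritization.

    min_depth
        Minimum independent supporting reads per analyzed sample (reads).
    min_mappability
        Regions with mappability strictly below this are discarded; a score
        exactly at the threshold is retained.
    maf_disease
        Maximum catalog allele frequency for disease-candidate filters.
    maf_comorbidity
        Looser frequency ceiling used for the comorbidity screen.
    cadd_min
        PHRED-scaled CADD score a nonsynonymous variant must strictly exceed
        to count as deleterious.
    splice_report_window
        Descriptive window (bp) used when tallying intronic variants near
        exon-intron boundaries; not a filter.
    canonical_splice_window
        +/- window (bp) defining a canonical splice-site variant.
    flank
        Flank (bp) added around exons when measuring target coverage.
    """

    min_depth: int = 10
    min_mappability: float = 0.25
    maf_disease: float = 1e-5
    maf_comorbidity: float = 1e-4
    cadd_min: float = 20.0
    splice_report_window: int = 100
    canonical_splice_window: int = 2
    flank: int = 50

    def __post_init__(self) -> None:
        for name in (
            "min_depth",
            "min_mappability",
            "maf_disease",
            "maf_comorbidity",
            "cadd_min",
            "splice_report_window",
            "canonical_splice_window",
            "flank",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.maf_disease > self.maf_comorbidity:
            raise ValueError("maf_disease must be <= maf_comorbidity")


def sort_variants(variants: Iterable[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Deterministic (chrom, pos, ref, alt) ordering with natural chromosome order."""

    def chrom_key(chrom: str) -> tuple[int, str]:
        c = chrom.removeprefix("chr")
        return (0, f"{int(c):03d}") if c.isdigit() else (1, c)

    return sorted(variants, key=lambda v: (chrom_key(v.chrom), v.pos, v.ref, v.alt))
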