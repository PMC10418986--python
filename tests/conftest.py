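import pytest

from priovar.model import (
    AnnotatedVariant,
    Cohort,
    EffectClass,
    FilterConfig,
    Genotype,
    RegionClass,
    Role,
    Sample,
    Trio,
)


@pytest.fixture
def config() -> FilterConfig:
    return FilterConfig()


@pytest.fixture
def trio_cohort() -> Cohort:
    """One affected trio proband plus two affected singletons (5 samples)."""
    return Cohort(
        samples=[
            Sample("P1", Role.PROBAND, affected=True, sex="M"),
            Sample("F1", Role.FATHER, affected=False),
            Sample("M1", Role.MOTHER, affected=False),
            Sample("P2", Role.UNRELATED_PROBAND, affected=True),
            Sample("P3", Role.UNRELATED_PROBAND, affected=True),
        ],
        trios=[Trio("P1", "F1", "M1")],
    )


def make_variant(
    pos: int = 100,
    chrom: str = "chr1",
    gene: str = "GENE1",
    effect: EffectClass = EffectClass.NONCODING,
    region: RegionClass = RegionClass.INTERGENIC,
    freqs: dict | None = None,
    genotypes: dict | None = None,
    depth: int = 30,
    samples=("P1", "F1", "M1", "P2", "P3"),
    **kwargs,
) -> AnnotatedVariant:
    """Variant factory: sensible QC-passing defaults, hom_ref everywhere."""
    gts = {s: Genotype.HOM_REF for s in samples}
    gts.update(genotypes or {})
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="T",
        gene=gene,
        region_class=region,
        effect_class=effect,
        allele_freqs=freqs or {},
        genotypes=gts,
        depths={s: depth for s in samples},
        mappability=kwargs.pop("mappability", 1.0),
        **kwargs,
    )
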