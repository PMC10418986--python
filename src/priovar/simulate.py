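"""Seeded generators emulating a small rare-disease exome study.

The generators produce the three inputs the pipeline consumes — an
annotated multi-sample variant table with a realistic region/effect
composition, low-depth gene count libraries, and ranked gene-similarity
tables — together with a *truth ledger* recording every planted signal, so
recovery can be scored exactly.

The default cohort mirrors a three-patient design: one affected proband
sequenced as a full trio with two healthy parents, plus two affected
singleton probands (five exomes in total). Default mixture weights for
region and effect classes follow the composition typical of exome callsets
(roughly 55% exonic variants, of which half are UTR; ~98% of intronic
variants within 100 bp of an exon-intron boundary; a fraction of a percent
carrying radical effects).

Randomness: a single integer seed drives everything. Each generator derives
its own independent stream via ``numpy.random.SeedSequence([seed, k])``
with a fixed per-generator stream id (variants k=0, counts k=1, similarity
k=2), so the outputs of one generator never shift when another is
reconfigured. Fixed seed implies byte-identical output.

Hard-negative mode draws every background catalog frequency strictly above
the comorbidity threshold, so that *no* background variant can pass any
frequency-gated filter and specificity checks become exact rather than
probabilistic. Realistic frequency mixtures (novel / rare / common) are the
default otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .expression import GeneCountMatrix
from .model import (
    AnnotatedVariant,
    Cohort,
    EffectClass,
    Genotype,
    RegionClass,
    Role,
    Sample,
    Trio,
)

# region composition of a typical exome callset (UTR-extended capture)
DEFAULT_REGION_MIX: dict[str, float] = {
    "utr5": 0.115,
    "utr3": 0.172,
    "protein_coding_exon": 0.224,
    "lncRNA_exon": 0.043,
    "intron": 0.436,
    "intergenic": 0.010,
}

# effect composition of coding-exon variants; radical classes are rare
DEFAULT_CODING_EFFECT_MIX: dict[str, float] = {
    "synonymous": 0.499,
    "nonsynonymous": 0.4615,
    "inframe_indel": 0.0145,
    "frameshift_indel": 0.012,
    "stopgain": 0.008,
    "stoploss": 0.005,
}


@dataclass(frozen=True)
class PlantedScenario:
    """One causal signal to insert into the synthetic cohort.

    scenario is one of ``recessive_trio``, ``recessive_singleton``,
    ``compound_het``, ``de_novo``, ``recurrent_comorbidity``. ``probands``
    names the affected carrier(s); recurrence scenarios take two or more.
    """

    scenario: str
    gene: str
    probands: tuple[str, ...]


def default_cohort() -> Cohort:
    """One affected trio proband plus two affected singletons (5 exomes)."""
    return Cohort(
        samples=[
            Sample("P1", Role.PROBAND, affected=True, sex="M"),
            Sample("F1", Role.FATHER, affected=False, sex="M"),
            Sample("M1", Role.MOTHER, affected=False, sex="F"),
            Sample("P2", Role.UNRELATED_PROBAND, affected=True, sex="M"),
            Sample("P3", Role.UNRELATED_PROBAND, affected=True, sex="F"),
        ],
        trios=[Trio(proband="P1", father="F1", mother="M1")],
    )


def default_scenarios() -> list[PlantedScenario]:
    """One causal signal per filter chain, mirroring a three-patient study."""
    return [
        PlantedScenario("recessive_trio", "GRT1", ("P1",)),
        PlantedScenario("recessive_singleton", "GRS2", ("P2",)),
        PlantedScenario("recessive_singleton", "GRS3", ("P3",)),
        PlantedScenario("compound_het", "GCH1", ("P1",)),
        PlantedScenario("compound_het", "GCH2", ("P2",)),
        PlantedScenario("de_novo", "GDN1", ("P1",)),
        PlantedScenario("recurrent_comorbidity", "GRC1", ("P2", "P3")),
    ]


@dataclass
class SimulationConfig:
    """Everything the generators need, under one integer seed.

    Frequency model: a background variant is novel (absent from every
    catalog) with probability ``w_novel``, rare (log-uniform on
    ``rare_range``) with ``w_rare``, and common (log-uniform on
    ``common_range``) otherwise. ``hard_negative`` overrides this with
    frequencies drawn strictly above ``hard_negative_floor``.

    Depths are negative-binomial with per-sample mean ``depth_mean`` and
    shape ``depth_shape`` (variance = mean + mean^2/shape).
    """

    seed: int
    n_variants: int = 10_000
    region_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REGION_MIX))
    coding_effect_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CODING_EFFECT_MIX)
    )
    w_novel: float = 0.002
    w_rare: float = 0.10
    rare_range: tuple[float, float] = (1e-6, 1e-3)
    common_range: tuple[float, float] = (1e-3, 0.5)
    hard_negative: bool = False
    hard_negative_floor: float = 2e-4
    depth_mean: float = 60.0
    depth_shape: float = 10.0
    planted_scenarios: list[PlantedScenario] = field(default_factory=default_scenarios)
    # count-library model
    n_genes: int = 2_000
    library_size: int = 1_000_000
    n_controls: int = 2
    rate_range: tuple[float, float] = (2e-6, 1e-4)
    # planted fold changes sit on expressed genes (>= ~50 expected control
    # reads): genes below that are undetectable at these library sizes
    planted_rate_range: tuple[float, float] = (5e-5, 2e-4)
    planted_log2fc: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for mix in (self.region_mix, self.coding_effect_mix):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"mixture weights sum to {total}, not 1")
        if not 0 <= self.w_novel + self.w_rare <= 1:
            raise ConfigurationError("frequency-model weights out of range")


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, stream]))


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


_BASES = np.array(["A", "C", "G", "T"])


def _hwe_genotype(u: float, carrier_p: float) -> Genotype:
    """Hardy-Weinberg draw from a uniform variate and an allele frequency."""
    if u < carrier_p**2:
        return Genotype.HOM_ALT
    if u < carrier_p**2 + 2 * carrier_p * (1 - carrier_p):
        return Genotype.HET
    return Genotype.HOM_REF


def generate_cohort(
    cfg: SimulationConfig,
) -> tuple[list[AnnotatedVariant], Cohort, dict[str, list[dict]]]:
    """Simulate an annotated multi-sample variant table with planted signals.

    Returns the variant list, the cohort, and a truth ledger mapping each
    scenario name to the planted variant records
    (chrom/pos/ref/alt/gene/probands). Every planted variant is constructed
    to pass exactly its intended filter chain: high depth and mappability,
    assembly-concordant, disruptive effect, and a catalog frequency at or
    below the relevant threshold.
    """
    rng = _rng(cfg.seed, 0)
    cohort = default_cohort()
    samples = cohort.sample_ids
    for sc in cfg.planted_scenarios:
        for p in sc.probands:
            if p not in samples:
                raise ConfigurationError(f"scenario references unknown proband {p!r}")
        if sc.scenario in ("recessive_trio", "de_novo", "compound_het"):
            pass  # trio requirements checked during planting

    regions = list(cfg.region_mix)
    region_p = np.array([cfg.region_mix[r] for r in regions])
    effects = list(cfg.coding_effect_mix)
    effect_p = np.array([cfg.coding_effect_mix[e] for e in effects])

    n = cfg.n_variants
    n_samples = len(samples)
    chroms = rng.integers(1, 23, n)
    # unique, deterministic positions: a jittered arithmetic grid
    positions = rng.integers(1_000, 4_000, n) + np.arange(n) * 5_000
    region_draw = rng.choice(len(regions), size=n, p=region_p)
    effect_draw = rng.choice(len(effects), size=n, p=effect_p)
    near_boundary = rng.random(n) < 0.98  # splice-proximal intronic fraction
    near_dist = 1 + rng.integers(0, 100, n)
    far_dist = 101 + np.floor(rng.exponential(400.0, n)).astype(int)
    freq_u = rng.random(n)
    hard_freqs = _loguniform(rng, cfg.hard_negative_floor, 0.5, n)
    rare_freqs = _loguniform(rng, *cfg.rare_range, n)
    common_freqs = _loguniform(rng, *cfg.common_range, n)
    cadds = np.round(rng.uniform(0, 40, n), 2)
    gt_u = rng.random((n, n_samples))
    shape = cfg.depth_shape
    depth_draw = rng.negative_binomial(
        shape, shape / (shape + cfg.depth_mean), (n, n_samples)
    )
    mapp_low = rng.random(n) >= 0.95
    mapp_vals = rng.uniform(0.05, 1.0, n)
    discordant = rng.random(n) >= 0.999
    allele_draw = rng.integers(0, 4, n)
    alt_shift = rng.integers(1, 4, n)

    variants: list[AnnotatedVariant] = []
    for i in range(n):
        region = RegionClass(regions[region_draw[i]])
        splice_dist: int | None
        if region is RegionClass.PROTEIN_CODING_EXON:
            effect = EffectClass(effects[effect_draw[i]])
            splice_dist = 0
        elif region is RegionClass.INTRON:
            # ~98% of intronic variants fall near an exon-intron boundary
            splice_dist = int(near_dist[i]) if near_boundary[i] else int(far_dist[i])
            effect = (
                EffectClass.SPLICE_SITE if splice_dist <= 2 else EffectClass.NONCODING
            )
        else:
            effect = EffectClass.NONCODING
            splice_dist = None

        if cfg.hard_negative:
            freqs = {"catalogA": float(hard_freqs[i])}
        elif freq_u[i] < cfg.w_novel:
            freqs = {}
        elif freq_u[i] < cfg.w_novel + cfg.w_rare:
            freqs = {"catalogA": float(rare_freqs[i])}
        else:
            freq = float(common_freqs[i])
            freqs = {"catalogA": freq, "catalogB": min(1.0, freq * 1.1)}
        carrier_p = min(0.5, max(freqs.values(), default=1e-4))
        variants.append(
            AnnotatedVariant(
                chrom=f"chr{chroms[i]}",
                pos=int(positions[i]),
                ref=str(_BASES[allele_draw[i]]),
                alt=str(_BASES[(allele_draw[i] + alt_shift[i]) % 4]),
                gene=f"BG{i % (n // 10) :05d}",
                region_class=region,
                effect_class=effect,
                splice_distance=splice_dist,
                cadd_phred=float(cadds[i])
                if effect is EffectClass.NONSYNONYMOUS
                else None,
                allele_freqs=freqs,
                known=bool(freqs),
                genotypes={
                    s: _hwe_genotype(gt_u[i, j], carrier_p)
                    for j, s in enumerate(samples)
                },
                depths={s: int(depth_draw[i, j]) for j, s in enumerate(samples)},
                mappability=float(mapp_vals[i]) if mapp_low[i] else 1.0,
                assembly_concordant=not bool(discordant[i]),
            )
        )

    # --- planted signals -------------------------------------------------
    ledger: dict[str, list[dict]] = {}
    plant_pos = iter(range(60_000_000, 60_000_000 + 10_000, 7))

    def base_variant(gene: str, effect: EffectClass, freqs: dict[str, float],
                     genotypes: dict[str, Genotype]) -> AnnotatedVariant:
        gts = {s: Genotype.HOM_REF for s in samples}
        gts.update(genotypes)
        pos = next(plant_pos)
        ref, alt = ("G", "A")
        return AnnotatedVariant(
            chrom="chr21",
            pos=pos,
            ref=ref,
            alt=alt,
            gene=gene,
            region_class=RegionClass.PROTEIN_CODING_EXON
            if effect is not EffectClass.SPLICE_SITE
            else RegionClass.INTRON,
            effect_class=effect,
            splice_distance=2 if effect is EffectClass.SPLICE_SITE else 0,
            cadd_phred=35.0 if effect is EffectClass.NONSYNONYMOUS else None,
            allele_freqs=freqs,
            known=bool(freqs),
            genotypes=gts,
            depths={s: 40 for s in samples},
            mappability=1.0,
            assembly_concordant=True,
        )

    def record(sc: PlantedScenario, v: AnnotatedVariant) -> None:
        ledger.setdefault(sc.scenario, []).append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": sc.gene,
                "probands": list(sc.probands),
            }
        )

    disruptive_effects = [
        EffectClass.SPLICE_SITE,
        EffectClass.STOPGAIN,
        EffectClass.FRAMESHIFT_INDEL,
        EffectClass.NONSYNONYMOUS,  # paired with CADD 35 in base_variant
    ]
    for k, sc in enumerate(cfg.planted_scenarios):
        effect = disruptive_effects[k % len(disruptive_effects)]
        rare_freq: dict[str, float] = {} if k % 2 == 0 else {"catalogA": 1e-6}
        if sc.scenario == "recessive_trio":
            (proband,) = sc.probands
            trio = cohort.trio_for(proband)
            if trio is None:
                raise ConfigurationError(
                    f"recessive_trio scenario for {proband!r} needs a trio"
                )
            v = base_variant(
                sc.gene, effect, rare_freq,
                {proband: Genotype.HOM_ALT, trio.father: Genotype.HET,
                 trio.mother: Genotype.HET},
            )
            variants.append(v)
            record(sc, v)
        elif sc.scenario == "recessive_singleton":
            (proband,) = sc.probands
            v = base_variant(sc.gene, effect, rare_freq, {proband: Genotype.HOM_ALT})
            variants.append(v)
            record(sc, v)
        elif sc.scenario == "compound_het":
            (proband,) = sc.probands
            trio = cohort.trio_for(proband)
            gts_a = {proband: Genotype.HET}
            gts_b = {proband: Genotype.HET}
            if trio is not None:  # in trans: one allele from each parent
                gts_a[trio.father] = Genotype.HET
                gts_b[trio.mother] = Genotype.HET
            for gts in (gts_a, gts_b):
                v = base_variant(sc.gene, effect, rare_freq, gts)
                variants.append(v)
                record(sc, v)
        elif sc.scenario == "de_novo":
            (proband,) = sc.probands
            if cohort.trio_for(proband) is None:
                raise ConfigurationError(
                    f"de_novo scenario for {proband!r} needs a trio"
                )
            v = base_variant(sc.gene, effect, rare_freq, {proband: Genotype.HET})
            variants.append(v)
            record(sc, v)
        elif sc.scenario == "recurrent_comorbidity":
            if len(sc.probands) < 2:
                raise ConfigurationError("recurrent_comorbidity needs >= 2 probands")
            for proband in sc.probands:
                v = base_variant(
                    sc.gene, effect, {"catalogA": 5e-5}, {proband: Genotype.HET}
                )
                variants.append(v)
                record(sc, v)
        else:
            raise ConfigurationError(f"unknown scenario {sc.scenario!r}")

    return variants, cohort, ledger


def generate_counts(
    cfg: SimulationConfig,
) -> tuple[GeneCountMatrix, dict[str, float]]:
    """Simulate low-depth count libraries with planted fold changes.

    Counts are Poisson(rate_g * library_size); a planted gene's patient
    rate is multiplied by 2^log2fc. Returns the matrix and a truth ledger
    mapping planted gene -> log2fc.
    """
    rng = _rng(cfg.seed, 1)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    planted = dict(cfg.planted_log2fc)
    unknown = set(planted) - set(genes)
    if unknown:
        raise ConfigurationError(f"planted genes not in matrix: {sorted(unknown)}")
    rates = _loguniform(rng, *cfg.rate_range, cfg.n_genes)
    planted_rates = _loguniform(rng, *cfg.planted_rate_range, cfg.n_genes)
    for i, g in enumerate(genes):
        if g in planted:
            rates[i] = planted_rates[i]
    if np.any(rates < 0):
        raise InputError("negative expression rate")
    samples = ["patient1"] + [f"control{i+1}" for i in range(cfg.n_controls)]
    groups = {s: ("patient" if s == "patient1" else "control") for s in samples}
    lib = {s: cfg.library_size for s in samples}
    counts = {}
    for s in samples:
        mult = np.array(
            [2.0 ** planted.get(g, 0.0) if groups[s] == "patient" else 1.0 for g in genes]
        )
        counts[s] = rng.poisson(rates * mult * lib[s])
    matrix = GeneCountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene")),
        library_sizes=lib,
        groups=groups,
    )
    return matrix, planted


def generate_similarity_tables(
    n_genes: int, n_shared: int, n: int = 100, seed: int = 0
) -> dict[str, pd.DataFrame]:
    """Two ranked similarity tables whose top-``n`` sets share exactly ``n_shared`` genes.

    Each table is keyed by its seed gene (``SEED1``/``SEED2``) and contains
    ``n_genes`` rows of (gene, score) with strictly decreasing scores, so
    top-n membership is unambiguous.
    """
    if not 0 <= n_shared <= n:
        raise InputError("need 0 <= n_shared <= n")
    needed = 2 * n - n_shared
    if n_genes < needed:
        raise InputError(
            f"n_genes={n_genes} cannot host two top-{n} lists sharing {n_shared}"
        )
    rng = _rng(seed, 2)
    pool = [f"SIM{i:05d}" for i in range(n_genes)]
    rng.shuffle(pool)
    shared = pool[:n_shared]
    only1 = pool[n_shared : n_shared + (n - n_shared)]
    only2 = pool[n_shared + (n - n_shared) : needed]
    rest = pool[needed:]

    def table(top_unique: list[str]) -> pd.DataFrame:
        top = shared + top_unique
        rng.shuffle(top)
        ordered = top + rest
        scores = np.round(np.linspace(0.99, 0.01, len(ordered)), 6)
        return pd.DataFrame({"gene": ordered, "score": scores})

    return {"SEED1": table(only1), "SEED2": table(only2)}


def write_similarity_tables(tables: dict[str, pd.DataFrame], path) -> None:
    """Write seed-keyed similarity tables as 3-column TSV (seed, gene, score)."""
    with open(path, "w") as fh:
        fh.write("#seed\tgene\tscore\n")
        for seed in sorted(tables):
            for row in tables[seed].itertuples(index=False):
                fh.write(f"{seed}\t{row.gene}\t{row.score}\n")
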