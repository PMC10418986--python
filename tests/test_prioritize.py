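"""Inheritance-model filtering: rare homozygous, compound het, de novo,
comorbidity and recurrence."""

import pytest

from conftest import make_variant
from priovar.errors import ConfigurationError
from priovar.model import (
    Cohort,
    EffectClass,
    FilterConfig,
    Genotype,
    Role,
    Sample,
    Trio,
)
from priovar.prioritize import (
    comorbidity_filter,
    compound_het,
    de_novo,
    disease_causing,
    rare_homozygous,
    recurrent_genes,
)


def hom_in(proband, **extra):
    gts = {proband: Genotype.HOM_ALT}
    gts.update(extra)
    return gts


class TestRareHomozygous:
    def test_novel_hom_variant_with_het_parents_is_retained(self, trio_cohort, config):
        # the classic recessive trio configuration: hom in the affected
        # child, het in both healthy parents, absent from all catalogs
        v = make_variant(
            effect=EffectClass.SPLICE_SITE,
            genotypes=hom_in("P1", F1=Genotype.HET, M1=Genotype.HET),
        )
        assert rare_homozygous([v], "P1", trio_cohort, config) == [v]

    def test_parent_homozygosity_excludes(self, trio_cohort, config):
        v = make_variant(genotypes=hom_in("P1", F1=Genotype.HOM_ALT))
        assert rare_homozygous([v], "P1", trio_cohort, config) == []

    def test_parental_exclusion_applies_to_singleton_probands_too(
        self, trio_cohort, config
    ):
        # the only sequenced parents in the cohort veto candidates of every
        # affected proband, related or not
        v = make_variant(genotypes=hom_in("P2", F1=Genotype.HOM_ALT))
        assert rare_homozygous([v], "P2", trio_cohort, config) == []

    def test_frequency_threshold_is_resource_maximum(self, trio_cohort, config):
        v = make_variant(
            freqs={"gnomAD": 3.19e-5, "1000G": 1e-6},
            genotypes=hom_in("P1"),
        )
        # 3.19e-5 exceeds the disease threshold (1e-5) ...
        assert rare_homozygous([v], "P1", trio_cohort, config) == []
        # ... but is eligible under the looser comorbidity ceiling (1e-4)
        loose = FilterConfig(maf_disease=1e-4)
        assert rare_homozygous([v], "P1", trio_cohort, loose) == [v]

    def test_missing_parent_genotype_retains_with_flag(self, trio_cohort, config):
        v = make_variant(genotypes=hom_in("P1", F1=Genotype.MISSING))
        (kept,) = rare_homozygous([v], "P1", trio_cohort, config)
        assert "parent_missing" in kept.flags

    def test_het_proband_not_a_candidate(self, trio_cohort, config):
        v = make_variant(genotypes={"P1": Genotype.HET})
        assert rare_homozygous([v], "P1", trio_cohort, config) == []

    def test_unknown_proband_rejected(self, trio_cohort, config):
        with pytest.raises(ConfigurationError):
            rare_homozygous([], "NOPE", trio_cohort, config)

    def test_adding_parents_never_adds_candidates(self, config):
        """Trio effect: parental genotypes only ever remove candidates."""
        singleton = Cohort(samples=[Sample("P1", Role.PROBAND, True)])
        trio = Cohort(
            samples=[
                Sample("P1", Role.PROBAND, True),
                Sample("F1", Role.FATHER, False),
                Sample("M1", Role.MOTHER, False),
            ],
            trios=[Trio("P1", "F1", "M1")],
        )
        variants = [
            make_variant(pos=1, genotypes=hom_in("P1", F1=Genotype.HET, M1=Genotype.HET)),
            make_variant(pos=2, genotypes=hom_in("P1", F1=Genotype.HOM_ALT)),
            make_variant(pos=3, genotypes=hom_in("P1", M1=Genotype.HOM_ALT)),
            make_variant(pos=4, genotypes=hom_in("P1")),
        ]
        solo = {v.pos for v in rare_homozygous(variants, "P1", singleton, config)}
        with_parents = {v.pos for v in rare_homozygous(variants, "P1", trio, config)}
        assert with_parents <= solo
        assert solo == {1, 2, 3, 4} and with_parents == {1, 4}

    def test_raising_maf_threshold_never_shrinks_list(self, trio_cohort, config):
        variants = [
            make_variant(pos=p, freqs={"a": f}, genotypes=hom_in("P1"))
            for p, f in [(1, 0.0), (2, 5e-6), (3, 5e-5), (4, 5e-4)]
        ]
        sizes = [
            len(rare_homozygous(variants, "P1", trio_cohort,
                                FilterConfig(maf_disease=m, maf_comorbidity=1.0)))
            for m in (1e-6, 1e-5, 1e-4, 1e-3)
        ]
        assert sizes == sorted(sizes) == [1, 2, 3, 4]


class TestDiseaseCausing:
    def test_disruptive_subset_and_nesting(self, trio_cohort, config):
        splice_hom = make_variant(
            pos=1, effect=EffectClass.SPLICE_SITE, genotypes=hom_in("P1")
        )
        silent_hom = make_variant(
            pos=2, effect=EffectClass.SYNONYMOUS, genotypes=hom_in("P1")
        )
        rh = rare_homozygous([splice_hom, silent_hom], "P1", trio_cohort, config)
        dc = disease_causing(rh, config)
        assert dc == [splice_hom]
        assert set(v.key for v in dc) <= set(v.key for v in rh)

    def test_independent_per_variant_predicate_agrees(self, trio_cohort, config):
        # oracle: re-evaluate the printed predicate clause by clause
        effects = [
            EffectClass.FRAMESHIFT_INDEL, EffectClass.SYNONYMOUS,
            EffectClass.STOPGAIN, EffectClass.NONCODING, EffectClass.SPLICE_SITE,
            EffectClass.SYNONYMOUS, EffectClass.NONCODING,
            EffectClass.SYNONYMOUS, EffectClass.NONCODING, EffectClass.SYNONYMOUS,
        ]
        variants = [
            make_variant(pos=i + 1, effect=e, genotypes=hom_in("P1"))
            for i, e in enumerate(effects)
        ]
        rh = rare_homozygous(variants, "P1", trio_cohort, config)
        expected = {
            v.pos
            for v in variants
            if v.effect_class.value in
            ("frameshift_indel", "splice_site", "stopgain", "stoploss")
        }
        assert {v.pos for v in disease_causing(rh, config)} == expected == {1, 3, 5}


class TestCompoundHet:
    def two_hets(self, proband, gene="GENE1", extra_a=None, extra_b=None):
        a = make_variant(
            pos=10, gene=gene, effect=EffectClass.FRAMESHIFT_INDEL,
            genotypes={proband: Genotype.HET, **(extra_a or {})},
        )
        b = make_variant(
            pos=20, gene=gene, effect=EffectClass.NONSYNONYMOUS, cadd_phred=30.0,
            genotypes={proband: Genotype.HET, **(extra_b or {})},
        )
        return a, b

    def test_singleton_pair_reported_phase_unknown(self, trio_cohort, config):
        a, b = self.two_hets("P2")
        result = compound_het([a, b], "P2", trio_cohort, config)
        assert list(result) == ["GENE1"]
        (pair,) = result["GENE1"]
        assert pair.phase == "phase_unknown"

    def test_trio_trans_pair_is_phase_confirmed(self, trio_cohort, config):
        a, b = self.two_hets(
            "P1", extra_a={"F1": Genotype.HET}, extra_b={"M1": Genotype.HET}
        )
        result = compound_het([a, b], "P1", trio_cohort, config)
        (pair,) = result["GENE1"]
        assert pair.phase == "phase_confirmed"

    def test_cis_configuration_excluded(self, trio_cohort, config):
        # both variants inherited from the mother: same haplotype
        a, b = self.two_hets(
            "P1", extra_a={"M1": Genotype.HET}, extra_b={"M1": Genotype.HET}
        )
        assert compound_het([a, b], "P1", trio_cohort, config) == {}

    def test_single_variant_gene_not_reported(self, trio_cohort, config):
        a, _ = self.two_hets("P2")
        assert compound_het([a], "P2", trio_cohort, config) == {}

    def test_non_disruptive_or_common_variants_ignored(self, trio_cohort, config):
        a, b = self.two_hets("P2")
        b.effect_class = EffectClass.SYNONYMOUS
        assert compound_het([a, b], "P2", trio_cohort, config) == {}
        a2, b2 = self.two_hets("P2")
        b2.allele_freqs = {"gnomAD": 1e-3}
        assert compound_het([a2, b2], "P2", trio_cohort, config) == {}


class TestDeNovo:
    def test_definition(self, trio_cohort, config):
        trio = trio_cohort.trios[0]
        v = make_variant(genotypes={"P1": Genotype.HET})
        assert de_novo([v], trio, config) == [v]

    def test_missing_parent_genotype_is_conservative(self, trio_cohort, config):
        trio = trio_cohort.trios[0]
        v = make_variant(genotypes={"P1": Genotype.HET, "M1": Genotype.MISSING})
        assert de_novo([v], trio, config) == []

    def test_low_depth_member_excludes(self, trio_cohort, config):
        trio = trio_cohort.trios[0]
        v = make_variant(genotypes={"P1": Genotype.HET})
        v.depths["F1"] = 9
        assert de_novo([v], trio, config) == []

    def test_incomplete_trio_is_configuration_error(self, config):
        with pytest.raises(ConfigurationError):
            de_novo([], None, config)

    def test_rare_disruptive_candidates_flagged(self, trio_cohort, config):
        trio = trio_cohort.trios[0]
        lof = make_variant(
            pos=1, effect=EffectClass.STOPGAIN, genotypes={"P1": Genotype.HET}
        )
        common = make_variant(
            pos=2, effect=EffectClass.STOPGAIN, freqs={"a": 0.01},
            genotypes={"P1": Genotype.HET},
        )
        result = de_novo([lof, common], trio, config)
        assert len(result) == 2
        assert "rare_disruptive" in lof.flags
        assert "rare_disruptive" not in common.flags


class TestComorbidityAndRecurrence:
    def test_printed_clauses(self, trio_cohort, config):
        keep = make_variant(
            pos=1, effect=EffectClass.STOPGAIN, freqs={"a": 5e-5},
            genotypes={"P2": Genotype.HET},
        )
        parent_hom = make_variant(
            pos=2, effect=EffectClass.STOPGAIN, freqs={"a": 5e-5},
            genotypes={"P1": Genotype.HET, "F1": Genotype.HOM_ALT},
        )
        not_disruptive = make_variant(
            pos=3, effect=EffectClass.SYNONYMOUS, freqs={"a": 1e-6},
            genotypes={"P2": Genotype.HET},
        )
        too_common = make_variant(
            pos=4, effect=EffectClass.STOPGAIN, freqs={"a": 5e-4},
            genotypes={"P2": Genotype.HET},
        )
        no_carrier = make_variant(pos=5, effect=EffectClass.STOPGAIN, freqs={"a": 5e-5})
        result = comorbidity_filter(
            [keep, parent_hom, not_disruptive, too_common, no_carrier],
            trio_cohort, config,
        )
        assert result == [keep]

    def test_recurrence_counts_probands_not_alleles(self):
        shared = make_variant(
            pos=1, gene="REC1",
            genotypes={"P2": Genotype.HET, "P3": Genotype.HOM_ALT},
        )
        private = make_variant(pos=2, gene="SOLO", genotypes={"P3": Genotype.HET})
        trio_gene = [
            make_variant(pos=3 + i, gene="REC2", genotypes={p: Genotype.HET})
            for i, p in enumerate(["P1", "P2", "P3"])
        ]
        result = recurrent_genes(
            [shared, private, *trio_gene], ["P1", "P2", "P3"], min_patients=2
        )
        assert result == {"REC1": {"P2", "P3"}, "REC2": {"P1", "P2", "P3"}}

    def test_min_patients_validation(self):
        with pytest.raises(ConfigurationError):
            recurrent_genes([], [], min_patients=0)
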