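"""Fisher-exact DE, BH correction, enrichment, intersections, qPCR."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bh_rejections_oracle, bh_step_up_oracle, fisher_two_sided_oracle
from priovar.errors import InputError
from priovar.expression import (
    DEConfig,
    GeneCountMatrix,
    bh_adjust,
    call_de_genes,
    ddct_relative_expression,
    enrichment_test,
    fisher_gene_test,
    intersect_with_de,
    log2_fold_change,
    top_n_intersection,
    ttest_two_tailed,
)


class TestFisherGeneTest:
    def test_empty_margins_give_one(self):
        assert fisher_gene_test(0, 1000, 0, 1000) == 1.0

    def test_enumeration_example(self):
        # [[3,7],[1,9]]: margins 10/10 and 4/16 enumerated by hand
        p = fisher_gene_test(3, 10, 1, 10)
        assert p == pytest.approx(0.582, abs=5e-4)
        assert p == pytest.approx(fisher_two_sided_oracle(3, 7, 1, 9), rel=1e-7)

    def test_row_swap_symmetry(self):
        assert fisher_gene_test(3, 10, 1, 10) == pytest.approx(
            fisher_gene_test(1, 10, 3, 10), rel=1e-12
        )

    def test_count_above_total_rejected(self):
        with pytest.raises(InputError):
            fisher_gene_test(11, 10, 0, 10)

    @settings(derandomize=True, max_examples=60)
    @given(
        n1=st.integers(1, 50), n2=st.integers(1, 50),
        f1=st.floats(0, 1), f2=st.floats(0, 1),
    )
    def test_agrees_with_exact_enumeration(self, n1, n2, f1, f2):
        a, c = round(n1 * f1), round(n2 * f2)
        assert fisher_gene_test(a, n1, c, n2) == pytest.approx(
            fisher_two_sided_oracle(a, n1 - a, c, n2 - c), rel=1e-7
        )


class TestLog2FoldChange:
    def test_equal_rates_zero(self):
        assert log2_fold_change(50, 1000, 50, 1000) == 0.0
        # with no pseudocount distortion, scaled margins are also exact
        assert log2_fold_change(50, 1000, 100, 2000, pseudocount=0) == 0.0

    def test_rate_ratio_1_5_gives_0_585(self):
        lfc = log2_fold_change(30, 1000, 20, 1000, pseudocount=0)
        assert round(lfc, 3) == 0.585

    def test_closed_form_ratio_three(self):
        lfc = log2_fold_change(30, 10**6, 10, 10**6, pseudocount=0)
        assert lfc == pytest.approx(math.log2(3))

    def test_zero_count_with_zero_pseudocount_rejected(self):
        with pytest.raises(InputError):
            log2_fold_change(0, 1000, 5, 1000, pseudocount=0)

    @settings(derandomize=True, max_examples=50)
    @given(
        cp=st.integers(0, 500), cc=st.integers(0, 500),
        np_=st.integers(500, 10**6), nc=st.integers(500, 10**6),
    )
    def test_antisymmetric_under_group_swap(self, cp, cc, np_, nc):
        fwd = log2_fold_change(cp, np_, cc, nc)
        rev = log2_fold_change(cc, nc, cp, np_)
        assert fwd == pytest.approx(-rev, abs=1e-12)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p_in,expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.05, 0.5], [0.015, 0.075, 0.5]),
        ],
    )
    def test_step_up_examples(self, p_in, expected):
        assert bh_adjust(p_in) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60)
    )
    def test_matches_direct_step_up_and_bounds(self, p_values):
        adjusted = bh_adjust(p_values)
        oracle = bh_step_up_oracle(p_values)
        assert adjusted == pytest.approx([min(1.0, x) for x in oracle], rel=1e-12)
        assert np.all(adjusted >= np.asarray(p_values) - 1e-15)
        assert np.all(adjusted <= 1.0)
        # the {p_adj <= alpha} set equals the classic step-up rejection set
        for alpha in (0.01, 0.05, 0.2):
            rejected = {i for i, q in enumerate(adjusted) if q <= alpha}
            assert rejected == bh_rejections_oracle(list(p_values), alpha)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=40))
    def test_order_preserving(self, p_values):
        adjusted = bh_adjust(p_values)
        order = np.argsort(p_values, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-15)


def matrix_from_counts(counts: dict, lib: int = 10**6) -> GeneCountMatrix:
    df = pd.DataFrame(counts, index=[f"G{i}" for i in range(len(next(iter(counts.values()))))])
    groups = {s: ("patient" if s.startswith("p") else "control") for s in counts}
    return GeneCountMatrix(df, {s: lib for s in counts}, groups)


class TestCallDeGenes:
    def test_identical_patient_and_pooled_controls_yield_nothing(self):
        counts = {"p1": [10, 20, 30], "c1": [10, 20, 30], "c2": [10, 20, 30]}
        results = call_de_genes(matrix_from_counts(counts))
        assert all(not r.significant for r in results)
        assert all(r.log2fc == pytest.approx(0.0, abs=0.3) for r in results)

    def test_all_zero_genes_excluded_from_testing_and_family(self):
        counts = {"p1": [0, 1000], "c1": [0, 10], "c2": [0, 10]}
        results = call_de_genes(matrix_from_counts(counts))
        assert [r.gene for r in results] == ["G1"]

    def test_fold_change_gate_blocks_small_effects(self):
        # a huge but sub-1.5-fold shift is never significant
        counts = {"p1": [123_000], "c1": [100_000], "c2": [100_000]}
        (r,) = call_de_genes(matrix_from_counts(counts))
        assert r.p < 1e-10
        assert abs(r.log2fc) < 0.585
        assert not r.significant

    def test_direction_flips_with_groups(self):
        counts = {"p1": [400], "c1": [100], "c2": [100]}
        (up,) = call_de_genes(matrix_from_counts(counts))
        assert up.direction == "up" and up.significant
        flipped = {"p1": [100], "c1": [400], "c2": [400]}
        (down,) = call_de_genes(matrix_from_counts(flipped))
        assert down.direction == "down"
        assert down.log2fc == pytest.approx(-up.log2fc, abs=0.02)

    def test_zero_library_size_rejected(self):
        df = pd.DataFrame({"p1": [0], "c1": [0]}, index=["G0"])
        m = GeneCountMatrix(df, {"p1": 0, "c1": 10}, {"p1": "patient", "c1": "control"})
        with pytest.raises(InputError):
            call_de_genes(m)

    def test_vote_mode_requires_consensus(self):
        # significant against c1 but not against c2 -> no call in vote mode
        counts = {"p1": [400], "c1": [100], "c2": [390]}
        (pooled,) = call_de_genes(matrix_from_counts(counts), mode="pooled")
        (voted,) = call_de_genes(matrix_from_counts(counts), mode="vote")
        assert not voted.significant
        assert voted.p_adj >= pooled.p

    def test_library_size_smaller_than_count_rejected(self):
        df = pd.DataFrame({"p1": [100], "c1": [1]}, index=["G0"])
        with pytest.raises(InputError):
            GeneCountMatrix(df, {"p1": 10, "c1": 10},
                            {"p1": "patient", "c1": "control"})


class TestEnrichment:
    def test_hits_equal_universe_not_enriched(self):
        genes = {"a", "b", "c"}
        assert enrichment_test(genes, genes, genes) == 1.0

    def test_disjoint_hits_and_set_give_one(self):
        p = enrichment_test({"a", "b"}, {"c", "d"}, set("abcdefgh"))
        assert p == pytest.approx(1.0)

    def test_hypergeometric_tail_example(self):
        # 2 of 5 hits in a 10-gene set, universe 100:
        # P[X >= 2], X ~ Hypergeom(100, 10, 5) computed by direct summation
        universe = [f"u{i}" for i in range(100)]
        gene_set = universe[:10]
        hits = universe[8:13]  # overlap of 2
        expected = sum(
            math.comb(10, k) * math.comb(90, 5 - k) / math.comb(100, 5)
            for k in (2, 3, 4, 5)
        )
        assert enrichment_test(hits, gene_set, universe) == pytest.approx(expected)

    def test_empty_universe_rejected(self):
        with pytest.raises(InputError):
            enrichment_test(set(), set(), set())


class TestTopNIntersection:
    def table(self, genes):
        return pd.DataFrame(
            {"gene": genes, "score": np.linspace(1, 0.5, len(genes))}
        )

    def test_identical_tables_intersect_to_top_n(self):
        genes = [f"g{i}" for i in range(20)]
        tables = {"S1": self.table(genes), "S2": self.table(genes)}
        assert top_n_intersection(tables, n=10) == set(genes[:10])

    def test_disjoint_tables_intersect_empty(self):
        tables = {
            "S1": self.table([f"a{i}" for i in range(10)]),
            "S2": self.table([f"b{i}" for i in range(10)]),
        }
        assert top_n_intersection(tables, n=10) == set()

    def test_seed_genes_excluded_from_result(self):
        genes = ["S1", "S2", "x", "y"]
        tables = {"S1": self.table(genes), "S2": self.table(genes)}
        assert top_n_intersection(tables, n=4) == {"x", "y"}

    def test_tie_break_is_deterministic(self):
        tied = pd.DataFrame({"gene": ["b", "a", "c"], "score": [0.5, 0.5, 0.5]})
        tables = {"S1": tied, "S2": tied.iloc[::-1].reset_index(drop=True)}
        assert top_n_intersection(tables, n=2) == {"a", "b"}  # lexicographic

    def test_intersect_with_de_keeps_significant_only(self):
        from priovar.expression import DEResult

        de = [
            DEResult("RAF1", -0.79, 1e-4, 1e-3, "down", True),
            DEResult("CREBBP", -0.73, 1e-4, 1e-3, "down", True),
            DEResult("OTHER", 0.1, 0.9, 0.95, "up", False),
        ]
        assert intersect_with_de({"RAF1", "CREBBP", "OTHER", "ABSENT"}, de) == [
            "CREBBP", "RAF1",
        ]


class TestQpcr:
    def test_zero_ddct_means_unchanged(self):
        assert ddct_relative_expression(20.0, 15.0, 5.0) == pytest.approx(1.0)

    def test_minus_one_ddct_doubles(self):
        assert ddct_relative_expression(19.0, 15.0, 5.0) == pytest.approx(2.0)

    def test_identical_groups_give_p_one(self):
        assert ttest_two_tailed([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_matches_textbook_equal_variance_t(self):
        a, b = [5.1, 4.9, 5.3], [4.0, 4.2, 3.9]
        from scipy import stats

        assert ttest_two_tailed(a, b) == pytest.approx(
            stats.ttest_ind(a, b, equal_var=True).pvalue
        )

    def test_single_replicate_rejected(self):
        with pytest.raises(InputError):
            ttest_two_tailed([1.0], [1.0, 2.0])

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(InputError):
            ddct_relative_expression(float("nan"), 15.0, 5.0)


def test_de_config_validation():
    with pytest.raises(ValueError):
        DEConfig(alpha=0.0)
    with pytest.raises(ValueError):
        DEConfig(pseudocount=0.0)
    with pytest.raises(ValueError):
        DEConfig(lfc_min=-1.0)
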