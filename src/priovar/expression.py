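"""Count-based differential expression and downstream expression analyses.

The differential-expression model is the classic per-gene 2x2 contingency
test for low-depth count libraries: for each gene, the patient's read count
against its library size is compared with the pooled controls' count
against their pooled library size using a two-sided Fisher exact test;
p-values are corrected across genes with the Benjamini-Hochberg step-up,
and a gene is called significant when both the adjusted p-value and a
fold-change gate pass. The fold change is a library-size-normalized rate
ratio with an additive pseudocount:

    log2FC = log2( ((c_p + pc) / n_p) / ((c_c + pc) / n_c) )

The module also provides a one-sided over-representation (hypergeometric)
test for gene sets, the top-n intersection of ranked gene-similarity
tables, and 2^-ddCt relative expression with an equal-variance two-tailed
t test for qPCR data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class DEConfig:
    """Significance thresholds for differential-expression calls.

    lfc_min: minimum absolute log2 fold change (0.585 ~ fold change 1.5).
    alpha: ceiling on the BH-adjusted p-value.
    pseudocount: additive count offset stabilizing the fold change at zero
    counts.
    """

    lfc_min: float = 0.585
    alpha: float = 0.05
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class GeneCountMatrix:
    """Gene-by-sample read counts with library sizes and group labels.

    A library size may exceed the column sum (unassigned reads) but must be
    at least every single gene's count in that sample.
    """

    counts: pd.DataFrame  # genes x samples, non-negative integers
    library_sizes: dict[str, int]
    groups: dict[str, str]  # sample -> "patient" | "control"

    def __post_init__(self) -> None:
        for sample in self.counts.columns:
            if sample not in self.library_sizes:
                raise InputError(f"no library size for sample {sample!r}")
            if sample not in self.groups:
                raise InputError(f"no group for sample {sample!r}")
            if self.groups[sample] not in ("patient", "control"):
                raise InputError(f"bad group {self.groups[sample]!r}")
            col = self.counts[sample]
            if (col < 0).any():
                raise InputError(f"negative count in sample {sample!r}")
            if int(col.max()) > self.library_sizes[sample]:
                raise InputError(
                    f"library size of {sample!r} smaller than a gene count"
                )
        for group in ("patient", "control"):
            if not any(g == group for g in self.groups.values()):
                raise InputError(f"no sample in group {group!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    @classmethod
    def read_tsv(
        cls,
        path,
        library_sizes: dict[str, int],
        groups: dict[str, str],
    ) -> "GeneCountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=counts, library_sizes=library_sizes, groups=groups)

    def write_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene")


@dataclass
class DEResult:
    gene: str
    log2fc: float
    p: float
    p_adj: float
    direction: str  # "up" | "down"
    significant: bool


def _check_margin(c: int, n: int, label: str) -> None:
    if n <= 0:
        raise InputError(f"{label}: total must be > 0")
    if not 0 <= c <= n:
        raise InputError(f"{label}: count {c} outside [0, {n}]")


def fisher_gene_test(
    c_patient: int, n_patient: int, c_control: int, n_control: int
) -> float:
    """Two-sided Fisher exact p for one gene's counts against library sizes.

    The 2x2 table is ``[[c_p, n_p - c_p], [c_c, n_c - c_c]]``; two-sidedness
    sums all hypergeometric outcomes no more probable than the observed
    table.
    """
    _check_margin(c_patient, n_patient, "patient")
    _check_margin(c_control, n_control, "control")
    table = [
        [c_patient, n_patient - c_patient],
        [c_control, n_control - c_control],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def log2_fold_change(
    c_patient: int,
    n_patient: int,
    c_control: int,
    n_control: int,
    pseudocount: float = 0.5,
) -> float:
    """Signed log2 ratio of library-size-normalized rates (patient / control).

    Antisymmetric under swapping the groups. A zero pseudocount is allowed
    only when both counts are positive.
    """
    _check_margin(c_patient, n_patient, "patient")
    _check_margin(c_control, n_control, "control")
    if pseudocount <= 0 and (c_patient == 0 or c_control == 0):
        raise InputError("pseudocount must be > 0 when a count is zero")
    rate_p = (c_patient + pseudocount) / n_patient
    rate_c = (c_control + pseudocount) / n_control
    return math.log2(rate_p / rate_c)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j>=i}( p_(j) * m / j ) on the ascending order statistics,
    capped at 1. Monotone in the raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de_genes(
    matrix: GeneCountMatrix,
    config: DEConfig | None = None,
    mode: str = "pooled",
) -> list[DEResult]:
    """Per-gene Fisher + fold-change differential-expression calls.

    The patient group is compared against the controls pooled into a single
    pseudo-library (counts and library sizes summed); genes with zero counts
    in both groups are excluded from testing and from the BH family size.
    A gene is significant iff |log2FC| >= ``lfc_min`` and BH-adjusted
    p <= ``alpha``.

    ``mode="vote"`` instead tests the patient against each control library
    separately and requires the significance rule to hold in every
    comparison (the reported p/p_adj/log2FC are the least favorable:
    max p_adj, min |log2FC|).
    """
    config = config or DEConfig()
    patient_samples = matrix.samples_in("patient")
    control_samples = matrix.samples_in("control")
    n_p = sum(matrix.library_sizes[s] for s in patient_samples)
    if n_p <= 0 or any(matrix.library_sizes[s] <= 0 for s in control_samples):
        raise InputError("zero total library size in a group")
    c_p_all = matrix.counts[patient_samples].sum(axis=1)

    if mode == "pooled":
        n_c = sum(matrix.library_sizes[s] for s in control_samples)
        c_c_all = matrix.counts[control_samples].sum(axis=1)
        tested = [
            g for g in matrix.genes if c_p_all[g] + c_c_all[g] > 0
        ]
        p_raw = [
            fisher_gene_test(int(c_p_all[g]), n_p, int(c_c_all[g]), n_c)
            for g in tested
        ]
        lfc = {
            g: log2_fold_change(
                int(c_p_all[g]), n_p, int(c_c_all[g]), n_c, config.pseudocount
            )
            for g in tested
        }
        p_adj = bh_adjust(p_raw)
        results = []
        for g, p, q in zip(tested, p_raw, p_adj):
            results.append(
                DEResult(
                    gene=g,
                    log2fc=lfc[g],
                    p=p,
                    p_adj=float(q),
                    direction="up" if lfc[g] >= 0 else "down",
                    significant=bool(abs(lfc[g]) >= config.lfc_min and q <= config.alpha),
                )
            )
        logger.info(
            "DE: %d genes tested, %d significant",
            len(results), sum(r.significant for r in results),
        )
        return results

    if mode != "vote":
        raise InputError(f"unknown mode {mode!r}")
    per_control = {
        ctrl: call_de_genes(
            GeneCountMatrix(
                counts=matrix.counts[patient_samples + [ctrl]],
                library_sizes=matrix.library_sizes,
                groups={**{s: "patient" for s in patient_samples}, ctrl: "control"},
            ),
            config,
            mode="pooled",
        )
        for ctrl in control_samples
    }
    by_gene: dict[str, list[DEResult]] = {}
    for results in per_control.values():
        for r in results:
            by_gene.setdefault(r.gene, []).append(r)
    out = []
    for g, rs in by_gene.items():
        if len(rs) < len(control_samples):
            continue  # not testable against every control
        worst = max(rs, key=lambda r: r.p_adj)
        min_lfc = min(rs, key=lambda r: abs(r.log2fc))
        same_dir = len({r.direction for r in rs}) == 1
        out.append(
            DEResult(
                gene=g,
                log2fc=min_lfc.log2fc,
                p=max(r.p for r in rs),
                p_adj=worst.p_adj,
                direction=min_lfc.direction,
                significant=bool(same_dir and all(r.significant for r in rs)),
            )
        )
    return sorted(out, key=lambda r: r.gene)


def write_de_results(results: Sequence[DEResult], path) -> None:
    """DE results as TSV with a fixed column order, sorted by gene."""
    with open(path, "w") as fh:
        fh.write("#gene\tlog2fc\tp\tp_adj\tdirection\tsignificant\n")
        for r in sorted(results, key=lambda r: r.gene):
            fh.write(
                f"{r.gene}\t{r.log2fc!r}\t{r.p!r}\t{r.p_adj!r}\t"
                f"{r.direction}\t{int(r.significant)}\n"
            )


def enrichment_test(
    hit_genes: Iterable[str], gene_set: Iterable[str], universe: Iterable[str]
) -> float:
    """One-sided (over-representation) Fisher exact p for a gene set.

    Hypergeometric upper tail: probability of drawing at least the observed
    overlap when sampling ``len(hits)`` genes from the universe.
    """
    universe = set(universe)
    if not universe:
        raise InputError("empty universe")
    hits = set(hit_genes) & universe
    gene_set = set(gene_set) & universe
    overlap = len(hits & gene_set)
    # sf(k-1) = P[X >= k] for X ~ Hypergeom(M=|U|, n=|set|, N=|hits|)
    return float(
        stats.hypergeom.sf(overlap - 1, len(universe), len(gene_set), len(hits))
    )


def top_n_intersection(
    similarity_tables: Mapping[str, pd.DataFrame],
    seed_genes: Sequence[str] | None = None,
    n: int = 100,
) -> set[str]:
    """Intersection of the top-``n`` most similar genes across seed genes.

    Each table has columns ``gene`` and ``score``; rows are ranked by score
    descending with ties broken by gene symbol ascending. The seed genes
    themselves are excluded from the result. A table shorter than ``n``
    contributes all its rows (logged).
    """
    seed_genes = list(seed_genes) if seed_genes is not None else list(similarity_tables)
    tops: list[set[str]] = []
    for seed in seed_genes:
        table = similarity_tables[seed]
        if len(table) < n:
            logger.warning(
                "similarity table for %s has only %d rows (< %d)", seed, len(table), n
            )
        ranked = table.sort_values(
            ["score", "gene"], ascending=[False, True], kind="mergesort"
        )
        tops.append(set(ranked["gene"].head(n)))
    common = set.intersection(*tops) if tops else set()
    return common - set(seed_genes)


def intersect_with_de(
    common_genes: Iterable[str], de_results: Sequence[DEResult]
) -> list[str]:
    """Genes from ``common_genes`` that are significantly differentially expressed."""
    significant = {r.gene for r in de_results if r.significant}
    return sorted(set(common_genes) & significant)


def read_similarity_tables(path) -> dict[str, pd.DataFrame]:
    """Read a 3-column TSV (seed, gene, score) into one table per seed gene."""
    df = pd.read_csv(path, sep="\t", names=["seed", "gene", "score"], comment="#")
    return {seed: g[["gene", "score"]].reset_index(drop=True)
            for seed, g in df.groupby("seed")}


def ddct_relative_expression(
    ct_target: float | np.ndarray,
    ct_reference: float | np.ndarray,
    calibrator_dct_mean: float,
) -> float | np.ndarray:
    """Relative expression 2^-ddCt against a housekeeping gene and calibrator.

    dCt = Ct_target - Ct_reference per sample; ddCt = dCt - mean calibrator
    dCt. A ddCt of -1 doubles relative expression.
    """
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_target)) and np.all(np.isfinite(ct_reference))):
        raise InputError("Ct values must be finite")
    ddct = (ct_target - ct_reference) - calibrator_dct_mean
    result = np.power(2.0, -ddct)
    return float(result) if result.ndim == 0 else result


def ttest_two_tailed(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sample, two-tailed, equal-variance Student's t test p-value.

    Requires at least two replicates per group. Degenerate zero-variance
    input is resolved by the mean difference: identical means give p = 1,
    different means with zero pooled variance give p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("t test needs >= 2 replicates per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)
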