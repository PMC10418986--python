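# Methods

## Scope and model

`priovar` implements the downstream analysis of a small rare-disease
sequencing study: it starts from *annotated* variant calls (gene, region
and effect classes, deleteriousness scores, catalog allele frequencies,
per-sample genotypes and depths) and from gene-level read counts, and ends
with candidate-variant shortlists, descriptive callset summaries,
differential-expression calls and gene-list intersections. Read alignment,
variant calling, consequence annotation and score computation (CADD,
mappability) are upstream of this package and consumed as inputs.

The disease model is autosomal recessive with full penetrance: a causal
genotype is either a rare homozygous variant or a pair of rare, deleterious
heterozygous variants in trans in one gene. De novo dominant variants are
screened as an alternative hypothesis.

## Prioritization filters

All frequency clauses use the **maximum** allele frequency across catalogs;
a variant absent from every catalog is treated as novel (frequency 0),
which keeps never-before-seen alleles candidate-eligible.

- **QC** — a variant is analyzed only if it has ≥ `min_depth` (default 10)
  supporting reads in every *affected* sample, mappability ≥ 0.25 (only
  scores strictly below the threshold are discarded; a missing score is
  kept and flagged), and consistent mapping between reference assemblies.
  The depth rule is restricted to affected samples by default because a
  parent's locally thin coverage should not delete a proband candidate; a
  `strict_depth` switch extends it to all samples.
- **Rare homozygous** — max frequency ≤ `maf_disease` (default 1e-5),
  hom-alt in the proband, not hom-alt in *any* healthy parent present in
  the cohort. The parental exclusion is cohort-wide rather than per-trio:
  in a design where only one family's parents are sequenced they still
  inform the singleton probands. A parent with an uncalled genotype does
  not veto a candidate (the variant is flagged `parent_missing` instead),
  since a conservative veto would silently empty the candidate lists of
  probands with partly genotyped families.
- **Disease-causing** — the rare-homozygous subset with a radical effect
  (frameshift indel, splice-site, stop-gain/-loss) or a nonsynonymous
  change with CADD PHRED strictly > 20. A nonsynonymous variant without a
  CADD score is non-disruptive (logged): inventing a score would fabricate
  evidence.
- **Compound het** — heterozygous, rare, disruptive variants grouped by
  gene; ≥ 2 distinct variants report the gene. With a genotyped trio, only
  pairs with one variant carried by exactly the father and the other by
  exactly the mother survive (`phase_confirmed`); without parents the pair
  is `phase_unknown` — a deliberately permissive surrogate, since phase
  cannot be established from singleton exomes.
- **De novo** — proband carries the allele, both parents confirmed
  hom-ref, all three samples at ≥ `min_depth`. Undefined without a
  complete trio; a missing parental genotype is conservative (not de
  novo). Rare + disruptive candidates carry a `rare_disruptive` flag.
- **Comorbidity screen** — a looser pass (max frequency ≤ 1e-4,
  disruptive, carried by ≥ 1 affected proband, not hom-alt in a healthy
  parent) feeding the recurrence analysis, which reports genes whose
  qualifying variants are carried by ≥ 2 distinct probands (probands, not
  alleles, are counted).

"Splice-site variant" as an *effect class* means the canonical ±2 bp
window; the 100 bp window is only a descriptive report bucket for the
summary (how many intronic variants sit near a boundary), never a filter.
All interval math is 1-based fully closed; the intronic base adjacent to
an exon boundary is at splice distance 1. Standard 0-based half-open BED
input would be shifted on read; the TSV dialect used here is documented as
1-based closed.

## Summary conventions

Percentages are rounded half away from zero at the stated precision and
always accompanied by the raw ratio. The "disruptive" tally of the
descriptive summary counts the radical effect classes only, so the
splice / stop-frameshift partition is exact by construction; the
score-gated nonsynonymous variants belong to the prioritization filters,
not to the descriptive partition. With the category counts of the
five-exome callset used in the tests, the recomputed lncRNA share of
exonic variants is 7.69%; a truncated 7.6% sometimes appears in narrative
summaries of the same numbers — the package reports the recomputed value.

## Differential expression

Designed for low-depth libraries (order 10^6 reads) with one patient
library versus a small pool of controls — too few replicates for a
dispersion-based model, hence the classic proportion test:

- per gene, a two-sided Fisher exact test on
  `[[c_patient, n_patient − c_patient], [c_control, n_control − c_control]]`,
  where `n` is the library size (two-sidedness sums all hypergeometric
  outcomes no more probable than the observed table);
- Benjamini–Hochberg step-up across all tested genes (genes with zero
  counts in both groups are excluded from testing *and* from the family
  size m);
- significance requires both adjusted p ≤ 0.05 and
  |log2FC| ≥ 0.585 (fold change 1.5).

The fold change is a library-size-normalized rate ratio with an additive
pseudocount (default 0.5), `log2(((c_p+pc)/n_p)/((c_c+pc)/n_c))` — chosen
because it is antisymmetric under group swap and finite at zero counts;
the pseudocount is configurable. Controls are pooled into one
pseudo-library by default (summed counts and library sizes); a per-control
"vote" mode (significant against every control separately, consistent
direction) is available but off by default, because pooling is the
better-powered choice when controls are honest replicates.

Because Fisher's test conditions on discrete margins it is conservative:
on null simulations the p ≤ 0.05 fraction runs well below 0.05 (about
0.04 at these depths). The acceptance suite asserts only the upper bound
(nominal + 3 binomial SE).

Gene-set over-representation is a plain one-sided hypergeometric tail.
Proprietary enrichment variants (e.g. EASE-style jackknifed Fisher) are
deliberately not reproduced; their p-values are not comparable.

Top-n similarity-list intersection ranks by score descending with ties
broken lexicographically by gene symbol (documented so the top-n set is
reproducible), and excludes the seed genes themselves from the result.

qPCR relative expression is 2^−ΔΔCt with ΔCt = Ct_target − Ct_reference
(housekeeping gene) and ΔΔCt relative to the mean calibrator ΔCt; group
comparison uses the equal-variance two-tailed Student t test. The
degenerate zero-variance case is resolved by the mean difference (p = 1
when equal, p = 0 otherwise) rather than returning NaN.

## Synthetic data

The generators emulate the *shape* of the study inputs, not their biology:

- **Cohort**: one affected trio proband plus two affected singletons
  (five exomes), matching a design where only one family's parents were
  sequenced.
- **Variants** (default 10,000): region mix ≈ 29% UTR / 22% coding / 4%
  lncRNA / 44% intron, coding effects ≈ 50% synonymous / 46%
  nonsynonymous / ~4% radical, ~98% of intronic variants within 100 bp of
  a boundary — the composition typical of UTR-extended exome captures.
  Catalog frequencies follow a novel (0.2%) / rare (10%, log-uniform
  1e-6–1e-3) / common (log-uniform 1e-3–0.5) mixture; genotypes are
  Hardy–Weinberg draws at the catalog frequency; depths are
  negative-binomial (mean 60, shape 10); mappability is 1.0 for 95% of
  sites.
- **Planted signals**: one variant (or pair) per scenario, constructed to
  pass exactly its filter chain — e.g. the recessive-trio plant is
  hom-alt in the proband, het in both parents, novel or at 1e-6, with a
  radical effect and depth 40.
- **Hard-negative mode** draws every background frequency strictly above
  the comorbidity threshold (log-uniform 2e-4–0.5), making
  sensitivity/specificity checks exact: any background variant failing a
  frequency clause cannot leak through, so recovery = 100% with zero
  false positives is a *deterministic* property of the filters, not a
  lucky draw.
- **Counts** (default 2,000 genes, library 10^6): per-gene rates
  log-uniform 2e-6–1e-4; planted fold changes sit on expressed genes
  (rates 5e-5–2e-4, i.e. ≳50 expected control reads) because genes below
  that are physically undetectable at these depths — the planted-recovery
  property tests the calling rule, not the detection limit.
- **Similarity tables** are constructed so the two top-100 sets share an
  exact, requested number of genes, with strictly decreasing scores.

One integer seed drives everything through
`numpy.random.SeedSequence([seed, stream])` with a fixed stream id per
generator (variants 0, counts 1, similarity 2), so reconfiguring one
generator never shifts another's output; fixed seed gives byte-identical
files.

What passing these tests does **not** show: the generators have no LD, no
sequencing-error or strand artifacts, no shared haplotypes between
probands, no real gene models (splice distances are drawn, not computed
from exon structures), and independent Poisson counts without biological
overdispersion. Results on real data depend on annotation quality and on
the adequacy of the catalog frequencies, none of which the synthetic
cohort can probe.

## Numerical choices

- Fisher p-values come from the exact hypergeometric enumeration (scipy's
  implementation); the test suite cross-checks against an independent
  exact-rational enumeration oracle at relative tolerance 1e-7, including
  the tie gate.
- BH adjustment delegates to the standard step-up implementation and is
  cross-checked against a direct from-definition oracle, including
  equality of the rejection set {p_adj ≤ α} with the classic step-up
  rule.
- CADD gate is a strict inequality (score exactly 20 fails); mappability
  gate keeps the boundary (exactly 0.25 passes); frequency gates are ≤.
- Multi-allelic VCF records are split per alternate allele before any
  filtering; a genotype carrying only a *different* alternate allele is
  recoded hom-ref for the allele under consideration and flagged
  (`recoded_other_alt:<sample>`), because every downstream predicate is
  per-allele.
- Report writers sort by (chromosome in natural order, position, allele)
  and emit `repr` floats, so identical inputs give byte-identical files.

## Problem sizes

Defaults used throughout the tests and the reproduction script: 10,000
variants × 5 samples for the prioritization properties; 2,000 genes × 3
libraries of 10^6 reads, 20 null seeds, for the differential-expression
properties; 1,000-gene pools for the top-100 intersection fixture. These
sizes make every property exact or tightly bounded while keeping a full
run in minutes on one core.

## Known limitations

- Phase confirmation uses parental carriage only; read-backed phasing is
  out of scope, so a `phase_confirmed` pair can still be wrong under
  genotyping error.
- The comorbidity screen requires carriage in ≥ 1 affected proband; a
  screen defined purely on frequency + effect would also admit
  parent-only variants. The carrier requirement is this package's
  documented choice.
- No manual-curation stage: outputs are fully deterministic and end where
  expert review would begin.
- The DE test treats pooled controls as one library; true inter-control
  variability is invisible to it (the vote mode is a blunt guard, not a
  variance model).
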