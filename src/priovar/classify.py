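"""QC filters and functional classification of annotated variants.

All interval arithmetic here is 1-based, fully closed: an exon ``(s, e)``
contains the positions ``s..e`` inclusive, and the first intronic base next
to an exon boundary sits at distance 1 from it.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

from .errors import InputError
from .model import (
    RADICAL_EFFECTS,
    AnnotatedVariant,
    Cohort,
    EffectClass,
    FilterConfig,
    RegionClass,
)

logger = logging.getLogger(__name__)


def apply_qc(
    variants: Iterable[AnnotatedVariant],
    cohort: Cohort,
    config: FilterConfig,
    strict_depth: bool = False,
) -> list[AnnotatedVariant]:
    """Remove low-confidence calls before any prioritization.

    A variant is retained when (i) its supporting depth is at least
    ``config.min_depth`` in every affected sample (every cohort sample when
    ``strict_depth``; a missing depth counts as 0), (ii) its mappability is
    at least ``config.min_mappability`` — only scores strictly *below* the
    threshold are discarded, and a null score is retained with a
    ``mappability_unknown`` flag — and (iii) its call is concordant between
    reference assemblies. Per-rule removal counts are logged. The filter is
    idempotent.
    """
    checked = cohort.sample_ids if strict_depth else cohort.affected_samples
    removed = {"depth": 0, "mappability": 0, "assembly": 0}
    kept: list[AnnotatedVariant] = []
    for v in variants:
        if any(v.depth(s) < config.min_depth for s in checked):
            removed["depth"] += 1
            continue
        if v.mappability is None:
            v.flags.add("mappability_unknown")
        elif v.mappability < config.min_mappability:
            removed["mappability"] += 1
            continue
        if not v.assembly_concordant:
            removed["assembly"] += 1
            continue
        kept.append(v)
    logger.info(
        "QC: kept %d variants (removed %d low-depth, %d low-mappability, "
        "%d assembly-discordant)",
        len(kept), removed["depth"], removed["mappability"], removed["assembly"],
    )
    return kept


def splice_distance(
    variant_pos: int, exon_intervals: Sequence[tuple[int, int]]
) -> int | None:
    """Distance (bp) from a position to the nearest exon-intron boundary.

    ``exon_intervals`` are the sorted, non-overlapping 1-based closed exons
    of one transcript. Returns 0 for an exonic position, the minimum of the
    distances to the flanking exon end / exon start for an intronic one
    (the intronic base adjacent to an exon boundary is at distance 1), and
    None outside the transcript span.
    """
    if not exon_intervals:
        raise InputError("empty exon interval list")
    prev_end = None
    for start, end in exon_intervals:
        if start > end:
            raise InputError(f"exon ({start},{end}) has start > end")
        if prev_end is not None and start <= prev_end:
            raise InputError("exon intervals must be sorted and non-overlapping")
        prev_end = end
    if variant_pos < exon_intervals[0][0] or variant_pos > exon_intervals[-1][1]:
        return None
    for k, (start, end) in enumerate(exon_intervals):
        if start <= variant_pos <= end:
            return 0
        if variant_pos < start:
            # intron between exon k-1 and exon k
            prev = exon_intervals[k - 1][1]
            return min(variant_pos - prev, start - variant_pos)
    raise AssertionError("unreachable")  # pragma: no cover


def is_disruptive(variant: AnnotatedVariant, config: FilterConfig) -> bool:
    """Predicate for a predicted disruptive effect on the gene product.

    True for radical effect classes (frameshift indels, splice-site,
    stop-gain, stop-loss) and for nonsynonymous substitutions whose CADD
    PHRED score strictly exceeds ``config.cadd_min``. A nonsynonymous
    variant without a CADD score is conservatively non-disruptive (logged).
    """
    if variant.effect_class in RADICAL_EFFECTS:
        return True
    if variant.effect_class is EffectClass.NONSYNONYMOUS:
        if variant.cadd_phred is None:
            logger.debug(
                "nonsynonymous variant %s:%d without CADD treated as non-disruptive",
                variant.chrom, variant.pos,
            )
            return False
        return variant.cadd_phred > config.cadd_min
    return False


#: region_class -> summary tally key; both UTRs collapse into one category.
_REGION_TALLY = {
    RegionClass.UTR5: "UTR",
    RegionClass.UTR3: "UTR",
    RegionClass.PROTEIN_CODING_EXON: "coding",
    RegionClass.LNCRNA_EXON: "lncRNA",
    RegionClass.INTRON: "intron",
    RegionClass.INTERGENIC: "intergenic",
}


def region_of(variant: AnnotatedVariant) -> str:
    """Summary tally key for a variant's genomic region."""
    return _REGION_TALLY[variant.region_class]


def merge_flanked_intervals(
    intervals: Sequence[tuple[int, int]], flank: int
) -> list[tuple[int, int]]:
    """Extend 1-based closed intervals by ``flank`` bp each side and merge overlaps."""
    if not intervals:
        raise InputError("empty interval set")
    extended = sorted((max(1, s - flank), e + flank) for s, e in intervals)
    merged = [extended[0]]
    for start, end in extended[1:]:
        if start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def low_coverage_fraction(
    target_intervals: Sequence[tuple[int, int]],
    per_base_coverage: Mapping[int, int],
    threshold: int,
    flank: int = 0,
) -> float:
    """Fraction of the flanked target footprint covered by < ``threshold`` reads.

    Targets are 1-based closed intervals, extended by ``flank`` bp on both
    sides and merged, so overlapping flanked targets count each base exactly
    once. ``per_base_coverage`` maps position to read depth; absent positions
    have depth 0.
    """
    merged = merge_flanked_intervals(target_intervals, flank)
    total = 0
    low = 0
    for start, end in merged:
        for pos in range(start, end + 1):
            total += 1
            if per_base_coverage.get(pos, 0) < threshold:
                low += 1
    return low / total
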