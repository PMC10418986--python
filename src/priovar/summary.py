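"""Descriptive cohort-level summary of an annotated variant set.

The summary mirrors the standard narrative breakdown of an exome callset:
known vs novel, exonic vs intronic, the UTR / protein-coding / lncRNA split
of exonic variants, the synonymous vs nonsynonymous split of coding
variants, the proximity of intronic variants to exon-intron boundaries, and
the tally of radical-effect ("disruptive") variants partitioned into
splice-proximal versus stop/frameshift classes.

Note that the disruptive tally here counts the radical effect classes only
(splice-site, stop-gain, stop-loss, frameshift); score-gated nonsynonymous
variants belong to the prioritization filters, not to this descriptive
partition, which is why ``disruptive_splice + disruptive_stop_fs`` always
equals ``disruptive``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import json

from .classify import region_of
from .model import AnnotatedVariant, EffectClass, FilterConfig, RegionClass

_STOP_FS = {EffectClass.STOPGAIN, EffectClass.STOPLOSS, EffectClass.FRAMESHIFT_INDEL}


def percent(numerator: int, denominator: int, digits: int = 2) -> float | None:
    """Percentage rounded half away from zero at ``digits`` decimals; None for 0/0."""
    if denominator == 0:
        return None
    q = Decimal(numerator) * 100 / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP))


@dataclass
class VariantSummary:
    """Exact tallies plus raw ratios for a variant set.

    Fractions are exact ratios in [0, 1] (``None`` when the denominator is
    zero); rounded percentages are derived views via :func:`percent`, never
    stored, so the raw ratios stay authoritative.
    """

    total: int
    known: int
    exonic: int
    intronic: int
    intergenic: int
    intronic_within_window: int
    utr: int
    coding: int
    lncrna: int
    synonymous: int
    nonsynonymous: int
    disruptive: int
    disruptive_splice: int
    disruptive_stop_fs: int

    def __post_init__(self) -> None:
        if self.utr + self.coding + self.lncrna != self.exonic:
            raise ValueError("UTR + coding + lncRNA must equal the exonic count")
        if self.disruptive_splice + self.disruptive_stop_fs != self.disruptive:
            raise ValueError("splice + stop/frameshift must equal the disruptive count")

    def _frac(self, num: int, den: int) -> float | None:
        return num / den if den else None

    @property
    def utr_frac(self) -> float | None:
        return self._frac(self.utr, self.exonic)

    @property
    def coding_frac(self) -> float | None:
        return self._frac(self.coding, self.exonic)

    @property
    def lncrna_frac(self) -> float | None:
        return self._frac(self.lncrna, self.exonic)

    @property
    def intronic_within_window_frac(self) -> float | None:
        return self._frac(self.intronic_within_window, self.intronic)

    @property
    def synonymous_frac(self) -> float | None:
        return self._frac(self.synonymous, self.coding)

    @property
    def nonsynonymous_frac(self) -> float | None:
        return self._frac(self.nonsynonymous, self.coding)

    @property
    def disruptive_frac(self) -> float | None:
        return self._frac(self.disruptive, self.total)

    @property
    def disruptive_splice_frac(self) -> float | None:
        return self._frac(self.disruptive_splice, self.disruptive)

    @property
    def disruptive_stop_fs_frac(self) -> float | None:
        return self._frac(self.disruptive_stop_fs, self.disruptive)

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        for name in (
            "utr_frac", "coding_frac", "lncrna_frac", "intronic_within_window_frac",
            "synonymous_frac", "nonsynonymous_frac", "disruptive_frac",
            "disruptive_splice_frac", "disruptive_stop_fs_frac",
        ):
            d[name] = getattr(self, name)
        return d

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#field\tvalue\n")
            for k, v in self.to_dict().items():
                fh.write(f"{k}\t{'' if v is None else v}\n")


def summarize(
    variants: Iterable[AnnotatedVariant], config: FilterConfig | None = None
) -> VariantSummary:
    """Tally a classified variant list into a :class:`VariantSummary`.

    The result is a pure function of the multiset of variants (permutation
    invariant). An intronic variant counts as boundary-proximal when its
    annotated splice distance is non-null and <= ``config.splice_report_window``.
    """
    config = config or FilterConfig()
    counts = dict.fromkeys(
        (
            "total", "known", "exonic", "intronic", "intergenic",
            "intronic_within_window", "utr", "coding", "lncrna",
            "synonymous", "nonsynonymous",
            "disruptive", "disruptive_splice", "disruptive_stop_fs",
        ),
        0,
    )
    for v in variants:
        counts["total"] += 1
        if v.known:
            counts["known"] += 1
        tally = region_of(v)
        if tally == "intron":
            counts["intronic"] += 1
            if (
                v.splice_distance is not None
                and v.splice_distance <= config.splice_report_window
            ):
                counts["intronic_within_window"] += 1
        elif tally == "intergenic":
            counts["intergenic"] += 1
        else:
            counts["exonic"] += 1
            key = {"UTR": "utr", "coding": "coding", "lncRNA": "lncrna"}[tally]
            counts[key] += 1
        if v.region_class is RegionClass.PROTEIN_CODING_EXON:
            if v.effect_class is EffectClass.SYNONYMOUS:
                counts["synonymous"] += 1
            elif v.effect_class is EffectClass.NONSYNONYMOUS:
                counts["nonsynonymous"] += 1
        if v.effect_class is EffectClass.SPLICE_SITE:
            counts["disruptive"] += 1
            counts["disruptive_splice"] += 1
        elif v.effect_class in _STOP_FS:
            counts["disruptive"] += 1
            counts["disruptive_stop_fs"] += 1
    return VariantSummary(**counts)
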