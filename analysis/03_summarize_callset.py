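#!/usr/bin/env python
"""Descriptive breakdown of the simulated callset.

Tallies the simulated variants into the standard narrative summary (known
vs novel, exonic split, boundary proximity of intronic variants, the
radical-effect partition) and prints the percentages alongside the exact
counts. Writes results/variant_summary.json.
"""

import json
from pathlib import Path

from priovar.io import read_annotation_table
from priovar.summary import percent, summarize

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    variants = read_annotation_table(BASE / "sim" / "variants.tsv")
    s = summarize(variants)
    s.write_json(BASE / "variant_summary.json")

    print(f"total variants: {s.total} ({s.known} known, "
          f"{percent(s.known, s.total)}%)")
    print(f"exonic: {s.exonic} = UTR {s.utr} ({percent(s.utr, s.exonic)}%) "
          f"+ coding {s.coding} ({percent(s.coding, s.exonic)}%) "
          f"+ lncRNA {s.lncrna} ({percent(s.lncrna, s.exonic)}%)")
    print(f"intronic: {s.intronic}, of which {s.intronic_within_window} "
          f"({percent(s.intronic_within_window, s.intronic)}%) lie within "
          f"100 bp of an exon-intron boundary")
    print(f"coding substitutions: {percent(s.synonymous, s.coding)}% synonymous, "
          f"{percent(s.nonsynonymous, s.coding)}% nonsynonymous")
    print(f"radical-effect variants: {s.disruptive} "
          f"({percent(s.disruptive, s.total)}% of total): "
          f"{s.disruptive_splice} splice ({percent(s.disruptive_splice, s.disruptive, 1)}%), "
          f"{s.disruptive_stop_fs} stop/frameshift "
          f"({percent(s.disruptive_stop_fs, s.disruptive, 1)}%)")


if __name__ == "__main__":
    main()
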