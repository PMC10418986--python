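#!/usr/bin/env python
"""Simulate the study inputs: a five-exome annotated variant table, a
low-depth count matrix, and ranked gene-similarity tables.

The cohort mirrors a three-patient rare-disease design (one trio proband,
two singletons). One causal signal is planted per inheritance scenario and
twenty fold changes of |log2FC| = 2 are planted in the count libraries; the
truth ledgers are written alongside so later steps can score recovery.

Writes results/sim/{variants.tsv, cohort.yaml, counts.tsv, samples.json,
truth.json, similarity.tsv}.
"""

import json
from pathlib import Path

import numpy as np

from priovar.io import write_annotation_table, write_cohort
from priovar.simulate import (
    SimulationConfig,
    generate_cohort,
    generate_counts,
    generate_similarity_tables,
    write_similarity_tables,
)

SEED = 20230731
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    chosen = rng.choice(2_000, 20, replace=False)
    planted_lfc = [(f"G{i:05d}", 2.0 if k % 2 else -2.0) for k, i in enumerate(chosen)]
    cfg = SimulationConfig(seed=SEED, n_variants=10_000, planted_log2fc=planted_lfc)

    variants, cohort, truth = generate_cohort(cfg)
    matrix, de_truth = generate_counts(cfg)
    tables = generate_similarity_tables(1_000, 62, n=100, seed=SEED)

    write_annotation_table(variants, OUT / "variants.tsv")
    write_cohort(cohort, OUT / "cohort.yaml")
    matrix.write_tsv(OUT / "counts.tsv")
    write_similarity_tables(tables, OUT / "similarity.tsv")
    (OUT / "samples.json").write_text(json.dumps(
        {s: {"library_size": matrix.library_sizes[s], "group": matrix.groups[s]}
         for s in matrix.counts.columns}, indent=2))
    (OUT / "truth.json").write_text(
        json.dumps({"variants": truth, "log2fc": dict(de_truth)}, indent=2))

    n_planted = sum(len(v) for v in truth.values())
    print(f"wrote {len(variants)} variants ({n_planted} planted across "
          f"{len(truth)} scenarios) and a {matrix.counts.shape[0]}-gene "
          f"count matrix for {matrix.counts.shape[1]} samples to {OUT}")


if __name__ == "__main__":
    main()
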