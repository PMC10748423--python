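#!/usr/bin/env python
"""Aggregate the base rankers over the gene space by geometric Borda scoring.

Produces the combined candidate ranking (geometric mean of observed ranks,
ascending), compares it against the arithmetic/median/L2 variants, writes
the candidate table and the top-100 gene set, and reports how many planted
positives each method places in its top 60.
"""

import importlib.util
from pathlib import Path

from screenrank import (
    GeneSetCollection,
    aggregate_variants,
    load_gene_space,
    select_top_k,
    write_gmt,
)

INDIR = Path("results/synthetic")
OUTDIR = Path("results")

_spec = importlib.util.spec_from_file_location(
    "base_step", Path(__file__).parent / "02_base_rankers_overlap.py"
)
_base_step = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_base_step)


def main() -> None:
    space = load_gene_space(INDIR / "gene_space.txt")
    rankers = _base_step.load_rankers()
    truth = set((INDIR / "planted_positives.txt").read_text().split())

    results = {}
    for method in ("geometric", "arithmetic", "median", "l2"):
        agg = aggregate_variants(rankers, space, method=method)
        top60 = {e.gene for e in agg.candidates[:60]}
        results[method] = (agg, len(top60 & truth))
        print(
            f"  {method:10s}: {len(agg.candidates)} candidates, "
            f"{len(top60 & truth)}/{len(truth)} positives in top 60"
        )

    agg, _ = results["geometric"]
    agg.write_tsv(OUTDIR / "aggregated.tsv", candidates_only=True)
    print(f"geometric candidate list -> {OUTDIR/'aggregated.tsv'}")

    k = min(100, len(agg.candidates))
    top_set = select_top_k(agg, k)
    coll = GeneSetCollection()
    coll.add(top_set)
    write_gmt(coll, OUTDIR / "top_candidates.gmt")
    print(f"top-{k} gene set '{top_set.term_name}' -> {OUTDIR/'top_candidates.gmt'}")


if __name__ == "__main__":
    main()
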