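#!/usr/bin/env python
"""Overrepresentation and novelty annotation of the aggregated candidates.

Tests the aggregated candidate list against a synthetic gene-set collection
(50 random terms plus one term enriched for the planted positives) with the
upper-tail hypergeometric test and BH adjustment, then partitions the
candidates against a synthetic known-therapeutic-target list.
"""

from pathlib import Path

import pandas as pd

from screenrank import (
    annotate_novelty,
    hypergeometric_enrichment,
    load_gene_space,
    simulate_annotations,
    simulate_target_list,
)
from screenrank.enrichment import write_results_tsv

INDIR = Path("results/synthetic")
OUTDIR = Path("results")
SEED = 0


def main() -> None:
    space = load_gene_space(INDIR / "gene_space.txt")
    aggregated = pd.read_csv(OUTDIR / "aggregated.tsv", sep="\t")
    candidates = aggregated["gene"].tolist()
    positives = (INDIR / "planted_positives.txt").read_text().split()

    collection = simulate_annotations(
        space, n_terms=50, size_range=(10, 100), seed=SEED,
        enriched_genes=positives, odds_ratio=8.0,
    )
    results = hypergeometric_enrichment(candidates, collection, space)
    write_results_tsv(results, OUTDIR / "ora.tsv")
    n_sig = sum(r.adjusted_p < 0.05 for r in results)
    print(f"ORA over {len(results)} terms -> {OUTDIR/'ora.tsv'}")
    print(f"  {n_sig} terms with adjusted p < 0.05")
    planted_term = next(r for r in results if r.term_id == "TERM_ENRICHED")
    print(
        f"  planted-enriched term: overlap {planted_term.overlap_count}/"
        f"{planted_term.term_size}, adjusted p = {planted_term.adjusted_p:.3g}"
    )

    targets = simulate_target_list(space, n_targets=50, seed=SEED)
    known, novel = annotate_novelty(candidates, targets)
    with (OUTDIR / "novelty.tsv").open("w", encoding="utf-8") as fh:
        fh.write("gene\tstatus\n")
        for g in known:
            fh.write(f"{g}\tknown_target\n")
        for g in novel:
            fh.write(f"{g}\tnovel\n")
    print(
        f"novelty: {len(known)} known targets + {len(novel)} novel = "
        f"{len(candidates)} candidates -> {OUTDIR/'novelty.tsv'}"
    )


if __name__ == "__main__":
    main()
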