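#!/usr/bin/env python
"""Build base rankers from the written screen tables and run overlap analysis.

Reads the TSVs produced by 01_simulate_screens.py back through the loaders
(a deliberate round-trip), converts each screen to its 1..k / k+1 rank
vector at alpha = 0.05, and counts per gene how many screens tested and
identified it.  Genes identified by two or more screens form the overlap
candidate list.
"""

from pathlib import Path

from screenrank import (
    build_base_ranker,
    compute_overlap,
    load_screen_table,
    select_multi_screen_candidates,
)

INDIR = Path("results/synthetic")
OUTDIR = Path("results")


def load_rankers():
    rankers = []
    for path in sorted(INDIR.glob("screen_*.tsv")):
        screen = load_screen_table(path, screen_id=path.stem, measure_column="p")
        rankers.append(build_base_ranker(screen, alpha=0.05))
    return rankers


def main() -> None:
    rankers = load_rankers()
    for r in rankers:
        print(f"  {r.screen_id}: k = {r.k} significant of {len(r.tested)} tested")

    table = compute_overlap(rankers)
    table.write_tsv(OUTDIR / "overlap.tsv", rankers)
    selected = select_multi_screen_candidates(table, min_count=2)
    (OUTDIR / "overlap_candidates.txt").write_text(
        "\n".join(selected) + "\n", encoding="utf-8"
    )
    print(f"{len(table)} genes tested by >= 1 screen -> {OUTDIR/'overlap.tsv'}")
    print(
        f"{len(selected)} genes identified by >= 2 screens "
        f"-> {OUTDIR/'overlap_candidates.txt'}"
    )
    truth = set((INDIR / "planted_positives.txt").read_text().split())
    print(f"  of which planted positives: {len(set(selected) & truth)}")


if __name__ == "__main__":
    main()
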