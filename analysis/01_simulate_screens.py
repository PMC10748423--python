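#!/usr/bin/env python
"""Simulate the default six-screen study and write it in loader formats.

Generates a 2,000-gene space, six screens with coverages from 25 genes to
whole genome, and 30 planted positives, then writes everything as the same
TSV/plain-text files the loaders consume, so the rest of the analysis runs
off disk exactly as it would on curated screen tables.
"""

from pathlib import Path

from screenrank import SyntheticConfig, simulate_screens
from screenrank.synthetic_data import write_screens

OUTDIR = Path("results/synthetic")
SEED = 0


def main() -> None:
    config = SyntheticConfig(seed=SEED)
    space, screens, truth = simulate_screens(config)
    write_screens(screens, OUTDIR, space=space)
    (OUTDIR / "planted_positives.txt").write_text(
        "\n".join(truth.positives) + "\n", encoding="utf-8"
    )
    print(f"gene space: {len(space)} genes -> {OUTDIR/'gene_space.txt'}")
    for screen in screens:
        n_meas = len(screen.records)
        print(f"  {screen.screen_id}: {len(screen.tested)} tested, {n_meas} measured")
    print(f"planted positives: {len(truth.positives)} -> {OUTDIR/'planted_positives.txt'}")


if __name__ == "__main__":
    main()
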