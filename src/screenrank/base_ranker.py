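"""Base-ranker construction: one screen's table -> a partial rank vector.

A screen's candidates with significance measure strictly below ``alpha``
(default 0.05) are ranked 1..k ascending by measure; every other tested gene
— including tested-but-unmeasured genes from hit-list-only screens — receives
the sentinel rank k+1.  Untested genes carry no rank at all, which is what
lets screens of wildly different coverage (tens of genes to whole genome) be
combined downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .gene_space_io import ScreenResult

logger = logging.getLogger(__name__)

__all__ = ["BaseRanker", "build_base_ranker", "filter_driver_genes"]

DEFAULT_ALPHA = 0.05


@dataclass
class BaseRanker:
    """A screen reduced to ranks: significant genes 1..k, the rest k+1.

    Invariants: ranks of significant genes are a permutation of 1..k;
    every tested non-significant gene has rank k+1; untested genes absent.
    """

    screen_id: str
    k: int
    ranks: dict[str, int]
    tested: set[str]
    alpha: float = DEFAULT_ALPHA

    def is_significant(self, gene: str) -> bool:
        return gene in self.ranks and self.ranks[gene] <= self.k

    @property
    def significant(self) -> list[str]:
        """Significant genes in rank order 1..k."""
        sig = [g for g, r in self.ranks.items() if r <= self.k]
        return sorted(sig, key=self.ranks.__getitem__)

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "gene": g,
                "rank": r,
                "significant": r <= self.k,
                "screen_id": self.screen_id,
            }
            for g, r in sorted(self.ranks.items(), key=lambda kv: (kv[1], kv[0]))
        ]
        return pd.DataFrame(rows, columns=["gene", "rank", "significant", "screen_id"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_base_ranker(screen: ScreenResult, alpha: float = DEFAULT_ALPHA) -> BaseRanker:
    """Convert a screen's significance table into its base ranker.

    Significant means measure strictly less than ``alpha``.  Ties in the
    measure are broken by larger effect size when the screen carries one,
    else by harmonized symbol order, so the ranking is deterministic.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    effects = screen.effect_sizes or {}
    significant = [g for g, m in screen.records.items() if m < alpha]
    significant.sort(key=lambda g: (screen.records[g], -effects.get(g, 0.0), g))
    k = len(significant)
    ranks = {g: i for i, g in enumerate(significant, start=1)}
    for g in screen.tested:
        if g not in ranks:
            ranks[g] = k + 1
    return BaseRanker(
        screen_id=screen.screen_id,
        k=k,
        ranks=ranks,
        tested=set(screen.tested),
        alpha=alpha,
    )


def filter_driver_genes(
    genes: Sequence[str] | Iterable[str], drivers: Iterable[str]
) -> list[str]:
    """Remove known malignancy-driver genes from a candidate list.

    Order is preserved; the number removed is logged.  Both inputs are
    assumed harmonized.
    """
    driver_set = set(drivers)
    genes = list(genes)
    kept = [g for g in genes if g not in driver_set]
    removed = len(genes) - len(kept)
    if removed:
        logger.info("driver filter: removed %d of %d gene(s)", removed, len(genes))
    if genes and not kept:
        logger.warning("driver filter: removed every candidate gene")
    return kept
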