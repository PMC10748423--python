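"""Simple overlap analysis: how many screens tested, and identified, each gene.

The overlap view complements formal rank aggregation: a gene identified by
two or more independent screens is corroborated evidence, but because screen
coverage varies enormously, genes tested in only one screen can never appear
here — which is exactly the blind spot aggregation addresses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .base_ranker import BaseRanker, filter_driver_genes

logger = logging.getLogger(__name__)

__all__ = ["OverlapRow", "OverlapTable", "compute_overlap", "select_multi_screen_candidates"]


@dataclass(frozen=True)
class OverlapRow:
    n_identified: int
    n_tested: int

    @property
    def pct_identified(self) -> float:
        return 100.0 * self.n_identified / self.n_tested if self.n_tested else 0.0


@dataclass
class OverlapTable:
    """Per-gene counts of screens testing / identifying it.

    ``pct_identified`` is reported rounded to the nearest integer in exports
    while full precision is retained here.
    """

    rows: dict[str, OverlapRow]
    screen_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self, rankers: Sequence[BaseRanker] | None = None) -> pd.DataFrame:
        """Tabular view: one row per gene, optional per-screen rank columns.

        Per-screen cells show the numeric rank for significant genes, the
        string ``k+1`` for tested-but-not-significant, and ``NA`` for untested.
        """
        records = []
        by_id = {r.screen_id: r for r in rankers} if rankers else {}
        for gene in sorted(self.rows):
            row = self.rows[gene]
            rec: dict[str, object] = {"gene": gene}
            for sid in self.screen_ids:
                ranker = by_id.get(sid)
                if ranker is None:
                    continue
                if gene not in ranker.ranks:
                    rec[sid] = "NA"
                elif ranker.ranks[gene] > ranker.k:
                    rec[sid] = "k+1"
                else:
                    rec[sid] = str(ranker.ranks[gene])
            rec["n_identified"] = row.n_identified
            rec["n_tested"] = row.n_tested
            rec["pct_identified"] = round(row.pct_identified)
            records.append(rec)
        return pd.DataFrame(records)

    def write_tsv(self, path: str | Path, rankers: Sequence[BaseRanker] | None = None) -> None:
        self.to_frame(rankers).to_csv(path, sep="\t", index=False)


def compute_overlap(rankers: Sequence[BaseRanker]) -> OverlapTable:
    """Count, per gene, the screens that tested it and those that identified it.

    A gene counts as identified in a screen iff its rank there is <= k.
    Genes tested by no screen do not appear.
    """
    if not rankers:
        raise ValueError("compute_overlap requires at least one base ranker")
    rows: dict[str, OverlapRow] = {}
    tested_counts: dict[str, int] = {}
    identified_counts: dict[str, int] = {}
    for ranker in rankers:
        for gene in ranker.tested:
            tested_counts[gene] = tested_counts.get(gene, 0) + 1
            if ranker.is_significant(gene):
                identified_counts[gene] = identified_counts.get(gene, 0) + 1
    for gene, n_tested in tested_counts.items():
        rows[gene] = OverlapRow(
            n_identified=identified_counts.get(gene, 0), n_tested=n_tested
        )
    return OverlapTable(rows=rows, screen_ids=tuple(r.screen_id for r in rankers))


def select_multi_screen_candidates(
    table: OverlapTable,
    min_count: int = 2,
    drivers: Iterable[str] = (),
) -> list[str]:
    """Genes identified by at least ``min_count`` screens, driver-filtered.

    Sorted by (n_identified desc, pct_identified desc, symbol).  Driver
    filtering happens last, on the final overlap list.
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    hits = [g for g, row in table.rows.items() if row.n_identified >= min_count]
    hits.sort(
        key=lambda g: (
            -table.rows[g].n_identified,
            -table.rows[g].pct_identified,
            g,
        )
    )
    return filter_driver_genes(hits, drivers)
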