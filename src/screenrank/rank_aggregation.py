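"""Geometric Borda rank aggregation of partial base rankers over a gene space.

Each gene's aggregate score is the geometric mean of its ranks across the
screens that *tested* it (computed as exp(mean(log rank)) in log space).
Lower scores mean stronger selection.  Screens that did not test a gene
contribute nothing by default: imputing a space-sized rank N+1 for every
untested screen would crush genes coming from small-coverage screens, and
"not tested" is a different statement from "tested but not significant"
(rank k+1).  The imputation variant is available behind ``impute_untested``
for sensitivity analysis.

Arithmetic, median and L2 (quadratic-mean) variants are provided as
comparison baselines around the geometric default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .base_ranker import BaseRanker
from .gene_space_io import GeneSet, GeneSpace

logger = logging.getLogger(__name__)

__all__ = [
    "AggregatedEntry",
    "AggregatedList",
    "aggregate_geometric",
    "aggregate_variants",
    "select_top_k",
]

METHODS = ("geometric", "arithmetic", "median", "l2")


@dataclass(frozen=True)
class AggregatedEntry:
    gene: str
    aggregate_score: float
    n_screens_tested: int
    n_screens_identified: int

    @property
    def ever_significant(self) -> bool:
        return self.n_screens_identified > 0


@dataclass
class AggregatedList:
    """The combined ranking: entries sorted ascending by aggregate score.

    ``entries`` holds every space gene tested by at least one screen;
    ``candidates`` restricts to genes significant in >= 1 screen — the
    exported candidate list — because genes whose only evidence is k+1
    ranks everywhere were never selected by anything.
    """

    entries: list[AggregatedEntry]
    method_tag: str
    screen_ids: tuple[str, ...] = ()
    per_screen_ranks: dict[str, dict[str, int]] | None = None

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def candidates(self) -> list[AggregatedEntry]:
        return [e for e in self.entries if e.ever_significant]

    def to_frame(self, candidates_only: bool = False) -> pd.DataFrame:
        entries = self.candidates if candidates_only else self.entries
        records = []
        for pos, e in enumerate(entries, start=1):
            rec: dict[str, object] = {
                "rank_position": pos,
                "gene": e.gene,
                "aggregate_score": e.aggregate_score,
                "n_tested": e.n_screens_tested,
                "n_identified": e.n_screens_identified,
            }
            if self.per_screen_ranks is not None:
                ranks = self.per_screen_ranks.get(e.gene, {})
                for sid in self.screen_ids:
                    rec[f"rank_{sid}"] = ranks.get(sid, "NA")
            records.append(rec)
        return pd.DataFrame(records)

    def write_tsv(self, path: str | Path, candidates_only: bool = False) -> None:
        self.to_frame(candidates_only).to_csv(path, sep="\t", index=False)


def _score(ranks: Sequence[int], method: str) -> float:
    # reduce in sorted order so the score is bit-identical regardless of the
    # order screens were supplied in
    ranks = sorted(ranks)
    n = len(ranks)
    if method == "geometric":
        if n == 1:  # exact identity for a single list, no exp/log round-trip
            return float(ranks[0])
        return math.exp(sum(math.log(r) for r in ranks) / n)
    if method == "arithmetic":
        return sum(ranks) / n
    if method == "median":
        ordered = sorted(ranks)
        mid = n // 2
        return float(ordered[mid]) if n % 2 else (ordered[mid - 1] + ordered[mid]) / 2.0
    if method == "l2":
        return math.sqrt(sum(r * r for r in ranks) / n)
    raise ValueError(f"unknown aggregation method {method!r}; expected one of {METHODS}")


def aggregate_variants(
    rankers: Sequence[BaseRanker],
    space: GeneSpace,
    method: str = "geometric",
    impute_untested: bool = False,
) -> AggregatedList:
    """Aggregate base rankers into one ranking with the chosen mean.

    Only genes belonging to the space and tested by at least one screen
    appear (the count excluded for being outside the space is logged).
    With ``impute_untested`` every space gene receives rank N+1 for each
    screen that did not test it, N being the space size.
    """
    if not rankers:
        raise ValueError("aggregation requires at least one base ranker")
    if method not in METHODS:
        raise ValueError(f"unknown aggregation method {method!r}; expected one of {METHODS}")
    seen_ids = [r.screen_id for r in rankers]
    if len(set(seen_ids)) != len(seen_ids):
        raise ValueError("duplicate screen_id among base rankers")

    tested_any: dict[str, None] = {}
    n_outside = 0
    for ranker in rankers:
        for gene in ranker.tested:
            if gene in space:
                tested_any.setdefault(gene)
            else:
                n_outside += 1
    if n_outside:
        logger.warning(
            "aggregation: excluded %d screen-gene observation(s) outside the gene space",
            n_outside,
        )
    if not tested_any:
        raise ValueError("no screen tests any gene of the space")

    imputed_rank = len(space) + 1
    entries: list[AggregatedEntry] = []
    per_screen: dict[str, dict[str, int]] = {}
    for gene in tested_any:
        ranks: list[int] = []
        gene_ranks: dict[str, int] = {}
        n_tested = 0
        n_identified = 0
        for ranker in rankers:
            r = ranker.ranks.get(gene)
            if r is None:
                if impute_untested:
                    ranks.append(imputed_rank)
                continue
            n_tested += 1
            if r <= ranker.k:
                n_identified += 1
            ranks.append(r)
            gene_ranks[ranker.screen_id] = r
        entries.append(
            AggregatedEntry(
                gene=gene,
                aggregate_score=_score(ranks, method),
                n_screens_tested=n_tested,
                n_screens_identified=n_identified,
            )
        )
        per_screen[gene] = gene_ranks

    # ties favor corroborated genes, then symbol order, for determinism
    entries.sort(
        key=lambda e: (
            e.aggregate_score,
            -e.n_screens_identified,
            -e.n_screens_tested,
            e.gene,
        )
    )
    tag = method + ("+imputed" if impute_untested else "")
    return AggregatedList(
        entries=entries,
        method_tag=tag,
        screen_ids=tuple(seen_ids),
        per_screen_ranks=per_screen,
    )


def aggregate_geometric(
    rankers: Sequence[BaseRanker],
    space: GeneSpace,
    impute_untested: bool = False,
) -> AggregatedList:
    """Geometric-mean Borda aggregation (the default method)."""
    return aggregate_variants(rankers, space, method="geometric", impute_untested=impute_untested)


def select_top_k(
    aggregated: AggregatedList,
    k_top: int,
    set_name: str = "T cell infiltration",
    candidates_only: bool = True,
) -> GeneSet:
    """The first ``k_top`` aggregated candidates as a named gene set."""
    entries = aggregated.candidates if candidates_only else aggregated.entries
    if not (1 <= k_top <= len(entries)):
        raise ValueError(
            f"k_top must be in [1, {len(entries)}], got {k_top}"
        )
    genes = tuple(e.gene for e in entries[:k_top])
    term_id = set_name.upper().replace(" ", "_")
    return GeneSet(term_id=term_id, term_name=set_name, genes=genes)
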