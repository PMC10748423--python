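"""Overrepresentation analysis (hypergeometric) and novelty annotation.

The ORA asks, per term, whether the candidate list contains more of the
term's members than expected for a random draw of the same size from the
background: one-sided upper-tail hypergeometric p = P(X >= overlap) with
X ~ Hypergeom(background_size, term_size, candidate_size), followed by
Benjamini-Hochberg adjustment across the tested terms.

By default the background is the supplied gene space restricted to genes
annotated in at least one term of the collection (common ORA practice);
``annotated_background=False`` uses the full space instead.

Novelty annotation partitions candidates against a known-therapeutic-target
list: candidates already under development versus novel ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .gene_space_io import GeneSetCollection, GeneSpace

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "hypergeometric_enrichment", "annotate_novelty", "results_to_frame"]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    p_value: float
    adjusted_p: float
    overlap_count: int
    term_size: int
    candidate_size: int
    background_size: int


def hypergeometric_enrichment(
    candidates: Sequence[str],
    collection: GeneSetCollection,
    background: GeneSpace,
    annotated_background: bool = True,
) -> list[EnrichmentResult]:
    """One-sided upper-tail hypergeometric test per term, BH-adjusted.

    Candidates outside the background are dropped with a warning; terms with
    no member in the background are skipped.  Results sorted by adjusted p.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    bg = set(background.symbols)
    if annotated_background:
        annotated: set[str] = set()
        for gene_set in collection:
            annotated.update(gene_set.genes)
        bg &= annotated
    if not bg:
        raise ValueError("empty enrichment background")

    cand_in = [g for g in dict.fromkeys(candidates) if g in bg]
    n_dropped = len(set(candidates)) - len(cand_in)
    if n_dropped:
        logger.warning(
            "enrichment: dropped %d candidate(s) outside the background", n_dropped
        )
    if not cand_in:
        raise ValueError("no candidate gene lies in the enrichment background")
    cand_set = set(cand_in)

    M, n_cand = len(bg), len(cand_set)
    raw: list[tuple[str, str, float, int, int]] = []
    for gene_set in collection:
        members = set(gene_set.genes) & bg
        if not members:
            logger.warning("enrichment: term %s has no member in background, skipped",
                           gene_set.term_id)
            continue
        overlap = len(members & cand_set)
        # P(X >= overlap), X ~ Hypergeom(M, |term|, n_cand)
        p = float(stats.hypergeom.sf(overlap - 1, M, len(members), n_cand))
        p = min(max(p, 0.0), 1.0)
        raw.append((gene_set.term_id, gene_set.term_name, p, overlap, len(members)))

    if not raw:
        raise ValueError("no term intersects the background")
    pvals = [r[2] for r in raw]
    adjusted = stats.false_discovery_control(pvals, method="bh")
    results = [
        EnrichmentResult(
            term_id=tid,
            term_name=tname,
            p_value=p,
            adjusted_p=min(float(adj), 1.0),
            overlap_count=overlap,
            term_size=tsize,
            candidate_size=n_cand,
            background_size=M,
        )
        for (tid, tname, p, overlap, tsize), adj in zip(raw, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.term_id))
    return results


def annotate_novelty(
    candidates: Sequence[str], known_targets: Iterable[str]
) -> tuple[list[str], list[str]]:
    """Partition candidates into (known targets, novel), preserving order."""
    target_set = set(known_targets)
    known = [g for g in candidates if g in target_set]
    novel = [g for g in candidates if g not in target_set]
    return known, novel


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "term_size": r.term_size,
                "overlap": r.overlap_count,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
            }
            for r in results
        ]
    )


def write_results_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
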