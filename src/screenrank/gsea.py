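"""Preranked gene-set enrichment analysis with a permutation null.

The ranking metric scores each gene as -log10(adjusted p) * (average log2
fold-change), so genes both strongly and significantly up in group 1 sit at
the top and strongly down genes at the bottom.  The enrichment statistic is
the weighted Kolmogorov-Smirnov running sum: walking down the ranked list,
hitting a set member increments the sum proportionally to |score|^p_exp
(normalised so hits total +1), missing decrements by 1/(N - m); the
enrichment score ES is the maximum-magnitude deviation.  With p_exp = 0 this
reduces to the classic KS statistic between hit and miss positions.

Significance comes from gene-label permutations — random same-size gene sets
— the only available null for preranked input.  The nominal p uses an
add-one estimator over the same-sign null ES values, NES divides ES by the
mean |same-sign null ES|, and the FDR q is Benjamini-Hochberg across the
evaluated sets (a single-set run reports fdr_q = nominal_p); the NES-histogram
FDR of other GSEA implementations needs many sets and is deliberately not
reproduced here.

A minimal two-group differential expression (Wilcoxon rank-sum + BH) is
included so a fully synthetic pipeline can feed the metric.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_space_io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "RankedMetric",
    "GseaResult",
    "rank_metric",
    "enrichment_score",
    "gsea_preranked",
    "simple_de",
]

#: adjusted p of exactly 0 is clamped here so the metric stays finite
P_CLAMP = 1e-300


@dataclass(frozen=True)
class RankedMetric:
    """Genes with their ranking scores, sorted descending.

    Ties in score are broken by symbol so the hit order — and therefore the
    enrichment score — is reproducible.
    """

    genes: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked metric contains duplicated genes")
        if any(b > a for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores are not sorted descending")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "score": self.scores})


def rank_metric(
    de_table: pd.DataFrame,
    gene_column: str = "gene",
    p_column: str = "adjusted_p",
    fc_column: str = "avg_log2FC",
) -> RankedMetric:
    """Score each gene as -log10(adjusted p) * avg_log2FC, sorted descending."""
    for col in (gene_column, p_column, fc_column):
        if col not in de_table.columns:
            raise ValueError(f"differential-expression table lacks column {col!r}")
    p = de_table[p_column].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("adjusted p-values must lie in [0, 1]")
    fc = de_table[fc_column].to_numpy(dtype=float)
    scores = -np.log10(np.clip(p, P_CLAMP, 1.0)) * fc
    order = sorted(
        range(len(scores)), key=lambda i: (-scores[i], str(de_table[gene_column].iloc[i]))
    )
    genes = tuple(str(de_table[gene_column].iloc[i]) for i in order)
    if len(set(genes)) != len(genes):
        raise ValueError("differential-expression table contains duplicated genes")
    return RankedMetric(genes=genes, scores=tuple(float(scores[i]) for i in order))


@dataclass
class GseaResult:
    gene_set_name: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    running_sum: np.ndarray
    n_permutations: int
    seed: int
    n_hits: int = 0


def _hit_weights(scores: np.ndarray, hit_idx: np.ndarray, p_exp: float) -> np.ndarray:
    w = np.abs(scores[hit_idx]) ** p_exp
    total = w.sum()
    if total <= 0.0:  # all hit scores are exactly 0: fall back to equal weights
        w = np.ones_like(w)
        total = w.sum()
    return w / total


def _es_from_hits(
    scores: np.ndarray, hit_idx: np.ndarray, p_exp: float
) -> float:
    """ES evaluated only at the extrema candidates (just after / just before
    each hit), where the piecewise-linear running sum attains its extremes."""
    n = len(scores)
    m = len(hit_idx)
    miss = 1.0 / (n - m)
    w = _hit_weights(scores, hit_idx, p_exp)
    cum = np.cumsum(w)
    j = np.arange(1, m + 1)
    after = cum - (hit_idx + 1 - j) * miss          # value right after each hit
    before = (cum - w) - (hit_idx + 1 - j) * miss   # value right before each hit
    es_pos = float(after.max())
    es_neg = float(before.min())
    # exact +/- magnitude ties resolve to the positive deviation
    return es_pos if es_pos >= -es_neg else es_neg


def enrichment_score(
    metric: RankedMetric,
    gene_set: Iterable[str],
    p_exp: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running-sum profile.

    The returned profile has N+1 points: it starts at 0 before the first
    gene and returns to 0 after the last.  Raises if the set shares no gene
    with the metric or covers the whole of it.
    """
    genes = metric.genes
    members = set(gene_set)
    hit_mask = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    m = int(hit_mask.sum())
    if m == 0:
        raise ValueError("gene set not represented in the ranked metric")
    if m >= len(genes):
        raise ValueError("gene set covers the entire ranked metric")
    scores = np.asarray(metric.scores, dtype=float)
    hit_idx = np.flatnonzero(hit_mask)
    w = _hit_weights(scores, hit_idx, p_exp)
    steps = np.full(len(genes), -1.0 / (len(genes) - m))
    steps[hit_idx] = w
    running = np.concatenate([[0.0], np.cumsum(steps)])
    running[-1] = 0.0  # pin the analytic endpoint; cumsum leaves float dust
    es = _es_from_hits(scores, hit_idx, p_exp)
    return es, running


def gsea_preranked(
    metric: RankedMetric,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    p_exp: float = 1.0,
    exhaustive: bool = False,
) -> list[GseaResult]:
    """Preranked GSEA over a collection of gene sets.

    The null is gene-label permutation: random same-size index sets, either
    ``n_perm`` sampled draws (seeded, reproducible) or — with ``exhaustive``
    and a small instance — every possible placement.  nominal_p is the
    add-one fraction of same-sign null ES at least as extreme as the observed
    ES; NES = ES / mean(|same-sign null ES|); fdr_q is BH across the sets.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    n = len(metric)
    scores = np.asarray(metric.scores, dtype=float)
    rng = np.random.default_rng(seed)
    metric_genes = set(metric.genes)
    results: list[GseaResult] = []
    for gene_set in sets:
        if len(gene_set.genes) > n:
            raise ValueError(
                f"gene set {gene_set.term_id!r} is larger than the ranked metric"
            )
        es, running = enrichment_score(metric, gene_set.genes, p_exp=p_exp)
        m = sum(1 for g in gene_set.genes if g in metric_genes)

        if exhaustive:
            n_comb = math.comb(n, m)
            if n_comb > 200_000:
                raise ValueError(
                    f"exhaustive null infeasible: C({n},{m}) = {n_comb} placements"
                )
            null_iter = (np.array(c) for c in itertools.combinations(range(n), m))
            null_es = np.fromiter(
                (_es_from_hits(scores, idx, p_exp) for idx in null_iter),
                dtype=float,
                count=n_comb,
            )
        else:
            null_es = np.empty(n_perm)
            for i in range(n_perm):
                idx = np.sort(rng.choice(n, size=m, replace=False))
                null_es[i] = _es_from_hits(scores, idx, p_exp)

        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        n_extreme = int(np.sum(np.abs(null_es[same_sign]) >= abs(es)))
        nominal_p = (1 + n_extreme) / (1 + n_same)
        denom_pool = np.abs(null_es[same_sign]) if n_same else np.abs(null_es)
        mean_abs = float(denom_pool.mean()) if len(denom_pool) else 1.0
        nes = es / mean_abs if mean_abs > 0 else 0.0
        results.append(
            GseaResult(
                gene_set_name=gene_set.term_name,
                es=es,
                nes=nes,
                nominal_p=min(nominal_p, 1.0),
                fdr_q=math.nan,  # filled below
                running_sum=running,
                n_permutations=len(null_es),
                seed=seed,
                n_hits=m,
            )
        )

    pvals = [r.nominal_p for r in results]
    if len(pvals) == 1:
        results[0].fdr_q = pvals[0]
    else:
        qvals = stats.false_discovery_control(pvals, method="bh")
        for r, q in zip(results, qvals):
            r.fdr_q = min(float(q), 1.0)
    return results


def results_to_frame(results: Sequence[GseaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_set": r.gene_set_name,
                "n_hits": r.n_hits,
                "es": r.es,
                "nes": r.nes,
                "nominal_p": r.nominal_p,
                "fdr_q": r.fdr_q,
                "n_permutations": r.n_permutations,
            }
            for r in results
        ]
    )


def simple_de(
    expression: pd.DataFrame,
    labels: Sequence[str],
    group1: str | None = None,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Two-group differential expression: Wilcoxon rank-sum + BH.

    ``expression`` is genes x samples; ``labels`` assigns each column to one
    of exactly two groups (>= 2 samples each).  Returns one row per gene with
    p_value, adjusted_p and avg_log2FC = log2((mean1 + eps) / (mean2 + eps)),
    group 1 being ``group1`` (default: the first column's label).
    """
    labels = list(labels)
    if len(labels) != expression.shape[1]:
        raise ValueError("labels must match the number of expression columns")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two groups, got {uniq}")
    if group1 is None:
        group1 = uniq[0]
    elif group1 not in uniq:
        raise ValueError(f"group1 {group1!r} not among labels {uniq}")
    group2 = next(u for u in uniq if u != group1)
    mask1 = np.array([l == group1 for l in labels])
    mask2 = ~mask1
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValueError("each group needs at least two samples")

    values = expression.to_numpy(dtype=float)
    x1 = values[:, mask1]
    x2 = values[:, mask2]
    res = stats.mannwhitneyu(x1, x2, axis=1, alternative="two-sided")
    pvals = np.asarray(res.pvalue, dtype=float)
    # constant rows (all ties) can yield nan under the normal approximation
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    pvals = np.clip(pvals, 0.0, 1.0)
    adj = np.minimum(stats.false_discovery_control(pvals, method="bh"), 1.0)
    log2fc = np.log2((x1.mean(axis=1) + eps) / (x2.mean(axis=1) + eps))
    return pd.DataFrame(
        {
            "gene": expression.index.astype(str),
            "p_value": pvals,
            "adjusted_p": adj,
            "avg_log2FC": log2fc,
        }
    ).reset_index(drop=True)


def write_de_tsv(de_table: pd.DataFrame, path: str | Path) -> None:
    de_table.to_csv(path, sep="\t", index=False)
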