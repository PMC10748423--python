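"""Synthetic screens, annotations and expression data with planted truth.

The generator emulates the statistical shape of a multi-screen meta-analysis:

* K screens of wildly heterogeneous coverage (a 25-gene boutique library up
  to whole genome), each testing a random subset of a shared gene space;
* a small set of planted true positives whose significance measures are
  drawn skewed-small, p ~ Beta(a, 1) with a < 1, but only with probability
  ``detect_prob`` per screen — modelling that a gene can be a genuine hit in
  one screening technology and invisible to another;
* uniform p-values for everything else (and for undetected positives);
* a two-group expression matrix (log-normal counts) in which the planted
  set's group-1 mean is shifted by ``shift`` log2 units, standing in for a
  tumor-infiltrating vs peripheral T-cell comparison;
* random gene-set collections, optionally with one term enriched for the
  planted positives, plus a synthetic therapeutic-target list.

Everything is a pure function of (config, seed): independent sub-streams are
spawned from the config seed, so simulate_screens and simulate_expression
agree on the planted positives without sharing state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gene_space_io import GeneSet, GeneSetCollection, GeneSpace, ScreenResult

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionConfig",
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_screens",
    "simulate_expression",
    "simulate_annotations",
    "simulate_target_list",
]

# sub-stream indices spawned off the config seed
_STREAM_TRUTH, _STREAM_SCREENS, _STREAM_EXPRESSION = 0, 1, 2


@dataclass(frozen=True)
class ExpressionConfig:
    """Two-group expression generator settings (log2-scale parameters)."""

    n_per_group: int = 20
    shift: float = 2.0          # planted group-1 mean shift, log2 units
    sigma: float = 0.5          # within-gene sd, log2 units
    baseline_mean: float = 3.0  # grand mean of per-gene baselines, log2 units
    baseline_sd: float = 1.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic meta-analysis.

    Defaults mirror the structure of the real six-screen setting: coverages
    from 1.25% (a 25-gene-scale library) through whole genome, 30 planted
    positives with Beta(0.1, 1) alternative p-values, and a 60% chance that
    a tested positive actually shows up in any given screen.
    """

    n_genes: int = 2000
    n_screens: int = 6
    coverages: tuple[float, ...] = (0.0125, 0.05, 0.1, 0.5, 1.0, 1.0)
    n_true: int = 30
    beta_a: float = 0.1
    detect_prob: float = 0.6
    seed: int = 0
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_screens < 1:
            raise ValueError(f"n_screens must be >= 1, got {self.n_screens}")
        if len(self.coverages) != self.n_screens:
            raise ValueError(
                f"coverages has {len(self.coverages)} entries for n_screens={self.n_screens}"
            )
        for c in self.coverages:
            if not (0.0 < c <= 1.0):
                raise ValueError(f"coverages entries must lie in (0, 1], got {c}")
        if not (0 <= self.n_true <= self.n_genes):
            raise ValueError(f"n_true must be in [0, n_genes], got {self.n_true}")
        if not (0.0 < self.beta_a <= 1.0):
            raise ValueError(f"beta_a must be in (0, 1], got {self.beta_a}")
        if not (0.0 <= self.detect_prob <= 1.0):
            raise ValueError(f"detect_prob must be in [0, 1], got {self.detect_prob}")
        if self.expression.n_per_group < 2:
            raise ValueError(
                f"expression.n_per_group must be >= 2, got {self.expression.n_per_group}"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted next to the simulated screens."""

    positives: tuple[str, ...]
    tested: dict[str, frozenset]          # screen_id -> tested genes
    alternative_draws: dict[str, frozenset]  # screen_id -> positives drawn from Beta


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    child = np.random.SeedSequence(config.seed).spawn(3)[stream]
    return np.random.default_rng(child)


def _symbols(n_genes: int) -> tuple[str, ...]:
    width = max(6, len(str(n_genes)))
    return tuple(f"G{i:0{width}d}" for i in range(1, n_genes + 1))


def _positives(config: SyntheticConfig) -> tuple[str, ...]:
    rng = _rng(config, _STREAM_TRUTH)
    symbols = _symbols(config.n_genes)
    idx = rng.choice(config.n_genes, size=config.n_true, replace=False)
    return tuple(symbols[i] for i in sorted(idx))


def simulate_screens(
    config: SyntheticConfig,
) -> tuple[GeneSpace, list[ScreenResult], SyntheticTruth]:
    """Generate the gene space, K screens and the planted truth.

    Each screen tests a seeded random subset of its coverage size (coverage
    1.0 screens test everything); tested positives draw p ~ Beta(a, 1) with
    probability ``detect_prob``, all other draws are Uniform(0, 1).
    """
    config.validate()
    symbols = _symbols(config.n_genes)
    space = GeneSpace(symbols)
    positives = _positives(config)
    pos_set = set(positives)

    rng = _rng(config, _STREAM_SCREENS)
    screens: list[ScreenResult] = []
    tested_masks: dict[str, frozenset] = {}
    alt_draws: dict[str, frozenset] = {}
    for i, coverage in enumerate(config.coverages, start=1):
        screen_id = f"screen_{i:02d}"
        n_tested = max(1, round(coverage * config.n_genes))
        if n_tested >= config.n_genes:
            tested = list(symbols)
        else:
            idx = rng.choice(config.n_genes, size=n_tested, replace=False)
            tested = [symbols[j] for j in sorted(idx)]
        records: dict[str, float] = {}
        alts: list[str] = []
        for gene in tested:
            if gene in pos_set and rng.random() < config.detect_prob:
                records[gene] = float(rng.beta(config.beta_a, 1.0))
                alts.append(gene)
            else:
                records[gene] = float(rng.random())
        screens.append(
            ScreenResult(
                screen_id=screen_id,
                measure_name="p",
                records=records,
                tested=set(tested),
            )
        )
        tested_masks[screen_id] = frozenset(tested)
        alt_draws[screen_id] = frozenset(alts)

    truth = SyntheticTruth(
        positives=positives, tested=tested_masks, alternative_draws=alt_draws
    )
    return space, screens, truth


def simulate_expression(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, list[str], tuple[str, ...]]:
    """Two-group expression matrix with the planted set mean-shifted.

    Counts are log-normal: per-gene baseline mu_g ~ N(baseline_mean,
    baseline_sd), sample values 2**N(mu_g, sigma); group-1 ("T") samples of
    planted genes use mu_g + shift.  Returns (genes x samples DataFrame,
    column labels, planted gene tuple).  Labels are balanced: the first
    n_per_group columns are group "T", the rest "P".
    """
    config.validate()
    expr = config.expression
    symbols = _symbols(config.n_genes)
    positives = _positives(config)
    pos_mask = np.isin(np.array(symbols), np.array(positives))

    rng = _rng(config, _STREAM_EXPRESSION)
    n = expr.n_per_group
    mu = rng.normal(expr.baseline_mean, expr.baseline_sd, size=config.n_genes)
    log_t = rng.normal(mu[:, None], expr.sigma, size=(config.n_genes, n))
    log_p = rng.normal(mu[:, None], expr.sigma, size=(config.n_genes, n))
    log_t[pos_mask, :] += expr.shift
    counts = np.power(2.0, np.concatenate([log_t, log_p], axis=1))
    columns = [f"T{i:02d}" for i in range(1, n + 1)] + [
        f"P{i:02d}" for i in range(1, n + 1)
    ]
    labels = ["T"] * n + ["P"] * n
    matrix = pd.DataFrame(counts, index=list(symbols), columns=columns)
    return matrix, labels, positives


def simulate_annotations(
    space: GeneSpace,
    n_terms: int = 50,
    size_range: tuple[int, int] = (10, 100),
    seed: int = 0,
    enriched_genes: Sequence[str] = (),
    odds_ratio: float = 1.0,
) -> GeneSetCollection:
    """Random gene-set collection over the space, optionally with one term
    ("TERM_ENRICHED") whose membership favors ``enriched_genes`` at the given
    odds ratio (weighted sampling without replacement)."""
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(space)):
        raise ValueError(
            f"size_range {size_range} invalid for a space of {len(space)} genes"
        )
    if odds_ratio < 1.0:
        raise ValueError(f"odds_ratio must be >= 1, got {odds_ratio}")
    rng = np.random.default_rng(seed)
    symbols = np.array(space.symbols)
    collection = GeneSetCollection()
    for t in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(symbols), size=size, replace=False)
        collection.add(
            GeneSet(
                term_id=f"TERM_{t:03d}",
                term_name=f"synthetic term {t}",
                genes=tuple(symbols[np.sort(idx)]),
            )
        )
    if enriched_genes:
        size = int(rng.integers(lo, hi + 1))
        weights = np.ones(len(symbols))
        enriched_set = set(enriched_genes)
        weights[[i for i, s in enumerate(symbols) if s in enriched_set]] = odds_ratio
        idx = rng.choice(
            len(symbols), size=size, replace=False, p=weights / weights.sum()
        )
        collection.add(
            GeneSet(
                term_id="TERM_ENRICHED",
                term_name="synthetic term enriched for planted positives",
                genes=tuple(symbols[np.sort(idx)]),
            )
        )
    return collection


def simulate_target_list(
    space: GeneSpace, n_targets: int = 50, seed: int = 0
) -> tuple[str, ...]:
    """A synthetic known-therapeutic-target list: a random draw from the space."""
    if not (0 <= n_targets <= len(space)):
        raise ValueError(f"n_targets must be in [0, {len(space)}], got {n_targets}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(space), size=n_targets, replace=False)
    symbols = np.array(space.symbols)
    return tuple(symbols[np.sort(idx)])


def write_screens(
    screens: Sequence[ScreenResult], outdir, space: GeneSpace | None = None
) -> list:
    """Write screens as loader-compatible TSVs (round-trip fixture support)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for screen in screens:
        path = outdir / f"{screen.screen_id}.tsv"
        rows = [
            {"gene": g, "p": screen.records.get(g, "")}
            for g in sorted(screen.tested)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        paths.append(path)
    if space is not None:
        space_path = outdir / "gene_space.txt"
        space_path.write_text("\n".join(space.symbols) + "\n", encoding="utf-8")
        paths.append(space_path)
    return paths
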