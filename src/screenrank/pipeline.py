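"""End-to-end orchestration: screens -> rankers -> overlap + aggregation ->
top-k gene set -> ORA + novelty -> preranked GSEA, with a machine-readable
run summary and full provenance (resolved config written next to outputs).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .base_ranker import build_base_ranker
from .enrichment import annotate_novelty, hypergeometric_enrichment, write_results_tsv
from .gene_space_io import (
    GeneSetCollection,
    GeneSpace,
    ScreenResult,
    check_against_space,
    load_gene_space,
    load_screen_table,
    read_gmt,
    write_gmt,
)
from .gsea import gsea_preranked, rank_metric, simple_de
from .gsea import results_to_frame as gsea_frame
from .overlap_analysis import compute_overlap, select_multi_screen_candidates
from .rank_aggregation import aggregate_geometric, select_top_k
from .synthetic_data import (
    SyntheticConfig,
    simulate_annotations,
    simulate_expression,
    simulate_screens,
    simulate_target_list,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunSummary", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the underlying cause."""


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Either ``synthetic`` is set (self-contained simulated run) or the path
    fields point at real inputs.  Threshold defaults are the analysis
    constants: alpha 0.05 (significance within a screen), min_screens 2
    (overlap selection), top_k 100 (GSEA gene set), GSEA FDR threshold 0.25.
    """

    outdir: str = "results/run"
    seed: int = 0
    alpha: float = 0.05
    min_screens: int = 2
    top_k: int = 100
    gsea_n_perm: int = 1000
    gsea_p_exp: float = 1.0
    gsea_fdr_threshold: float = 0.25
    synthetic: SyntheticConfig | None = None
    gene_space_path: str | None = None
    screen_tables: list[dict[str, str]] = field(default_factory=list)
    drivers_path: str | None = None
    gene_sets_path: str | None = None
    targets_path: str | None = None
    de_table_path: str | None = None
    run_gsea: bool = True

    def validate(self) -> None:
        for name in ("alpha", "top_k", "gsea_n_perm", "gsea_fdr_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_screens < 1:
            raise ValueError("min_screens must be >= 1")
        if self.synthetic is None and not (self.gene_space_path and self.screen_tables):
            raise ValueError(
                "config needs either a synthetic block or gene_space_path + screen_tables"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic", None)
        config = cls(**raw)
        if synth is not None:
            from .synthetic_data import ExpressionConfig

            expr = synth.pop("expression", None)
            if expr is not None:
                synth["expression"] = ExpressionConfig(**expr)
            if "coverages" in synth:
                synth["coverages"] = tuple(synth["coverages"])
            config.synthetic = SyntheticConfig(**synth)
        return config

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        if self.synthetic is not None:
            raw["synthetic"] = dataclasses.asdict(self.synthetic)
            raw["synthetic"]["coverages"] = list(self.synthetic.coverages)
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class RunSummary:
    seed: int
    version: str
    method_tag: str
    n_screens: int
    n_space: int
    n_candidates_aggregated: int
    n_overlap_candidates: int
    n_known_targets: int
    n_novel: int
    gsea: list[dict[str, float | str | bool]]
    outputs: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _stage(name: str):
    """Wrap a stage so failures abort with the stage name and cause."""

    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return decorator


def _load_inputs(config: RunConfig, outdir: Path):
    if config.synthetic is not None:
        synth = dataclasses.replace(config.synthetic, seed=config.seed)
        space, screens, truth = simulate_screens(synth)
        drivers: tuple[str, ...] = ()
        hi = max(2, min(100, len(space) // 5))
        gene_sets = simulate_annotations(
            space,
            size_range=(min(10, hi), hi),
            seed=config.seed,
            enriched_genes=truth.positives,
            odds_ratio=8.0,
        )
        targets = simulate_target_list(space, seed=config.seed)
        return space, screens, drivers, gene_sets, targets, synth, truth
    space = load_gene_space(config.gene_space_path)
    screens = [
        load_screen_table(
            spec["path"],
            screen_id=spec.get("screen_id", Path(spec["path"]).stem),
            measure_column=spec.get("measure_column", "p"),
            gene_column=spec.get("gene_column", "gene"),
        )
        for spec in config.screen_tables
    ]
    drivers = ()
    if config.drivers_path:
        drivers = tuple(load_gene_space(config.drivers_path).symbols)
    gene_sets = read_gmt(config.gene_sets_path) if config.gene_sets_path else None
    targets = (
        tuple(load_gene_space(config.targets_path).symbols)
        if config.targets_path
        else ()
    )
    return space, screens, drivers, gene_sets, targets, None, None


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute every stage and write all outputs under ``config.outdir``.

    Re-running with the same config and seed reproduces every output file
    (timestamps aside).  Any stage error aborts with the stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.resolved.yaml")
    outputs: dict[str, str] = {"config": str(outdir / "config.resolved.yaml")}

    load = _stage("load_inputs")(_load_inputs)
    space, screens, drivers, gene_sets, targets, synth, truth = load(config, outdir)

    @_stage("base_rankers")
    def _rankers():
        rankers = []
        for screen in screens:
            check_against_space(screen, space)
            rankers.append(build_base_ranker(screen, alpha=config.alpha))
        import pandas as pd

        frame = pd.concat([r.to_frame() for r in rankers], ignore_index=True)
        path = outdir / "base_rankers.tsv"
        frame.to_csv(path, sep="\t", index=False)
        outputs["base_rankers"] = str(path)
        return rankers

    rankers = _rankers()

    @_stage("overlap")
    def _overlap():
        table = compute_overlap(rankers)
        path = outdir / "overlap.tsv"
        table.write_tsv(path, rankers)
        outputs["overlap"] = str(path)
        selected = select_multi_screen_candidates(
            table, min_count=config.min_screens, drivers=drivers
        )
        sel_path = outdir / "overlap_candidates.txt"
        sel_path.write_text("\n".join(selected) + ("\n" if selected else ""), "utf-8")
        outputs["overlap_candidates"] = str(sel_path)
        return table, selected

    overlap_table, overlap_candidates = _overlap()

    @_stage("aggregation")
    def _aggregate():
        agg = aggregate_geometric(rankers, space)
        path = outdir / "aggregated.tsv"
        agg.write_tsv(path, candidates_only=True)
        outputs["aggregated"] = str(path)
        return agg

    aggregated = _aggregate()
    candidates = [e.gene for e in aggregated.candidates]

    @_stage("top_k_set")
    def _top_set():
        k = min(config.top_k, len(candidates))
        if k < config.top_k:
            logger.warning(
                "top_k %d exceeds candidate count %d; using all candidates",
                config.top_k, len(candidates),
            )
        gene_set = select_top_k(aggregated, k)
        coll = GeneSetCollection()
        coll.add(gene_set)
        path = outdir / "top_candidates.gmt"
        write_gmt(coll, path)
        outputs["top_set"] = str(path)
        return gene_set

    top_set = _top_set()

    @_stage("overrepresentation")
    def _ora():
        if gene_sets is None or len(gene_sets) == 0:
            logger.info("no gene-set collection supplied; skipping ORA")
            return None
        results = hypergeometric_enrichment(candidates, gene_sets, space)
        path = outdir / "ora.tsv"
        write_results_tsv(results, path)
        outputs["ora"] = str(path)
        return results

    _ora()

    @_stage("novelty")
    def _novelty():
        known, novel = annotate_novelty(candidates, targets)
        path = outdir / "novelty.tsv"
        with path.open("w", encoding="utf-8") as fh:
            fh.write("gene\tstatus\n")
            for g in known:
                fh.write(f"{g}\tknown_target\n")
            for g in novel:
                fh.write(f"{g}\tnovel\n")
        outputs["novelty"] = str(path)
        return known, novel

    known, novel = _novelty()

    gsea_rows: list[dict[str, float | str | bool]] = []
    if config.run_gsea:

        @_stage("gsea")
        def _gsea():
            import pandas as pd

            if synth is not None:
                matrix, labels, _ = simulate_expression(synth)
                de = simple_de(matrix, labels, group1="T")
            elif config.de_table_path:
                de = pd.read_csv(config.de_table_path, sep=None, engine="python")
            else:
                logger.info("no expression or DE input; skipping GSEA")
                return []
            de_path = outdir / "de_table.tsv"
            de.to_csv(de_path, sep="\t", index=False)
            outputs["de_table"] = str(de_path)
            metric = rank_metric(de)
            coll = GeneSetCollection()
            coll.add(top_set)
            results = gsea_preranked(
                metric,
                coll,
                n_perm=config.gsea_n_perm,
                seed=config.seed,
                p_exp=config.gsea_p_exp,
            )
            path = outdir / "gsea.tsv"
            gsea_frame(results).to_csv(path, sep="\t", index=False)
            outputs["gsea"] = str(path)
            return [
                {
                    "gene_set": r.gene_set_name,
                    "es": r.es,
                    "nes": r.nes,
                    "nominal_p": r.nominal_p,
                    "fdr_q": r.fdr_q,
                    "passes_fdr_threshold": bool(r.fdr_q < config.gsea_fdr_threshold),
                }
                for r in results
            ]

        gsea_rows = _gsea()

    summary = RunSummary(
        seed=config.seed,
        version=__version__,
        method_tag=aggregated.method_tag,
        n_screens=len(screens),
        n_space=len(space),
        n_candidates_aggregated=len(candidates),
        n_overlap_candidates=len(overlap_candidates),
        n_known_targets=len(known),
        n_novel=len(novel),
        gsea=gsea_rows,
        outputs=outputs,
    )
    summary.to_json(outdir / "summary.json")
    logger.info(
        "pipeline done: %d aggregated candidates (%d known targets, %d novel), "
        "%d overlap candidates",
        summary.n_candidates_aggregated,
        summary.n_known_targets,
        summary.n_novel,
        summary.n_overlap_candidates,
    )
    return summary
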