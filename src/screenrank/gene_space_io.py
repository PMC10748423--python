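"""Loading, validation and harmonization of gene spaces, screen tables and gene sets.

All downstream analysis is defined over a fixed *underlying space* of gene
symbols (for the motivating application, a GRCm38 symbol set).  Screens from
different labs and organisms report symbols in inconsistent case
(mouse ``Aak1`` vs human ``AAK1``); harmonization here is deliberately minimal
— trim whitespace and uppercase — because true ortholog mapping is out of
scope and case-folded symbol identity is the working stand-in.

Formats are deliberately plain: one-symbol-per-line gene spaces, delimited
screen tables with a header, and GMT gene-set collections.  Loading never
silently drops a record: every de-duplication or exclusion is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSpace",
    "ScreenResult",
    "GeneSet",
    "GeneSetCollection",
    "harmonize_symbol",
    "load_gene_space",
    "load_screen_table",
    "read_gmt",
    "write_gmt",
]


def harmonize_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: whitespace-trimmed, uppercased.

    Idempotent and total on non-empty strings.  Raises ``ValueError`` on an
    empty (or all-whitespace) symbol.
    """
    if not isinstance(symbol, str):
        raise ValueError(f"gene symbol must be a string, got {type(symbol).__name__}")
    out = symbol.strip().upper()
    if not out:
        raise ValueError("empty gene symbol")
    return out


@dataclass(frozen=True)
class GeneSpace:
    """The fixed universe of gene symbols over which aggregation and
    enrichment backgrounds are defined.

    Symbols are unique (post-harmonization) and keep first-seen order.
    """

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise ValueError("empty gene space")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("gene space symbols are not unique")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: object) -> bool:
        return symbol in self._index

    def __iter__(self):
        return iter(self.symbols)

    @property
    def _index(self) -> frozenset:
        # cached membership set; frozen dataclass, so stash via __dict__
        cached = self.__dict__.get("_index_cache")
        if cached is None:
            cached = frozenset(self.symbols)
            object.__setattr__(self, "_index_cache", cached)
        return cached

    @classmethod
    def from_symbols(cls, symbols: Iterable[str]) -> "GeneSpace":
        """Harmonize, de-duplicate (first-seen order) and wrap symbols."""
        seen: dict[str, None] = {}
        n_dup = 0
        for s in symbols:
            h = harmonize_symbol(s)
            if h in seen:
                n_dup += 1
            else:
                seen[h] = None
        if n_dup:
            logger.warning("gene space: de-duplicated %d repeated symbol(s)", n_dup)
        return cls(tuple(seen))


@dataclass
class ScreenResult:
    """One screen's tested genes and their significance measures.

    ``records`` maps gene -> significance value in [0, 1] (p-value or FDR as
    published by the original authors).  ``tested`` may be a superset of
    ``records``: screens that publish only a hit list plus library membership
    yield tested-but-unmeasured genes.  ``direction_labels`` optionally carries
    predicted gain/loss-of-function calls; ``effect_sizes`` optionally carries
    a per-gene effect magnitude used only for tie-breaking.
    """

    screen_id: str
    measure_name: str
    records: dict[str, float]
    tested: set[str]
    direction_labels: dict[str, str] | None = None
    effect_sizes: dict[str, float] | None = None

    def __post_init__(self) -> None:
        missing = set(self.records) - self.tested
        if missing:
            raise ValueError(
                f"screen {self.screen_id!r}: {len(missing)} measured gene(s) not in tested set"
            )
        bad = {g: v for g, v in self.records.items() if not (0.0 <= v <= 1.0)}
        if bad:
            g, v = next(iter(bad.items()))
            raise ValueError(
                f"screen {self.screen_id!r}: significance measure out of [0,1] "
                f"for {g!r} ({v!r})"
            )


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.term_id!r} has no members")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.term_id!r} has duplicated members")


@dataclass
class GeneSetCollection:
    """Named term -> member-gene sets (GMT-shaped)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]

    def add(self, gene_set: GeneSet) -> None:
        self.sets[gene_set.term_id] = gene_set


def load_gene_space(path: str | Path) -> GeneSpace:
    """Read a one-symbol-per-line gene space file.

    Blank lines and lines starting with ``#`` are ignored.  Symbols are
    harmonized and de-duplicated (first-seen order, warning on duplicates).
    An empty file raises ``ValueError("empty gene space")``.
    """
    path = Path(path)
    symbols: list[str] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbols.append(line)
    if not symbols:
        raise ValueError("empty gene space")
    return GeneSpace.from_symbols(symbols)


def _sniff_sep(path: Path) -> str:
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if line.count("\t") >= line.count(",") else ","
    return "\t"


def load_screen_table(
    path: str | Path,
    screen_id: str,
    measure_column: str,
    gene_column: str = "gene",
    measure_name: str | None = None,
    effect_column: str | None = None,
    direction_column: str | None = None,
) -> ScreenResult:
    """Load one screen's candidate table (TSV or CSV, auto-detected).

    Rows with an empty significance cell are recorded as tested-only.  A
    measure outside [0, 1] is an error naming the offending row; unknown
    columns are an error.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    for col in filter(None, [gene_column, measure_column, effect_column, direction_column]):
        if col not in df.columns:
            raise ValueError(
                f"screen table {path.name}: unknown column {col!r} "
                f"(have: {', '.join(df.columns)})"
            )

    records: dict[str, float] = {}
    tested: set[str] = set()
    effects: dict[str, float] = {}
    directions: dict[str, str] = {}
    n_dup = 0
    for i, row in enumerate(df.to_dict("records"), start=2):  # header is row 1
        gene = harmonize_symbol(str(row[gene_column]))
        if gene in tested:
            n_dup += 1
        tested.add(gene)
        raw = row[measure_column]
        if pd.isna(raw) or str(raw).strip() == "":
            pass  # tested but unmeasured
        else:
            try:
                value = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"screen table {path.name} row {i}: measure {raw!r} is not a number"
                ) from exc
            if not (0.0 <= value <= 1.0):
                raise ValueError(
                    f"screen table {path.name} row {i}: measure {value} outside [0,1]"
                )
            records[gene] = value
        if effect_column is not None:
            raw_e = row[effect_column]
            if not pd.isna(raw_e) and str(raw_e).strip() != "":
                effects[gene] = float(raw_e)
        if direction_column is not None:
            raw_d = row[direction_column]
            if not pd.isna(raw_d) and str(raw_d).strip() != "":
                directions[gene] = str(raw_d).strip()
    if n_dup:
        logger.warning("screen %s: %d duplicated gene row(s) collapsed", screen_id, n_dup)
    return ScreenResult(
        screen_id=screen_id,
        measure_name=measure_name or measure_column,
        records=records,
        tested=tested,
        direction_labels=directions or None,
        effect_sizes=effects or None,
    )


def check_against_space(screen: ScreenResult, space: GeneSpace) -> list[str]:
    """Report (not drop) screen genes absent from the underlying space.

    Such genes stay in the screen's own ranking but are excluded from
    aggregation output; callers log the returned list.
    """
    outside = sorted(g for g in screen.tested if g not in space)
    if outside:
        logger.warning(
            "screen %s: %d tested gene(s) outside the gene space (kept in screen, "
            "excluded from aggregation)",
            screen.screen_id,
            len(outside),
        )
    return outside


def read_gmt(path: str | Path, harmonize: bool = True) -> GeneSetCollection:
    """Read a GMT file: ``term_id TAB description TAB gene1 TAB gene2 ...``.

    A line with fewer than 3 fields is an error naming the line number.
    Duplicated members within a line are de-duplicated with a warning.
    """
    path = Path(path)
    collection = GeneSetCollection()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT {path.name} line {lineno}: fewer than 3 fields")
            term_id, description, *members = fields
            members = [m for m in members if m.strip()]
            if harmonize:
                members = [harmonize_symbol(m) for m in members]
            seen: dict[str, None] = {}
            for m in members:
                if m in seen:
                    logger.warning(
                        "GMT %s line %d: duplicated member %s de-duplicated",
                        path.name, lineno, m,
                    )
                else:
                    seen[m] = None
            collection.add(GeneSet(term_id=term_id, term_name=description, genes=tuple(seen)))
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; ``read_gmt(write_gmt(c))`` is lossless."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for gene_set in collection:
            fh.write("\t".join([gene_set.term_id, gene_set.term_name, *gene_set.genes]) + "\n")
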