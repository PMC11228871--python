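"""Text-format I/O for arrayed colony screens.

All on-disk formats are UTF-8 tab-separated values with ``#`` comment lines
and 1-based (row, col) plate coordinates, the convention used by plate
robotics. Temperatures are opaque condition labels (``"30C"``, ``"19C"``);
the pipeline never does arithmetic on them.

Formats
-------
colony table : plate_id, temperature, replicate, row, col, gene_id, size
    One row per pinned colony. An empty ``size`` field means the colony is
    missing (failed pinning), which is distinct from a measured size of 0
    (a dead colony). ``gene_id`` may be omitted if a layout resolves it.
layout table : plate_id, row, col, gene_id
    Grid position -> deletion-strain gene for each physical plate. The grid
    dimensions are recorded in a ``# grid=RxC`` comment.
annotation table : gene_id, term_id, term_name
    Flat gene -> ontology-group associations (a minimal GAF-like dialect,
    assumed pre-slimmed; no ontology-graph propagation is performed).
manifest : YAML file naming one query screen's colony tables and the
    reference/cold temperature labels.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, IntegrityError, ParseError

#: Sentinel gene identifier for an intentionally empty grid position.
EMPTY = "EMPTY"

COLONY_COLUMNS = ["plate_id", "temperature", "replicate", "row", "col", "gene_id", "size"]
LAYOUT_COLUMNS = ["plate_id", "row", "col", "gene_id"]
ANNOTATION_COLUMNS = ["gene_id", "term_id", "term_name"]

_POSITION_KEY = ["plate_id", "temperature", "replicate", "row", "col"]
_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


@dataclass(frozen=True)
class PlateLayout:
    """Grid-position -> gene map for one physical plate.

    ``positions`` maps 1-based (row, col) to a gene identifier. Positions
    holding :data:`EMPTY` are omitted. A gene may occupy several positions
    (replicate spots) but each position is unique by construction.
    """

    plate_id: str
    grid_rows: int
    grid_cols: int
    positions: Mapping[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigurationError("grid dimensions must be positive")
        for (r, c), gene in self.positions.items():
            if not (1 <= r <= self.grid_rows and 1 <= c <= self.grid_cols):
                raise IntegrityError(
                    f"plate {self.plate_id!r}: position ({r}, {c}) outside "
                    f"{self.grid_rows}x{self.grid_cols} grid"
                )
            if not gene:
                raise IntegrityError(f"plate {self.plate_id!r}: empty gene_id at ({r}, {c})")

    def gene_at(self, row: int, col: int) -> str | None:
        return self.positions.get((row, col))


@dataclass(frozen=True)
class ScreenManifest:
    """Input description for one query screen.

    ``colony_tables`` lists the colony-size TSVs holding this screen's
    measurements (any split across files is allowed). Both temperature
    labels must occur in the data; each must have at least one replicate.
    """

    query_label: str
    ref_temperature: str
    cold_temperature: str
    colony_tables: tuple[str, ...]
    layout: str | None = None

    def __post_init__(self) -> None:
        if not self.query_label:
            raise ConfigurationError("manifest needs a query_label")
        if self.ref_temperature == self.cold_temperature:
            raise ConfigurationError("reference and cold temperature labels must differ")
        if not self.colony_tables:
            raise ConfigurationError("manifest lists no colony tables")


@dataclass
class GeneAnnotation:
    """Flat gene -> ontology-term associations plus term names."""

    gene_to_terms: dict[str, set[str]]
    term_names: dict[str, str]

    def __post_init__(self) -> None:
        for gene, terms in self.gene_to_terms.items():
            if not isinstance(gene, str) or not gene:
                raise IntegrityError("annotated gene_id must be a nonempty string")
            if not terms:
                raise IntegrityError(f"gene {gene!r} has an empty term set")

    def term_to_genes(self) -> dict[str, set[str]]:
        """Invert the association map (term -> genes)."""
        out: dict[str, set[str]] = {}
        for gene, terms in self.gene_to_terms.items():
            for term in terms:
                out.setdefault(term, set()).add(gene)
        return out


# ---------------------------------------------------------------------------
# colony tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: list[str], optional: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def _to_int(df: pd.DataFrame, col: str, path: str | Path) -> pd.Series:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = coerced.isna() | (coerced != coerced.round())
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 1-based (comment lines not counted)
        raise ParseError(f"{path}: data row {row}: column {col!r} is not an integer: {df[col][bad.idxmax()]!r}")
    return coerced.astype(int)


def read_colony_table(path: str | Path, layouts: Mapping[str, PlateLayout] | None = None) -> pd.DataFrame:
    """Read a colony-size table.

    Returns a DataFrame with columns plate_id, temperature, replicate (int),
    row (int), col (int), gene_id (str or NaN), size (float, NaN = missing
    colony). If ``layouts`` is given, gene identities are resolved from it;
    a per-row gene_id that disagrees with the layout is an integrity error
    (no silent precedence).
    """
    required = [c for c in COLONY_COLUMNS if c != "gene_id"]
    df = _read_tsv(path, required)
    if "gene_id" not in df.columns:
        if layouts is None:
            raise ParseError(f"{path}: no gene_id column and no layout supplied")
        df["gene_id"] = ""

    out = pd.DataFrame({
        "plate_id": df["plate_id"],
        "temperature": df["temperature"],
        "replicate": _to_int(df, "replicate", path),
        "row": _to_int(df, "row", path),
        "col": _to_int(df, "col", path),
        "gene_id": df["gene_id"].mask(df["gene_id"] == ""),
    })
    size = pd.to_numeric(df["size"].mask(df["size"] == ""), errors="coerce")
    bad = size.isna() & (df["size"] != "")
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise ParseError(f"{path}: data row {row}: column 'size' is not a number: {df['size'][bad.idxmax()]!r}")
    if (size.dropna() < 0).any():
        raise IntegrityError(f"{path}: negative colony size")
    out["size"] = size

    if (out["row"] < 1).any() or (out["col"] < 1).any() or (out["replicate"] < 1).any():
        raise IntegrityError(f"{path}: row, col and replicate must be >= 1")
    dup = out.duplicated(subset=_POSITION_KEY)
    if dup.any():
        first = out.loc[dup.idxmax(), _POSITION_KEY].tolist()
        raise IntegrityError(f"{path}: duplicated position {tuple(first)}")

    if layouts is not None:
        resolved = []
        for rec in out.itertuples(index=False):
            layout = layouts.get(rec.plate_id)
            if layout is None:
                raise IntegrityError(f"{path}: plate {rec.plate_id!r} has no layout")
            if rec.row > layout.grid_rows or rec.col > layout.grid_cols:
                raise IntegrityError(
                    f"{path}: position ({rec.row}, {rec.col}) outside plate {rec.plate_id!r} grid"
                )
            gene = layout.gene_at(rec.row, rec.col)
            if isinstance(rec.gene_id, str) and gene is not None and rec.gene_id != gene:
                raise IntegrityError(
                    f"{path}: gene_id {rec.gene_id!r} disagrees with layout gene {gene!r} "
                    f"at plate {rec.plate_id!r} ({rec.row}, {rec.col})"
                )
            resolved.append(rec.gene_id if isinstance(rec.gene_id, str) else gene)
        out["gene_id"] = resolved
    return out


def write_colony_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a colony table; missing sizes become empty fields."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# coldscreen colony table; tab-separated; 1-based coordinates\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="", float_format=_FLOAT_FMT,
                  columns=COLONY_COLUMNS, lineterminator="\n")


# ---------------------------------------------------------------------------
# layouts
# ---------------------------------------------------------------------------

_GRID_RE = re.compile(r"grid=(\d+)x(\d+)")


def read_layout(path: str | Path) -> dict[str, PlateLayout]:
    """Read a layout table; returns one :class:`PlateLayout` per plate_id."""
    path = Path(path)
    grid: tuple[int, int] | None = None
    if path.exists():
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                m = _GRID_RE.search(line)
                if m:
                    grid = (int(m.group(1)), int(m.group(2)))
                if not line.startswith("#"):
                    break
    df = _read_tsv(path, LAYOUT_COLUMNS)
    rows = _to_int(df, "row", path)
    cols = _to_int(df, "col", path)
    if grid is None:
        grid = (int(rows.max()) if len(rows) else 1, int(cols.max()) if len(cols) else 1)
    if df.duplicated(subset=["plate_id", "row", "col"]).any():
        raise IntegrityError(f"{path}: duplicated layout position")
    layouts: dict[str, dict[tuple[int, int], str]] = {}
    for plate, r, c, gene in zip(df["plate_id"], rows, cols, df["gene_id"]):
        if gene == EMPTY:
            continue
        layouts.setdefault(plate, {})[(int(r), int(c))] = gene
    return {
        plate: PlateLayout(plate, grid[0], grid[1], positions)
        for plate, positions in layouts.items()
    }


def write_layout(layouts: Iterable[PlateLayout], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    layouts = list(layouts)
    if not layouts:
        raise ConfigurationError("no layouts to write")
    dims = {(lo.grid_rows, lo.grid_cols) for lo in layouts}
    if len(dims) != 1:
        raise ConfigurationError("all layouts in one file must share grid dimensions")
    (rows, cols), = dims
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# coldscreen plate layout; 1-based coordinates; grid={rows}x{cols}\n")
        fh.write("\t".join(LAYOUT_COLUMNS) + "\n")
        for lo in layouts:
            for (r, c) in sorted(lo.positions):
                fh.write(f"{lo.plate_id}\t{r}\t{c}\t{lo.positions[(r, c)]}\n")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> GeneAnnotation:
    df = _read_tsv(path, ANNOTATION_COLUMNS)
    gene_to_terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    for i, (gene, term, name) in enumerate(zip(df["gene_id"], df["term_id"], df["term_name"])):
        if not gene:
            raise ParseError(f"{path}: data row {i + 2}: empty gene_id")
        if not term:
            raise ParseError(f"{path}: data row {i + 2}: empty term_id")
        if term in term_names and term_names[term] != name:
            raise IntegrityError(f"{path}: term {term!r} has conflicting names")
        term_names[term] = name
        gene_to_terms.setdefault(gene, set()).add(term)
    return GeneAnnotation(gene_to_terms, term_names)


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# coldscreen gene annotation; gene_id -> ontology term\n")
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for gene in sorted(annotation.gene_to_terms):
            for term in sorted(annotation.gene_to_terms[gene]):
                fh.write(f"{gene}\t{term}\t{annotation.term_names.get(term, '')}\n")


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> ScreenManifest:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: manifest must be a mapping")
    known = {"query_label", "ref_temperature", "cold_temperature", "colony_tables", "layout"}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigurationError(f"{path}: unknown manifest key(s): {unknown}")
    try:
        return ScreenManifest(
            query_label=data["query_label"],
            ref_temperature=data.get("ref_temperature", "30C"),
            cold_temperature=data.get("cold_temperature", "19C"),
            colony_tables=tuple(data.get("colony_tables", ())),
            layout=data.get("layout"),
        )
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing manifest key {exc}") from exc


def write_manifest(manifest: ScreenManifest, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {
        "query_label": manifest.query_label,
        "ref_temperature": manifest.ref_temperature,
        "cold_temperature": manifest.cold_temperature,
        "colony_tables": list(manifest.colony_tables),
    }
    if manifest.layout is not None:
        data["layout"] = manifest.layout
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
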