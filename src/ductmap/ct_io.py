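"""Ct-matrix I/O and expression transformation.

Single-cell qPCR data arrive as cycle-threshold (Ct) matrices: one row per
captured cell, one column per gene assay.  A reaction either crosses the
fluorescence threshold at some cycle Ct in (0, 40] or never fires, in which
case the export carries a sentinel code (999 by convention for Biomark
exports).  Downstream analysis works on the limit-of-detection referenced
expression value

    Et = max(0, LOD - Ct)

in log2 units (one PCR cycle is one doubling), so non-detects and reactions
at or beyond the LOD map to zero expression.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GROUPS",
    "NONDETECT_CODE",
    "DEFAULT_LOD",
    "CT_MAX",
    "GenePanel",
    "CellMeta",
    "CtMatrix",
    "ExpressionMatrix",
    "load_ct_matrix",
    "write_ct_matrix",
    "ct_to_expression",
    "qc_filter",
]

#: Experimental groups: littermate controls, surgical controls (day-3 plombage
#: and phrenic-nerve transection), and post-pneumonectomy days 1, 3 and 7.
GROUPS = ("littermate_control", "surgical_control", "day1", "day3", "day7")

#: Sentinel for a reaction that never crossed threshold (Biomark convention).
NONDETECT_CODE = 999.0

#: Default limit of detection, in PCR cycles.
DEFAULT_LOD = 24.0

#: PCR cycle-count ceiling; any finite Ct must lie in (0, CT_MAX].
CT_MAX = 40.0

_META_COLUMNS = ("cell_id", "group")


class CtParseError(ValueError):
    """Raised when a Ct file violates the format contract."""


@dataclass(frozen=True)
class GenePanel:
    """An ordered qPCR assay panel (default size 96)."""

    gene_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.gene_names) == 0:
            raise ValueError("gene panel must be non-empty")
        if len(set(self.gene_names)) != len(self.gene_names):
            dupes = sorted({g for g in self.gene_names if list(self.gene_names).count(g) > 1})
            raise ValueError(f"duplicate gene names in panel: {dupes}")

    @property
    def size(self) -> int:
        return len(self.gene_names)

    def index_of(self, genes: Iterable[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes not in panel: {missing}")
        return np.array([pos[g] for g in genes], dtype=int)


@dataclass(frozen=True)
class CellMeta:
    """Per-cell metadata for a capture site.

    Only ``capture_flag == "single"`` cells enter analysis; sites flagged
    ``excluded`` (doublets, triplets, debris) are kept in files for
    book-keeping but never placed in matrices.
    """

    cell_id: str
    group: str
    capture_flag: str = "single"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.capture_flag not in ("single", "excluded"):
            raise ValueError(f"capture_flag must be 'single' or 'excluded', got {self.capture_flag!r}")


def _check_cells(cells: Sequence[CellMeta]) -> None:
    seen: set[str] = set()
    for c in cells:
        if c.cell_id in seen:
            raise ValueError(f"duplicate cell_id {c.cell_id!r}")
        seen.add(c.cell_id)


@dataclass(frozen=True)
class CtMatrix:
    """Censored Ct values for single cells over a gene panel.

    ``ct[i, g]`` is either a finite cycle threshold in (0, 40] or
    ``nondetect_code`` for a failed/undetected reaction.
    """

    cells: tuple[CellMeta, ...]
    panel: GenePanel
    ct: np.ndarray
    nondetect_code: float = NONDETECT_CODE

    def __post_init__(self) -> None:
        _check_cells(self.cells)
        ct = np.asarray(self.ct, dtype=float)
        if ct.shape != (len(self.cells), self.panel.size):
            raise ValueError(
                f"ct shape {ct.shape} does not match {len(self.cells)} cells x {self.panel.size} genes"
            )
        detected = ct != self.nondetect_code
        bad = detected & ~((ct > 0) & (ct <= CT_MAX) & np.isfinite(ct))
        if bad.any():
            i, g = np.argwhere(bad)[0]
            raise ValueError(
                f"Ct value {ct[i, g]!r} out of (0, {CT_MAX}] for cell "
                f"{self.cells[i].cell_id!r}, gene {self.panel.gene_names[g]!r}"
            )
        object.__setattr__(self, "ct", ct)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def detected(self) -> np.ndarray:
        """Boolean mask of reactions that produced a signal."""
        return self.ct != self.nondetect_code

    @property
    def groups(self) -> np.ndarray:
        return np.array([c.group for c in self.cells])

    @property
    def cell_ids(self) -> np.ndarray:
        return np.array([c.cell_id for c in self.cells])

    def subset(self, idx: np.ndarray) -> "CtMatrix":
        cells = tuple(self.cells[i] for i in np.atleast_1d(idx))
        return replace(self, cells=cells, ct=self.ct[idx])


@dataclass(frozen=True)
class ExpressionMatrix:
    """LOD-referenced log2 expression (Et = max(0, LOD - Ct))."""

    cells: tuple[CellMeta, ...]
    panel: GenePanel
    et: np.ndarray
    lod: float = DEFAULT_LOD

    def __post_init__(self) -> None:
        _check_cells(self.cells)
        et = np.asarray(self.et, dtype=float)
        if et.shape != (len(self.cells), self.panel.size):
            raise ValueError(
                f"et shape {et.shape} does not match {len(self.cells)} cells x {self.panel.size} genes"
            )
        if not np.isfinite(et).all() or (et < 0).any():
            raise ValueError("expression values must be finite and >= 0")
        object.__setattr__(self, "et", et)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def groups(self) -> np.ndarray:
        return np.array([c.group for c in self.cells])

    @property
    def cell_ids(self) -> np.ndarray:
        return np.array([c.cell_id for c in self.cells])

    def gene_values(self, gene: str) -> np.ndarray:
        (g,) = self.panel.index_of([gene])
        return self.et[:, g]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_ct_field(raw: str, *, row: int, column: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise CtParseError(f"non-numeric Ct value {raw!r} at row {row}, column {column!r}") from None


def load_ct_matrix(path: str | Path, dialect: str = "wide_csv") -> CtMatrix:
    """Read a Ct matrix from CSV.

    ``wide_csv``: columns ``cell_id, group, <gene>, <gene>, ...``.
    ``long_csv``: columns ``cell_id, group, gene, ct`` (one reaction per row);
    gene order follows first appearance, cell order follows first appearance.
    """
    path = Path(path)
    if dialect not in ("wide_csv", "long_csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CtParseError(f"{path}: empty file") from None
        rows = list(reader)

    if "cell_id" not in header:
        raise CtParseError(f"{path}: missing cell_id column")
    if "group" not in header:
        raise CtParseError(f"{path}: missing group column")

    if dialect == "wide_csv":
        id_col = header.index("cell_id")
        group_col = header.index("group")
        gene_cols = [(j, name) for j, name in enumerate(header) if name not in _META_COLUMNS]
        genes = [name for _, name in gene_cols]
        cells, ct_rows = [], []
        for i, row in enumerate(rows, start=1):
            try:
                cells.append(CellMeta(cell_id=row[id_col], group=row[group_col]))
            except ValueError as exc:
                raise CtParseError(f"{path}: row {i}: {exc}") from exc
            ct_rows.append([_parse_ct_field(row[j], row=i, column=name) for j, name in gene_cols])
        try:
            return CtMatrix(cells=tuple(cells), panel=GenePanel(tuple(genes)), ct=np.array(ct_rows))
        except ValueError as exc:
            raise CtParseError(f"{path}: {exc}") from exc

    # long_csv
    for col in ("gene", "ct"):
        if col not in header:
            raise CtParseError(f"{path}: missing {col} column")
    idx = {name: header.index(name) for name in ("cell_id", "group", "gene", "ct")}
    cell_order: dict[str, str] = {}
    gene_order: list[str] = []
    values: dict[tuple[str, str], float] = {}
    for i, row in enumerate(rows, start=1):
        cid, grp, gene = row[idx["cell_id"]], row[idx["group"]], row[idx["gene"]]
        if cid not in cell_order:
            cell_order[cid] = grp
        elif cell_order[cid] != grp:
            raise CtParseError(f"{path}: conflicting group for cell_id {cid!r} at row {i}")
        if gene not in gene_order:
            gene_order.append(gene)
        key = (cid, gene)
        if key in values:
            raise CtParseError(f"{path}: duplicate entry for cell {cid!r}, gene {gene!r} at row {i}")
        values[key] = _parse_ct_field(row[idx["ct"]], row=i, column="ct")
    try:
        cells = tuple(CellMeta(cell_id=c, group=g) for c, g in cell_order.items())
    except ValueError as exc:
        raise CtParseError(f"{path}: {exc}") from exc
    missing = [(c.cell_id, g) for c in cells for g in gene_order if (c.cell_id, g) not in values]
    if missing:
        raise CtParseError(f"{path}: missing reactions for {missing[:3]}...")
    ct = np.array([[values[(c.cell_id, g)] for g in gene_order] for c in cells])
    try:
        return CtMatrix(cells=cells, panel=GenePanel(tuple(gene_order)), ct=ct)
    except ValueError as exc:
        raise CtParseError(f"{path}: {exc}") from exc


def write_ct_matrix(ct: CtMatrix, path: str | Path, dialect: str = "wide_csv") -> None:
    """Write a Ct matrix as CSV (values to 2 decimals; sentinel written as-is)."""
    path = Path(path)

    def fmt(v: float) -> str:
        return f"{v:g}" if v == ct.nondetect_code else f"{v:.2f}"

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if dialect == "wide_csv":
            writer.writerow(["cell_id", "group", *ct.panel.gene_names])
            for cell, row in zip(ct.cells, ct.ct):
                writer.writerow([cell.cell_id, cell.group, *[fmt(v) for v in row]])
        elif dialect == "long_csv":
            writer.writerow(["cell_id", "group", "gene", "ct"])
            for cell, row in zip(ct.cells, ct.ct):
                for gene, v in zip(ct.panel.gene_names, row):
                    writer.writerow([cell.cell_id, cell.group, gene, fmt(v)])
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def ct_to_expression(ct: CtMatrix, lod: float = DEFAULT_LOD) -> ExpressionMatrix:
    """Convert censored Ct values to LOD-referenced log2 expression.

    Et[i, g] = max(0, lod - Ct[i, g]); non-detects and reactions at or past
    the LOD become 0.  Monotone decreasing in Ct, so any distance-based
    downstream stage sees the same neighbour structure regardless of the
    (affine) choice of reference.
    """
    if not (0 < lod <= CT_MAX):
        raise ValueError(f"lod must be in (0, {CT_MAX}], got {lod}")
    et = np.maximum(0.0, lod - ct.ct)
    et[~ct.detected] = 0.0
    return ExpressionMatrix(cells=ct.cells, panel=ct.panel, et=et, lod=lod)


def qc_filter(ct: CtMatrix, min_detected: int) -> CtMatrix:
    """Keep cells with at least ``min_detected`` detected genes, order preserved."""
    if min_detected < 0:
        raise ValueError("min_detected must be >= 0")
    keep = np.flatnonzero(ct.detected.sum(axis=1) >= min_detected)
    return ct.subset(keep)
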