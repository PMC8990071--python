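"""Cohort data model, delimited-text I/O, and record-level filters.

A cohort is a flat single-cell table: one row per segmented cell carrying
identifiers (cell, position, core, slide, patient), centroid coordinates in
pixels, a segmentation quality score in [0, 1], one intensity column per
panel marker, and an assigned cell type.  The canonical interchange format
is delimited text with a single header row; a column mapping
(:class:`FormatSpec`) adapts foreign headers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .panel import MarkerPanel, UNASSIGNED, default_panel

ID_COLUMNS = ("cell_id", "patient_id", "slide_id", "core_id", "position_id")
COORD_COLUMNS = ("x", "y")
MANDATORY_COLUMNS = ID_COLUMNS + COORD_COLUMNS + ("qc_score",)


@dataclass(frozen=True)
class CellRecord:
    """A single segmented cell (convenience view of one table row)."""

    cell_id: str
    patient_id: str
    slide_id: str
    core_id: str
    position_id: str
    x: float
    y: float
    qc_score: float
    intensities: Mapping[str, float]
    cell_type: str = UNASSIGNED


@dataclass
class CohortTable:
    """An ordered collection of cells plus the panel and a provenance log.

    ``cells`` holds one row per cell; marker intensities live in columns
    named exactly after the panel markers.  Derived columns (corrected
    intensities, model readouts) are added by downstream stages.
    """

    cells: pd.DataFrame
    panel: MarkerPanel = field(default_factory=default_panel)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def markers(self) -> tuple[str, ...]:
        return self.panel.names

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def copy(self) -> "CohortTable":
        return CohortTable(self.cells.copy(), self.panel, list(self.provenance))

    def record(self, i: int) -> CellRecord:
        row = self.cells.iloc[i]
        return CellRecord(
            cell_id=str(row["cell_id"]),
            patient_id=str(row["patient_id"]),
            slide_id=str(row["slide_id"]),
            core_id=str(row["core_id"]),
            position_id=str(row["position_id"]),
            x=float(row["x"]),
            y=float(row["y"]),
            qc_score=float(row["qc_score"]),
            intensities={m: float(row[m]) for m in self.markers},
            cell_type=str(row.get("cell_type", UNASSIGNED)),
        )

    def validate(self) -> None:
        """Enforce the record invariants; raise ``ValueError`` on breach."""
        df = self.cells
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"missing mandatory column: {col!r}")
        missing = [m for m in self.markers if m not in df.columns]
        if missing:
            raise ValueError(f"missing marker columns: {missing}")
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ValueError(f"duplicate cell_id: {dup!r}")
        qc = df["qc_score"].to_numpy(float)
        if np.any((qc < 0) | (qc > 1)):
            raise ValueError("qc_score outside [0, 1]")
        marker_values = df[list(self.markers)].to_numpy(float)
        if np.any(marker_values < 0):
            raise ValueError("negative marker intensity")
        if np.any(df[["x", "y"]].to_numpy(float) < 0):
            raise ValueError("negative coordinates")


@dataclass(frozen=True)
class FormatSpec:
    """How to read a foreign delimited file: delimiter and column mapping.

    ``columns`` maps canonical names (ids, coordinates, qc_score, marker
    names) to the header names used in the file; identity if omitted.
    """

    delimiter: str = ","
    columns: Mapping[str, str] | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "FormatSpec":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(
            delimiter=data.get("delimiter", ","),
            columns=data.get("columns"),
        )

    def rename_map(self) -> dict[str, str]:
        """file-header -> canonical-name mapping."""
        if not self.columns:
            return {}
        return {v: k for k, v in self.columns.items()}


def read_cohort(
    path: str | Path,
    format_spec: FormatSpec | None = None,
    panel: MarkerPanel | None = None,
) -> CohortTable:
    """Read a delimited single-cell table into a :class:`CohortTable`.

    Rows with non-numeric or missing intensities/coordinates are rejected
    with a warning; a missing mandatory column is a hard error naming it.
    """
    spec = format_spec or FormatSpec()
    panel = panel or default_panel()
    df = pd.read_csv(path, sep=spec.delimiter, dtype=str)
    df = df.rename(columns=spec.rename_map())

    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col!r}")
    missing = [m for m in panel.names if m not in df.columns]
    if missing:
        raise ValueError(f"missing marker column(s): {missing}")

    numeric_cols = list(COORD_COLUMNS) + ["qc_score"] + list(panel.names)
    parsed = df.copy()
    for col in numeric_cols:
        parsed[col] = pd.to_numeric(parsed[col], errors="coerce")
    bad = parsed[numeric_cols].isna().any(axis=1)
    n_rejected = int(bad.sum())
    if n_rejected:
        warnings.warn(
            f"rejected {n_rejected} malformed row(s) while reading {path}",
            stacklevel=2,
        )
    parsed = parsed.loc[~bad].reset_index(drop=True)
    if "cell_type" not in parsed.columns:
        parsed["cell_type"] = UNASSIGNED

    table = CohortTable(parsed, panel)
    table.log(f"read_cohort: {len(parsed)} records from {path}, {n_rejected} rejected")
    table.validate()
    return table


def write_cohort(
    table: CohortTable,
    path: str | Path,
    format_spec: FormatSpec | None = None,
) -> Path:
    """Write the cohort as delimited text; round-trips through ``read_cohort``.

    A sidecar ``<path>.provenance.log`` captures the table's operation log.
    """
    spec = format_spec or FormatSpec()
    path = Path(path)
    out = table.cells
    if spec.columns:
        out = out.rename(columns=dict(spec.columns))
    out.to_csv(path, sep=spec.delimiter, index=False)
    sidecar = path.with_name(path.name + ".provenance.log")
    sidecar.write_text("\n".join(table.provenance) + "\n" if table.provenance else "")
    return path


def filter_margins(
    table: CohortTable, x_margin: float = 15.0, y_margin: float = 10.0
) -> CohortTable:
    """Drop cells inside the image margins of their position.

    Margins are two-sided: a cell is removed when ``x < x_margin`` or
    ``x > width - x_margin`` (same for y with ``y_margin``).  Idempotent.
    """
    w, h = table.panel.image_width, table.panel.image_height
    if x_margin >= w / 2 or y_margin >= h / 2:
        raise ValueError("margins cover the whole image; all cells would drop")
    x = table.cells["x"].to_numpy(float)
    y = table.cells["y"].to_numpy(float)
    keep = (x >= x_margin) & (x <= w - x_margin) & (y >= y_margin) & (y <= h - y_margin)
    dropped = int((~keep).sum())
    out = CohortTable(
        table.cells.loc[keep].reset_index(drop=True), table.panel, list(table.provenance)
    )
    out.log(f"filter_margins(x={x_margin}, y={y_margin}): dropped {dropped} cells")
    return out


def filter_population(cells, min_n: int = 100, inclusive: bool = True):
    """Gate a cell population on minimum size.

    Returns the input unchanged when it passes (``len >= min_n`` by
    default, strict ``>`` with ``inclusive=False``), else ``None`` — the
    sentinel downstream heterogeneity metrics report as "not computed".
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    n = len(cells)
    ok = n >= min_n if inclusive else n > min_n
    return cells if ok else None
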