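"""Tabular containers and CSV dialects.

Two tables travel through the pipeline:

* a **count table** (one row per cell): ``cell_id,strain,condition_uM,count``
  with non-negative integer counts and (strain, condition_uM, cell_id) unique;
* a **spot table** (one row per detected fluorescent spot):
  ``spot_id,cell_id,intensity,peak_height`` plus a separate single-column list
  of negative-control spot intensities (``intensity``) and an optional cell
  roster carrying strain/condition metadata so that spotless (silent) cells
  survive quantification with count 0.

Both are plain pandas DataFrames; the helpers here only validate and round-trip
them so every stage fails loudly on malformed input, naming the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._exceptions import DataError

__all__ = [
    "COUNT_COLUMNS",
    "SPOT_COLUMNS",
    "CELL_COLUMNS",
    "validate_counts",
    "read_counts_csv",
    "write_counts_csv",
    "SpotTable",
    "read_spot_table",
    "write_spot_table",
]

COUNT_COLUMNS = ["cell_id", "strain", "condition_uM", "count"]
SPOT_COLUMNS = ["spot_id", "cell_id", "intensity", "peak_height"]
CELL_COLUMNS = ["cell_id", "strain", "condition_uM"]


def _check_columns(df: pd.DataFrame, expected, source: str) -> None:
    if list(df.columns) != list(expected):
        raise DataError(
            f"{source}: expected header {','.join(expected)}, got {','.join(map(str, df.columns))}"
        )


def validate_counts(df: pd.DataFrame, source: str = "<counts>") -> pd.DataFrame:
    """Validate a per-cell count table and return it with ``count`` as int64.

    Raises DataError (naming ``source``) on a wrong header, an empty table,
    negative or non-integer counts, or duplicate (strain, condition_uM,
    cell_id) keys.
    """
    _check_columns(df, COUNT_COLUMNS, source)
    if len(df) == 0:
        raise DataError(f"{source}: count table is empty")
    counts = pd.to_numeric(df["count"], errors="coerce")
    if counts.isna().any():
        row = int(df.index[counts.isna()][0])
        raise DataError(f"{source}: non-numeric count at row {row}")
    if (counts < 0).any() or (counts != np.floor(counts)).any():
        row = int(df.index[(counts < 0) | (counts != np.floor(counts))][0])
        raise DataError(f"{source}: counts must be non-negative integers (row {row})")
    key = df[["strain", "condition_uM", "cell_id"]]
    if key.duplicated().any():
        raise DataError(f"{source}: duplicate (strain, condition_uM, cell_id) keys")
    out = df.copy()
    out["count"] = counts.astype(np.int64)
    out["condition_uM"] = pd.to_numeric(out["condition_uM"])
    if (out["condition_uM"] < 0).any():
        raise DataError(f"{source}: condition_uM must be >= 0")
    return out


def read_counts_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: no such file")
    df = pd.read_csv(path)
    return validate_counts(df, source=str(path))


def write_counts_csv(df: pd.DataFrame, path) -> None:
    validate_counts(df, source="<in-memory counts>")
    df.to_csv(path, index=False, columns=COUNT_COLUMNS)


@dataclass
class SpotTable:
    """Per-spot intensities plus the negative-control intensity population.

    spots               : DataFrame with SPOT_COLUMNS
    control_intensities : background-spot intensities from a no-target control
    cells               : optional roster (CELL_COLUMNS); when present every
                          spot must reference a roster cell, and quantification
                          emits count 0 for roster cells without spots.
    """

    spots: pd.DataFrame
    control_intensities: np.ndarray = field(default_factory=lambda: np.empty(0))
    cells: Optional[pd.DataFrame] = None

    def __post_init__(self):
        _check_columns(self.spots, SPOT_COLUMNS, "<spots>")
        self.control_intensities = np.asarray(self.control_intensities, dtype=float)
        if (self.control_intensities < 0).any():
            raise DataError("control intensities must be non-negative")
        inten = pd.to_numeric(self.spots["intensity"], errors="coerce")
        if inten.isna().any() or (inten < 0).any():
            raise DataError("spot intensities must be non-negative numbers")
        if self.cells is not None:
            _check_columns(self.cells, CELL_COLUMNS, "<cells>")
            if self.cells["cell_id"].duplicated().any():
                raise DataError("cell roster contains duplicate cell_id values")
            known = set(self.cells["cell_id"])
            orphans = set(self.spots["cell_id"]) - known
            if orphans:
                raise DataError(
                    f"spots reference unknown cells: {sorted(map(str, orphans))[:5]}"
                )


def read_spot_table(spots_path, control_path=None, cells_path=None) -> SpotTable:
    """Read the spot-table CSV dialect (spots, optional control and roster)."""
    spots_path = Path(spots_path)
    if not spots_path.exists():
        raise DataError(f"{spots_path}: no such file")
    spots = pd.read_csv(spots_path)
    _check_columns(spots, SPOT_COLUMNS, str(spots_path))
    control = np.empty(0)
    if control_path is not None:
        cp = Path(control_path)
        if not cp.exists():
            raise DataError(f"{cp}: no such file")
        cdf = pd.read_csv(cp)
        _check_columns(cdf, ["intensity"], str(cp))
        control = cdf["intensity"].to_numpy(dtype=float)
    cells = None
    if cells_path is not None:
        kp = Path(cells_path)
        if not kp.exists():
            raise DataError(f"{kp}: no such file")
        cells = pd.read_csv(kp)
        _check_columns(cells, CELL_COLUMNS, str(kp))
    return SpotTable(spots=spots, control_intensities=control, cells=cells)


def write_spot_table(table: SpotTable, spots_path, control_path=None, cells_path=None) -> None:
    table.spots.to_csv(spots_path, index=False, columns=SPOT_COLUMNS)
    if control_path is not None:
        pd.DataFrame({"intensity": table.control_intensities}).to_csv(control_path, index=False)
    if cells_path is not None and table.cells is not None:
        table.cells.to_csv(cells_path, index=False, columns=CELL_COLUMNS)
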