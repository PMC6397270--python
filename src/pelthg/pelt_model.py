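"""Domain types and CSV I/O for fur-sample and organ tables.

A flattened otter pelt is sampled on a rectangular grid. Each cell yields one
topcoat and one undercoat fur sample whose total-mercury concentration (THg,
µg/g dry fur) is measured; a subset of topcoat samples additionally carries a
methylmercury (MeHg) value. Pelts differ in physical size, so every pelt is
rescaled to a canonical frame: x in [-1, 1] across the transverse axis,
y in [-1, 1] along the median sagittal axis, origin at their intersection.
(row, col) are 0-based integer indices on the canonical grid; distances for
spatial statistics are Euclidean in (x, y).

Grids may have holes (paws are discarded during pelt processing); holes are
never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("topcoat", "undercoat")
ANATOMICAL_REGIONS = ("head", "body", "legs", "tail")
FUR_REGIONS = ("dorsal", "furline", "ventral")
ORGANS = ("brain", "liver", "kidney", "muscle")

FUR_COLUMNS = [
    "pelt_id", "layer", "x", "y", "row", "col",
    "anatomical_region", "fur_region", "thg_ug_g", "mehg_ug_g",
]
ORGAN_COLUMNS = ["pelt_id", "organ", "thg_ug_g"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates a domain invariant (range, enum, uniqueness)."""


@dataclass(frozen=True)
class SamplePoint:
    """One fur measurement at a grid cell of one pelt layer."""

    pelt_id: str
    layer: str
    x: float
    y: float
    row: int
    col: int
    anatomical_region: str
    fur_region: str
    thg: float
    mehg: float | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.anatomical_region not in ANATOMICAL_REGIONS:
            raise ValidationError(
                f"unknown anatomical_region {self.anatomical_region!r}")
        if self.fur_region not in FUR_REGIONS:
            raise ValidationError(f"unknown fur_region {self.fur_region!r}")
        if self.row < 0 or self.col < 0:
            raise ValidationError("row/col must be non-negative")
        if not np.isfinite(self.thg) or self.thg < 0:
            raise ValidationError(f"thg must be >= 0, got {self.thg}")
        if self.mehg is not None and (not np.isfinite(self.mehg) or self.mehg < 0):
            raise ValidationError(f"mehg must be >= 0, got {self.mehg}")


@dataclass
class PeltGrid:
    """All sample points of one pelt + layer on the canonical grid."""

    pelt_id: str
    layer: str
    points: list[SamplePoint]
    dims: tuple[int, int]  # (n_rows, n_cols)

    def __post_init__(self) -> None:
        n_rows, n_cols = self.dims
        if not self.points:
            raise ValidationError(f"empty grid for pelt {self.pelt_id}")
        seen: set[tuple[int, int]] = set()
        for p in self.points:
            if p.pelt_id != self.pelt_id or p.layer != self.layer:
                raise ValidationError(
                    f"point ({p.pelt_id}, {p.layer}) does not belong to grid "
                    f"({self.pelt_id}, {self.layer})")
            if p.row >= n_rows or p.col >= n_cols:
                raise ValidationError(
                    f"point index ({p.row}, {p.col}) outside dims {self.dims}")
            key = (p.row, p.col)
            if key in seen:
                raise ValidationError(
                    f"duplicate cell {key} in pelt {self.pelt_id} {self.layer}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of canonical (x, y) coordinates."""
        return np.array([(p.x, p.y) for p in self.points], dtype=float)

    @property
    def thg(self) -> np.ndarray:
        return np.array([p.thg for p in self.points], dtype=float)

    @property
    def mehg(self) -> np.ndarray:
        """MeHg values with NaN where absent."""
        return np.array(
            [np.nan if p.mehg is None else p.mehg for p in self.points],
            dtype=float)

    def values(self, value_field: str = "thg") -> np.ndarray:
        if value_field == "thg":
            return self.thg
        if value_field == "mehg":
            return self.mehg
        raise ValueError(f"unknown value field {value_field!r}")

    def with_points(self, points: Sequence[SamplePoint]) -> "PeltGrid":
        return PeltGrid(self.pelt_id, self.layer, list(points), self.dims)


@dataclass(frozen=True)
class OrganRecord:
    """THg concentration of one internal organ of one animal (µg/g dry)."""

    pelt_id: str
    organ: str
    thg: float

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValidationError(f"unknown organ {self.organ!r}")
        if not np.isfinite(self.thg) or self.thg < 0:
            raise ValidationError(f"organ thg must be >= 0, got {self.thg}")


def canonical_xy(row: int, col: int, dims: tuple[int, int]) -> tuple[float, float]:
    """Map grid indices to the canonical frame.

    Columns span x in [-1, 1] (transverse axis), rows span y in [-1, 1] with
    row 0 (the head) at y = +1. Single-row or single-column grids map to 0.
    """
    n_rows, n_cols = dims
    x = -1.0 + 2.0 * col / (n_cols - 1) if n_cols > 1 else 0.0
    y = 1.0 - 2.0 * row / (n_rows - 1) if n_rows > 1 else 0.0
    return x, y


def _grids_from_frame(df: pd.DataFrame, dims: tuple[int, int] | None) -> list[PeltGrid]:
    grids = []
    for (pelt_id, layer), g in df.groupby(["pelt_id", "layer"], sort=True):
        pts = []
        for idx, r in g.iterrows():
            mehg = r["mehg_ug_g"]
            try:
                pts.append(SamplePoint(
                    pelt_id=str(pelt_id), layer=str(layer),
                    x=float(r["x"]), y=float(r["y"]),
                    row=int(r["row"]), col=int(r["col"]),
                    anatomical_region=str(r["anatomical_region"]),
                    fur_region=str(r["fur_region"]),
                    thg=float(r["thg_ug_g"]),
                    mehg=None if pd.isna(mehg) else float(mehg),
                ))
            except ValidationError as e:
                raise ValidationError(f"row {idx}: {e}") from e
        d = dims or (int(g["row"].max()) + 1, int(g["col"].max()) + 1)
        grids.append(PeltGrid(str(pelt_id), str(layer), pts, d))
    return grids


def read_fur_csv(path: str | Path, dims: tuple[int, int] | None = None) -> list[PeltGrid]:
    """Read a long-format fur-sample CSV into one PeltGrid per (pelt, layer).

    Rows with missing THg are dropped (count logged). Grid dims default to the
    per-group maximum index + 1 when not given.
    """
    df = pd.read_csv(path)
    missing = [c for c in FUR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"fur CSV missing column(s): {', '.join(missing)}")
    n_na = int(df["thg_ug_g"].isna().sum())
    if n_na:
        logger.info("dropped %d rows with missing thg from %s", n_na, path)
        df = df.dropna(subset=["thg_ug_g"])
    return _grids_from_frame(df, dims)


def grids_to_frame(grids: Iterable[PeltGrid]) -> pd.DataFrame:
    rows = [
        {
            "pelt_id": p.pelt_id, "layer": p.layer, "x": p.x, "y": p.y,
            "row": p.row, "col": p.col,
            "anatomical_region": p.anatomical_region,
            "fur_region": p.fur_region,
            "thg_ug_g": p.thg,
            "mehg_ug_g": np.nan if p.mehg is None else p.mehg,
        }
        for g in grids for p in g.points
    ]
    return pd.DataFrame(rows, columns=FUR_COLUMNS)


def write_fur_csv(grids: Iterable[PeltGrid], path: str | Path) -> Path:
    """Write grids to CSV; inverse of read_fur_csv up to row order."""
    path = Path(path)
    grids_to_frame(grids).to_csv(path, index=False)
    return path


def read_organ_csv(path: str | Path) -> list[OrganRecord]:
    df = pd.read_csv(path)
    missing = [c for c in ORGAN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"organ CSV missing column(s): {', '.join(missing)}")
    recs = []
    for idx, r in df.iterrows():
        try:
            recs.append(OrganRecord(str(r["pelt_id"]), str(r["organ"]),
                                    float(r["thg_ug_g"])))
        except ValidationError as e:
            raise ValidationError(f"row {idx}: {e}") from e
    return recs


def write_organ_csv(records: Iterable[OrganRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{"pelt_id": r.pelt_id, "organ": r.organ, "thg_ug_g": r.thg}
         for r in records],
        columns=ORGAN_COLUMNS,
    ).to_csv(path, index=False)
    return path


def organ_table(records: Iterable[OrganRecord]) -> dict[str, dict[str, float]]:
    """Nested {pelt_id: {organ: thg}} lookup."""
    out: dict[str, dict[str, float]] = {}
    for r in records:
        out.setdefault(r.pelt_id, {})[r.organ] = r.thg
    return out
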