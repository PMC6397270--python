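"""Min-max normalization of pelts and cross-pelt composite construction.

Raw THg levels differ several-fold between animals (diet, exposure history),
so cross-animal spatial patterns are compared on a unitless scale: each
pelt-layer is min-max normalized to [0, 1] using its own extremes,

    c_norm = (c - c_min) / (c_max - c_min),

and pelts are then averaged cell-by-cell on the canonical grid to form a
composite pelt per layer. Normalization is per pelt AND per layer, so the
composite topcoat and undercoat are each on their own [0, 1] scale.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .pelt_model import PeltGrid, SamplePoint, canonical_xy

logger = logging.getLogger(__name__)


class CompositeError(ValueError):
    pass


@dataclass
class NormalizedGrid:
    """A PeltGrid rescaled to [0, 1]; retains the source extremes (µg/g)."""

    pelt_id: str
    layer: str
    points: list[SamplePoint]   # thg holds the normalized value
    dims: tuple[int, int]
    c_min: float
    c_max: float


@dataclass
class CompositeCell:
    row: int
    col: int
    x: float
    y: float
    value: float                # mean normalized value, in [0, 1]
    n_pelts: int
    anatomical_region: str
    fur_region: str


@dataclass
class CompositePelt:
    """Cross-pelt average of normalized values on the canonical grid."""

    layer: str
    cells: list[CompositeCell]
    dims: tuple[int, int]

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def values(self) -> np.ndarray:
        return np.array([c.value for c in self.cells])

    @property
    def coords(self) -> np.ndarray:
        return np.array([(c.x, c.y) for c in self.cells])


def normalize_pelt(grid: PeltGrid) -> NormalizedGrid:
    """Min-max normalize one pelt layer to [0, 1] with its own extremes."""
    vals = grid.thg
    c_min, c_max = float(vals.min()), float(vals.max())
    if c_max == c_min:
        raise CompositeError(
            f"pelt {grid.pelt_id} {grid.layer}: all values equal, "
            "normalization denominator is zero; exclude this pelt")
    from dataclasses import replace
    pts = [replace(p, thg=float((p.thg - c_min) / (c_max - c_min)))
           for p in grid.points]
    return NormalizedGrid(grid.pelt_id, grid.layer, pts, grid.dims,
                          c_min=c_min, c_max=c_max)


def resample_to_dims(grid: NormalizedGrid,
                     dims: tuple[int, int]) -> NormalizedGrid:
    """Nearest-cell reassignment onto a common canonical grid.

    Pelts digitized at different raw grid sizes are matched by canonical
    (row, col) index; each point moves to the nearest cell of `dims` in the
    canonical frame, and collisions average.
    """
    if grid.dims == dims:
        return grid
    n_rows, n_cols = dims
    from dataclasses import replace
    assigned: dict[tuple[int, int], list[SamplePoint]] = {}
    for p in grid.points:
        col = int(round((p.x + 1) / 2 * (n_cols - 1))) if n_cols > 1 else 0
        row = int(round((1 - p.y) / 2 * (n_rows - 1))) if n_rows > 1 else 0
        assigned.setdefault((row, col), []).append(p)
    pts = []
    for (row, col), group in sorted(assigned.items()):
        x, y = canonical_xy(row, col, dims)
        base = group[0]
        pts.append(replace(base, row=row, col=col, x=x, y=y,
                           thg=float(np.mean([q.thg for q in group]))))
    return NormalizedGrid(grid.pelt_id, grid.layer, pts, dims,
                          c_min=grid.c_min, c_max=grid.c_max)


def build_composite(grids: list[NormalizedGrid], layer: str) -> CompositePelt:
    """Average normalized values cell-by-cell across pelts.

    A composite cell exists wherever at least one pelt has that cell; its
    value is the unweighted mean over contributing pelts, its region labels
    the majority vote (ties resolved by the first pelt's label, logged).
    """
    grids = [g for g in grids if g.layer == layer]
    if not grids:
        raise CompositeError(f"no grids with layer {layer!r}")
    if len({g.dims for g in grids}) != 1:
        raise CompositeError("grids must share canonical dims; resample first")
    dims = grids[0].dims
    by_cell: dict[tuple[int, int], list[SamplePoint]] = {}
    for g in grids:
        for p in g.points:
            by_cell.setdefault((p.row, p.col), []).append(p)
    cells = []
    for (row, col), pts in sorted(by_cell.items()):
        anat_votes = Counter(p.anatomical_region for p in pts)
        fur_votes = Counter(p.fur_region for p in pts)
        anat, n_anat = anat_votes.most_common(1)[0]
        if sum(v == n_anat for v in anat_votes.values()) > 1:
            anat = pts[0].anatomical_region
            logger.info("label tie at cell (%d, %d); using first pelt's %s",
                        row, col, anat)
        fur, n_fur = fur_votes.most_common(1)[0]
        if sum(v == n_fur for v in fur_votes.values()) > 1:
            fur = pts[0].fur_region
        cells.append(CompositeCell(
            row=row, col=col, x=pts[0].x, y=pts[0].y,
            value=float(np.mean([p.thg for p in pts])),
            n_pelts=len(pts), anatomical_region=anat, fur_region=fur))
    return CompositePelt(layer=layer, cells=cells, dims=dims)


def range_ratio(topcoat_values, undercoat_values) -> float:
    """(max - min of undercoat) / (max - min of topcoat).

    Quantifies how much wider the undercoat concentration range is than the
    topcoat's; report to 2 decimals.
    """
    tc = np.asarray(topcoat_values, dtype=float)
    uc = np.asarray(undercoat_values, dtype=float)
    if tc.size == 0 or uc.size == 0:
        raise CompositeError("both layers must be nonempty")
    tc_range = float(tc.max() - tc.min())
    if tc_range == 0:
        raise CompositeError("topcoat range is zero")
    return float((uc.max() - uc.min()) / tc_range)
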