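"""Synthetic pelt generator.

Emulates the statistical structure of gridded otter-pelt mercury data so the
full analysis pipeline is testable without field data: four pelts of ~89-98
grid points each, topcoat THg lower and far less variable than undercoat,
spatially correlated within-pelt variation with a hotspot at the head and a
coldspot at the tail, MeHg close to 96% of topcoat THg measured on a
stratified subset, and per-animal organ concentrations linked to fur through
a configurable conversion model.

Per-pelt defaults (means, sds, undercoat ratios, point counts) are set to the
observed per-pelt summaries of the four study animals. The within-pelt
correlation length is a free parameter (no published estimate exists); the
default of 0.4 canonical units gives smooth multi-cell clusters on a pelt
spanning [-1, 1].

Spatial fields are exact multivariate-normal draws with exponential
covariance exp(-d/l) via dense Cholesky (grids are at most a few hundred
points); negative concentrations are truncated at zero rather than resampled,
a small documented bias at the configured means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .pelt_model import (
    ANATOMICAL_REGIONS,
    PeltGrid,
    SamplePoint,
    canonical_xy,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# Table-2-style per-pelt defaults: topcoat mean/sd (µg/g), undercoat-to-
# topcoat mean ratio, undercoat/topcoat variance multiplier, holes per pelt
# (discarded paws) on the 12 x 9 grid -> n = 89, 98, 96, 95.
_TC_MEAN = (1.55, 4.60, 1.42, 4.44)
_TC_SD = (0.20, 0.20, 0.37, 0.16)
_UC_RATIO = (1.41, 2.05, 2.01, 1.10)
_UC_VARMULT = (9.6, 121.0, 16.7, 31.6)
_N_HOLES = (19, 10, 12, 13)


def _per_pelt(value, n: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.full(n, arr[0])
    if arr.size < n:
        raise ConfigError(f"{name} has {arr.size} entries for {n} pelts")
    return arr[:n]


@dataclass
class SimConfig:
    """Parameters of the synthetic pelt ensemble."""

    n_pelts: int = 4
    n_rows: int = 12
    n_cols: int = 9
    topcoat_mean: Sequence[float] | float = _TC_MEAN
    topcoat_sd: Sequence[float] | float = _TC_SD
    uc_mean_ratio: Sequence[float] | float = _UC_RATIO
    uc_var_multiplier: Sequence[float] | float = _UC_VARMULT
    n_holes: Sequence[int] | int = _N_HOLES
    corr_length: float = 0.4          # canonical units
    layer_corr: float = 0.3           # topcoat-undercoat field correlation
    hotspot_amplitude: float = 3.0    # in field-sd units, at the head
    coldspot_amplitude: float = 3.0   # in field-sd units, at the tail
    hotspot_center: tuple[float, float] = (0.0, 0.9)
    coldspot_center: tuple[float, float] = (0.0, -0.9)
    bump_radius: float = 0.35
    noise_frac: float = 0.2           # share of layer variance that is i.i.d.
    mehg_fraction: float = 0.957      # true MeHg/THg slope
    mehg_noise_sd: float = 0.05       # µg/g
    mehg_per_stratum: int = 1
    organ_noise_sd: float = 0.0       # lognormal sd on generated organ THg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.corr_length <= 0:
            raise ConfigError("corr_length must be > 0")
        if not 0 < self.mehg_fraction <= 1:
            raise ConfigError("mehg_fraction must be in (0, 1]")
        if not 0 <= self.noise_frac < 1:
            raise ConfigError("noise_frac must be in [0, 1)")
        if not -1 < self.layer_corr < 1:
            raise ConfigError("layer_corr must be in (-1, 1)")
        n = self.n_pelts
        self._tc_mean = _per_pelt(self.topcoat_mean, n, "topcoat_mean")
        self._tc_sd = _per_pelt(self.topcoat_sd, n, "topcoat_sd")
        self._uc_ratio = _per_pelt(self.uc_mean_ratio, n, "uc_mean_ratio")
        self._uc_varmult = _per_pelt(self.uc_var_multiplier, n, "uc_var_multiplier")
        self._n_holes = _per_pelt(self.n_holes, n, "n_holes").astype(int)
        if np.any(self._tc_sd <= 0):
            raise ConfigError("topcoat_sd must be > 0")
        if np.any(self._uc_varmult < 1):
            raise ConfigError("uc_var_multiplier must be >= 1")

    @property
    def dims(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


def default_region_layout(n_rows: int, n_cols: int):
    """Region labels for each grid cell.

    Head rows at the top, tail rows at the bottom, legs on the flanks beside
    the fore/hind body, body elsewhere. The pelt is cut open along the ventral
    axis, so the dorsal stripe runs down the middle columns, the ventral edges
    lie at the outer columns, and the furline sits between them.
    """
    anat = np.empty((n_rows, n_cols), dtype=object)
    fur = np.empty((n_rows, n_cols), dtype=object)
    head_rows = max(1, round(n_rows / 6))
    tail_rows = max(1, round(n_rows / 6))
    for r in range(n_rows):
        for c in range(n_cols):
            x, y = canonical_xy(r, c, (n_rows, n_cols))
            if r < head_rows:
                a = "head"
            elif r >= n_rows - tail_rows:
                a = "tail"
            elif abs(x) > 0.75 and (r < n_rows // 2 or r >= n_rows - tail_rows - 2):
                a = "legs"  # flanks near fore/hind limbs
            else:
                a = "body"
            if abs(x) <= 1 / 3:
                f = "dorsal"
            elif abs(x) <= 0.75:
                f = "furline"
            else:
                f = "ventral"
            anat[r, c] = a
            fur[r, c] = f
    return anat, fur


def _hole_cells(n_rows: int, n_cols: int, n_holes: int) -> set[tuple[int, int]]:
    """Cells dropped as discarded paws: nearest to the four grid corners."""
    corners = [(0, 0), (0, n_cols - 1), (n_rows - 1, 0), (n_rows - 1, n_cols - 1)]
    cells = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    scored = sorted(
        cells,
        key=lambda rc: (min((rc[0] - cr) ** 2 + (rc[1] - cc) ** 2
                            for cr, cc in corners), rc),
    )
    return set(scored[:n_holes])


def _correlated_fields(coords: np.ndarray, corr_length: float, rho: float,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-variance Gaussian fields with exp(-d/l) covariance and
    cross-correlation rho between layers."""
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cov = np.exp(-d / corr_length) + 1e-10 * np.eye(len(coords))
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as e:
        raise FloatingPointError(
            "spatial covariance not positive definite after jitter") from e
    z1 = chol @ rng.standard_normal(len(coords))
    z2 = chol @ rng.standard_normal(len(coords))
    return z1, rho * z1 + np.sqrt(1 - rho ** 2) * z2


def _bumps(coords: np.ndarray, config: SimConfig) -> np.ndarray:
    """Hotspot/coldspot surface in field-sd units."""
    out = np.zeros(len(coords))
    for center, amp in ((config.hotspot_center, config.hotspot_amplitude),
                        (config.coldspot_center, -config.coldspot_amplitude)):
        d2 = np.sum((coords - np.asarray(center)) ** 2, axis=1)
        out += amp * np.exp(-d2 / (2 * config.bump_radius ** 2))
    return out


def generate_pelt(config: SimConfig, pelt_index: int) -> tuple[PeltGrid, PeltGrid]:
    """Generate the topcoat and undercoat grids of one pelt.

    value = layer mean + spatially correlated field (scaled to the layer's
    field variance) + hotspot/coldspot bumps + independent noise, truncated
    at zero. Same config + seed is bit-reproducible.
    """
    if not 0 <= pelt_index < config.n_pelts:
        raise ConfigError(f"pelt_index {pelt_index} out of range")
    rng = np.random.default_rng([config.seed, pelt_index])
    n_rows, n_cols = config.dims
    anat, fur = default_region_layout(n_rows, n_cols)
    holes = _hole_cells(n_rows, n_cols, int(config._n_holes[pelt_index]))
    cells = [(r, c) for r in range(n_rows) for c in range(n_cols)
             if (r, c) not in holes]
    coords = np.array([canonical_xy(r, c, config.dims) for r, c in cells])

    z_tc, z_uc = _correlated_fields(coords, config.corr_length,
                                    config.layer_corr, rng)
    bump = _bumps(coords, config)

    tc_mean = config._tc_mean[pelt_index]
    tc_sd = config._tc_sd[pelt_index]
    uc_mean = tc_mean * config._uc_ratio[pelt_index]
    uc_sd = tc_sd * np.sqrt(config._uc_varmult[pelt_index])

    grids = []
    for layer, mean, sd, z in (("topcoat", tc_mean, tc_sd, z_tc),
                               ("undercoat", uc_mean, uc_sd, z_uc)):
        field_sd = sd * np.sqrt(1 - config.noise_frac)
        noise_sd = sd * np.sqrt(config.noise_frac)
        vals = mean + field_sd * (z + bump) + noise_sd * rng.standard_normal(len(cells))
        vals = np.maximum(vals, 0.0)
        pts = [
            SamplePoint(
                pelt_id=f"pelt{pelt_index + 1}", layer=layer,
                x=coords[i, 0], y=coords[i, 1], row=r, col=c,
                anatomical_region=anat[r, c], fur_region=fur[r, c],
                thg=float(vals[i]))
            for i, (r, c) in enumerate(cells)
        ]
        grids.append(PeltGrid(f"pelt{pelt_index + 1}", layer, pts, config.dims))
    return grids[0], grids[1]


def attach_mehg(grid: PeltGrid, fraction: float, noise_sd: float,
                seed: int) -> PeltGrid:
    """Set mehg = fraction * thg + Gaussian noise on a topcoat grid.

    Values are truncated to [0, 1.3 * thg]; MeHg modestly above THg is kept
    to emulate analytical error between the two assays.
    """
    if grid.layer != "topcoat":
        raise ConfigError("MeHg is simulated for the topcoat layer only")
    if not 0 < fraction <= 1.3:
        raise ConfigError(f"mehg fraction must be in (0, 1.3], got {fraction}")
    rng = np.random.default_rng(seed)
    pts = []
    for p in grid.points:
        mehg = fraction * p.thg + noise_sd * rng.standard_normal()
        mehg = float(np.clip(mehg, 0.0, 1.3 * p.thg))
        pts.append(replace(p, mehg=mehg))
    return grid.with_points(pts)


def stratified_mehg_subset(grid: PeltGrid, n_per_stratum: int,
                           seed: int) -> list[SamplePoint]:
    """Stratified random subset by THg tertile x anatomical region.

    Tertile breakpoints are the 1/3 and 2/3 empirical quantiles of THg; up to
    n_per_stratum points are drawn without replacement from each non-empty
    stratum. Degenerate quantiles (ties, all-equal values) collapse tertiles,
    down to a single concentration stratum per region.
    """
    if n_per_stratum < 1:
        raise ConfigError("n_per_stratum must be >= 1")
    rng = np.random.default_rng(seed)
    thg = grid.thg
    if thg.min() == thg.max():
        breaks = np.array([])  # all equal: one concentration stratum
    else:
        breaks = np.unique(np.quantile(thg, [1 / 3, 2 / 3]))
    tert = np.digitize(thg, breaks, right=True)
    chosen: list[SamplePoint] = []
    for region in ANATOMICAL_REGIONS:
        for t in np.unique(tert):
            idx = [i for i, p in enumerate(grid.points)
                   if p.anatomical_region == region and tert[i] == t]
            if not idx:
                continue
            take = rng.choice(len(idx), size=min(n_per_stratum, len(idx)),
                              replace=False)
            chosen.extend(grid.points[idx[k]] for k in sorted(take))
    return chosen


def restrict_mehg(grid: PeltGrid, subset: Sequence[SamplePoint]) -> PeltGrid:
    """Keep mehg only at the subset's cells (the assayed samples)."""
    keep = {(p.row, p.col) for p in subset}
    pts = [p if (p.row, p.col) in keep else replace(p, mehg=None)
           for p in grid.points]
    return grid.with_points(pts)


def generate_organs(grids: Sequence[PeltGrid], model, noise_sd: float = 0.0,
                    seed: int = 0) -> list:
    """Per-animal organ THg generated from head-region topcoat fur.

    For each pelt the topcoat point nearest the head-region centre is the
    generating point: organ THg = conversion(fur THg there), times lognormal
    noise when noise_sd > 0. With zero noise the organ-prediction error is
    exactly zero at the generating points, making head/topcoat the planted
    optimal sampling region.
    """
    from .error_surface import predict_organ  # local import avoids cycle
    from .pelt_model import ORGANS, OrganRecord

    rng = np.random.default_rng(seed)
    records = []
    for g in grids:
        if g.layer != "topcoat":
            continue
        head = [p for p in g.points if p.anatomical_region == "head"]
        if not head:
            raise ConfigError(f"pelt {g.pelt_id} has no head-region points")
        cx = float(np.mean([p.x for p in head]))
        cy = float(np.mean([p.y for p in head]))
        ref = min(head, key=lambda p: (p.x - cx) ** 2 + (p.y - cy) ** 2)
        for organ in ORGANS:
            y = predict_organ(ref.thg, model, organ)
            if noise_sd > 0:
                y *= float(np.exp(noise_sd * rng.standard_normal()))
            records.append(OrganRecord(g.pelt_id, organ, y))
    return records


def simulate_dataset(config: SimConfig, model=None):
    """Full synthetic study: fur grids (MeHg on a stratified topcoat subset)
    plus per-animal organ records.

    Returns (grids, organ_records). `model` defaults to the placeholder
    identity conversion.
    """
    from .error_surface import ConversionModel

    model = model or ConversionModel.placeholder()
    grids: list[PeltGrid] = []
    for i in range(config.n_pelts):
        tc, uc = generate_pelt(config, i)
        tc = attach_mehg(tc, config.mehg_fraction, config.mehg_noise_sd,
                         seed=config.seed * 1009 + 17 + i)
        subset = stratified_mehg_subset(tc, config.mehg_per_stratum,
                                        seed=config.seed * 2003 + 29 + i)
        tc = restrict_mehg(tc, subset)
        grids.extend([tc, uc])
    organs = generate_organs(grids, model, noise_sd=config.organ_noise_sd,
                             seed=config.seed * 3001 + 41)
    return grids, organs
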