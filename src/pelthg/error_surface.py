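"""Organ-prediction percent-error surface and optimal sampling region.

Published fur-to-organ regressions predict internal THg (brain, liver,
kidney, muscle) from a fur THg measurement. If fur THg varies across the
pelt, the prediction error depends on where the fur sample was taken. For
each fur point the four organ concentrations are predicted from that point's
THg, compared with the animal's measured organ values,

    %Error = |(y_hat - y) / y| * 100,

and combined into a weighted mean with the brain counted twice (its central
role in mercury toxicity):

    e_w = (2 e_brain + e_liver + e_kidney + e_muscle) / 5.

Per-point weighted errors are averaged across pelts on the canonical grid
(weighting per point first, then averaging across animals) and the local Gi*
cluster analysis is run on that averaged surface: a significant cold cluster
marks the region where fur best predicts internal burden.

The published conversion coefficients are external inputs supplied by the
user; the built-in default is a clearly-labelled synthetic placeholder
(log10-scale identity) suitable only for pipeline exercises, and reports
based on it are flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pelt_model import ORGANS, OrganRecord, PeltGrid, organ_table
from .spatial import GiStarField, hotspot_map

ORGAN_WEIGHTS = {"brain": 2.0, "liver": 1.0, "kidney": 1.0, "muscle": 1.0}


class ConversionError(ValueError):
    pass


@dataclass(frozen=True)
class OrganCoefficients:
    scale: str                 # "linear" | "log10"
    a: float                   # intercept
    b: float                   # slope

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log10"):
            raise ConversionError(f"unknown scale {self.scale!r}")


@dataclass
class ConversionModel:
    """Per-organ fur-to-organ THg regression coefficients."""

    coefficients: dict[str, OrganCoefficients]
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        missing = [o for o in ORGANS if o not in self.coefficients]
        if missing:
            raise ConversionError(
                f"conversion model missing organ(s): {', '.join(missing)}")

    @property
    def is_placeholder(self) -> bool:
        return self.provenance == "synthetic placeholder"

    @classmethod
    def placeholder(cls) -> "ConversionModel":
        """Synthetic stand-in: log10 identity (organ THg = fur THg).

        Not a published relationship; exercises the pipeline only.
        """
        return cls({o: OrganCoefficients("log10", 0.0, 1.0) for o in ORGANS},
                   provenance="synthetic placeholder")

    @classmethod
    def from_dict(cls, d: dict, provenance: str = "user-supplied"
                  ) -> "ConversionModel":
        coeffs = {organ: OrganCoefficients(str(v["scale"]), float(v["a"]),
                                           float(v["b"]))
                  for organ, v in d.items()}
        return cls(coeffs, provenance=provenance)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConversionModel":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d, provenance=str(path))


@dataclass
class ErrorSurface:
    """Per-point organ prediction errors for one pelt layer."""

    pelt_id: str
    layer: str
    coords: np.ndarray                  # (n, 2)
    rows: np.ndarray
    cols: np.ndarray
    anatomical_region: np.ndarray
    per_organ: dict[str, np.ndarray]    # % errors per organ
    weighted: np.ndarray                # brain-weighted mean % error
    weights: dict[str, float] = field(default_factory=lambda: dict(ORGAN_WEIGHTS))


def predict_organ(fur_thg: float, model: ConversionModel, organ: str) -> float:
    """Predicted organ THg (µg/g) from a fur THg measurement."""
    if organ not in model.coefficients:
        raise ConversionError(f"organ {organ!r} missing from model")
    c = model.coefficients[organ]
    if c.scale == "linear":
        if fur_thg < 0:
            raise ValueError("fur_thg must be >= 0")
        return c.a + c.b * fur_thg
    if fur_thg <= 0:
        raise ValueError("fur_thg must be > 0 on the log10 scale")
    return float(10 ** (c.a + c.b * np.log10(fur_thg)))


def percent_error(predicted: float, observed: float) -> float:
    """|(y_hat - y) / y| * 100; observed must be positive."""
    if observed <= 0:
        raise ValueError("observed organ THg must be > 0")
    return abs((predicted - observed) / observed) * 100.0


def weighted_error(errors: dict[str, float],
                   weights: dict[str, float] | None = None) -> float:
    """Brain-weighted mean percent error across the four organs."""
    weights = weights or ORGAN_WEIGHTS
    missing = [o for o in ORGANS if o not in errors]
    if missing:
        raise ValueError(f"missing organ error(s): {', '.join(missing)}")
    total_w = sum(weights[o] for o in ORGANS)
    return float(sum(weights[o] * errors[o] for o in ORGANS) / total_w)


def pelt_error_surface(grid: PeltGrid, organs: dict[str, float],
                       model: ConversionModel) -> ErrorSurface:
    """Per-point per-organ and weighted percent errors for one pelt layer.

    Points whose fur THg is outside the conversion model's domain (zero on a
    log10 scale) have no defined prediction and are excluded, with a logged
    count.
    """
    import logging
    missing = [o for o in ORGANS if o not in organs]
    if missing:
        raise ValueError(
            f"pelt {grid.pelt_id} lacks organ(s): {', '.join(missing)}")
    log_scale = any(c.scale == "log10" for c in model.coefficients.values())
    points = [p for p in grid.points if not (log_scale and p.thg <= 0)]
    n_dropped = len(grid.points) - len(points)
    if n_dropped:
        logging.getLogger(__name__).info(
            "pelt %s %s: %d zero-THg point(s) outside the log10 conversion "
            "domain excluded from the error surface",
            grid.pelt_id, grid.layer, n_dropped)
    if not points:
        raise ValueError(
            f"pelt {grid.pelt_id} {grid.layer}: no points in the conversion "
            "model's domain")
    per_organ = {}
    for organ in ORGANS:
        y = organs[organ]
        per_organ[organ] = np.array(
            [percent_error(predict_organ(p.thg, model, organ), y)
             for p in points])
    weighted = np.array([
        weighted_error({o: per_organ[o][i] for o in ORGANS})
        for i in range(len(points))])
    return ErrorSurface(
        pelt_id=grid.pelt_id, layer=grid.layer,
        coords=np.array([(p.x, p.y) for p in points]),
        rows=np.array([p.row for p in points]),
        cols=np.array([p.col for p in points]),
        anatomical_region=np.array([p.anatomical_region for p in points]),
        per_organ=per_organ, weighted=weighted)


def average_error_surface(surfaces: list[ErrorSurface]) -> ErrorSurface:
    """Unweighted mean of weighted errors at each canonical cell across pelts."""
    if not surfaces:
        raise ValueError("no surfaces to average")
    layer = surfaces[0].layer
    by_cell: dict[tuple[int, int], list[int]] = {}
    acc: dict[tuple[int, int], dict] = {}
    for s in surfaces:
        if s.layer != layer:
            raise ValueError("surfaces must share a layer")
        for i in range(len(s.weighted)):
            key = (int(s.rows[i]), int(s.cols[i]))
            a = acc.setdefault(key, {"w": [], "coords": s.coords[i],
                                     "region": s.anatomical_region[i],
                                     "per_organ": {o: [] for o in ORGANS}})
            a["w"].append(s.weighted[i])
            for o in ORGANS:
                a["per_organ"][o].append(s.per_organ[o][i])
    keys = sorted(acc)
    return ErrorSurface(
        pelt_id="composite", layer=layer,
        coords=np.array([acc[k]["coords"] for k in keys]),
        rows=np.array([k[0] for k in keys]),
        cols=np.array([k[1] for k in keys]),
        anatomical_region=np.array([acc[k]["region"] for k in keys]),
        per_organ={o: np.array([np.mean(acc[k]["per_organ"][o]) for k in keys])
                   for o in ORGANS},
        weighted=np.array([np.mean(acc[k]["w"]) for k in keys]))


@dataclass
class OptimalRegionSummary:
    best_region: str
    best_layer: str
    mean_error_by_region_layer: dict[tuple[str, str], float]
    cold_cluster_regions: dict[str, list[str]]   # layer -> regions with cold labels
    placeholder_model: bool


def optimal_region(grids: list[PeltGrid], organs: list[OrganRecord],
                   model: ConversionModel):
    """Error surfaces per layer, Gi* on the averaged surface, and a summary.

    Returns (surfaces, gi_fields, summary) where surfaces and gi_fields are
    keyed by layer. The summary reports the anatomical region x layer with
    the lowest mean brain-weighted error and any significant low-error (cold)
    clusters; it is flagged when the conversion model is the synthetic
    placeholder.
    """
    table = organ_table(organs)
    per_layer_surfaces: dict[str, list[ErrorSurface]] = {}
    for g in grids:
        if g.pelt_id not in table:
            raise ValueError(f"no organ records for pelt {g.pelt_id}")
        s = pelt_error_surface(g, table[g.pelt_id], model)
        per_layer_surfaces.setdefault(g.layer, []).append(s)

    surfaces: dict[str, ErrorSurface] = {}
    gi_fields: dict[str, GiStarField] = {}
    means: dict[tuple[str, str], float] = {}
    cold: dict[str, list[str]] = {}
    for layer, ss in per_layer_surfaces.items():
        avg = average_error_surface(ss)
        surfaces[layer] = avg
        from .spatial import derive_band, gi_star
        vg = derive_band(avg.coords, avg.weighted)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gi = gi_star(avg.coords, avg.weighted, band_distance=vg.range_)
        gi_fields[layer] = gi
        cold[layer] = sorted({
            str(avg.anatomical_region[i]) for i in range(len(gi.labels))
            if gi.labels[i] == "cold"})
        for region in sorted({str(r) for r in avg.anatomical_region}):
            m = avg.anatomical_region == region
            means[(region, layer)] = float(avg.weighted[m].mean())

    best_region, best_layer = min(means, key=means.get)
    summary = OptimalRegionSummary(
        best_region=best_region, best_layer=best_layer,
        mean_error_by_region_layer=means, cold_cluster_regions=cold,
        placeholder_model=model.is_placeholder)
    return surfaces, gi_fields, summary
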