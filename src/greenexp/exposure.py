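"""Greenspace coverage and population-weighted exposure.

The physical coverage rate of a zone is the plain mean of the fractional
greenspace grid over its cells,

    GC = (1/N) * sum_i G_i ,

while the exposure index weights each cell's *buffered* greenspace fraction
by the people living there,

    GE^d = sum_i P_i * G_i^d / sum_i P_i ,

where G_i^d is the mean greenspace fraction over all cells whose center lies
within Euclidean distance d of cell i's center. GE^d therefore measures the
greenness of the environments people actually occupy; comparing it with GC
exposes the "overestimation" that pure supply metrics commit when people
cluster away from green areas.

Both quantities are carried as fractions in [0, 1]; percentages appear only
in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid_io import Grid, ZoneSet, rasterize_zones

__all__ = [
    "ExposureResult",
    "aggregate_fraction",
    "focal_fraction",
    "greenspace_coverage",
    "population_weighted_exposure",
    "exposure_report",
    "results_to_frame",
    "buffer_sensitivity",
]


@dataclass
class ExposureResult:
    """Per-zone coverage and exposure, one entry per buffer radius."""

    zone_id: str
    GC: float | None = None
    GE_by_radius: dict[float, float] = field(default_factory=dict)
    n_cells: int = 0
    pop_total: float = 0.0
    cell_pairs: np.ndarray | None = None  # (n, 2): P_i, G_i^d at primary radius
    error: str | None = None


def aggregate_fraction(fine: Grid, factor: int) -> Grid:
    """Block-average a binary map to a coarser fractional grid.

    Each coarse cell is the mean of its ``factor x factor`` block over the
    valid fine cells; it is nodata only when the whole block is nodata.
    Dimensions must divide evenly — no implicit padding.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rows, cols = fine.shape
    if rows % factor or cols % factor:
        raise ValueError(
            f"grid shape {fine.shape} not divisible by factor {factor}"
        )
    vals = fine.values[fine.valid_mask]
    if vals.size and not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("aggregate_fraction expects a binary {0,1} map")
    r, c = rows // factor, cols // factor
    blocks = fine.values.reshape(r, factor, c, factor)
    valid = fine.valid_mask.reshape(r, factor, c, factor)
    n_valid = valid.sum(axis=(1, 3))
    total = np.where(valid, blocks, 0.0).sum(axis=(1, 3))
    out = np.divide(total, n_valid, out=np.zeros((r, c)), where=n_valid > 0)
    return Grid(
        values=out,
        cell_size=fine.cell_size * factor,
        origin=fine.origin,
        nodata_mask=n_valid == 0,
        crs_epsg=fine.crs_epsg,
    )


def _disc_kernel(radius_m: float, cell_size: float) -> np.ndarray:
    """Binary disc: offsets whose center distance is <= radius (inclusive)."""
    n = int(np.floor(radius_m / cell_size + 1e-9))
    if n == 0:
        return np.ones((1, 1))
    dy, dx = np.mgrid[-n : n + 1, -n : n + 1]
    d2 = (dx * cell_size) ** 2 + (dy * cell_size) ** 2
    # inclusive boundary with a relative tolerance for exact-radius cells
    return (d2 <= radius_m**2 * (1.0 + 1e-12)).astype(float)


def focal_fraction(green: Grid, radius_m: float) -> Grid:
    """Buffered greenspace fraction G^d: circular focal mean.

    The kernel holds every cell whose center lies within Euclidean distance
    ``radius_m`` of the focal cell's center (boundary inclusive; the center
    cell always belongs). At raster edges and next to nodata cells the
    kernel is renormalized over the cells actually available, so constants
    are fixed points and no artificial suppression appears at the fringe.
    """
    if radius_m < 0:
        raise ValueError("radius_m must be >= 0")
    kernel = _disc_kernel(radius_m, green.cell_size)
    valid = green.valid_mask.astype(float)
    vals = np.where(green.valid_mask, green.values, 0.0)
    num = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    out = np.clip(out, 0.0, 1.0)
    return Grid(
        values=out,
        cell_size=green.cell_size,
        origin=green.origin,
        nodata_mask=green.nodata_mask.copy(),
        crs_epsg=green.crs_epsg,
    )


def greenspace_coverage(green: Grid, zone_mask: np.ndarray, zone_id: str = "") -> float:
    """Physical coverage rate GC: unweighted mean fraction over the zone."""
    sel = zone_mask & green.valid_mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"empty zone{': ' + zone_id if zone_id else ''}")
    return float(green.values[sel].mean())


def population_weighted_exposure(
    pop: Grid, green_d: Grid, zone_mask: np.ndarray, zone_id: str = ""
) -> float:
    """Population-weighted exposure GE^d over a zone."""
    pop.assert_aligned(green_d)
    sel = zone_mask & pop.valid_mask & green_d.valid_mask
    p = pop.values[sel]
    total = p.sum()
    if total <= 0:
        raise ValueError(
            f"no population in zone{': ' + zone_id if zone_id else ''}"
        )
    return float((p * green_d.values[sel]).sum() / total)


def exposure_report(
    green: Grid,
    pop: Grid,
    zones: ZoneSet,
    radii: list[float],
) -> list[ExposureResult]:
    """Per-zone GC and GE^d for every buffer radius.

    G^d is computed over the full raster before zonal masking, so green
    areas just outside a zone still count toward the exposure of residents
    near its edge. Zones violating a precondition (no valid cells, zero
    population) come back flagged with an error message instead of being
    dropped. ``cell_pairs`` holds the per-cell (P_i, G_i^d) pairs for the
    first radius in ``radii`` — the primary radius of the analysis.
    """
    if not radii:
        raise ValueError("radii must be non-empty")
    green.assert_aligned(pop)
    labels = rasterize_zones(zones, green)
    focal = {d: focal_fraction(green, d) for d in radii}
    results: list[ExposureResult] = []
    primary = radii[0]
    for k, zone in enumerate(zones, start=1):
        res = ExposureResult(zone_id=zone.zone_id)
        zmask = labels == k
        try:
            res.GC = greenspace_coverage(green, zmask, zone.zone_id)
            sel = zmask & green.valid_mask
            res.n_cells = int(sel.sum())
            res.pop_total = float(pop.values[sel & pop.valid_mask].sum())
            for d in radii:
                res.GE_by_radius[d] = population_weighted_exposure(
                    pop, focal[d], zmask, zone.zone_id
                )
            psel = zmask & pop.valid_mask & focal[primary].valid_mask
            res.cell_pairs = np.column_stack(
                [pop.values[psel], focal[primary].values[psel]]
            )
        except ValueError as exc:
            res.error = str(exc)
        results.append(res)
    return results


def results_to_frame(results: list[ExposureResult]) -> pd.DataFrame:
    """Flatten exposure results to one row per zone (fractions as-is)."""
    rows = []
    for r in results:
        row: dict = {"zone_id": r.zone_id, "GC": r.GC, "n_cells": r.n_cells,
                     "pop_total": r.pop_total}
        for d, ge in sorted(r.GE_by_radius.items()):
            row[f"GE_{int(d)}"] = ge
        row["error"] = r.error or ""
        rows.append(row)
    return pd.DataFrame(rows)


def buffer_sensitivity(
    results: list[ExposureResult], d1: float, d2: float
) -> float:
    """Mean absolute GE discrepancy between two radii, in percentage points."""
    diffs = []
    for r in results:
        if r.error:
            continue
        if d1 not in r.GE_by_radius or d2 not in r.GE_by_radius:
            raise ValueError(
                f"zone {r.zone_id}: radii {d1} and {d2} not both present"
            )
        diffs.append(abs(r.GE_by_radius[d1] - r.GE_by_radius[d2]))
    if not diffs:
        raise ValueError("no zones with both radii")
    return float(np.mean(diffs) * 100.0)
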