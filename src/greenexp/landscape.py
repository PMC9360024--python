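"""Landscape-pattern metrics of a binary greenspace map.

Configuration covariates for the driver analysis: patch structure (mean and
largest patch size, perimeter-area ratio, shape index) and edge density.
Patches are connected components of the foreground; perimeter is the exposed
cell-edge length, counting edges shared with background, nodata, or the
raster boundary. A patch's shape index, 0.25 * perimeter / sqrt(area),
equals 1 for a solid square and grows with boundary complexity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .grid_io import Grid

__all__ = [
    "PatchSet",
    "binarize",
    "label_patches",
    "landscape_summary",
]


@dataclass
class PatchSet:
    labels: np.ndarray          # 0 background, k >= 1 patch id
    areas: np.ndarray           # m^2, index k-1
    perimeters: np.ndarray      # m, index k-1
    cell_size: float

    @property
    def n_patches(self) -> int:
        return len(self.areas)


def binarize(green: Grid, threshold: float = 0.5) -> Grid:
    """Threshold a fractional grid: cell -> 1 iff fraction >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    vals = (green.values >= threshold).astype(float)
    vals[green.nodata_mask] = 0.0
    return Grid(
        values=vals,
        cell_size=green.cell_size,
        origin=green.origin,
        nodata_mask=green.nodata_mask.copy(),
        crs_epsg=green.crs_epsg,
    )


def label_patches(binary: Grid, connectivity: int = 8) -> PatchSet:
    """Connected greenspace patches with per-patch area and perimeter.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent,
    the landscape-ecology default). Nodata cells are background for both
    labeling and perimeter exposure.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    vals = binary.values[binary.valid_mask]
    if vals.size and not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("label_patches expects a binary {0,1} map")
    fg = (binary.values == 1.0) & binary.valid_mask
    labels = measure.label(fg, connectivity=1 if connectivity == 4 else 2)
    n = int(labels.max())
    cell = binary.cell_size
    if n == 0:
        return PatchSet(labels=labels, areas=np.empty(0),
                        perimeters=np.empty(0), cell_size=cell)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    areas = counts.astype(float) * cell**2

    # exposed edges: for each of the 4 directions, foreground cells whose
    # neighbor is background/nodata/out-of-bounds
    edge_counts = np.zeros(n + 1, dtype=np.int64)
    padded = np.pad(fg, 1, constant_values=False)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neighbor_fg = padded[1 + dr : padded.shape[0] - 1 + dr,
                             1 + dc : padded.shape[1] - 1 + dc]
        exposed = fg & ~neighbor_fg
        np.add.at(edge_counts, labels[exposed], 1)
    perimeters = edge_counts[1:].astype(float) * cell
    return PatchSet(labels=labels, areas=areas, perimeters=perimeters,
                    cell_size=cell)


def landscape_summary(patches: PatchSet, zone_area_m2: float) -> dict[str, float]:
    """The six landscape covariates of the driver table.

    gcr — greenspace coverage rate, foreground area / zone area;
    mean/largest patch size in m^2 (plus lpi, largest patch as a fraction
    of the zone); mean per-patch perimeter-area ratio in m/m^2; mean shape
    index; edge density in m/ha (total patch perimeter over zone area).
    With zero patches all metrics are 0.
    """
    if not zone_area_m2 > 0:
        raise ValueError("zone_area_m2 must be positive")
    if patches.n_patches == 0:
        return {"gcr": 0.0, "mean_patch_size": 0.0, "largest_patch_size": 0.0,
                "lpi": 0.0, "pa_ratio": 0.0, "shape_index": 0.0, "ed": 0.0}
    areas, perims = patches.areas, patches.perimeters
    total_area = float(areas.sum())
    largest = float(areas.max())
    total_perim = float(perims.sum())
    ha_per_zone = zone_area_m2 / 10_000.0
    return {
        "gcr": total_area / zone_area_m2,
        "mean_patch_size": float(areas.mean()),
        "largest_patch_size": largest,
        "lpi": largest / zone_area_m2,
        "pa_ratio": float((perims / areas).mean()),
        "shape_index": float((0.25 * perims / np.sqrt(areas)).mean()),
        "ed": total_perim / ha_per_zone,
    }
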