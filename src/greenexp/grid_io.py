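"""Gridded raster and zone-polygon I/O.

Rasters are single-band float32 GeoTIFFs in a projected (metric) coordinate
system; nodata is carried as an explicit tag. Zones are GeoJSON
FeatureCollections of polygons with a ``zone_id`` property and, where the
seasonal analysis needs it, a ``hemisphere`` ("N"/"S") property.

Everything downstream assumes all grids of one analysis share cell size and
alignment; resampling is deliberately out of scope and any mismatch raises.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import shapely
import tifffile
from shapely.geometry import shape as shapely_shape, mapping as shapely_mapping

__all__ = [
    "Grid",
    "Zone",
    "ZoneSet",
    "GridAlignmentError",
    "read_grid",
    "write_grid",
    "read_zones",
    "write_zones",
    "rasterize_zones",
]

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# GeoKey ids
_GT_MODEL_TYPE = 1024  # 1 = projected, 2 = geographic
_PROJECTED_CS_TYPE = 3072

_NODATA_VALUE = -9999.0


class GridAlignmentError(ValueError):
    """Grids in one analysis do not share cell size / shape / origin."""


@dataclass
class Grid:
    """A georeferenced single-variable raster.

    Parameters
    ----------
    values : 2-D float array
        Greenspace fraction in [0, 1] or population count >= 0.
    cell_size : float
        Edge length of a (square) cell in meters.
    origin : (float, float)
        Projected (x, y) of the top-left corner of the top-left cell.
    nodata_mask : 2-D bool array
        True where the cell carries no data.
    crs_epsg : int
        EPSG code of the projected CRS (metadata only; no reprojection).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None
    crs_epsg: int = 32633

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be a 2-D array")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata_mask shape must match values shape")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each of grid shape."""
        rows, cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def assert_aligned(self, other: "Grid") -> None:
        if self.shape != other.shape:
            raise GridAlignmentError(
                f"grid shapes differ: {self.shape} vs {other.shape}"
            )
        if not np.isclose(self.cell_size, other.cell_size):
            raise GridAlignmentError(
                f"cell sizes differ: {self.cell_size} vs {other.cell_size}"
            )
        if not np.allclose(self.origin, other.origin):
            raise GridAlignmentError(
                f"origins differ: {self.origin} vs {other.origin}"
            )


@dataclass
class Zone:
    zone_id: str
    geometry: Any  # shapely polygon / multipolygon
    attributes: dict = field(default_factory=dict)

    @property
    def hemisphere(self) -> str | None:
        return self.attributes.get("hemisphere")


@dataclass
class ZoneSet:
    zones: list[Zone]

    def __post_init__(self) -> None:
        ids = [z.zone_id for z in self.zones]
        if len(set(ids)) != len(ids):
            raise ValueError("zone_ids must be unique")
        for z in self.zones:
            if not z.geometry.is_valid:
                raise ValueError(f"zone {z.zone_id!r}: invalid polygon")

    def __iter__(self):
        return iter(self.zones)

    def __len__(self) -> int:
        return len(self.zones)


def _validate_role(values: np.ndarray, mask: np.ndarray, role: str) -> None:
    valid = values[~mask]
    if role == "greenspace":
        if valid.size and (valid.min() < 0 or valid.max() > 1):
            raise ValueError(
                "greenspace raster has values outside [0, 1]; "
                f"range is [{valid.min():g}, {valid.max():g}]"
            )
    elif role == "population":
        if valid.size and valid.min() < 0:
            raise ValueError(
                f"population raster has negative values (min {valid.min():g})"
            )
    else:
        raise ValueError(f"unknown grid role {role!r}")


def write_grid(grid: Grid, path) -> None:
    """Write a Grid as a single-band float32 GeoTIFF with nodata tag."""
    data = np.asarray(grid.values, dtype=np.float32).copy()
    data[grid.nodata_mask] = _NODATA_VALUE
    geokeys = (
        1, 1, 0, 2,                      # version header, 2 keys
        _GT_MODEL_TYPE, 0, 1, 1,         # projected CRS
        _PROJECTED_CS_TYPE, 0, 1, grid.crs_epsg,
    )
    x0, y0 = grid.origin
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_GDAL_NODATA, "s", 0, str(_NODATA_VALUE)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def read_grid(path, role: str = "greenspace") -> Grid:
    """Read a single-band georeferenced GeoTIFF.

    ``role`` ("greenspace" or "population") selects the value-range check.
    Rasters without georeferencing keys, or in a geographic (degree) CRS,
    are rejected: buffer distances are in meters.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        if _GEO_KEY_DIRECTORY not in tags or _MODEL_PIXEL_SCALE not in tags:
            raise ValueError(f"unreferenced raster: {path}")
        geokeys = tags[_GEO_KEY_DIRECTORY].value
        keymap = {
            geokeys[i]: geokeys[i + 3] for i in range(4, len(geokeys), 4)
        }
        if keymap.get(_GT_MODEL_TYPE) == 2:
            raise ValueError(
                f"raster {path} is in a geographic (degree) CRS; reproject "
                "to a projected metric CRS before use (buffer math needs meters)"
            )
        scale = tags[_MODEL_PIXEL_SCALE].value
        if not np.isclose(scale[0], scale[1]):
            raise ValueError("non-square cells are not supported")
        tiepoint = tags[_MODEL_TIEPOINT].value if _MODEL_TIEPOINT in tags else (
            0, 0, 0, 0, 0, 0
        )
        nodata = _NODATA_VALUE
        if _GDAL_NODATA in tags:
            nodata = float(tags[_GDAL_NODATA].value)
        data = page.asarray().astype(float)
    if data.ndim != 2:
        raise ValueError("expected a single-band raster")
    mask = np.isclose(data, nodata) | ~np.isfinite(data)
    data = data.copy()
    data[mask] = 0.0
    _validate_role(data, mask, role)
    return Grid(
        values=data,
        cell_size=float(scale[0]),
        origin=(float(tiepoint[3]), float(tiepoint[4])),
        nodata_mask=mask,
        crs_epsg=int(keymap.get(_PROJECTED_CS_TYPE, 0)),
    )


def write_zones(zones: ZoneSet, path) -> None:
    features = []
    for z in zones:
        props = {"zone_id": z.zone_id, **z.attributes}
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": shapely_mapping(z.geometry),
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def read_zones(path) -> ZoneSet:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("zones file must be a GeoJSON FeatureCollection")
    zones = []
    for feat in doc["features"]:
        props = dict(feat.get("properties") or {})
        zone_id = props.pop("zone_id", None)
        if zone_id is None:
            raise ValueError("every zone feature needs a 'zone_id' property")
        zones.append(
            Zone(
                zone_id=str(zone_id),
                geometry=shapely_shape(feat["geometry"]),
                attributes=props,
            )
        )
    return ZoneSet(zones)


def rasterize_zones(zones: ZoneSet, template: Grid) -> np.ndarray:
    """Label template cells by the zone containing their center.

    Returns an integer array of the template's shape: 0 outside every zone,
    ``k`` for the k-th zone (1-based, in zone list order). A cell whose
    center lies in several (overlapping) zones keeps the earliest zone in
    list order; a warning is emitted. Centers exactly on a polygon boundary
    count as inside ("covers" semantics).
    """
    xs, ys = template.cell_centers()
    labels = np.zeros(template.shape, dtype=np.int32)
    overlap = False
    for k, zone in enumerate(zones, start=1):
        inside = shapely.intersects_xy(zone.geometry, xs, ys)
        taken = inside & (labels > 0)
        if taken.any():
            overlap = True
        labels[inside & (labels == 0)] = k
    if overlap:
        warnings.warn(
            "overlapping zones: cells assigned to the first zone in list order",
            stacklevel=2,
        )
    return labels
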