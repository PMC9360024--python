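"""Seasonal exposure, inequality, and spatiotemporal variation statistics.

Vegetation phenology makes greenspace exposure seasonal: deciduous canopies
drop their greenness in winter, arid-region grass browns in dry seasons.
This module labels calendar months into local seasons per hemisphere,
recomputes exposure and its Gini for each season, and condenses the
within-city spatial variability into

    csv  = sigma / mu        (coefficient of spatial variation of the
                              gridded exposure field, one value per season)
    cstv = std over the four seasonal csv values,

where sigma and mu are the population (ddof=0) standard deviation and the
mean — the four seasons are the complete set of seasons, not a sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import exposure_report
from .grid_io import Grid, ZoneSet, rasterize_zones
from .inequality import DEFAULT_THRESHOLDS, zone_gini

__all__ = [
    "SEASONS",
    "SeasonalExposure",
    "season_of",
    "csv_stat",
    "cstv_stat",
    "seasonal_report",
    "seasonal_to_frame",
]

SEASONS = ("spring", "summer", "autumn", "winter")

# Northern-hemisphere month -> season; the south is shifted by two quarters.
_NORTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}
_OPPOSITE = {"spring": "autumn", "summer": "winter",
             "autumn": "spring", "winter": "summer"}

#: Calendar quarters usable as stack keys instead of local season names.
QUARTER_MONTHS = {"DJF": 12, "MAM": 3, "JJA": 6, "SON": 9}


@dataclass
class SeasonalExposure:
    zone_id: str
    GE: dict[str, float] = field(default_factory=dict)
    gini: dict[str, float] = field(default_factory=dict)
    csv: dict[str, float] = field(default_factory=dict)
    cstv: float | None = None
    dGini_sw: float | None = None       # gini_summer - gini_winter
    dcsv_sw: float | None = None        # csv_summer - csv_winter
    error: str | None = None


def season_of(month: int, hemisphere: str) -> str:
    """Local season of a calendar month ("N" or "S" hemisphere)."""
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    if hemisphere not in ("N", "S"):
        raise ValueError(f"hemisphere must be 'N' or 'S', got {hemisphere!r}")
    season = _NORTH[int(month)]
    return season if hemisphere == "N" else _OPPOSITE[season]


def csv_stat(exposure_cells: np.ndarray) -> float:
    """Coefficient of spatial variation sigma/mu of a zone's exposure field."""
    cells = np.asarray(exposure_cells, dtype=float)
    if cells.size == 0:
        raise ValueError("csv_stat needs at least one cell")
    mu = cells.mean()
    if mu == 0:
        raise ValueError("zero-mean exposure")
    return float(cells.std(ddof=0) / mu)


def cstv_stat(csv_by_season: dict[str, float]) -> float:
    """Population SD over the four seasonal csv values."""
    missing = [s for s in SEASONS if s not in csv_by_season]
    if missing:
        raise ValueError(f"missing seasons: {missing}")
    vals = np.array([csv_by_season[s] for s in SEASONS], dtype=float)
    return float(vals.std(ddof=0))


def _season_keyed(
    green_by_season: dict[str, Grid], hemisphere: str | None
) -> dict[str, Grid]:
    """Resolve a season- or calendar-quarter-keyed stack to local seasons."""
    keys = set(green_by_season)
    if keys == set(SEASONS):
        return green_by_season
    if keys == set(QUARTER_MONTHS):
        if hemisphere is None:
            raise ValueError(
                "calendar-quarter stack needs the zone's hemisphere attribute"
            )
        return {
            season_of(month, hemisphere): grid
            for q, grid in green_by_season.items()
            for month in [QUARTER_MONTHS[q]]
        }
    raise ValueError(
        "stack keys must be the four seasons or the four calendar quarters"
    )


def seasonal_report(
    green_by_season: dict[str, Grid],
    pop: Grid,
    zones: ZoneSet,
    radius: float,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> list[SeasonalExposure]:
    """Per-zone seasonal exposure, Gini, csv, cstv and summer-winter deltas.

    ``green_by_season`` may be keyed by local season names or by calendar
    quarters (DJF/MAM/JJA/SON); in the latter case each zone's
    ``hemisphere`` attribute maps quarters to its local seasons. csv is
    computed over the zone's per-cell buffered exposure field G^d —
    spatial variation of supply around residents, not population-weighted.
    """
    sample = next(iter(green_by_season.values()))
    labels = rasterize_zones(zones, sample)
    quarter_keyed = set(green_by_season) == set(QUARTER_MONTHS)

    # exposure/gini per season-labeled grid (computed once per distinct grid)
    reports = {
        key: exposure_report(grid, pop, zones, [radius])
        for key, grid in green_by_season.items()
    }
    from .exposure import focal_fraction

    focal = {key: focal_fraction(grid, radius)
             for key, grid in green_by_season.items()}

    out: list[SeasonalExposure] = []
    for k, zone in enumerate(zones, start=1):
        res = SeasonalExposure(zone_id=zone.zone_id)
        try:
            if quarter_keyed:
                if zone.hemisphere not in ("N", "S"):
                    raise ValueError(
                        f"zone {zone.zone_id}: hemisphere attribute required "
                        "('N' or 'S') for calendar-quarter stacks"
                    )
                key_of = {
                    season_of(QUARTER_MONTHS[q], zone.hemisphere): q
                    for q in QUARTER_MONTHS
                }
            else:
                key_of = {s: s for s in SEASONS}
            zmask = labels == k
            for season in SEASONS:
                key = key_of[season]
                rep = reports[key][k - 1]
                if rep.error:
                    raise ValueError(rep.error)
                res.GE[season] = rep.GE_by_radius[radius]
                res.gini[season] = zone_gini(rep, thresholds).gini
                fsel = zmask & focal[key].valid_mask
                res.csv[season] = csv_stat(focal[key].values[fsel])
            res.cstv = cstv_stat(res.csv)
            res.dGini_sw = res.gini["summer"] - res.gini["winter"]
            res.dcsv_sw = res.csv["summer"] - res.csv["winter"]
        except ValueError as exc:
            res.error = str(exc)
        out.append(res)
    return out


def seasonal_to_frame(results: list[SeasonalExposure]) -> pd.DataFrame:
    rows = []
    for r in results:
        row: dict = {"zone_id": r.zone_id}
        for s in SEASONS:
            row[f"GE_{s}"] = r.GE.get(s)
            row[f"gini_{s}"] = r.gini.get(s)
            row[f"csv_{s}"] = r.csv.get(s)
        row["cstv"] = r.cstv
        row["dGini_sw"] = r.dGini_sw
        row["dcsv_sw"] = r.dcsv_sw
        row["error"] = r.error or ""
        rows.append(row)
    return pd.DataFrame(rows)
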