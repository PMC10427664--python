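"""Derive the four continuous species traits from raw measurements.

Body size is the geometric mean of shell length and height; geographic range
is the convex-hull area of projected point occurrences with a 100 km^2 floor
for single-occurrence (and otherwise degenerate) species; thermal range is
the spread of sea-surface temperature over the grid cells a species' hull
intersects; minimum bathymetry may be imputed from verbal habitat
descriptors when no numeric depth is reported.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point, box

from .types import OccurrenceSet, ShelfGrid

__all__ = [
    "body_size",
    "convex_hull_area",
    "geographic_range_area",
    "occupied_cells",
    "thermal_range",
    "impute_min_bathymetry",
    "RANGE_FLOOR_KM2",
    "BATHYMETRY_DESCRIPTORS",
]

logger = logging.getLogger(__name__)

#: operational range size assigned to single-occurrence species (10 x 10 km)
RANGE_FLOOR_KM2 = 100.0

#: verbal habitat descriptors accepted in place of a numeric minimum depth
BATHYMETRY_DESCRIPTORS = {
    "subtidal": 5.0,
    "sublittoral": 5.0,
    "shallow water": 10.0,
}


def body_size(length_mm: float, height_mm: float) -> float:
    """Geometric mean of shell length (anterior-posterior) and height
    (dorsal-ventral), in mm."""
    if not (length_mm > 0 and height_mm > 0):
        raise ValueError("shell length and height must be positive")
    return math.sqrt(length_mm * height_mm)


def _check_finite(points: Sequence[tuple[float, float]]) -> None:
    for x, y in points:
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValueError(f"non-finite coordinate: ({x}, {y})")


def _hull_geometry(points: Sequence[tuple[float, float]]):
    """Convex hull of projected points; may be a Point, LineString or Polygon."""
    if len(points) == 0:
        raise ValueError("at least one point required")
    _check_finite(points)
    return MultiPoint([Point(x, y) for x, y in points]).convex_hull


def convex_hull_area(points: Sequence[tuple[float, float]]) -> float:
    """Area (km^2) of the 2-D convex hull; 0 for degenerate point sets."""
    return float(_hull_geometry(points).area)


def geographic_range_area(
    occ: OccurrenceSet,
    floor_km2: float = RANGE_FLOOR_KM2,
    override: float | None = None,
) -> float:
    """Convex-hull range area with the operational floor.

    ``override`` replaces the computed value for species whose limited range
    is known independently (e.g. a single estuary)."""
    if override is not None:
        if override < 0:
            raise ValueError("override range area must be nonnegative")
        return float(override)
    if not occ.points:
        raise ValueError(f"{occ.species_id}: no point occurrences")
    return max(convex_hull_area(occ.points), float(floor_km2))


def occupied_cells(occ: OccurrenceSet, grid: ShelfGrid) -> set[str]:
    """Grid cells intersected by the species' convex hull.

    A polygonal hull claims every cell it overlaps with positive area; a
    degenerate hull (point or segment) claims the cells it touches. Cells
    listed directly on the occurrence set are passed through unchanged.
    """
    if len(grid) == 0:
        raise ValueError("grid is empty")
    out: set[str] = set()
    for cid in occ.cells:
        if cid not in grid:
            raise KeyError(f"{occ.species_id}: cell {cid!r} not in grid")
        out.add(cid)
    if occ.points:
        hull = _hull_geometry(occ.points)
        minx, miny, maxx, maxy = hull.bounds
        h = grid.cell_size_km / 2.0
        cx = grid.cells["cx"].to_numpy(float)
        cy = grid.cells["cy"].to_numpy(float)
        near = (
            (cx + h >= minx) & (cx - h <= maxx) & (cy + h >= miny) & (cy - h <= maxy)
        )
        polygonal = hull.area > 0
        for i in np.nonzero(near)[0]:
            cell = box(cx[i] - h, cy[i] - h, cx[i] + h, cy[i] + h)
            if polygonal:
                if hull.intersection(cell).area > 0:
                    out.add(grid.cells.at[i, "cell_id"])
            elif cell.intersects(hull):
                out.add(grid.cells.at[i, "cell_id"])
    if not out:
        logger.warning("%s: occurrences fall outside the grid", occ.species_id)
    return out


def thermal_range(cells: Iterable[str], grid: ShelfGrid) -> float:
    """Spread (max - min, degC) of cell SST over occupied cells."""
    ssts = []
    for cid in cells:
        if cid not in grid:
            raise KeyError(f"cell {cid!r} not in grid")
        v = grid.sst(cid)
        if math.isnan(v):
            logger.warning("cell %s has no SST; excluded from thermal range", cid)
            continue
        ssts.append(v)
    if not ssts:
        raise ValueError("no occupied cell has an SST value")
    return float(max(ssts) - min(ssts))


def impute_min_bathymetry(descriptor: str) -> tuple[float | None, bool]:
    """Minimum bathymetry (m) from a verbal habitat descriptor.

    Returns ``(depth_m, imputed_flag)``; unrecognized descriptors yield
    ``(None, False)`` with a log entry, so sensitivity runs can exclude
    imputed species."""
    key = descriptor.strip().lower()
    if key in BATHYMETRY_DESCRIPTORS:
        return BATHYMETRY_DESCRIPTORS[key], True
    logger.info("unrecognized bathymetry descriptor: %r", descriptor)
    return None, False
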