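"""Readers and writers for the pipeline's delimited-text and GeoJSON formats.

Species tables are UTF-8 CSV with a header; published trait compilations
spell their headers differently, so column names pass through a
configurable alias table. Missing
values are empty fields, never sentinel numbers (a minimum bathymetry of
0 m is a legal intertidal value). Grids are GeoJSON FeatureCollections of
square cells; trees are newick; fossil ranges and stage scales are CSV.
"""

from __future__ import annotations

import json
import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .treeutils import FamilyTree
from .types import (
    FossilRange,
    FossilRangeSet,
    OccurrenceSet,
    ShelfGrid,
    SpeciesRecord,
    StageScale,
)
from .types import (
    ATTACHMENT_CATEGORIES,
    FEEDING_CATEGORIES,
    MOBILITY_CATEGORIES,
    POSITION_CATEGORIES,
)

__all__ = [
    "DEFAULT_ALIASES",
    "read_species_table",
    "write_species_table",
    "read_occurrences",
    "write_occurrences",
    "read_grid_geojson",
    "write_grid_geojson",
    "read_newick",
    "read_fossil_ranges",
    "write_fossil_ranges",
    "read_stage_scale",
    "write_stage_scale",
]

logger = logging.getLogger(__name__)

#: canonical column -> accepted header spellings (lower-cased before matching)
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "species_id": ("species_id", "species", "taxon", "scientific_name"),
    "family": ("family",),
    "exploited": ("exploited", "exploited_flag", "is_exploited"),
    "in_fao": ("in_fao", "fao", "fao_flag", "in_fao_production"),
    "size_mm": ("size_mm", "size", "shell_size", "body_size_mm"),
    "min_bathy_m": ("min_bathy_m", "mb", "min_bathymetry", "minimum_bathymetry_m"),
    "bathy_imputed": ("bathy_imputed", "bathymetry_imputed"),
    "gra_km2": ("gra_km2", "gra", "geographic_range_area", "range_area_km2"),
    "tr_c": ("tr_c", "tr", "thermal_range", "thermal_range_c"),
    "feeding": ("feeding", "feeding_type"),
    "attachment": ("attachment", "substratum_attachment"),
    "mobility": ("mobility",),
    "position": ("position", "living_position"),
    "qhat": ("qhat", "q_hat", "q"),
    "peril": ("peril", "peril_score"),
}

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n", ""}

_CATEGORIES = {
    "feeding": FEEDING_CATEGORIES,
    "attachment": ATTACHMENT_CATEGORIES,
    "mobility": MOBILITY_CATEGORIES,
    "position": POSITION_CATEGORIES,
}


def _parse_bool(value, context: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise ValueError(f"{context}: cannot parse boolean {value!r}")


def _parse_opt_float(value) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.lower() == "nan":
        return None
    return float(s)


def read_species_table(
    path: str, aliases: Mapping[str, tuple[str, ...]] | None = None
) -> list[SpeciesRecord]:
    """Read a species trait table, validating categories and invariants.

    Rows with out-of-vocabulary categorical values are rejected with a
    logged reason; a duplicated species id is an error.
    """
    aliases = dict(DEFAULT_ALIASES, **(aliases or {}))
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    lower_cols = {c.strip().lower(): c for c in df.columns}
    colmap: dict[str, str] = {}
    for canon, names in aliases.items():
        for name in names:
            if name.lower() in lower_cols:
                colmap[canon] = lower_cols[name.lower()]
                break
    required = {"species_id", "family", "exploited"}
    missing = required - set(colmap)
    if missing:
        raise ValueError(f"species table missing required columns: {sorted(missing)}")

    def get(row, canon):
        return row[colmap[canon]] if canon in colmap else None

    records: list[SpeciesRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        sid = str(get(row, "species_id")).strip()
        if sid in seen:
            raise ValueError(f"duplicate species_id: {sid!r}")
        seen.add(sid)
        cats: dict[str, str | None] = {}
        bad = None
        for name, allowed in _CATEGORIES.items():
            raw = get(row, name)
            val = None if raw is None or str(raw).strip() == "" else str(raw).strip().lower()
            if val is not None and val not in allowed:
                bad = (name, val)
                break
            cats[name] = val
        if bad:
            logger.warning(
                "row %d (%s) rejected: %s=%r not in the closed vocabulary",
                i, sid, bad[0], bad[1],
            )
            continue
        rec = SpeciesRecord(
            species_id=sid,
            family=str(get(row, "family")).strip(),
            exploited=_parse_bool(get(row, "exploited"), sid),
            in_fao=_parse_bool(get(row, "in_fao"), sid) if "in_fao" in colmap else False,
            shell_size=_parse_opt_float(get(row, "size_mm")),
            min_bathymetry=_parse_opt_float(get(row, "min_bathy_m")),
            bathymetry_imputed=(
                _parse_bool(get(row, "bathy_imputed"), sid)
                if "bathy_imputed" in colmap
                else False
            ),
            geographic_range_area=_parse_opt_float(get(row, "gra_km2")),
            thermal_range=_parse_opt_float(get(row, "tr_c")),
            feeding=cats["feeding"],
            attachment=cats["attachment"],
            mobility=cats["mobility"],
            position=cats["position"],
            qhat=_parse_opt_float(get(row, "qhat")),
            peril=_parse_opt_float(get(row, "peril")),
        )
        rec.validate()
        records.append(rec)
    return records


def write_species_table(records: list[SpeciesRecord], path: str) -> None:
    """Write records as CSV with canonical headers; absent values are empty."""
    rows = []
    for r in records:
        rows.append(
            {
                "species_id": r.species_id,
                "family": r.family,
                "exploited": r.exploited,
                "in_fao": r.in_fao,
                "size_mm": r.shell_size,
                "min_bathy_m": r.min_bathymetry,
                "bathy_imputed": r.bathymetry_imputed,
                "gra_km2": r.geographic_range_area,
                "tr_c": r.thermal_range,
                "feeding": r.feeding,
                "attachment": r.attachment,
                "mobility": r.mobility,
                "position": r.position,
                "qhat": r.qhat,
                "peril": r.peril,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_occurrences(path: str) -> dict[str, OccurrenceSet]:
    """Read occurrences: CSV with either (species_id, x_km, y_km) points or
    (species_id, cell_id) cell occupancies."""
    df = pd.read_csv(path)
    cols = {c.lower() for c in df.columns}
    out: dict[str, OccurrenceSet] = {}
    if {"x_km", "y_km"} <= cols:
        for sid, grp in df.groupby("species_id"):
            occ = OccurrenceSet(
                species_id=str(sid),
                points=[(float(x), float(y)) for x, y in zip(grp["x_km"], grp["y_km"])],
            )
            occ.validate()
            out[str(sid)] = occ
    elif "cell_id" in cols:
        for sid, grp in df.groupby("species_id"):
            occ = OccurrenceSet(
                species_id=str(sid), cells={str(c) for c in grp["cell_id"]}
            )
            occ.validate()
            out[str(sid)] = occ
    else:
        raise ValueError("occurrence file needs x_km/y_km or cell_id columns")
    return out


def write_occurrences(occ: dict[str, OccurrenceSet], path: str) -> None:
    rows = []
    any_points = any(o.points for o in occ.values())
    for sid in sorted(occ):
        o = occ[sid]
        if any_points:
            for x, y in o.points:
                rows.append({"species_id": sid, "x_km": x, "y_km": y})
        else:
            for cid in sorted(o.cells):
                rows.append({"species_id": sid, "cell_id": cid})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_grid_geojson(path: str) -> ShelfGrid:
    """Read a square-cell grid from a GeoJSON FeatureCollection.

    Cell identity and attributes come from feature properties (cell_id,
    sst_mean, climate_zone, region, coast); the centroid and the common cell
    size come from the polygon ring."""
    with open(path) as fh:
        gj = json.load(fh)
    rows = []
    sizes = []
    for feat in gj["features"]:
        props = feat.get("properties", {})
        geom = feat["geometry"]
        if geom["type"] != "Polygon":
            raise ValueError("grid cells must be Polygon features")
        ring = geom["coordinates"][0]
        xs = [p[0] for p in ring]
        ys = [p[1] for p in ring]
        rows.append(
            {
                "cell_id": str(props["cell_id"]),
                "cx": (min(xs) + max(xs)) / 2.0,
                "cy": (min(ys) + max(ys)) / 2.0,
                "sst_mean": props.get("sst_mean", math.nan),
                "climate_zone": props.get("climate_zone"),
                "region": props.get("region"),
                "coast": props.get("coast"),
            }
        )
        sizes.append(max(xs) - min(xs))
    if not rows:
        raise ValueError("empty grid")
    return ShelfGrid(pd.DataFrame(rows), cell_size_km=float(np.median(sizes)))


def write_grid_geojson(grid: ShelfGrid, path: str, extra: pd.DataFrame | None = None) -> None:
    """Write the grid (optionally joined with per-cell extra columns keyed on
    cell_id) as a GeoJSON FeatureCollection of squares."""
    cells = grid.cells
    if extra is not None:
        cells = cells.merge(extra, on="cell_id", how="left")
    h = grid.cell_size_km / 2.0
    feats = []
    for _, row in cells.iterrows():
        cx, cy = float(row["cx"]), float(row["cy"])
        props = {}
        for k, v in row.items():
            if k in ("cx", "cy"):
                continue
            if isinstance(v, float) and math.isnan(v):
                v = None
            elif isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating,)):
                v = float(v)
            elif isinstance(v, (np.bool_,)):
                v = bool(v)
            props[k] = v
        ring = [
            [cx - h, cy - h],
            [cx + h, cy - h],
            [cx + h, cy + h],
            [cx - h, cy + h],
            [cx - h, cy - h],
        ]
        feats.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_newick(path: str) -> FamilyTree:
    """Read a time-scaled tree; errors on missing branch lengths, warns when
    the tree is not ultrametric, preserves polytomies."""
    return FamilyTree.from_newick(path, path=True)


def read_fossil_ranges(path: str, scale: StageScale | None = None) -> FossilRangeSet:
    """Read genus first/last stage occurrences; validates against ``scale``."""
    df = pd.read_csv(path, dtype=str)
    needed = {"genus", "family", "first_stage", "last_stage"}
    if not needed <= {c.lower() for c in df.columns}:
        raise ValueError(f"fossil table needs columns {sorted(needed)}")
    df.columns = [c.lower() for c in df.columns]
    ranges = FossilRangeSet(
        [
            FossilRange(
                genus=str(r.genus).strip(),
                family=str(r.family).strip(),
                first_stage=str(r.first_stage).strip(),
                last_stage=str(r.last_stage).strip(),
            )
            for r in df.itertuples(index=False)
        ]
    )
    if scale is not None:
        ranges.validate(scale)
    return ranges


def write_fossil_ranges(ranges: FossilRangeSet, path: str) -> None:
    pd.DataFrame(
        [
            {
                "genus": r.genus,
                "family": r.family,
                "first_stage": r.first_stage,
                "last_stage": r.last_stage,
            }
            for r in ranges.records
        ]
    ).to_csv(path, index=False)


def read_stage_scale(path: str) -> StageScale:
    """Read a stage scale CSV (name, base_age, top_age), oldest first."""
    df = pd.read_csv(path)
    return StageScale(
        names=[str(n) for n in df["name"]],
        base_age=[float(v) for v in df["base_age"]],
        top_age=[float(v) for v in df["top_age"]],
    )


def write_stage_scale(scale: StageScale, path: str) -> None:
    pd.DataFrame(
        {"name": scale.names, "base_age": scale.base_age, "top_age": scale.top_age}
    ).to_csv(path, index=False)
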