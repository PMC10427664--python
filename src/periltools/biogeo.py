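"""Per-cell richness, exploitation and vulnerability on the shelf grid.

Species contribute to every grid cell their hull-derived occupancy touches,
regardless of where they are fished, so maps reflect the broadest spatial
footprint exploitation could have. Vulnerability layers count, per cell, the
species whose PERIL score strictly exceeds a global or region-specific
quantile threshold.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .peril import classify
from .types import ShelfGrid, SpeciesRecord, ThresholdRule, VulnerabilityLayer

__all__ = [
    "richness_map",
    "proportion_map",
    "assign_regions",
    "species_regions",
    "vulnerability_layer",
]

logger = logging.getLogger(__name__)

#: tropic and polar-circle latitudes bounding the default climate bands
TROPICAL_LAT = 23.44
POLAR_LAT = 66.56


def richness_map(
    occupancy: Mapping[str, set[str]],
    keep: Callable[[str], bool] | None = None,
) -> pd.Series:
    """Count species per cell, optionally filtered by a per-species predicate."""
    if not occupancy:
        raise ValueError("occupancy is empty")
    counts: dict[str, int] = {}
    for sp, cells in occupancy.items():
        if keep is not None and not keep(sp):
            continue
        for cid in cells:
            counts[cid] = counts.get(cid, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def proportion_map(numerator: pd.Series, denominator: pd.Series) -> pd.Series:
    """Elementwise per-cell fraction; NaN where the denominator is zero.

    The numerator must count a subset of the denominator's species, so every
    numerator cell must appear in the denominator."""
    extra = set(numerator.index) - set(denominator.index)
    if extra:
        raise ValueError(f"numerator cells missing from denominator: {sorted(extra)[:5]}")
    num = numerator.reindex(denominator.index, fill_value=0).astype(float)
    den = denominator.astype(float)
    out = num / den.where(den > 0)
    return out


def assign_regions(
    grid: ShelfGrid, scheme: Mapping[str, str] | None = None, default: str | None = None
) -> dict[str, str]:
    """Deterministic region label per cell.

    With a ``scheme`` table the label is looked up (falling back to
    ``default`` if given, else erroring on uncovered cells). Without one,
    the packaged scheme assigns latitudinal climate bands from the cell
    centroid (|lat| <= 23.44 tropical, <= 66.56 temperate, else polar),
    crossed with the grid's coastline label when a ``coast`` column exists.
    """
    out: dict[str, str] = {}
    if scheme is not None:
        for cid in grid.cell_ids:
            if cid in scheme:
                out[cid] = scheme[cid]
            elif default is not None:
                out[cid] = default
            else:
                raise KeyError(f"cell {cid!r} not covered by the region scheme")
        return out
    has_coast = "coast" in grid.cells.columns and grid.cells["coast"].notna().any()
    for i, cid in enumerate(grid.cell_ids):
        lat = abs(grid.latitude_deg(cid))
        zone = "tropical" if lat <= TROPICAL_LAT else (
            "temperate" if lat <= POLAR_LAT else "polar"
        )
        if has_coast:
            out[cid] = f"{zone}:{grid.cells.at[i, 'coast']}"
        else:
            out[cid] = zone
    return out


def species_regions(
    occupancy: Mapping[str, set[str]], cell_regions: Mapping[str, str]
) -> dict[str, str]:
    """Assign each species the region holding most of its occupied cells;
    ties break alphabetically."""
    out: dict[str, str] = {}
    for sp, cells in occupancy.items():
        tally: dict[str, int] = {}
        for cid in cells:
            reg = cell_regions[cid]
            tally[reg] = tally.get(reg, 0) + 1
        if not tally:
            continue
        out[sp] = min(tally, key=lambda r: (-tally[r], r))
    return out


def vulnerability_layer(
    records: list[SpeciesRecord],
    occupancy: Mapping[str, set[str]],
    rule: ThresholdRule,
    cell_regions: Mapping[str, str] | None = None,
) -> VulnerabilityLayer:
    """Per-cell vulnerability tallies under a quantile threshold rule.

    Each cell reports its species count, exploited count, vulnerable count
    (PERIL strictly above the rule's global or regional quantile), the
    vulnerable-and-exploited count, the proportion of species exploited, the
    proportion of exploited species that are vulnerable, and the proportion
    of vulnerable species that are exploited. Species without occupied cells
    are excluded with a log entry.
    """
    by_id = {r.species_id: r for r in records}
    scored = {
        sid: r.peril
        for sid, r in by_id.items()
        if r.peril is not None and occupancy.get(sid)
    }
    dropped = [r.species_id for r in records if r.species_id not in scored]
    if dropped:
        logger.warning(
            "%d species excluded from the layer (no score or no cells)", len(dropped)
        )
    if not scored:
        raise ValueError("no scored species with occupied cells")

    if rule.scope == "regional":
        if cell_regions is None:
            raise ValueError("regional scope requires cell region labels")
        sp_region = species_regions(
            {sid: occupancy[sid] for sid in scored}, cell_regions
        )
        labels = classify(scored, rule, regions=sp_region)
    else:
        labels = classify(scored, rule)
    vulnerable = {sid for sid, lab in zip(scored, labels) if lab == "above"}

    cells = sorted({cid for sid in scored for cid in occupancy[sid]})
    idx = {cid: k for k, cid in enumerate(cells)}
    n_sp = np.zeros(len(cells), dtype=int)
    n_ex = np.zeros(len(cells), dtype=int)
    n_vu = np.zeros(len(cells), dtype=int)
    n_ve = np.zeros(len(cells), dtype=int)
    for sid in scored:
        ex = by_id[sid].exploited
        vu = sid in vulnerable
        for cid in occupancy[sid]:
            k = idx[cid]
            n_sp[k] += 1
            n_ex[k] += ex
            n_vu[k] += vu
            n_ve[k] += ex and vu
    with np.errstate(invalid="ignore", divide="ignore"):
        prop_ex = np.where(n_sp > 0, n_ex / np.maximum(n_sp, 1), np.nan)
        prop_ve = np.where(n_ex > 0, n_ve / np.maximum(n_ex, 1), np.nan)
        prop_ev = np.where(n_vu > 0, n_ve / np.maximum(n_vu, 1), np.nan)
    table = pd.DataFrame(
        {
            "cell_id": cells,
            "n_species": n_sp,
            "n_exploited": n_ex,
            "n_vulnerable": n_vu,
            "n_vulnerable_exploited": n_ve,
            "prop_exploited": prop_ex,
            "prop_vulnerable_exploited": prop_ve,
            "prop_exploited_among_vulnerable": prop_ev,
        }
    )
    layer = VulnerabilityLayer(
        table=table,
        threshold_scope=rule.scope,
        threshold_quantile=rule.quantile,
    )
    layer.validate()
    return layer
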