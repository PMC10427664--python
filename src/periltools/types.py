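"""Domain types for the vulnerability-analysis pipeline.

The central objects are :class:`SpeciesRecord` (one shallow-marine bivalve
species with its four continuous traits, functional categories, exploitation
flags and derived scores), :class:`OccurrenceSet` (projected point occurrences
and/or grid-cell occupancies), :class:`ShelfGrid` (the equal-area 50 x 50 km
continental-shelf grid with per-cell sea-surface temperature and region
labels), the fossil-range containers feeding the clade-volatility estimate,
and :class:`VulnerabilityLayer` (per-cell counts and proportions of exploited
and vulnerable species under a quantile threshold rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEEDING_CATEGORIES",
    "ATTACHMENT_CATEGORIES",
    "MOBILITY_CATEGORIES",
    "POSITION_CATEGORIES",
    "SpeciesRecord",
    "OccurrenceSet",
    "ShelfGrid",
    "StageScale",
    "FossilRange",
    "FossilRangeSet",
    "IntervalCounts",
    "PerilComponents",
    "ThresholdRule",
    "VulnerabilityLayer",
    "PhyloDResult",
    "SignalResult",
    "ModelFit",
]

FEEDING_CATEGORIES = frozenset(
    {"suspension", "deposit", "chemosymbiotic", "carnivore", "other"}
)
ATTACHMENT_CATEGORIES = frozenset({"attached", "unattached"})
MOBILITY_CATEGORIES = frozenset({"mobile", "immobile"})
POSITION_CATEGORIES = frozenset({"infaunal", "epifaunal"})


@dataclass
class SpeciesRecord:
    """One species: traits, exploitation flags and derived scores.

    Continuous traits: ``shell_size`` is the geometric mean of shell length
    and height (mm); ``min_bathymetry`` the shallowest reported occurrence
    depth (m, 0 = intertidal, may be absent); ``geographic_range_area`` the
    convex-hull range area (km^2, floored at 100); ``thermal_range`` the
    spread of sea-surface temperature across occupied grid cells (degC).
    ``qhat`` is the family's per-capita genus extinction rate through the
    Cenozoic (per Myr); ``peril`` the composite vulnerability score in [0, 1],
    absent until computed.
    """

    species_id: str
    family: str
    exploited: bool
    in_fao: bool = False
    shell_size: float | None = None
    min_bathymetry: float | None = None
    bathymetry_imputed: bool = False
    geographic_range_area: float | None = None
    thermal_range: float | None = None
    feeding: str | None = None
    attachment: str | None = None
    mobility: str | None = None
    position: str | None = None
    qhat: float | None = None
    peril: float | None = None

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated field invariant."""
        if self.shell_size is not None and not self.shell_size > 0:
            raise ValueError(f"{self.species_id}: shell_size must be > 0")
        if self.min_bathymetry is not None and self.min_bathymetry < 0:
            raise ValueError(f"{self.species_id}: min_bathymetry must be >= 0")
        if (
            self.geographic_range_area is not None
            and self.geographic_range_area < 100.0
        ):
            raise ValueError(
                f"{self.species_id}: geographic_range_area below the 100 km^2 floor"
            )
        if self.thermal_range is not None and self.thermal_range < 0:
            raise ValueError(f"{self.species_id}: thermal_range must be >= 0")
        if self.qhat is not None and self.qhat < 0:
            raise ValueError(f"{self.species_id}: qhat must be >= 0")
        if self.peril is not None and not (0.0 <= self.peril <= 1.0):
            raise ValueError(f"{self.species_id}: peril outside [0, 1]")
        for name, value, allowed in (
            ("feeding", self.feeding, FEEDING_CATEGORIES),
            ("attachment", self.attachment, ATTACHMENT_CATEGORIES),
            ("mobility", self.mobility, MOBILITY_CATEGORIES),
            ("position", self.position, POSITION_CATEGORIES),
        ):
            if value is not None and value not in allowed:
                raise ValueError(
                    f"{self.species_id}: {name}={value!r} not in {sorted(allowed)}"
                )


def records_to_frame(records: Sequence[SpeciesRecord]) -> pd.DataFrame:
    """Tabulate species records (one row per species, NaN for absent values)."""
    rows = []
    for r in records:
        rows.append(
            {
                "species_id": r.species_id,
                "family": r.family,
                "exploited": r.exploited,
                "in_fao": r.in_fao,
                "size_mm": np.nan if r.shell_size is None else r.shell_size,
                "min_bathy_m": np.nan if r.min_bathymetry is None else r.min_bathymetry,
                "bathy_imputed": r.bathymetry_imputed,
                "gra_km2": np.nan
                if r.geographic_range_area is None
                else r.geographic_range_area,
                "tr_c": np.nan if r.thermal_range is None else r.thermal_range,
                "feeding": r.feeding,
                "attachment": r.attachment,
                "mobility": r.mobility,
                "position": r.position,
                "qhat": np.nan if r.qhat is None else r.qhat,
                "peril": np.nan if r.peril is None else r.peril,
            }
        )
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[SpeciesRecord]:
    """Inverse of :func:`records_to_frame`; validates each row."""

    def _opt(v):
        if v is None:
            return None
        if isinstance(v, float) and math.isnan(v):
            return None
        return v

    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        rec = SpeciesRecord(
            species_id=str(d["species_id"]),
            family=str(d["family"]),
            exploited=bool(d["exploited"]),
            in_fao=bool(d.get("in_fao", False)),
            shell_size=_opt(d.get("size_mm")),
            min_bathymetry=_opt(d.get("min_bathy_m")),
            bathymetry_imputed=bool(d.get("bathy_imputed", False)),
            geographic_range_area=_opt(d.get("gra_km2")),
            thermal_range=_opt(d.get("tr_c")),
            feeding=_opt(d.get("feeding")),
            attachment=_opt(d.get("attachment")),
            mobility=_opt(d.get("mobility")),
            position=_opt(d.get("position")),
            qhat=_opt(d.get("qhat")),
            peril=_opt(d.get("peril")),
        )
        rec.validate()
        records.append(rec)
    return records


@dataclass
class OccurrenceSet:
    """Point occurrences (projected km) and/or direct cell occupancies."""

    species_id: str
    points: list[tuple[float, float]] = field(default_factory=list)
    cells: set[str] = field(default_factory=set)

    def validate(self) -> None:
        if not self.points and not self.cells:
            raise ValueError(f"{self.species_id}: no points and no cells")
        for x, y in self.points:
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"{self.species_id}: non-finite coordinate ({x}, {y})")


class ShelfGrid:
    """Equal-area square-cell grid of the continental shelf.

    Cells live in a Lambert cylindrical equal-area projection (km units).
    Each cell carries its centroid, mean sea-surface temperature, a climate
    zone and a region label (climate zone x coastline).
    """

    #: spherical-datum radius used to translate projected y back to latitude
    EARTH_RADIUS_KM = 6371.0

    def __init__(self, cells: pd.DataFrame, cell_size_km: float = 50.0):
        required = {"cell_id", "cx", "cy"}
        missing = required - set(cells.columns)
        if missing:
            raise ValueError(f"grid table missing columns: {sorted(missing)}")
        if cells["cell_id"].duplicated().any():
            dups = cells.loc[cells["cell_id"].duplicated(), "cell_id"].tolist()
            raise ValueError(f"duplicate cell_ids: {dups[:5]}")
        self.cells = cells.reset_index(drop=True).copy()
        for col in ("sst_mean",):
            if col not in self.cells.columns:
                self.cells[col] = np.nan
        for col in ("climate_zone", "region"):
            if col not in self.cells.columns:
                self.cells[col] = None
        self.cell_size_km = float(cell_size_km)
        self._index = {cid: i for i, cid in enumerate(self.cells["cell_id"])}

    def __len__(self) -> int:
        return len(self.cells)

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self._index

    @property
    def cell_ids(self) -> list[str]:
        return list(self.cells["cell_id"])

    def sst(self, cell_id: str) -> float:
        return float(self.cells.at[self._index[cell_id], "sst_mean"])

    def centroid(self, cell_id: str) -> tuple[float, float]:
        i = self._index[cell_id]
        return float(self.cells.at[i, "cx"]), float(self.cells.at[i, "cy"])

    def bounds(self, cell_id: str) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the square cell in projected km."""
        cx, cy = self.centroid(cell_id)
        h = self.cell_size_km / 2.0
        return (cx - h, cy - h, cx + h, cy + h)

    def latitude_deg(self, cell_id: str) -> float:
        """Geographic latitude of the cell centroid on the spherical datum."""
        _, cy = self.centroid(cell_id)
        s = min(1.0, max(-1.0, cy / self.EARTH_RADIUS_KM))
        return math.degrees(math.asin(s))


@dataclass
class StageScale:
    """Ordered geological stages with base (older) and top (younger) ages in Ma."""

    names: list[str]
    base_age: list[float]
    top_age: list[float]

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.base_age) == len(self.top_age) == n) or n == 0:
            raise ValueError("stage scale must be nonempty with aligned columns")
        for i in range(n):
            if not self.base_age[i] > self.top_age[i]:
                raise ValueError(
                    f"stage {self.names[i]}: base_age must exceed top_age"
                )
            if i > 0 and abs(self.top_age[i - 1] - self.base_age[i]) > 1e-9:
                raise ValueError(
                    f"stages {self.names[i - 1]} and {self.names[i]} are not contiguous"
                )
        self._index = {name: i for i, name in enumerate(self.names)}
        if len(self._index) != n:
            raise ValueError("stage names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index(self, name: str) -> int:
        if name not in self._index:
            raise KeyError(f"unknown stage: {name!r}")
        return self._index[name]

    def duration(self, name: str) -> float:
        i = self.index(name)
        return self.base_age[i] - self.top_age[i]

    def stage_of_age(self, age_ma: float) -> str:
        """Stage containing an age (stages own their base, youngest owns 0)."""
        if age_ma > self.base_age[0] or age_ma < self.top_age[-1]:
            raise ValueError(f"age {age_ma} Ma outside the scale")
        for i, name in enumerate(self.names):
            if age_ma > self.top_age[i] or (i == len(self.names) - 1):
                return name
        return self.names[-1]  # pragma: no cover


@dataclass(frozen=True)
class FossilRange:
    """A genus' first/last stratigraphic occurrence, by stage name."""

    genus: str
    family: str
    first_stage: str
    last_stage: str


@dataclass
class FossilRangeSet:
    """Genus-level stratigraphic ranges, validated against a stage scale."""

    records: list[FossilRange]

    def validate(self, scale: StageScale) -> None:
        seen = set()
        for r in self.records:
            if r.genus in seen:
                raise ValueError(f"duplicate genus: {r.genus}")
            seen.add(r.genus)
            i0, i1 = scale.index(r.first_stage), scale.index(r.last_stage)
            if i0 > i1:
                raise ValueError(
                    f"{r.genus}: first_stage {r.first_stage} younger than "
                    f"last_stage {r.last_stage}"
                )

    def families(self) -> list[str]:
        return sorted({r.family for r in self.records})

    def for_family(self, family: str) -> "FossilRangeSet":
        return FossilRangeSet([r for r in self.records if r.family == family])


@dataclass
class IntervalCounts:
    """Boundary-crosser tallies for one stage: Nb cross the bottom boundary,
    Nbt cross both bottom and top, dt is the stage duration (Myr)."""

    stage: str
    Nb: int
    Nbt: int
    dt: float

    def __post_init__(self) -> None:
        if not (0 <= self.Nbt <= self.Nb):
            raise ValueError("require 0 <= Nbt <= Nb")
        if not self.dt > 0:
            raise ValueError("require dt > 0")


@dataclass
class PerilComponents:
    """The three min-max-rescaled components and the combined score."""

    species_id: str
    qhat_scaled: float
    invgr_scaled: float
    invtr_scaled: float
    score: float


@dataclass
class ThresholdRule:
    """Quantile threshold for 'vulnerable' (e.g. 0.5 = median, 0.8 = top 20%),
    applied over the global score pool or within regions."""

    quantile: float = 0.5
    scope: str = "global"

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")
        if self.scope not in {"global", "regional"}:
            raise ValueError("scope must be 'global' or 'regional'")


@dataclass
class VulnerabilityLayer:
    """Per-cell exploitation/vulnerability tallies under one threshold rule.

    ``table`` columns: cell_id, n_species, n_exploited, n_vulnerable,
    n_vulnerable_exploited, prop_exploited, prop_vulnerable_exploited
    (share of exploited species that are vulnerable) and
    prop_exploited_among_vulnerable. Proportions are NaN where the
    denominator is zero.
    """

    table: pd.DataFrame
    threshold_scope: str
    threshold_quantile: float
    quantile_convention: str = "linear"

    def validate(self) -> None:
        t = self.table
        if (t[["n_species", "n_exploited", "n_vulnerable", "n_vulnerable_exploited"]] < 0).any().any():
            raise ValueError("negative counts")
        if (t["n_exploited"] > t["n_species"]).any():
            raise ValueError("n_exploited exceeds n_species")
        if (
            t["n_vulnerable_exploited"]
            > np.minimum(t["n_vulnerable"], t["n_exploited"])
        ).any():
            raise ValueError("n_vulnerable_exploited exceeds min(n_vulnerable, n_exploited)")


@dataclass
class PhyloDResult:
    """Phylogenetic D for a binary trait with its two simulation nulls."""

    D: float
    p_random: float
    p_brownian: float
    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    n_sim: int


@dataclass
class SignalResult:
    """Continuous-trait phylogenetic signal: Pagel's lambda and/or Blomberg's K."""

    lam: float | None = None
    logL_lambda: float | None = None
    K: float | None = None
    p_K: float | None = None


@dataclass
class ModelFit:
    """Random-intercept logistic fit on the standardized predictor scale."""

    coefficients: dict[str, float]
    intercept: float
    sigma_family: float
    loglik: float
    converged: bool
    n_obs: int
    n_families: int
    separation_flag: bool = False
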