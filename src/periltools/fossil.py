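"""Per-capita genus extinction rates from stratigraphic ranges.

Clade volatility (q-hat) for a family is estimated from the first and last
stage-level occurrences of its genera with the boundary-crosser protocol:
for each stage, Nb genera cross the bottom boundary and Nbt of those also
cross the top; the per-capita extinction rate for the stage is
``q = -ln(Nbt / Nb) / dt``. Single-stage genera (singletons) cross no
boundary and contribute to neither count. Stage rates are aggregated across
the Cenozoic into a single family rate.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

from .types import FossilRangeSet, IntervalCounts, StageScale

__all__ = [
    "boundary_crossers",
    "interval_extinction_rate",
    "family_qhat",
    "qhat_table",
]

logger = logging.getLogger(__name__)


def boundary_crossers(
    ranges: FossilRangeSet, stage: str, scale: StageScale
) -> IntervalCounts:
    """Count genera crossing the bottom (Nb) and both (Nbt) boundaries of a stage.

    A genus crosses the bottom boundary of ``stage`` when its first stage is
    strictly older and its last stage is ``stage`` or younger; it also
    crosses the top when its last stage is strictly younger.
    """
    s = scale.index(stage)
    nb = nbt = 0
    for r in ranges.records:
        first = scale.index(r.first_stage)
        last = scale.index(r.last_stage)
        if first < s <= last:
            nb += 1
            if last > s:
                nbt += 1
    return IntervalCounts(stage=stage, Nb=nb, Nbt=nbt, dt=scale.duration(stage))


def interval_extinction_rate(counts: IntervalCounts) -> float:
    """Per-capita extinction rate ``-ln(Nbt/Nb)/dt`` for one stage.

    Returns ``inf`` (flagged by the caller) when every bottom-crosser dies
    within the stage (Nbt = 0)."""
    if counts.Nb <= 0:
        raise ValueError(f"{counts.stage}: Nb must be positive")
    if counts.Nbt == 0:
        logger.warning(
            "%s: complete extinction of boundary crossers (Nb=%d); rate undefined",
            counts.stage,
            counts.Nb,
        )
        return math.inf
    return -math.log(counts.Nbt / counts.Nb) / counts.dt


def family_qhat(
    ranges: FossilRangeSet,
    scale: StageScale,
    family: str,
    method: str = "weighted_mean",
) -> float | None:
    """Cenozoic-wide per-capita extinction rate for one family (per Myr).

    ``weighted_mean`` (default) duration-weights the defined per-stage rates:
    ``sum(q_i * dt_i) / sum(dt_i)`` over stages with Nb > 0 and Nbt > 0.
    ``pooled`` keeps the same numerator (``q_i * dt_i = ln(Nb_i / Nbt_i)``)
    but divides by the total duration of all stages the family crosses into
    (Nb > 0), including stages whose crossers all die. Returns ``None`` when
    no stage yields a defined rate.
    """
    if method not in {"weighted_mean", "pooled"}:
        raise ValueError("method must be 'weighted_mean' or 'pooled'")
    fam = ranges.for_family(family)
    if not fam.records:
        logger.warning("family %s has no fossil ranges", family)
        return None
    num = 0.0
    dt_defined = 0.0
    dt_crossed = 0.0
    for stage in scale.names:
        counts = boundary_crossers(fam, stage, scale)
        if counts.Nb == 0:
            continue
        dt_crossed += counts.dt
        if counts.Nbt == 0:
            logger.warning(
                "family %s, stage %s: all %d boundary crossers go extinct; "
                "interval dropped from the weighted mean",
                family,
                stage,
                counts.Nb,
            )
            continue
        num += math.log(counts.Nb / counts.Nbt)
        dt_defined += counts.dt
    denom = dt_defined if method == "weighted_mean" else dt_crossed
    if denom <= 0:
        logger.warning("family %s: no usable boundary-crossing intervals", family)
        return None
    return num / denom


def qhat_table(
    ranges: FossilRangeSet, scale: StageScale, method: str = "weighted_mean"
) -> pd.DataFrame:
    """Family-level rate table: family, qhat, n_genera, n_intervals."""
    rows = []
    for family in ranges.families():
        fam = ranges.for_family(family)
        n_intervals = sum(
            1
            for stage in scale.names
            if boundary_crossers(fam, stage, scale).Nb > 0
        )
        rows.append(
            {
                "family": family,
                "qhat": family_qhat(ranges, scale, family, method=method),
                "n_genera": len(fam.records),
                "n_intervals": n_intervals,
            }
        )
    return pd.DataFrame(rows)
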