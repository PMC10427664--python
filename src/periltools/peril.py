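"""The PERIL score: clade volatility + inverted geographic and thermal range.

The raw components are the family extinction rate q-hat, ``1/ln(r)`` for the
convex-hull range area r (km^2, floored at 100 so ln r > 0) and ``1/T`` for
the thermal range T (degC). Ranges are inverted so that widespread and
eurythermal species score low. Each component is min-max rescaled to [0, 1]
across the full analyzed species set; the default score is the mean of the
three rescaled components, which keeps scores in [0, 1] (a raw-sum variant
is available via ``combine="sum"``). Species are classified vulnerable when
their score strictly exceeds a global or regional quantile of the scores.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np

from .types import PerilComponents, SpeciesRecord, ThresholdRule

__all__ = ["rescale01", "peril_scores", "classify"]

logger = logging.getLogger(__name__)


def rescale01(values: Sequence[float]) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant vector maps to all zeros."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("rescaling needs at least 2 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite value in rescale01 input")
    lo, hi = v.min(), v.max()
    if hi == lo:
        logger.warning("degenerate spread in rescale01: all values equal %g", lo)
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def peril_scores(
    records: Sequence[SpeciesRecord], combine: str = "mean"
) -> list[PerilComponents]:
    """Compute PERIL components and scores across a species set.

    Rescaling context is the full input set, so a score is only meaningful
    relative to the species it was computed with. Records missing any of
    q-hat, range area or thermal range are skipped with a log entry. Species
    with T = 0 (single-cell occupancies) take the largest raw 1/T observed
    among T > 0 species, i.e. they are treated as maximally stenothermal.
    Scores are written back onto the records.
    """
    if combine not in {"mean", "sum"}:
        raise ValueError("combine must be 'mean' or 'sum'")
    usable: list[SpeciesRecord] = []
    for r in records:
        if (
            r.qhat is None
            or r.geographic_range_area is None
            or r.thermal_range is None
        ):
            logger.warning("%s: missing PERIL component; skipped", r.species_id)
            continue
        if r.geographic_range_area < 100.0:
            raise ValueError(
                f"{r.species_id}: range area below the 100 km^2 floor"
            )
        usable.append(r)
    if len(usable) < 2:
        raise ValueError("PERIL rescaling needs at least 2 complete records")

    qhat = np.array([r.qhat for r in usable])
    invgr = np.array([1.0 / math.log(r.geographic_range_area) for r in usable])
    tvals = np.array([r.thermal_range for r in usable])
    positive = tvals > 0
    invtr = np.empty(len(usable))
    if positive.any():
        invtr[positive] = 1.0 / tvals[positive]
        invtr[~positive] = invtr[positive].max()
    else:
        logger.warning("every species has zero thermal range")
        invtr[:] = 1.0

    q_s = rescale01(qhat)
    g_s = rescale01(invgr)
    t_s = rescale01(invtr)
    total = q_s + g_s + t_s
    score = total / 3.0 if combine == "mean" else total

    out = []
    for i, r in enumerate(usable):
        r.peril = float(score[i])
        out.append(
            PerilComponents(
                species_id=r.species_id,
                qhat_scaled=float(q_s[i]),
                invgr_scaled=float(g_s[i]),
                invtr_scaled=float(t_s[i]),
                score=float(score[i]),
            )
        )
    return out


def classify(
    scores: Mapping[str, float] | Sequence[float],
    rule: ThresholdRule,
    regions: Mapping[str, str] | None = None,
    reference_scores: Sequence[float] | None = None,
) -> list[str]:
    """Label each score ``"above"`` or ``"below"`` a quantile threshold.

    The threshold is the linear-interpolation quantile of the reference pool
    (the scores themselves unless ``reference_scores`` is supplied, e.g. to
    classify an FAO subset against the global pool). Membership is strict:
    ties with the threshold fall below. Regional scope computes one
    threshold per region from the species of that region.
    """
    if isinstance(scores, Mapping):
        ids = list(scores.keys())
        vals = np.array([scores[k] for k in ids], dtype=float)
    else:
        ids = list(range(len(scores)))
        vals = np.asarray(scores, dtype=float)
    if vals.size == 0:
        raise ValueError("no scores to classify")

    if rule.scope == "global":
        pool = (
            np.asarray(reference_scores, dtype=float)
            if reference_scores is not None
            else vals
        )
        threshold = float(np.quantile(pool, rule.quantile))
        return ["above" if v > threshold else "below" for v in vals]

    if regions is None:
        raise ValueError("regional scope requires region labels")
    region_of = [regions[i] for i in ids]
    labels = [""] * len(ids)
    for region in sorted(set(region_of)):
        idx = [k for k, reg in enumerate(region_of) if reg == region]
        pool = vals[idx]
        if len(pool) < 5:
            logger.warning(
                "region %s has only %d species; threshold is low-sample",
                region,
                len(pool),
            )
        threshold = float(np.quantile(pool, rule.quantile))
        for k in idx:
            labels[k] = "above" if vals[k] > threshold else "below"
    return labels
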