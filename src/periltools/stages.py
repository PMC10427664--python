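"""Default Cenozoic stage scale (ICS chronostratigraphic ages, Ma).

Any contiguous, strictly decreasing stage table can replace this default;
the rate machinery only consumes stage order and durations.
"""

from __future__ import annotations

from .types import StageScale

# (name, base_age Ma, top_age Ma), oldest first, contiguous down to the present
_CENOZOIC = [
    ("Danian", 66.0, 61.6),
    ("Selandian", 61.6, 59.2),
    ("Thanetian", 59.2, 56.0),
    ("Ypresian", 56.0, 47.8),
    ("Lutetian", 47.8, 41.2),
    ("Bartonian", 41.2, 37.71),
    ("Priabonian", 37.71, 33.9),
    ("Rupelian", 33.9, 27.82),
    ("Chattian", 27.82, 23.03),
    ("Aquitanian", 23.03, 20.44),
    ("Burdigalian", 20.44, 15.97),
    ("Langhian", 15.97, 13.82),
    ("Serravallian", 13.82, 11.63),
    ("Tortonian", 11.63, 7.246),
    ("Messinian", 7.246, 5.333),
    ("Zanclean", 5.333, 3.6),
    ("Piacenzian", 3.6, 2.58),
    ("Gelasian", 2.58, 1.8),
    ("Calabrian", 1.8, 0.774),
    ("Chibanian", 0.774, 0.129),
    ("Late Pleistocene", 0.129, 0.0117),
    ("Holocene", 0.0117, 0.0),
]


def default_stage_scale() -> StageScale:
    """The packaged Cenozoic stage scale (Danian through Holocene)."""
    names = [s[0] for s in _CENOZOIC]
    base = [s[1] for s in _CENOZOIC]
    top = [s[2] for s in _CENOZOIC]
    return StageScale(names=names, base_age=base, top_age=top)
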