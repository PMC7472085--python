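"""Valence–arousal quadrant labelling.

Self-assessment ratings live on a bounded scale (1–5 or 1–9 depending on the
dataset). The circumplex model of affect splits the valence–arousal plane into
four quadrants: HVHA, HVLA, LVHA, LVLA (high/low valence × high/low arousal).
A rating strictly above the scale midpoint counts as "high" on that axis; the
midpoint itself is assigned to "low". The cut is configurable because the
convention at the boundary is exactly that — a convention.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Canonical class order; integer codes used throughout the package index into it.
QUADRANTS: tuple[str, ...] = ("HVHA", "HVLA", "LVHA", "LVLA")

_CODE = {name: i for i, name in enumerate(QUADRANTS)}


def quadrant_code(name: str) -> int:
    """Integer class code for a quadrant name (HVHA=0, HVLA=1, LVHA=2, LVLA=3)."""
    return _CODE[name]


@dataclass(frozen=True)
class RatingRecord:
    """One (valence, arousal) self-assessment on a bounded scale."""

    valence: float
    arousal: float
    scale: tuple[float, float] = (1.0, 9.0)

    def __post_init__(self) -> None:
        lo, hi = self.scale
        if not lo < hi:
            raise ValueError(f"rating scale must satisfy min < max, got {self.scale}")
        for axis, v in (("valence", self.valence), ("arousal", self.arousal)):
            if not lo <= v <= hi:
                raise ValueError(f"{axis}={v} outside rating scale [{lo}, {hi}]")


def midpoint(scale: tuple[float, float]) -> float:
    """Default high/low threshold: the midpoint of the rating scale."""
    return 0.5 * (scale[0] + scale[1])


def quadrant(r: RatingRecord, threshold: float | None = None) -> str:
    """Map a rating to its quadrant label.

    ``valence > threshold`` is high valence, ``arousal > threshold`` high
    arousal; the comparison is strict, so a rating exactly at the threshold is
    low. Threshold defaults to the scale midpoint (3.0 on 1–5, 5.0 on 1–9).
    """
    if threshold is None:
        thr = midpoint(r.scale)
    else:
        lo, hi = r.scale
        if not lo <= threshold <= hi:
            raise ValueError(
                f"threshold {threshold} outside rating scale [{lo}, {hi}]")
        thr = threshold
    v_high = r.valence > thr
    a_high = r.arousal > thr
    if v_high:
        return "HVHA" if a_high else "HVLA"
    return "LVHA" if a_high else "LVLA"
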