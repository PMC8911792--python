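"""Derived CIELab color quantities for extract characterization.

From the measured opponent components a* (red/green) and b* (yellow/blue),
two standard polar descriptors are derived:

    chroma    C* = sqrt(a*² + b*²)           (distance from the neutral axis)
    hue angle H* = atan2(b*, a*) in degrees, mapped to [0, 360)

Red-dominant extracts (anthocyanin-rich) sit in the first trigonometric
quadrant at small hue angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .dataset import round_half_up

__all__ = ["LabColor", "chroma_hue", "quadrant"]


@dataclass(frozen=True)
class LabColor:
    """CIELab triplet: luminosity L* in [0, 100], opponent components a*, b*."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0 <= self.L <= 100:
            raise ValueError(f"L* must lie in [0, 100], got {self.L}")


def chroma_hue(
    color: LabColor, decimals_c: int = 2, decimals_h: int = 1
) -> tuple[float, float]:
    """Chroma C* and hue angle H* (degrees, [0, 360)), half-up rounded.

    Undefined at the neutral axis a* = b* = 0.
    """
    if color.a == 0 and color.b == 0:
        raise ValueError("hue angle undefined at the neutral axis (a* = b* = 0)")
    c = math.hypot(color.a, color.b)
    h = math.degrees(math.atan2(color.b, color.a)) % 360.0
    if h >= 360.0:  # a tiny negative b* can round the modulo up to 360 exactly
        h = 0.0
    h = round_half_up(h, decimals_h)
    if h >= 360.0:  # rounding can also close the half-open interval
        h -= 360.0
    return round_half_up(c, decimals_c), h


def quadrant(hue_deg: float) -> int:
    """Trigonometric quadrant (1–4) of a hue angle in [0, 360).

    Boundary angles open the next quadrant: 0° → 1, 90° → 2, 180° → 3,
    270° → 4.
    """
    if not 0 <= hue_deg < 360:
        raise ValueError(f"hue must lie in [0, 360), got {hue_deg}")
    return int(hue_deg // 90) + 1
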