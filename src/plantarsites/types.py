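"""Shared domain types.

The in-memory containers are deliberately thin: images are ``uint8``
``(H, W, 3)`` numpy arrays in RGB channel order, binary masks are boolean
``(H, W)`` arrays, and everything positional uses the package-wide 0-based
top-left ``(x=column, y=row)`` convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

SIDES = ("left", "right")
SITE_IDS = tuple(range(1, 10))

#: human-readable anatomy behind each site id
SITE_ANATOMY = {
    1: "hallux",
    2: "third toe",
    3: "fifth toe",
    4: "first metatarsal head",
    5: "third metatarsal head",
    6: "fifth metatarsal head",
    7: "medial midfoot",
    8: "lateral midfoot",
    9: "heel",
}


def round_half_away(value: float) -> int:
    """Round half away from zero (symmetric, unlike banker's rounding)."""
    return int(math.copysign(math.floor(abs(value) + 0.5), value))


def as_scene(pixels: np.ndarray) -> np.ndarray:
    """Validate and return an RGB scene array."""
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("scene must be an (H, W, 3) array")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("scene must be non-empty")
    return arr.astype(np.uint8, copy=False)


def as_mask(bits: np.ndarray) -> np.ndarray:
    """Validate and return a boolean binary mask."""
    arr = np.asarray(bits)
    if arr.ndim != 2:
        raise ValueError("mask must be a 2-D array")
    return arr.astype(bool, copy=False)


@dataclass(frozen=True)
class SitePoint:
    """One estimated (or reference) monofilament testing site."""

    site_id: int
    side: str
    x: int
    y: int
    evidence: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.site_id not in SITE_IDS:
            raise ValueError(f"site_id must be 1..9, got {self.site_id}")
        if self.side not in SIDES:
            raise ValueError(f"side must be left/right, got {self.side!r}")

    @property
    def point(self) -> tuple[int, int]:
        return (self.x, self.y)

    def distance_to(self, other: "SitePoint | tuple[float, float]") -> float:
        ox, oy = (other.x, other.y) if isinstance(other, SitePoint) else other
        return math.hypot(self.x - ox, self.y - oy)


@dataclass
class ThresholdReport:
    """Outcome of the dynamic V-channel threshold computation."""

    v_histogram: np.ndarray  # 256 counts
    peak_value: int
    threshold: int


@dataclass
class CalibrationInfo:
    """Pixel-to-millimetre scale and where it came from."""

    mm_per_px: float | None
    marker_boxes: list[tuple[int, int, int, int]] = field(default_factory=list)
    source: str = "absent"  # markers | config | absent

    def to_px(self, mm: float, fallback_px: float) -> float:
        """Convert a millimetre radius to pixels, or use the pixel fallback
        when no calibration is available."""
        if self.source == "absent" or self.mm_per_px is None:
            return fallback_px
        return mm / self.mm_per_px


@dataclass
class FootRegion:
    """One segmented foot: scene-sized mask plus bookkeeping."""

    mask: np.ndarray
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    side: str
    area: int

    @property
    def bbox_center_x(self) -> float:
        return (self.bbox[0] + self.bbox[2] - 1) / 2.0
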