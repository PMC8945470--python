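"""Place the plantar testing sites 4-9 by the guideline construction.

The central and heel regions follow foot skeletal anatomy much more
predictably than the toes, so their sites are placed geometrically:

1. scan two horizontal rows of the binary foot mask, at 40% and 80% of its
   vertical extent, and take the outermost foreground transitions on each —
   the left/right border points — plus their midpoints;
2. the line through the two midpoints is the foot axis; two inner
   guidelines pass through the points at w/4 and 3w/4 of the upper row's
   width (w) and run parallel to the axis.  The quarter positions split the
   forefoot into four segments because the hallux is proportionally wide
   and the fourth/fifth toes sit close together;
3. walking each guideline upward from the bottom of the mask, the first
   background-to-foreground transition marks the start of the heel;
4. each site lies on its assigned guideline at a configured fraction of
   the extent from its heel start up to the topmost foreground row of the
   mask, measured upward from the heel start.  (The per-line topmost point
   would be unstable where a guideline threads the gap between two toes.)
   Medial/lateral assignments mirror between left and right feet.

The default fractions (metatarsal heads at 0.72, midfoot at 0.45, heel at
0.12) encode standard monofilament-site anatomy and are configurable, not
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import PlantarConfig
from .errors import LineMissesFoot, RowMissesFoot
from .types import SitePoint, round_half_away


@dataclass(frozen=True)
class Guideline:
    """A straight reference line ``x = x0 + slope * (y - y0)``."""

    x0: float
    y0: float
    slope: float  # dx per dy

    def x_at(self, y: float) -> float:
        return self.x0 + self.slope * (y - self.y0)


@dataclass
class GuidelineSet:
    """Axis, border and inner guidelines of one vertically aligned foot."""

    upper_row: int
    lower_row: int
    upper_points: tuple[float, float, float]  # (x_left, x_right, x_center)
    lower_points: tuple[float, float, float]
    axis: Guideline
    medial_border: Guideline
    lateral_border: Guideline
    left_inner: Guideline
    right_inner: Guideline
    axis_angle: float  # degrees, positive = clockwise lean

    def line(self, name: str, side: str) -> Guideline:
        """Resolve an anatomical line name for a foot side.

        The medial edge (hallux side) of a left foot is its image-left;
        for a right foot the assignment mirrors."""
        if name == "center":
            return self.axis
        if name not in ("medial_inner", "lateral_inner"):
            raise ValueError(f"unknown guideline {name!r}")
        medial_is_left = side == "left"
        want_left = (name == "medial_inner") == medial_is_left
        return self.left_inner if want_left else self.right_inner


def row_transitions(mask: np.ndarray, row_fraction: float) -> tuple[float, float, float, int]:
    """Outermost foreground transitions on the scan row at ``row_fraction``
    of the mask's vertical extent; returns (x_left, x_right, x_center, row)."""
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        raise RowMissesFoot("mask has no foreground")
    top, bottom = int(rows[0]), int(rows[-1])
    row = top + int(round(row_fraction * (bottom - top)))
    cols = np.flatnonzero(np.abs(np.diff(mask[row].astype(np.int8))))
    on = np.flatnonzero(mask[row])
    if on.size == 0:
        raise RowMissesFoot(f"scan row {row} does not intersect the foot")
    x_left, x_right = float(on[0]), float(on[-1])
    del cols  # transitions and run ends agree for a binary row
    return x_left, x_right, (x_left + x_right) / 2.0, row


def build_guidelines(mask: np.ndarray, params: PlantarConfig | None = None) -> GuidelineSet:
    """Construct the axis, border and w/4 / 3w/4 inner guidelines."""
    params = params or PlantarConfig()
    xl_u, xr_u, xc_u, row_u = row_transitions(mask, params.upper_row_fraction)
    xl_l, xr_l, xc_l, row_l = row_transitions(mask, params.lower_row_fraction)
    if row_l == row_u:
        raise RowMissesFoot("guideline scan rows coincide; foot too short")
    slope = (xc_l - xc_u) / (row_l - row_u)
    w = xr_u - xl_u
    axis = Guideline(x0=xc_u, y0=row_u, slope=slope)
    return GuidelineSet(
        upper_row=row_u,
        lower_row=row_l,
        upper_points=(xl_u, xr_u, xc_u),
        lower_points=(xl_l, xr_l, xc_l),
        axis=axis,
        medial_border=Guideline(x0=xl_u, y0=row_u, slope=slope),
        lateral_border=Guideline(x0=xr_u, y0=row_u, slope=slope),
        left_inner=Guideline(x0=xl_u + w / 4.0, y0=row_u, slope=slope),
        right_inner=Guideline(x0=xl_u + 3.0 * w / 4.0, y0=row_u, slope=slope),
        axis_angle=math.degrees(math.atan(-slope)),
    )


def _line_foreground_rows(mask: np.ndarray, line: Guideline) -> np.ndarray:
    """Rows at which the rasterized line (1 px vertical steps) lies on
    foreground."""
    h, w = mask.shape
    ys = np.arange(h)
    xs = np.round(line.x_at(ys)).astype(int)
    ok = (xs >= 0) & (xs < w)
    hit = np.zeros(h, dtype=bool)
    hit[ok] = mask[ys[ok], xs[ok]]
    return np.flatnonzero(hit)


def detect_heel_start(mask: np.ndarray, line: Guideline) -> int:
    """First background-to-foreground transition walking the line upward
    from the bottom image edge."""
    rows = _line_foreground_rows(np.asarray(mask, dtype=bool), line)
    if rows.size == 0:
        raise LineMissesFoot("guideline does not intersect the foot mask")
    return int(rows[-1])


def place_plantar_sites(
    mask: np.ndarray,
    guidelines: GuidelineSet,
    side: str,
    params: PlantarConfig | None = None,
) -> list[SitePoint]:
    """Emit sites 4-9 at their configured fractions along the guidelines."""
    params = params or PlantarConfig()
    mask = np.asarray(mask, dtype=bool)
    # extent is measured to the mask's global top row: the per-line top is
    # unstable where a near-vertical guideline threads between two toes
    mask_top = int(np.flatnonzero(mask.any(axis=1))[0])
    sites = []
    for site_id in sorted(params.proportions):
        line_name, fraction = params.proportions[site_id]
        line = guidelines.line(line_name, side)
        rows = _line_foreground_rows(mask, line)
        if rows.size == 0:
            raise LineMissesFoot(f"guideline for site {site_id} misses the foot")
        heel_y = int(rows[-1])
        extent = heel_y - mask_top
        y = heel_y - fraction * extent
        sites.append(
            SitePoint(
                site_id=site_id,
                side=side,
                x=round_half_away(line.x_at(y)),
                y=round_half_away(y),
                evidence=frozenset({"proportion"}),
            )
        )
    return sites
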