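"""Crop, de-rotate and split a segmented foot; map points back to the scene.

The toe and plantar site detectors assume a vertically aligned foot (toes
up).  Feet in acquisition scenes can be tilted by tens of degrees, so each
segmented region is cropped with a small margin, its tilt is estimated from
the chord between the topmost and bottommost foreground pixels, and the
sub-image is rotated upright.  Because that chord estimator is biased on an
asymmetric silhouette (the hallux tip is medial of the heel apex), the
estimate-and-rotate step is applied twice by default; the iteration
converges to the pose in which the chord is vertical, which is the
canonical "upright" pose of this package.

Every crop/pad/rotate step is recorded in an invertible
:class:`TransformChain` so site estimates made in the normalized frame can
be remapped exactly to original scene coordinates.

Angle convention: degrees, positive when the foot leans clockwise on
screen (top of the foot to the right of the heel), range (-90, 90].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import AffineTransform, warp

from .config import NormalizeConfig
from .errors import DegenerateRegion, OutOfBounds
from .types import FootRegion, round_half_away


@dataclass(frozen=True)
class Translate:
    dx: float
    dy: float

    def forward(self, p: tuple[float, float]) -> tuple[float, float]:
        return (p[0] + self.dx, p[1] + self.dy)

    def inverse(self, p: tuple[float, float]) -> tuple[float, float]:
        return (p[0] - self.dx, p[1] - self.dy)


@dataclass(frozen=True)
class Rotate:
    """Rotation about ``center`` by ``angle_degrees``; positive angles are
    clockwise on screen (the mathematically positive sense with y down)."""

    center: tuple[float, float]
    angle_degrees: float

    def _apply(self, p: tuple[float, float], degrees: float) -> tuple[float, float]:
        a = math.radians(degrees)
        c, s = math.cos(a), math.sin(a)
        x, y = p[0] - self.center[0], p[1] - self.center[1]
        return (self.center[0] + c * x - s * y, self.center[1] + s * x + c * y)

    def forward(self, p: tuple[float, float]) -> tuple[float, float]:
        return self._apply(p, self.angle_degrees)

    def inverse(self, p: tuple[float, float]) -> tuple[float, float]:
        return self._apply(p, -self.angle_degrees)


@dataclass
class TransformChain:
    """Ordered scene -> normalized transform steps, each invertible."""

    steps: list = field(default_factory=list)
    scene_shape: tuple[int, int] | None = None  # (H, W) for bounds checks

    def forward(self, p: tuple[float, float]) -> tuple[float, float]:
        for step in self.steps:
            p = step.forward(p)
        return p

    def inverse(self, p: tuple[float, float]) -> tuple[float, float]:
        for step in reversed(self.steps):
            p = step.inverse(p)
        return p


def remap_point(p: tuple[float, float], chain: TransformChain) -> tuple[int, int]:
    """Map a point from normalized coordinates back to integer scene
    pixels, raising :class:`OutOfBounds` if it leaves the scene raster."""
    x, y = chain.inverse(p)
    xi, yi = round_half_away(x), round_half_away(y)
    if chain.scene_shape is not None:
        h, w = chain.scene_shape
        if not (0 <= xi < w and 0 <= yi < h):
            raise OutOfBounds(f"remapped point ({xi}, {yi}) outside {w}x{h} scene")
    return (xi, yi)


def estimate_orientation(mask: np.ndarray, min_extent_px: int = 3) -> float:
    """Tilt of the chord from the topmost foreground pixels (centroid
    column) to the bottommost, relative to the vertical axis."""
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        raise DegenerateRegion("empty mask has no orientation")
    top, bottom = int(rows[0]), int(rows[-1])
    if bottom - top + 1 < min_extent_px:
        raise DegenerateRegion(
            f"mask extent {bottom - top + 1} px below minimum {min_extent_px}"
        )
    x_top = float(np.flatnonzero(mask[top]).mean())
    x_bottom = float(np.flatnonzero(mask[bottom]).mean())
    return math.degrees(math.atan2(x_top - x_bottom, bottom - top))


@dataclass
class NormalizedFoot:
    """A vertically aligned foot sub-image with its provenance transform."""

    image: np.ndarray  # (S, S, 3) uint8, padded square canvas
    mask: np.ndarray  # (S, S) bool
    side: str
    angle: float  # total estimated tilt that was removed, degrees
    chain: TransformChain
    crop_box: tuple[int, int, int, int]  # scene-coordinate crop, half-open

    @property
    def foot_length(self) -> int:
        """Vertical extent L of the mask foreground, pixels."""
        rows = np.flatnonzero(self.mask.any(axis=1))
        return int(rows[-1] - rows[0] + 1) if rows.size else 0

    @property
    def row_range(self) -> tuple[int, int]:
        rows = np.flatnonzero(self.mask.any(axis=1))
        if rows.size == 0:
            return (0, 0)
        return (int(rows[0]), int(rows[-1]) + 1)

    def toes_view(self, toes_fraction: float = 0.25) -> tuple[int, int]:
        r0, r1 = self.row_range
        split = r0 + int(round(toes_fraction * (r1 - r0)))
        return (r0, min(split, r1))

    def plantar_view(self, toes_fraction: float = 0.25) -> tuple[int, int]:
        r0, r1 = self.row_range
        return (self.toes_view(toes_fraction)[1], r1)

    def foot_width_fn(self) -> np.ndarray:
        """Per-row foreground width (pixels) over the whole canvas."""
        return self.mask.sum(axis=1).astype(int)


def _rotate_about_center(image: np.ndarray, mask: np.ndarray, degrees: float):
    """Rotate image (bilinear) and mask (nearest) so that a foot tilted
    clockwise by ``degrees`` becomes upright; exposed corners become black,
    preserving the dark-background assumption."""
    h, w = mask.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    # forward step (old -> new coords) is a rotation by -degrees; warp needs
    # the output->input map, i.e. the rotation by +degrees
    a = math.radians(degrees)
    c, s = math.cos(a), math.sin(a)
    cx, cy = center
    matrix = np.array(
        [
            [c, -s, cx - c * cx + s * cy],
            [s, c, cy - s * cx - c * cy],
            [0.0, 0.0, 1.0],
        ]
    )
    tform = AffineTransform(matrix=matrix)
    rot_img = warp(image, tform, order=1, preserve_range=True, cval=0.0)
    rot_mask = warp(mask.astype(float), tform, order=0, preserve_range=True, cval=0.0)
    step = Rotate(center=center, angle_degrees=-degrees)
    return rot_img.astype(np.uint8), rot_mask > 0.5, step


def normalize_foot(
    scene: np.ndarray,
    region: FootRegion,
    params: NormalizeConfig | None = None,
) -> NormalizedFoot:
    """Crop a foot region with margin, pad to a rotation-safe square canvas
    and iteratively rotate it upright."""
    params = params or NormalizeConfig()
    h, w = region.mask.shape
    x0, y0, x1, y1 = region.bbox
    margin = int(round(params.margin_fraction * max(x1 - x0, y1 - y0)))
    cx0, cy0 = max(0, x0 - margin), max(0, y0 - margin)
    cx1, cy1 = min(w, x1 + margin), min(h, y1 + margin)
    crop_img = np.asarray(scene)[cy0:cy1, cx0:cx1]
    crop_mask = np.asarray(region.mask, dtype=bool)[cy0:cy1, cx0:cx1]

    chain = TransformChain(scene_shape=(h, w))
    chain.steps.append(Translate(dx=-cx0, dy=-cy0))

    # pad to a square large enough that no rotation clips the foot
    ch, cw = crop_mask.shape
    side_len = int(math.ceil(math.hypot(ch, cw))) + 2
    py = (side_len - ch) // 2
    px = (side_len - cw) // 2
    img = np.zeros((side_len, side_len, 3), dtype=np.uint8)
    img[py : py + ch, px : px + cw] = crop_img
    mask = np.zeros((side_len, side_len), dtype=bool)
    mask[py : py + ch, px : px + cw] = crop_mask
    chain.steps.append(Translate(dx=px, dy=py))

    total = 0.0
    for _ in range(max(1, params.refine_iterations)):
        angle = estimate_orientation(mask, params.min_extent_px)
        if abs(angle) < 0.05:
            break
        img, mask, step = _rotate_about_center(img, mask, angle)
        chain.steps.append(step)
        total += angle

    return NormalizedFoot(
        image=img,
        mask=mask,
        side=region.side,
        angle=total,
        chain=chain,
        crop_box=(cx0, cy0, cx1, cy1),
    )
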