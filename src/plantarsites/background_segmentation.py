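"""Separate the feet from the dark acquisition background.

The acquisition scene is two bare feet in front of a dark matte board with
two brightly colored square calibration targets of known physical size near
the top corners.  Because lighting is uncontrolled, a fixed threshold is
unreliable; instead the scene's V channel (per-pixel max of R, G, B)
histogram is dominated by the dark background, and the binarization
threshold is set dynamically to two and a half times the histogram mode
(clamped below by ``t_min`` so that a mode of 0 cannot select everything).

The thresholded image is cleaned with a morphological opening, connected
components overlapping the calibration markers are discarded, and the two
largest remaining components above a minimum area fraction are the feet,
side-labeled by horizontal position.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hsv
from skimage.morphology import closing as binary_closing
from skimage.morphology import disk
from skimage.morphology import opening as binary_opening

from .config import MarkersConfig, MorphologyConfig, PipelineConfig
from .errors import DegenerateRegion, FeetNotFound
from .types import CalibrationInfo, FootRegion, ThresholdReport, as_scene


def luma(scene: np.ndarray) -> np.ndarray:
    """ITU-R 601 grayscale of an RGB scene, float in [0, 255]."""
    rgb = np.asarray(scene, dtype=np.float64)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def value_channel(scene: np.ndarray) -> np.ndarray:
    """HSV value plane: per-pixel maximum of the RGB channels."""
    return np.asarray(scene).max(axis=2)


def dynamic_threshold(scene: np.ndarray, t_min: int = 20, factor: float = 2.5) -> ThresholdReport:
    """Threshold = ``clip(round(factor * mode(V histogram)), t_min, 255)``.

    Histogram ties break toward the lowest intensity.  The result depends
    only on the histogram, never on pixel positions.
    """
    scene = as_scene(scene)
    hist = np.bincount(value_channel(scene).ravel(), minlength=256)
    peak = int(hist.argmax())  # argmax returns the lowest index on ties
    threshold = int(np.clip(round(factor * peak), t_min, 255))
    return ThresholdReport(v_histogram=hist, peak_value=peak, threshold=threshold)


def binarize(scene: np.ndarray, threshold: int) -> np.ndarray:
    """Grayscale-thresholded foreground (luma >= threshold)."""
    return luma(scene) >= threshold


def segment_feet(
    scene: np.ndarray,
    config: PipelineConfig | None = None,
    marker_boxes: list[tuple[int, int, int, int]] | None = None,
) -> tuple[list[FootRegion], ThresholdReport]:
    """Segment exactly two foot regions from a scene.

    Returns the regions ordered image-left first, with anatomical side
    labels taken from ``feet.image_left_is``.  Raises
    :class:`FeetNotFound` when fewer than two sufficiently large
    components survive — the signal that the image needs manual review.
    """
    config = config or PipelineConfig()
    scene = as_scene(scene)
    h, w = scene.shape[:2]
    report = dynamic_threshold(scene, config.threshold.t_min, config.threshold.factor)
    binary = binarize(scene, report.threshold)

    radius = config.morphology.scaled_radius(config.morphology.open_radius_px, w)
    opened = binary_opening(binary, disk(radius))

    labels, n = ndi.label(opened)
    if n == 0:
        raise FeetNotFound("no foreground components after thresholding")

    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    if marker_boxes:
        for x0, y0, x1, y1 in marker_boxes:
            x0, y0 = max(0, x0), max(0, y0)
            hit = np.unique(labels[y0:y1, x0:x1])
            keep[hit[hit > 0]] = False

    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(n + 1))
    min_area = config.feet.min_area_fraction * h * w
    candidates = [i for i in range(1, n + 1) if keep[i] and areas[i] >= min_area]
    if len(candidates) < 2:
        raise FeetNotFound(
            f"found {len(candidates)} qualifying component(s), need 2 feet"
        )
    candidates.sort(key=lambda i: areas[i], reverse=True)
    chosen = candidates[:2]

    regions = []
    slices = ndi.find_objects(labels)
    for comp in chosen:
        sl = slices[comp - 1]
        mask = labels == comp
        bbox = (sl[1].start, sl[0].start, sl[1].stop, sl[0].stop)
        regions.append(FootRegion(mask=mask, bbox=bbox, side="left", area=int(areas[comp])))
    regions.sort(key=lambda r: r.bbox_center_x)
    left_side = config.feet.image_left_is
    regions[0].side = left_side
    regions[1].side = "left" if left_side == "right" else "right"
    return regions, report


_MOORE_OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered closed chain of the outer boundary pixels (Moore tracing,
    8-connected), as an (N, 2) array of (row, col)."""
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    start = (int(rows.min()), int(cols[rows == rows.min()].min()))
    chain = [start]
    prev_dir = 2  # pretend we entered the topmost-leftmost pixel moving east
    current = start
    guard = 4 * padded.size
    while guard > 0:
        guard -= 1
        found = False
        for k in range(8):
            d = (prev_dir + 5 + k) % 8  # start scan from backtrack neighbor
            dy, dx = _MOORE_OFFSETS[d]
            ny, nx = current[0] + dy, current[1] + dx
            if padded[ny, nx]:
                current = (ny, nx)
                prev_dir = d
                found = True
                break
        if not found:  # isolated pixel
            break
        if current == start and len(chain) > 2:
            break
        chain.append(current)
    return np.asarray(chain) - 1  # undo padding offset


def _smooth_closed(points: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(points) <= window:
        return points.astype(float)
    kernel = np.ones(window) / window
    out = np.empty(points.shape, dtype=float)
    for axis in range(2):
        wrapped = np.concatenate([points[-(window // 2):, axis],
                                  points[:, axis],
                                  points[: window // 2, axis]])
        out[:, axis] = np.convolve(wrapped, kernel, mode="valid")[: len(points)]
    return out


def extract_foot_contour(
    region: FootRegion,
    morphology: MorphologyConfig | None = None,
    smooth_window: int = 5,
    image_width: int | None = None,
) -> dict:
    """Closed outer contour of a foot region.

    The mask is closed morphologically (filling small bays left by the
    threshold step), the largest component's outer boundary is traced as an
    ordered pixel chain, and the chain coordinates are smoothed with a
    cyclic moving average.  Returns ``{"pixels": (N, 2) int (row, col),
    "smoothed": (N, 2) float}``.
    """
    morphology = morphology or MorphologyConfig()
    mask = np.asarray(region.mask, dtype=bool)
    if mask.sum() < 3:
        raise DegenerateRegion("contour needs at least 3 foreground pixels")
    width = image_width or mask.shape[1]
    radius = morphology.scaled_radius(morphology.close_radius_px, width)
    closed = binary_closing(mask, disk(radius))
    labels, n = ndi.label(closed)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        closed = labels == (1 + int(np.argmax(sizes)))
    chain = _trace_boundary(closed)
    return {"pixels": chain, "smoothed": _smooth_closed(chain, smooth_window)}


def detect_markers(
    scene: np.ndarray,
    spec: MarkersConfig | None = None,
) -> CalibrationInfo:
    """Find the square calibration targets and derive mm-per-pixel.

    For each configured color range the largest connected component with a
    roughly square bounding box is accepted; the scale is the mean of
    ``size_mm / edge_px`` over accepted markers (edge = mean bounding-box
    edge).  Finding no marker is a state, not an error: the scale falls
    back to ``fallback_mm_per_px`` from config, or is reported absent, in
    which case downstream radii operate in pixels.
    """
    spec = spec or MarkersConfig()
    scene = as_scene(scene)
    hsv = rgb2hsv(scene)
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2] * 255.0
    boxes = []
    scales = []
    for rng in spec.colors:
        lo, hi = rng.hue
        in_hue = (hue >= lo) & (hue <= hi) if lo <= hi else (hue >= lo) | (hue <= hi % 360)
        inside = in_hue & (sat >= rng.sat_min) & (val >= rng.val_min)
        labels, n = ndi.label(inside)
        if n == 0:
            continue
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        best = 1 + int(np.argmax(sizes))
        if sizes[best - 1] < spec.min_area_px:
            continue
        sl = ndi.find_objects(labels)[best - 1]
        bh = sl[0].stop - sl[0].start
        bw = sl[1].stop - sl[1].start
        aspect = bw / bh if bh else np.inf
        if not (spec.aspect_range[0] <= aspect <= spec.aspect_range[1]):
            continue
        boxes.append((sl[1].start, sl[0].start, sl[1].stop, sl[0].stop))
        scales.append(spec.size_mm / ((bh + bw) / 2.0))
    if scales:
        return CalibrationInfo(
            mm_per_px=float(np.mean(scales)), marker_boxes=boxes, source="markers"
        )
    if spec.fallback_mm_per_px is not None:
        return CalibrationInfo(mm_per_px=spec.fallback_mm_per_px, source="config")
    return CalibrationInfo(mm_per_px=None, source="absent")
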