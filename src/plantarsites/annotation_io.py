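"""Reading and writing the formats the pipeline touches.

Two annotation layers accompany each plantar scene:

* a binary foot mask (foreground feet = 1) used to score background
  segmentation, stored as a grayscale PNG;
* an 18-color testing-site mask — one distinct color per (side, site) pair,
  9 sites per foot — used to score site localization, stored as an RGB PNG.

The color-mask codec is shape-agnostic: annotated regions may be discs,
squares or free-form blobs.  Decoding matches each pixel to the nearest
palette color within a Chebyshev (per-channel) tolerance, which keeps the
round trip robust to mild JPEG compression of the annotation layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .errors import AmbiguousColor, UnknownColor
from .types import SIDES, SitePoint, round_half_away

#: default annotation palette: 18 well-separated RGB colors (minimum
#: pairwise Chebyshev distance 127).  Labels 1-9 are the left-foot sites
#: 1-9, labels 10-18 the right-foot sites 1-9.
DEFAULT_PALETTE_COLORS: tuple[tuple[int, int, int], ...] = (
    (255, 0, 0), (0, 255, 0), (0, 0, 255),
    (255, 255, 0), (255, 0, 255), (0, 255, 255),
    (255, 128, 0), (128, 0, 255), (0, 128, 0),
    (128, 128, 255), (255, 128, 128), (128, 255, 128),
    (128, 0, 0), (0, 0, 128), (128, 128, 0),
    (0, 128, 128), (128, 0, 128), (255, 255, 255),
)


@dataclass(frozen=True)
class Palette:
    """Label ↔ color ↔ (side, site) correspondence for annotation masks."""

    colors: tuple[tuple[int, int, int], ...] = DEFAULT_PALETTE_COLORS

    def __post_init__(self) -> None:
        if len(self.colors) != 18:
            raise ValueError("palette must define exactly 18 colors")
        if len(set(self.colors)) != 18:
            raise ValueError("palette colors must be distinct")

    def label_for(self, side: str, site_id: int) -> int:
        if side not in SIDES or site_id not in range(1, 10):
            raise ValueError(f"no label for ({side!r}, {site_id})")
        return site_id + (0 if side == "left" else 9)

    def site_for(self, label: int) -> tuple[str, int]:
        if label not in range(1, 19):
            raise ValueError(f"label must be 1..18, got {label}")
        return ("left", label) if label <= 9 else ("right", label - 9)

    def color_for(self, label: int) -> tuple[int, int, int]:
        return self.colors[label - 1]


@dataclass
class SiteAnnotationMask:
    """Label grid over a scene: 0 = unannotated, 1..18 = one (side, site)."""

    labels: np.ndarray  # (H, W) uint8 of {0} | {1..18}
    palette: Palette = field(default_factory=Palette)

    def present_labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)


def decode_annotation_mask(
    raster: np.ndarray,
    palette: Palette | None = None,
    tolerance: int = 20,
    strict: bool = False,
) -> SiteAnnotationMask:
    """Convert an RGB annotation raster into a label grid.

    A pixel is background when every channel is within ``tolerance`` of 0;
    otherwise it must match exactly one palette color within the Chebyshev
    tolerance.  Matching two colors raises :class:`AmbiguousColor`; matching
    none raises :class:`UnknownColor` in strict mode and decodes to 0
    otherwise.
    """
    palette = palette or Palette()
    rgb = np.asarray(raster, dtype=np.int16)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("annotation raster must be (H, W, 3)")
    colors = np.asarray(palette.colors, dtype=np.int16)  # (18, 3)
    # (H, W, 18) Chebyshev distances to each palette color
    dist = np.abs(rgb[:, :, None, :] - colors[None, None, :, :]).max(axis=3)
    matches = dist <= tolerance
    n_matches = matches.sum(axis=2)
    if np.any(n_matches > 1):
        ys, xs = np.nonzero(n_matches > 1)
        raise AmbiguousColor(
            f"pixel ({xs[0]}, {ys[0]}) matches {int(n_matches[ys[0], xs[0]])} palette colors"
        )
    labels = np.where(n_matches == 1, matches.argmax(axis=2) + 1, 0).astype(np.uint8)
    background = np.abs(rgb).max(axis=2) <= tolerance
    if strict:
        unknown = (n_matches == 0) & ~background
        if np.any(unknown):
            ys, xs = np.nonzero(unknown)
            raise UnknownColor(
                f"pixel ({xs[0]}, {ys[0]}) color {tuple(int(c) for c in rgb[ys[0], xs[0]])} "
                "matches no palette entry"
            )
    return SiteAnnotationMask(labels=labels, palette=palette)


def encode_annotation_mask(mask: SiteAnnotationMask) -> np.ndarray:
    """Render a label grid back to an RGB raster (inverse of decoding)."""
    labels = np.asarray(mask.labels)
    lut = np.zeros((19, 3), dtype=np.uint8)
    for label in range(1, 19):
        lut[label] = mask.palette.color_for(label)
    return lut[labels]


def site_centroids(mask: SiteAnnotationMask) -> list[SitePoint]:
    """One :class:`SitePoint` per annotated label, at the integer-rounded
    centroid (round half away from zero) of that label's pixels."""
    points = []
    for label in mask.present_labels():
        ys, xs = np.nonzero(mask.labels == label)
        side, site_id = mask.palette.site_for(label)
        points.append(
            SitePoint(
                site_id=site_id,
                side=side,
                x=round_half_away(float(xs.mean())),
                y=round_half_away(float(ys.mean())),
                evidence=frozenset({"annotation"}),
            )
        )
    return points


# --- raster and tabular file I/O -----------------------------------------

def read_scene(path) -> np.ndarray:
    """Load a JPEG/PNG scene as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def write_scene(path, pixels: np.ndarray) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="RGB").save(path)


def read_binary_mask(path) -> np.ndarray:
    with Image.open(path) as img:
        return np.asarray(img.convert("L")) > 127


def write_binary_mask(path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)).save(path)


def read_annotation_image(path) -> np.ndarray:
    return read_scene(path)


def write_annotation_image(path, mask: SiteAnnotationMask) -> None:
    write_scene(path, encode_annotation_mask(mask))


SITE_CSV_COLUMNS = ["image", "side", "site_id", "x", "y"]


def write_site_points(path, points: list[SitePoint], image: str) -> None:
    """Write site points as CSV with header ``image,side,site_id,x,y``
    plus a JSON mirror next to it."""
    frame = site_points_frame({image: points})
    frame.to_csv(path, index=False)
    json_path = str(path)
    json_path = json_path[: -len(".csv")] + ".json" if json_path.endswith(".csv") else json_path + ".json"
    records = frame.to_dict(orient="records")
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(records, fh, indent=1)


def site_points_frame(by_image: dict[str, list[SitePoint]]) -> pd.DataFrame:
    rows = [
        {"image": image, "side": p.side, "site_id": p.site_id, "x": p.x, "y": p.y}
        for image, points in by_image.items()
        for p in sorted(points, key=lambda q: (q.side, q.site_id))
    ]
    return pd.DataFrame(rows, columns=SITE_CSV_COLUMNS)


def read_site_points(path) -> dict[str, list[SitePoint]]:
    """Read a site CSV back into per-image point lists."""
    frame = pd.read_csv(path)
    missing = set(SITE_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"site CSV missing columns: {sorted(missing)}")
    out: dict[str, list[SitePoint]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(str(row.image), []).append(
            SitePoint(site_id=int(row.site_id), side=str(row.side), x=int(row.x), y=int(row.y))
        )
    return out
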