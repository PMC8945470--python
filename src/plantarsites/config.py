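"""Pipeline configuration.

All tunable constants of the pipeline live here as nested dataclasses with
the defaults used throughout the package.  A YAML file with the same nested
key structure can override any subset of them; unknown keys are rejected so
that typos fail loudly before any image is touched.

Coordinate convention used everywhere in this package: 0-based, origin at
the top-left pixel, ``x`` is the column index and ``y`` the row index.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigError


@dataclass
class ThresholdConfig:
    """Dynamic background threshold: ``clip(round(factor * V-mode), t_min, 255)``."""

    factor: float = 2.5
    #: lower clamp; a histogram mode of 0 would otherwise select everything
    t_min: int = 20


@dataclass
class MorphologyConfig:
    """Structuring-element sizes for the binary clean-up steps.

    ``open_radius_px`` is specified at ``reference_width`` pixels of scene
    width and scaled linearly for other resolutions (never below 1 px).
    """

    open_radius_px: float = 5.0
    close_radius_px: float = 5.0
    reference_width: int = 5328

    def scaled_radius(self, radius: float, image_width: int) -> int:
        return max(1, round(radius * image_width / self.reference_width))


@dataclass
class MarkerColorRange:
    """Hue/saturation/value bounds classifying marker pixels.

    Hue and saturation are invariant to the multiplicative brightness
    changes uncontrolled lighting causes, which plain RGB bounds are not.
    Hue is in degrees (the range may wrap past 360), saturation in [0, 1],
    value in [0, 255].
    """

    name: str = "marker"
    hue: tuple[float, float] = (0.0, 360.0)
    sat_min: float = 0.4
    val_min: float = 80.0


def _default_marker_colors() -> list[MarkerColorRange]:
    # yellow and pink sticky-note targets; skin (hue ~21 deg, saturation
    # ~0.34) falls outside both ranges
    return [
        MarkerColorRange(name="yellow", hue=(38.0, 72.0), sat_min=0.5, val_min=120.0),
        MarkerColorRange(name="pink", hue=(300.0, 355.0), sat_min=0.45, val_min=120.0),
    ]


@dataclass
class MarkersConfig:
    colors: list[MarkerColorRange] = field(default_factory=_default_marker_colors)
    #: physical edge length of the square markers, millimetres
    size_mm: float = 76.0
    #: accepted bounding-box aspect-ratio interval for a square target
    aspect_range: tuple[float, float] = (0.7, 1.43)
    #: smallest pixel area considered a marker (rejects color speckle)
    min_area_px: int = 100
    #: fallback scale when no marker is found (None -> calibration absent)
    fallback_mm_per_px: float | None = None


@dataclass
class FeetConfig:
    #: minimum component area, as a fraction of the scene area, per foot
    min_area_fraction: float = 0.01
    #: anatomical side of the region on the image-left (patient supine,
    #: camera facing the soles: image-left is the patient's right foot)
    image_left_is: str = "right"


@dataclass
class NormalizeConfig:
    #: crop margin as a fraction of the larger bounding-box edge
    margin_fraction: float = 0.05
    #: top fraction of the foot rows assigned to the toes sub-view
    toes_fraction: float = 0.25
    #: estimate-rotate passes; the chord estimator underestimates large
    #: tilts on rounded silhouettes, and iterating converges the pose to
    #: chord-vertical (three passes leave well under a degree of residual)
    refine_iterations: int = 3
    #: minimum mask extent (px) below which orientation is undefined
    min_extent_px: int = 3


@dataclass
class ToesConfig:
    #: contour-peak prominence threshold, fraction of foot length
    peak_prominence: float = 0.02
    #: moving-average window (columns) applied to the contour profile
    smooth_window: int = 5
    #: vertical offset of the intensity track, fraction of foot length
    offset_fraction: float = 0.05
    #: expected hallux bright-span width, fraction of foot width
    hallux_span: float = 0.40
    #: tolerance on the hallux span width, fraction of foot width
    hallux_span_tolerance: float = 0.15
    #: expected small-toe bright-span width, fraction of foot width
    small_span: float = 0.15
    #: tolerance on small-toe span widths, fraction of foot width
    proportion_tolerance: float = 0.10
    #: hallux column expected at this fraction of foot width from the
    #: medial edge
    hallux_band_center: float = 0.20
    #: half-width of the acceptance band around ``hallux_band_center``
    band_tolerance: float = 0.10
    #: hallux site depth below the contour peak, fraction of foot length
    hallux_depth: float = 0.10
    #: small-toe site depth below the contour, fraction of foot length
    small_toe_depth: float = 0.05
    #: robust percentiles used for the track's adaptive midpoint threshold
    robust_percentiles: tuple[float, float] = (5.0, 95.0)
    #: below this robust min/max spread the bright/dark split is flagged
    #: low-confidence (uniform track)
    min_contrast: float = 20.0


def _default_proportions() -> dict[int, tuple[str, float]]:
    # site -> (guideline, fraction of the heel-to-toe extent, from the heel
    # upward).  The metatarsal-head row sits at ~72% of the foot extent,
    # the midfoot sites at ~45%, the heel site at ~12%.
    return {
        4: ("medial_inner", 0.72),
        5: ("center", 0.72),
        6: ("lateral_inner", 0.72),
        7: ("medial_inner", 0.45),
        8: ("lateral_inner", 0.45),
        9: ("center", 0.12),
    }


@dataclass
class PlantarConfig:
    #: fractions of the foot-mask vertical extent at which the two
    #: horizontal guideline rows are scanned
    upper_row_fraction: float = 0.40
    lower_row_fraction: float = 0.80
    proportions: dict[int, tuple[str, float]] = field(default_factory=_default_proportions)

    def validate(self) -> None:
        for site, (line, f) in self.proportions.items():
            if site not in range(4, 10):
                raise ConfigError(f"plantar proportion for non-plantar site {site}")
            if line not in ("medial_inner", "center", "lateral_inner"):
                raise ConfigError(f"unknown guideline {line!r} for site {site}")
            if not 0.0 <= f < 1.0:
                raise ConfigError(f"fraction {f} for site {site} outside [0, 1)")
        if set(self.proportions) != set(range(4, 10)):
            raise ConfigError("plantar proportions must cover sites 4..9")


@dataclass
class EvaluationConfig:
    #: admissible-error radius for toe sites 1-3, millimetres
    toe_radius_mm: float = 5.0
    #: admissible-error radius for central/heel sites 4-9, millimetres
    central_radius_mm: float = 10.0
    #: fallback radii in pixels when no millimetre calibration is available
    toe_radius_px: float = 10.0
    central_radius_px: float = 20.0
    #: normalized-Hamming margin under which a segmented edge is "correct"
    edge_margin: float = 0.05

    def radius_mm(self, site_id: int) -> float:
        return self.toe_radius_mm if site_id <= 3 else self.central_radius_mm

    def radius_px_fallback(self, site_id: int) -> float:
        return self.toe_radius_px if site_id <= 3 else self.central_radius_px


@dataclass
class AnnotationConfig:
    #: Chebyshev per-channel tolerance when matching palette colors
    color_tolerance: int = 20
    #: error on off-palette colors instead of ignoring them
    strict: bool = False


@dataclass
class PipelineConfig:
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    morphology: MorphologyConfig = field(default_factory=MorphologyConfig)
    markers: MarkersConfig = field(default_factory=MarkersConfig)
    feet: FeetConfig = field(default_factory=FeetConfig)
    normalize: NormalizeConfig = field(default_factory=NormalizeConfig)
    toes: ToesConfig = field(default_factory=ToesConfig)
    plantar: PlantarConfig = field(default_factory=PlantarConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)

    def validate(self) -> "PipelineConfig":
        if self.threshold.factor <= 0:
            raise ConfigError("threshold.factor must be positive")
        if not 0 <= self.threshold.t_min <= 255:
            raise ConfigError("threshold.t_min must be in [0, 255]")
        if self.feet.image_left_is not in ("left", "right"):
            raise ConfigError("feet.image_left_is must be 'left' or 'right'")
        if not 0 < self.normalize.toes_fraction < 1:
            raise ConfigError("normalize.toes_fraction must be in (0, 1)")
        if self.normalize.margin_fraction < 0:
            raise ConfigError("normalize.margin_fraction must be >= 0")
        self.plantar.validate()
        return self


def _update_dataclass(obj: Any, data: dict, path: str = "") -> None:
    names = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        where = f"{path}{key}"
        if key not in names:
            raise ConfigError(f"unknown config key: {where}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _update_dataclass(current, value, where + ".")
        elif key == "proportions" and isinstance(value, dict):
            setattr(obj, key, {int(k): (v[0], float(v[1])) for k, v in value.items()})
        elif key == "colors" and isinstance(value, list):
            ranges = []
            for entry in value:
                rng = MarkerColorRange()
                for k, v in entry.items():
                    if not hasattr(rng, k):
                        raise ConfigError(f"unknown marker color key: {where}.{k}")
                    setattr(rng, k, tuple(v) if isinstance(v, (list, tuple)) else v)
                ranges.append(rng)
            setattr(obj, key, ranges)
        elif isinstance(value, list) and isinstance(current, tuple):
            setattr(obj, key, tuple(value))
        else:
            setattr(obj, key, value)


def load_config(path: str | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from defaults, an optional YAML file
    and an optional override mapping (applied in that order)."""
    cfg = PipelineConfig()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        _update_dataclass(cfg, data)
    if overrides:
        _update_dataclass(cfg, overrides)
    return cfg.validate()
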