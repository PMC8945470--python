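"""Seeded generator of synthetic plantar scenes with exact ground truth.

Real two-feet acquisition photographs with clinician annotations are not
freely available, so this module emulates the acquisition setup the
pipeline targets: two bright foot-shaped silhouettes over a dark matte
board, five toes per foot with variable prominence and spacing, foot
orientation varying by tens of degrees, uneven lighting with optional
reflections, and two square calibration markers of known physical size
near the top corners.

Foot geometry is analytic — a heel ellipse, a tapered midfoot profile with
a medial arch concavity, and five toe capsules on a descending arc — so
every ground-truth quantity (foot mask, site centers, millimetres per
pixel) is known exactly and independently of the segmentation pipeline.
Toe-site truth comes in closed form from the capsule apexes; the plantar
sites 4-9 are defined by the same guideline construction the package
documents, applied to the clean upright silhouette.

Pose convention: the canonical "upright" pose of a generated foot is the
one in which the chord from the topmost silhouette pixel (the hallux tip)
to the bottommost (the heel apex) is vertical — exactly the pose the
normalization stage converges to — and ``orientation_degrees`` tilts the
foot clockwise from that pose.  Geometry is deterministic in its
parameters; only scene noise consumes the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .annotation_io import Palette, SiteAnnotationMask
from .config import PlantarConfig
from .errors import InvalidParams, LayoutConflict, UnknownPreset
from .types import CalibrationInfo, SIDES

# --- axis-frame template (a LEFT foot; x in fractions of the foot width W,
# --- y in fractions of the foot length L, medial edge at x = 0) ----------

#: (center x, capsule radius [of W], apex y [of L]) for toes 1 (hallux) .. 5
TOE_TEMPLATE = (
    (0.18, 0.160, 0.000),
    (0.44, 0.070, 0.035),
    (0.60, 0.065, 0.055),
    (0.75, 0.060, 0.085),
    (0.89, 0.055, 0.115),
)
#: row where the foot body begins / toe stems end (fractions of L)
BODY_TOP = 0.16
TOE_STEM_BOTTOM = 0.18
#: (y, half-width, arch dip) control points; half-widths in fractions of W,
#: the dip is subtracted from the medial half-width scaled by arch_concavity
BODY_PROFILE = (
    (0.16, 0.46, 0.00),
    (0.30, 0.50, 0.00),
    (0.42, 0.46, 0.04),
    (0.54, 0.40, 0.10),
    (0.66, 0.36, 0.07),
    (0.76, 0.33, 0.02),
    (0.86, 0.33, 0.00),
)
HEEL_CENTER_Y, HEEL_SEMI_Y, HEEL_HALF_W = 0.86, 0.14, 0.33
#: rows above this fraction of L get the inter-toe valley shading
VALLEY_ZONE = 0.24
VALLEY_DARK = 0.35


@dataclass(frozen=True)
class FootGeometryParams:
    """Anatomy knobs of one synthetic foot."""

    foot_length_mm: float = 246.0
    width_ratio: float = 0.40
    #: per-toe multiplicative jitter on the template radii
    toe_radius_scale: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    #: 0 = template spacing, 1 = inter-toe gaps fully closed
    toe_overlap: float = 0.0
    #: lateral lean of the toes (shifts apexes toward the axis)
    toe_tilt_degrees: float = 0.0
    #: clockwise tilt of the whole foot from the canonical upright pose
    orientation_degrees: float = 0.0
    side: str = "left"
    skin_color: tuple[int, int, int] = (205, 160, 135)
    #: 0 = straight medial border, 1 = deep arch
    arch_concavity: float = 0.5

    def validate(self) -> "FootGeometryParams":
        if self.foot_length_mm <= 0 or not 0.2 <= self.width_ratio <= 0.6:
            raise InvalidParams("foot length/width out of range")
        if len(self.toe_radius_scale) != 5 or any(s <= 0 for s in self.toe_radius_scale):
            raise InvalidParams("five positive toe radius scales required")
        radii = [t[1] * s for t, s in zip(TOE_TEMPLATE, self.toe_radius_scale)]
        if max(radii) != radii[0]:
            raise InvalidParams("hallux radius must remain the largest")
        if not 0.0 <= self.toe_overlap <= 1.0:
            raise InvalidParams("toe_overlap must be in [0, 1]")
        if not -60.0 <= self.orientation_degrees <= 60.0:
            raise InvalidParams("orientation must be within +-60 degrees")
        if self.side not in SIDES:
            raise InvalidParams(f"side must be left/right, got {self.side!r}")
        if not 0.0 <= self.arch_concavity <= 1.0:
            raise InvalidParams("arch_concavity must be in [0, 1]")
        return self

    @property
    def toe_radii_mm(self) -> tuple[float, ...]:
        w_mm = self.foot_length_mm * self.width_ratio
        return tuple(t[1] * s * w_mm for t, s in zip(TOE_TEMPLATE, self.toe_radius_scale))


def _rot(deg: float):
    a = math.radians(deg)
    return math.cos(a), math.sin(a)


class FootModel:
    """Analytic silhouette of one foot at a given scale."""

    def __init__(self, params: FootGeometryParams, mm_per_px: float):
        if mm_per_px <= 0:
            raise InvalidParams("mm_per_px must be positive")
        self.params = params.validate()
        self.mm_per_px = mm_per_px
        self.L = params.foot_length_mm / mm_per_px
        self.W = self.L * params.width_ratio
        self.toes = self._toe_layout()
        # chord tilt of the axis-frame template: hallux tip -> heel apex
        hx = self.toes[0][0]
        self.alpha0 = math.degrees(math.atan2(hx - 0.5 * self.W, self.L))

    def _toe_layout(self) -> list[tuple[float, float, float]]:
        """(center x, radius, apex y) per toe, in axis-frame pixels, with
        overlap closing the gaps and tilt shifting apexes laterally."""
        p = self.params
        base = [
            (t[0] * self.W, t[1] * s * self.W, t[2] * self.L)
            for t, s in zip(TOE_TEMPLATE, p.toe_radius_scale)
        ]
        # close inter-toe gaps by the overlap factor, walking from the hallux
        out = [base[0]]
        for k in range(1, 5):
            cx_prev, r_prev, _ = out[k - 1]
            cx, r, apex = base[k]
            gap = (cx - r) - (cx_prev + r_prev)
            gap = max(0.0, gap) * (1.0 - p.toe_overlap)
            out.append((cx_prev + r_prev + gap + r, r, apex))
        if p.toe_tilt_degrees:
            shift = math.tan(math.radians(p.toe_tilt_degrees))
            out = [
                (cx + shift * (TOE_STEM_BOTTOM * self.L - apex), r, apex)
                for cx, r, apex in out
            ]
        # mirror for a right foot: medial edge moves to high x
        if p.side == "right":
            out = [(self.W - cx, r, apex) for cx, r, apex in out]
        return out

    def _half_widths(self, yf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(medial, lateral) half-widths in px for y as a fraction of L."""
        ys = np.array([p[0] for p in BODY_PROFILE])
        hw = np.array([p[1] for p in BODY_PROFILE])
        dip = np.array([p[2] for p in BODY_PROFILE])
        half = np.interp(yf, ys, hw)
        medial = half - self.params.arch_concavity * np.interp(yf, ys, dip)
        lateral = half.copy()
        heel = yf > HEEL_CENTER_Y
        if np.any(heel):
            t = (yf[heel] - HEEL_CENTER_Y) / HEEL_SEMI_Y
            cap = HEEL_HALF_W * np.sqrt(np.clip(1.0 - t**2, 0.0, None))
            medial[heel] = cap
            lateral[heel] = cap
        return medial * self.W, lateral * self.W

    def membership(self, xu: np.ndarray, yu: np.ndarray) -> np.ndarray:
        """Silhouette test in axis-frame pixel coordinates."""
        xu = np.asarray(xu, dtype=float)
        yu = np.asarray(yu, dtype=float)
        inside = np.zeros(xu.shape, dtype=bool)
        # body
        yf = yu / self.L
        in_rows = (yf >= BODY_TOP) & (yf <= 1.0)
        if np.any(in_rows):
            med, lat = self._half_widths(yf[in_rows])
            dx = xu[in_rows] - 0.5 * self.W
            if self.params.side == "right":
                med, lat = lat, med
            inside[in_rows] = (-med <= dx) & (dx <= lat)
        # toe capsules
        stem_bottom = TOE_STEM_BOTTOM * self.L
        for cx, r, apex in self.toes:
            ty = np.clip(yu, apex + r, stem_bottom)
            inside |= (xu - cx) ** 2 + (yu - ty) ** 2 <= r**2
        return inside

    def valley_factor(self, xu: np.ndarray, yu: np.ndarray) -> np.ndarray:
        """Brightness multiplier producing dark inter-toe webbing."""
        xu = np.asarray(xu, dtype=float)
        yu = np.asarray(yu, dtype=float)
        ratio = np.full(xu.shape, np.inf)
        for cx, r, _ in self.toes:
            ratio = np.minimum(ratio, np.abs(xu - cx) / r)
        t = np.clip((ratio - 0.9) / (1.15 - 0.9), 0.0, 1.0)
        factor = 1.0 - (1.0 - VALLEY_DARK) * t
        factor[yu / self.L >= VALLEY_ZONE] = 1.0
        return factor


@dataclass
class FootInstance:
    """A rasterized foot on its own square canvas, plus exact truth."""

    params: FootGeometryParams
    mask: np.ndarray  # (S, S) bool, at the requested orientation
    valley: np.ndarray  # (S, S) float brightness multiplier
    sites: dict[int, tuple[float, float]]  # site id -> canvas (x, y)
    #: canvas (x, y) of each toe tip (topmost capsule point), toes 1..5
    toe_tips: tuple[tuple[float, float], ...]
    canvas_center: tuple[float, float]
    model: FootModel


def generate_foot(
    params: FootGeometryParams,
    mm_per_px: float,
    plantar: PlantarConfig | None = None,
) -> FootInstance:
    """Rasterize one foot at its orientation and derive its site truth.

    Toe sites (1-3) come in closed form from the toe-capsule apexes in the
    upright pose: the hallux site 10% of the foot length below its apex,
    the third/fifth-toe sites 5% below theirs.  Plantar sites (4-9) come
    from the guideline construction applied to the clean upright
    silhouette.  The orientation rotation is applied jointly to the mask
    and the truth points, so truth is exact at any tilt.
    """
    plantar = plantar or PlantarConfig()
    model = FootModel(params, mm_per_px)
    side_len = int(math.ceil(math.hypot(model.L, model.W))) + 8
    c0 = ((side_len - 1) / 2.0, (side_len - 1) / 2.0)
    uc = (0.5 * model.W, 0.5 * model.L)
    ys, xs = np.mgrid[0:side_len, 0:side_len]

    def axis_coords(theta_from_chord: float):
        """Axis-frame coordinates of each canvas pixel for a foot rotated
        clockwise by ``theta_from_chord`` from the canonical pose."""
        total = theta_from_chord - model.alpha0  # rotation applied to axis frame
        c, s = _rot(-total)
        dx = xs - c0[0]
        dy = ys - c0[1]
        xu = uc[0] + c * dx - s * dy
        yu = uc[1] + s * dx + c * dy
        return xu, yu

    # upright (chord-vertical) raster for the construction-based truth
    xu0, yu0 = axis_coords(0.0)
    chord_mask = model.membership(xu0, yu0)
    rows = np.flatnonzero(chord_mask.any(axis=1))
    l_chord = float(rows[-1] - rows[0] + 1)

    def to_chord(p: tuple[float, float]) -> tuple[float, float]:
        c, s = _rot(-model.alpha0)
        dx, dy = p[0] - uc[0], p[1] - uc[1]
        return (c0[0] + c * dx - s * dy, c0[1] + s * dx + c * dy)

    tips_chord = []
    for cx, r, apex in model.toes:
        qx, qy = to_chord((cx, apex + r))  # top-sphere center
        tips_chord.append((qx, qy - r))
    sites_chord: dict[int, tuple[float, float]] = {}
    for site_id, toe_idx, depth in ((1, 0, 0.10), (2, 2, 0.05), (3, 4, 0.05)):
        tx, ty = tips_chord[toe_idx]
        sites_chord[site_id] = (tx, ty + depth * l_chord)

    from .plantar_sites import build_guidelines, place_plantar_sites

    guidelines = build_guidelines(chord_mask, plantar)
    for sp in place_plantar_sites(chord_mask, guidelines, params.side, plantar):
        sites_chord[sp.site_id] = (float(sp.x), float(sp.y))

    # rotate raster and truth jointly to the requested orientation
    theta = params.orientation_degrees
    if abs(theta) < 1e-9:
        mask, xu, yu = chord_mask, xu0, yu0
    else:
        xu, yu = axis_coords(theta)
        mask = model.membership(xu, yu)
    valley = model.valley_factor(xu, yu)
    c, s = _rot(theta)

    def spin(q):
        return (
            c0[0] + c * (q[0] - c0[0]) - s * (q[1] - c0[1]),
            c0[1] + s * (q[0] - c0[0]) + c * (q[1] - c0[1]),
        )

    return FootInstance(
        params=params,
        mask=mask,
        valley=valley,
        sites={sid: spin(q) for sid, q in sites_chord.items()},
        toe_tips=tuple(spin(q) for q in tips_chord),
        canvas_center=c0,
        model=model,
    )


# --- scene rendering ------------------------------------------------------

@dataclass
class MarkerSpec:
    color: tuple[int, int, int]
    position: tuple[int, int]  # top-left corner (x, y)


@dataclass
class SceneParams:
    """Acquisition-scene knobs; the seed fixes all randomness."""

    width: int = 1332
    height: int = 1029
    mm_per_px: float = 0.76
    background_gray: int = 12
    marker_size_mm: float = 76.0
    markers: tuple[MarkerSpec, ...] | None = None  # None -> top corners
    #: unit-free gradient strength: pixel gain spans [1-a, 1+a]
    lighting_amplitude: float = 0.1
    lighting_direction: tuple[float, float] = (1.0, 0.2)
    #: (cx, cy, rx, ry, gray) background reflection ellipses
    reflections: tuple[tuple[float, float, float, float, float], ...] = ()
    #: (cx, cy, rx, ry, strength) soft Gaussian shadow lobes multiplying the
    #: scene by 1 - strength at their center; they emulate the shadowing of
    #: the plantar surface that uncontrolled light sources produce
    shadows: tuple[tuple[float, float, float, float, float], ...] = ()
    noise_sigma: float = 3.0
    seed: int = 0

    def default_markers(self) -> tuple[MarkerSpec, ...]:
        size = int(round(self.marker_size_mm / self.mm_per_px))
        return (
            MarkerSpec(color=(255, 235, 59), position=(60, 40)),
            MarkerSpec(color=(255, 105, 180), position=(self.width - 60 - size, 40)),
        )


@dataclass
class FixtureGroundTruth:
    """Generator-side truth accompanying one rendered scene."""

    foot_masks: dict[str, np.ndarray]  # side -> scene-sized bool mask
    sites: dict[tuple[str, int], tuple[float, float]]  # (side, id) -> (x, y)
    annotation: SiteAnnotationMask
    calibration: CalibrationInfo
    orientations: dict[str, float]

    def combined_mask(self) -> np.ndarray:
        masks = list(self.foot_masks.values())
        out = masks[0].copy()
        for m in masks[1:]:
            out |= m
        return out


def render_scene(
    feet: list[tuple[FootGeometryParams, tuple[float, float]]],
    scene: SceneParams | None = None,
    plantar: PlantarConfig | None = None,
    site_disc_mm: float = 4.0,
) -> tuple[np.ndarray, FixtureGroundTruth]:
    """Render a two-feet scene and emit its exact ground truth.

    ``feet`` pairs each foot's geometry with the scene position of its
    canvas center.  Truth (masks, site centers) is emitted before noise is
    applied; noise and lighting only affect the rendered pixels.
    """
    scene = scene or SceneParams()
    h, w = scene.height, scene.width
    rng = np.random.default_rng(scene.seed)

    ys, xs = np.mgrid[0:h, 0:w]
    d = np.asarray(scene.lighting_direction, dtype=float)
    norm = np.hypot(*d)
    d = d / norm if norm else np.array([1.0, 0.0])
    proj = xs * d[0] + ys * d[1]
    span = proj.max() - proj.min()
    u = (proj - proj.min()) / span if span else np.zeros_like(proj, dtype=float)
    gain = 1.0 + scene.lighting_amplitude * (2.0 * u - 1.0)

    img = np.empty((h, w, 3), dtype=float)
    img[:] = scene.background_gray
    for cx, cy, rx, ry, gray in scene.reflections:
        blob = ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 <= 1.0
        img[blob] = gray

    foot_masks: dict[str, np.ndarray] = {}
    sites: dict[tuple[str, int], tuple[float, float]] = {}
    orientations: dict[str, float] = {}
    for params, (px, py) in feet:
        inst = generate_foot(params, scene.mm_per_px, plantar)
        side_len = inst.mask.shape[0]
        ox = int(round(px - inst.canvas_center[0]))
        oy = int(round(py - inst.canvas_center[1]))
        x0, y0 = max(0, ox), max(0, oy)
        x1, y1 = min(w, ox + side_len), min(h, oy + side_len)
        if x1 <= x0 or y1 <= y0:
            raise LayoutConflict("foot canvas falls outside the scene")
        sub_mask = inst.mask[y0 - oy : y1 - oy, x0 - ox : x1 - ox]
        scene_mask = np.zeros((h, w), dtype=bool)
        scene_mask[y0:y1, x0:x1] = sub_mask
        if params.side in foot_masks:
            raise LayoutConflict(f"two feet labeled {params.side!r}")
        for other in foot_masks.values():
            if np.any(other & scene_mask):
                raise LayoutConflict("feet silhouettes overlap")
        shade = inst.valley[y0 - oy : y1 - oy, x0 - ox : x1 - ox]
        color = np.asarray(params.skin_color, dtype=float)
        region = img[y0:y1, x0:x1]
        region[sub_mask] = color[None, :] * shade[sub_mask, None]
        foot_masks[params.side] = scene_mask
        orientations[params.side] = params.orientation_degrees
        for sid, (qx, qy) in inst.sites.items():
            sites[(params.side, sid)] = (qx + ox, qy + oy)

    markers = scene.markers if scene.markers is not None else scene.default_markers()
    size = int(round(scene.marker_size_mm / scene.mm_per_px))
    for marker in markers:
        mx, my = marker.position
        img[my : my + size, mx : mx + size] = marker.color

    img *= gain[:, :, None]
    for cx, cy, rx, ry, strength in scene.shadows:
        lobe = np.exp(-(((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2))
        img *= (1.0 - strength * lobe)[:, :, None]
    if scene.noise_sigma > 0:
        img += rng.normal(0.0, scene.noise_sigma, size=img.shape)
    pixels = np.clip(img, 0, 255).astype(np.uint8)

    palette = Palette()
    labels = np.zeros((h, w), dtype=np.uint8)
    disc_r = max(1.0, site_disc_mm / scene.mm_per_px)
    for (side, sid), (sx, sy) in sites.items():
        rr = int(math.ceil(disc_r))
        yy0, yy1 = max(0, int(sy) - rr - 1), min(h, int(sy) + rr + 2)
        xx0, xx1 = max(0, int(sx) - rr - 1), min(w, int(sx) + rr + 2)
        wy, wx = np.mgrid[yy0:yy1, xx0:xx1]
        disc = (wx - sx) ** 2 + (wy - sy) ** 2 <= disc_r**2
        labels[yy0:yy1, xx0:xx1][disc] = palette.label_for(side, sid)

    truth = FixtureGroundTruth(
        foot_masks=foot_masks,
        sites=sites,
        annotation=SiteAnnotationMask(labels=labels, palette=palette),
        calibration=CalibrationInfo(mm_per_px=scene.mm_per_px, source="markers"),
        orientations=orientations,
    )
    return pixels, truth


# --- fixture suites -------------------------------------------------------

@dataclass
class Fixture:
    name: str
    scene: np.ndarray
    truth: FixtureGroundTruth
    feet: list[tuple[FootGeometryParams, tuple[float, float]]]
    scene_params: SceneParams


PRESETS = ("benign", "tilt_sweep", "lighting_sweep", "toe_overlap_sweep", "marker_proximity")


def _benign_foot(rng: np.random.Generator, side: str, orientation: float | None = None) -> FootGeometryParams:
    jitter = tuple(float(rng.uniform(0.94, 1.06)) for _ in range(5))
    return FootGeometryParams(
        foot_length_mm=float(rng.uniform(225.0, 265.0)),
        width_ratio=float(rng.uniform(0.38, 0.42)),
        toe_radius_scale=jitter,
        toe_overlap=0.0,
        orientation_degrees=float(
            rng.uniform(-35.0, 35.0) if orientation is None else orientation
        ),
        side=side,
        arch_concavity=float(rng.uniform(0.3, 0.7)),
    )


def _feet_positions(scene: SceneParams, rng: np.random.Generator | None = None,
                    y_frac: float = 0.58) -> dict[str, tuple[float, float]]:
    jx = jy = 0.0
    positions = {}
    for side_of_image, xf in (("left", 0.30), ("right", 0.70)):
        if rng is not None:
            jx, jy = rng.uniform(-15, 15), rng.uniform(-15, 15)
        # image-left region is the patient's right foot
        side = "right" if side_of_image == "left" else "left"
        positions[side] = (xf * scene.width + jx, y_frac * scene.height + jy)
    return positions


def fixture_suite(preset: str, n: int, seed: int = 0) -> list[Fixture]:
    """Generate ``n`` reproducible fixtures from a named preset.

    * ``benign`` — uncorrelated draws from the study's nominal acquisition
      conditions (mild gradient, light noise, no reflections);
    * ``tilt_sweep`` — fixed anatomy, orientations evenly spanning +-40
      degrees;
    * ``lighting_sweep`` — fixed anatomy, gradient amplitude increasing
      monotonically from 0 to 0.9 across the suite;
    * ``toe_overlap_sweep`` — toe gaps closing progressively;
    * ``marker_proximity`` — longer feet placed progressively closer to
      the calibration markers.
    """
    if preset not in PRESETS:
        raise UnknownPreset(f"unknown preset {preset!r}; choose from {PRESETS}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    fixtures = []
    for i in range(n):
        scene = SceneParams(seed=int(rng.integers(0, 2**31)))
        if preset == "benign":
            feet_params = {s: _benign_foot(rng, s) for s in SIDES}
            scene = replace(
                scene,
                lighting_amplitude=float(rng.uniform(0.05, 0.2)),
                lighting_direction=(float(rng.uniform(-1, 1)), float(rng.uniform(-0.3, 0.3))),
                noise_sigma=float(rng.uniform(2.0, 4.0)),
            )
            positions = _feet_positions(scene, rng)
        elif preset == "tilt_sweep":
            theta = -40.0 + 80.0 * (i / max(1, n - 1))
            feet_params = {s: _benign_foot(_fixed_rng(seed, s), s, orientation=theta) for s in SIDES}
            scene = replace(scene, lighting_amplitude=0.1, noise_sigma=2.0)
            positions = _feet_positions(scene)
        elif preset == "lighting_sweep":
            # severity 0..1 scales both the gradient and a shadow lobe cast
            # over the image-left foot's toe region
            t = i / max(1, n - 1)
            feet_params = {s: _benign_foot(_fixed_rng(seed, s), s, orientation=10.0) for s in SIDES}
            positions = _feet_positions(scene)
            px, py = positions["right"]  # image-left foot
            scene = replace(
                scene,
                lighting_amplitude=float(0.6 * t),
                lighting_direction=(1.0, 0.1),
                shadows=((px + 20.0, py - 110.0, 100.0, 150.0, float(0.95 * t)),),
                noise_sigma=2.0,
            )
        elif preset == "toe_overlap_sweep":
            overlap = 0.85 * (i / max(1, n - 1))
            feet_params = {
                s: replace(_benign_foot(_fixed_rng(seed, s), s, orientation=0.0),
                           toe_overlap=float(overlap))
                for s in SIDES
            }
            scene = replace(scene, lighting_amplitude=0.1, noise_sigma=2.0)
            positions = _feet_positions(scene)
        else:  # marker_proximity
            y_frac = 0.58 - 0.10 * (i / max(1, n - 1))
            feet_params = {}
            for s in SIDES:
                foot = _benign_foot(_fixed_rng(seed, s), s, orientation=0.0)
                feet_params[s] = replace(foot, foot_length_mm=280.0)
            scene = replace(scene, lighting_amplitude=0.1, noise_sigma=2.0)
            positions = _feet_positions(scene, y_frac=y_frac)
        feet = [(feet_params[s], positions[s]) for s in SIDES]
        pixels, truth = render_scene(feet, scene)
        fixtures.append(
            Fixture(name=f"{preset}_{i:03d}", scene=pixels, truth=truth,
                    feet=feet, scene_params=scene)
        )
    return fixtures


def _fixed_rng(seed: int, side: str) -> np.random.Generator:
    """Deterministic per-side anatomy shared across a sweep."""
    return np.random.default_rng((seed, 0 if side == "left" else 1))
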