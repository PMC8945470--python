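"""Locate the toe testing sites: hallux (site 1), third toe (2), fifth toe (3).

Two complementary signals drive the toe detectors on a vertically aligned
foot:

* the **contour profile** — the per-column topmost foreground row.  Toe
  tips are its prominent local minima (a "peak" of the foot outline).
* the **offset intensity track** — the grayscale intensity sampled along
  the contour shifted toward the phalanges by 5% of the foot length.
  Between the toes the track crosses shadowed inter-toe webbing and reads
  dark; over a toe it reads bright.  Classifying the track into alternating
  bright/dark spans yields one bright span per visible toe, with the hallux
  span expected to cover ~40% of the foot width and each small toe ~15%.

The hallux column is the first prominent contour peak scanned from the
medial edge (left-to-right for a left foot, right-to-left for a right
foot), which is robust to the occasional foot whose second toe is more
prominent than the hallux.  Its site lies 10% of the foot length below the
contour peak.  The small-toe sites are only emitted when their bright span
has a plausible width and at least one of the color or contour cues is
present — a site that cannot be supported by evidence is omitted, never
guessed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .background_segmentation import luma
from .config import ToesConfig
from .errors import EmptyToesView, NoPeakFound
from .foot_normalization import NormalizedFoot
from .types import SitePoint, round_half_away


@dataclass
class ContourProfile:
    """Per-column topmost foreground row of a vertically aligned foot."""

    y_top: np.ndarray  # float per column; NaN where invalid
    valid: np.ndarray  # bool per column
    foot_length: int  # L, px
    col_range: tuple[int, int]  # half-open [first, last+1) valid column span

    @property
    def foot_width(self) -> int:
        return self.col_range[1] - self.col_range[0]

    def smoothed(self, window: int = 5) -> np.ndarray:
        """Moving-average of y_top over valid columns (edges shrink)."""
        y = self.y_top.copy()
        c0, c1 = self.col_range
        if window > 1 and c1 - c0 >= window:
            kernel = np.ones(window) / window
            y[c0 : c1] = np.convolve(
                np.pad(y[c0:c1], window // 2, mode="edge"), kernel, mode="valid"
            )[: c1 - c0]
        return y


def upper_contour_profile(foot: NormalizedFoot) -> ContourProfile:
    """Scan each column top-down for the first foreground row."""
    mask = foot.mask
    if not mask.any():
        raise EmptyToesView("normalized foot mask is empty")
    valid = mask.any(axis=0)
    y_top = np.full(mask.shape[1], np.nan)
    y_top[valid] = mask.argmax(axis=0)[valid]
    cols = np.flatnonzero(valid)
    return ContourProfile(
        y_top=y_top,
        valid=valid,
        foot_length=foot.foot_length,
        col_range=(int(cols[0]), int(cols[-1]) + 1),
    )


def contour_peaks(profile: ContourProfile, params: ToesConfig) -> np.ndarray:
    """Columns of prominent local minima of ``y_top`` (toe tips), i.e. of
    sign inversions of the first derivative that exceed the prominence
    threshold (a fraction of foot length)."""
    c0, c1 = profile.col_range
    y = profile.smoothed(params.smooth_window)[c0:c1]
    # remove the linear trend left by any residual foot tilt: on a sloped
    # profile scipy's prominence (relative to the higher base) shrinks for
    # downhill toes even when their dips are clearly present
    cols = np.arange(c1 - c0, dtype=float)
    slope, intercept = np.polyfit(cols, y, 1)
    detrended = y - (slope * cols + intercept)
    prominence = params.peak_prominence * profile.foot_length
    peaks, _ = find_peaks(-detrended, prominence=prominence)
    # detrending biases the argmin along the slope; relocate each detected
    # peak to the local minimum of the undetrended profile
    refined = []
    for p in peaks:
        lo, hi = max(0, p - 4), min(len(y), p + 5)
        refined.append(lo + int(np.argmin(y[lo:hi])))
    return np.asarray(sorted(set(refined)), dtype=int) + c0


def _refine_apex(profile: ContourProfile, col: int, params: ToesConfig,
                 window_fraction: float = 0.08, plateau_tol: float = 1.5) -> int:
    """Deflatten an integer contour peak: the toe apex arc is locally flat,
    so the raw argmin wobbles by a few columns; the centroid of the
    near-apex plateau is a stable sub-pixel apex estimate."""
    c0, c1 = profile.col_range
    half = max(2, round(window_fraction * profile.foot_width))
    lo, hi = max(c0, col - half), min(c1, col + half + 1)
    y = profile.y_top[lo:hi]
    cols = np.arange(lo, hi)
    ok = ~np.isnan(y)
    if not ok.any():
        return col
    near = ok & (y <= np.nanmin(y) + plateau_tol)
    return round_half_away(float(cols[near].mean()))


def locate_hallux(
    profile: ContourProfile,
    side: str,
    params: ToesConfig | None = None,
) -> SitePoint:
    """Site 1: first prominent contour peak from the medial edge, placed
    10% of the foot length below the contour line."""
    params = params or ToesConfig()
    peaks = contour_peaks(profile, params)
    if peaks.size == 0:
        raise NoPeakFound("contour profile has no prominent local minimum")
    c0, c1 = profile.col_range
    w_f = profile.foot_width
    medial_first = peaks if side == "left" else peaks[::-1]
    chosen = int(medial_first[0])

    # the hallux peak is expected around 20% of the foot width from the
    # medial edge; a peak far outside that band indicates a tilted phalange
    # and triggers a constrained re-search within the band
    from_medial = (chosen - c0) if side == "left" else (c1 - 1 - chosen)
    band = params.band_tolerance * w_f
    expected = params.hallux_band_center * w_f
    if abs(from_medial - expected) > band:
        in_band = [
            p
            for p in peaks
            if abs(((p - c0) if side == "left" else (c1 - 1 - p)) - expected) <= band
        ]
        if in_band:
            chosen = int(in_band[0] if side == "left" else in_band[-1])

    chosen = _refine_apex(profile, chosen, params)
    y_peak = float(profile.y_top[chosen])
    return SitePoint(
        site_id=1,
        side=side,
        x=chosen,
        y=round_half_away(y_peak + params.hallux_depth * profile.foot_length),
        evidence=frozenset({"contour"}),
    )


@dataclass
class Span:
    start: int  # inclusive column
    stop: int  # exclusive column
    bright: bool

    @property
    def width(self) -> int:
        return self.stop - self.start

    @property
    def center(self) -> int:
        return (self.start + self.stop - 1) // 2


@dataclass
class ToeTrack:
    """Grayscale intensity along the offset contour, split into spans."""

    columns: np.ndarray
    intensity: np.ndarray
    threshold: float
    spans: list[Span]
    peaks: np.ndarray  # contour-peak columns
    low_confidence: bool

    def bright_spans(self) -> list[Span]:
        return [s for s in self.spans if s.bright]


def analyze_toe_track(
    foot: NormalizedFoot,
    profile: ContourProfile,
    params: ToesConfig | None = None,
) -> ToeTrack:
    """Sample the grayscale image along the contour offset downward by
    ``offset_fraction`` of the foot length and classify columns into
    alternating bright (toe) / dark (inter-toe valley) spans using the
    midpoint of the track's robust min/max as threshold."""
    params = params or ToesConfig()
    c0, c1 = profile.col_range
    cols = np.arange(c0, c1)
    offset = params.offset_fraction * profile.foot_length
    rows = np.clip(
        (profile.y_top[c0:c1] + offset).round().astype(int), 0, foot.mask.shape[0] - 1
    )
    gray = luma(foot.image)
    intensity = gray[rows, cols]

    lo, hi = np.percentile(intensity, params.robust_percentiles)
    threshold = (lo + hi) / 2.0
    low_confidence = (hi - lo) < params.min_contrast
    bright = intensity >= threshold
    if low_confidence:
        bright = np.ones_like(bright)

    spans: list[Span] = []
    run_start = 0
    for i in range(1, len(bright) + 1):
        if i == len(bright) or bright[i] != bright[run_start]:
            spans.append(Span(start=int(cols[run_start]),
                              stop=int(cols[i - 1]) + 1,
                              bright=bool(bright[run_start])))
            run_start = i
    return ToeTrack(
        columns=cols,
        intensity=intensity,
        threshold=float(threshold),
        spans=spans,
        peaks=contour_peaks(profile, params),
        low_confidence=low_confidence,
    )


def place_small_toe_sites(
    track: ToeTrack,
    profile: ContourProfile,
    side: str,
    params: ToesConfig | None = None,
) -> list[SitePoint]:
    """Sites 2 (third toe) and 3 (fifth toe) from the toe track.

    The bright span nearest the medial edge whose width is near 40% of the
    foot width is the hallux; the remaining bright spans, ordered medially
    to laterally, are toes 2..5.  Site 2 comes from the third toe's span
    and site 3 from the fifth toe's, each emitted only when the span width
    is within tolerance of 15% of the foot width and carries color and/or
    contour evidence.  Sites that fail the rule are omitted."""
    params = params or ToesConfig()
    w_f = profile.foot_width
    bright = track.bright_spans()
    if track.low_confidence or not bright:
        return []
    ordered = bright if side == "left" else list(reversed(bright))

    # the hallux span is the bright span nearest the medial edge whose
    # width is plausible for a hallux; narrow slivers medial of it are
    # silhouette-margin artifacts and are discarded
    hallux_tol = params.hallux_span_tolerance * w_f
    hallux_idx = next(
        (
            i
            for i, span in enumerate(ordered)
            if abs(span.width - params.hallux_span * w_f) <= hallux_tol
        ),
        None,
    )
    small = ordered[hallux_idx + 1 :] if hallux_idx is not None else []

    # assign spans to anatomical toes 2..5 walking medially -> laterally.
    # The expected pattern is four plausible small-toe spans; a merged or
    # hidden toe breaks the positional count (a merged pair can itself pass
    # the width test), so any deviation from the complete pattern means the
    # assignment cannot be trusted and no small-toe site is emitted.
    plausible = 0
    for span in small[:4]:
        if abs(span.width - params.small_span * w_f) > params.proportion_tolerance * w_f:
            break
        plausible += 1
    if plausible < 4:
        return []

    sites = []
    # small[0] -> 2nd toe, small[1] -> 3rd toe (site 2), small[3] -> 5th (site 3)
    for site_id, idx in ((2, 1), (3, 3)):
        span = small[idx]
        evidence = {"color", "proportion"}
        span_peaks = [p for p in track.peaks if span.start <= p < span.stop]
        if span_peaks:
            evidence.add("contour")
            x = int(span_peaks[len(span_peaks) // 2])
        else:
            x = span.center
        y_top = profile.y_top[x]
        if np.isnan(y_top):
            continue
        sites.append(
            SitePoint(
                site_id=site_id,
                side=side,
                x=x,
                y=round_half_away(float(y_top) + params.small_toe_depth * profile.foot_length),
                evidence=frozenset(evidence),
            )
        )
    return sites
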