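"""End-to-end orchestration: scene in, nine testing sites per foot out.

Stage order: markers and calibration, background segmentation into two
foot regions, per-foot normalization to the upright pose, toe-site
detection on the contour/track signals, plantar-site placement on the
guideline construction, and remapping of every estimate back to scene
coordinates through the recorded transform chain.

Failures degrade gracefully: a foot that cannot be processed is dropped
with a warning, a site whose evidence rule is not met is simply absent
from the result (never guessed), and only the inability to find two feet
at all aborts the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation_io
from .background_segmentation import detect_markers, segment_feet
from .config import PipelineConfig
from .errors import (
    DegenerateRegion,
    EmptyToesView,
    LineMissesFoot,
    NoPairs,
    NoPeakFound,
    OutOfBounds,
    RowMissesFoot,
)
from .evaluation_metrics import EvaluationReport, summarize
from .foot_normalization import normalize_foot, remap_point
from .plantar_sites import build_guidelines, place_plantar_sites
from .toe_sites import analyze_toe_track, locate_hallux, place_small_toe_sites, upper_contour_profile
from .types import CalibrationInfo, FootRegion, SitePoint, ThresholdReport

logger = logging.getLogger("plantarsites")


@dataclass
class PipelineResult:
    """Scene-coordinate site estimates plus run diagnostics."""

    sites: list[SitePoint] = field(default_factory=list)
    calibration: CalibrationInfo | None = None
    threshold: ThresholdReport | None = None
    regions: list[FootRegion] = field(default_factory=list)
    stage_status: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def by_key(self) -> dict[tuple[str, int], tuple[int, int]]:
        return {(p.side, p.site_id): (p.x, p.y) for p in self.sites}

    def sites_for(self, side: str) -> list[SitePoint]:
        return [p for p in self.sites if p.side == side]


def run_pipeline(scene: np.ndarray, config: PipelineConfig | None = None) -> PipelineResult:
    """Locate the monofilament testing sites in one acquisition scene.

    Raises :class:`~plantarsites.errors.FeetNotFound` when the scene does
    not yield two foot regions; all other failures are per-foot or
    per-site and reported through ``warnings``.
    """
    config = config or PipelineConfig()
    result = PipelineResult()

    result.calibration = detect_markers(scene, config.markers)
    result.stage_status["markers"] = result.calibration.source

    regions, report = segment_feet(scene, config, result.calibration.marker_boxes)
    result.threshold = report
    result.regions = regions
    result.stage_status["segmentation"] = "ok"

    for region in regions:
        try:
            _process_foot(scene, region, config, result)
        except (DegenerateRegion, EmptyToesView, RowMissesFoot, LineMissesFoot) as exc:
            result.warnings.append(f"{region.side} foot dropped: {exc}")
            result.stage_status[f"foot_{region.side}"] = "failed"
    return result


def _process_foot(
    scene: np.ndarray,
    region: FootRegion,
    config: PipelineConfig,
    result: PipelineResult,
) -> None:
    foot = normalize_foot(scene, region, config.normalize)
    profile = upper_contour_profile(foot)

    estimates: list[SitePoint] = []
    try:
        estimates.append(locate_hallux(profile, foot.side, config.toes))
    except NoPeakFound as exc:
        result.warnings.append(f"{foot.side} foot: hallux not found ({exc})")

    track = analyze_toe_track(foot, profile, config.toes)
    small = place_small_toe_sites(track, profile, foot.side, config.toes)
    estimates.extend(small)
    for sid in (2, 3):
        if sid not in {p.site_id for p in small}:
            result.warnings.append(
                f"{foot.side} foot: site {sid} omitted (toe evidence rule not met)"
            )

    guidelines = build_guidelines(foot.mask, config.plantar)
    estimates.extend(place_plantar_sites(foot.mask, guidelines, foot.side, config.plantar))

    for point in estimates:
        try:
            x, y = remap_point((point.x, point.y), foot.chain)
        except OutOfBounds as exc:
            result.warnings.append(
                f"{foot.side} foot: site {point.site_id} dropped ({exc})"
            )
            continue
        result.sites.append(
            SitePoint(site_id=point.site_id, side=point.side, x=x, y=y,
                      evidence=point.evidence)
        )
    result.stage_status[f"foot_{foot.side}"] = "ok"


def evaluate_run(
    results_dir: str | Path,
    truth_dir: str | Path,
    config: PipelineConfig | None = None,
) -> EvaluationReport:
    """Score a directory of pipeline outputs against matched truth files.

    Both directories are expected to hold ``<name>.sites.csv`` files with
    the standard ``image,side,site_id,x,y`` layout; pairing is by file
    name.  A ``<name>.calibration.json`` next to the truth file supplies
    the millimetre scale for the error radii (pixel fallbacks otherwise).
    """
    config = config or PipelineConfig()
    results_dir, truth_dir = Path(results_dir), Path(truth_dir)
    truth_files = sorted(truth_dir.glob("*.sites.csv"))
    rows = []
    mm_scales = []
    for truth_file in truth_files:
        name = truth_file.name[: -len(".sites.csv")]
        result_file = results_dir / truth_file.name
        if not result_file.exists():
            continue
        truth_pts = annotation_io.read_site_points(truth_file)
        est_pts = annotation_io.read_site_points(result_file)
        cal_file = truth_dir / f"{name}.calibration.json"
        if cal_file.exists():
            import json

            with open(cal_file, "r", encoding="utf-8") as fh:
                mm_scales.append(float(json.load(fh)["mm_per_px"]))
        for image, points in truth_pts.items():
            est_by_key = {
                (p.side, p.site_id): p for p in est_pts.get(image, [])
            }
            for ref in points:
                est = est_by_key.get((ref.side, ref.site_id))
                rows.append(
                    {
                        "image": image,
                        "side": ref.side,
                        "site_id": ref.site_id,
                        "true_x": ref.x,
                        "true_y": ref.y,
                        "est_x": est.x if est else np.nan,
                        "est_y": est.y if est else np.nan,
                    }
                )
    if not rows:
        raise NoPairs(f"no matched site files between {results_dir} and {truth_dir}")
    cal = CalibrationInfo(
        mm_per_px=float(np.mean(mm_scales)) if mm_scales else None,
        source="markers" if mm_scales else "absent",
    )
    return summarize(pd.DataFrame(rows), cal=cal, evaluation=config.evaluation)
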