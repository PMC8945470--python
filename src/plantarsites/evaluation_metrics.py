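"""Segmentation and localization quality metrics.

Four quantities score the pipeline:

* feet-detection accuracy — fraction of feet segmented as distinct blobs;
* normalized Hamming dissimilarity ``d(A, B)`` between binary masks — the
  population count of ``A XOR B`` divided by the number of pixels, a
  resolution-invariant edge/region error in ``[0, 1]``;
* testing-site location accuracy ``Acc_TSL(r)`` — fraction of estimated
  sites strictly within a Euclidean radius ``r`` of their references
  (5 mm for the toe sites 1-3, 10 mm for the central/heel sites 4-9);
* Jaccard similarity coefficient (intersection over union) between binary
  regions.

Missing site estimates count as misses in ``Acc_TSL``: that is the only way
a per-site accuracy can fall below 100% for a pipeline that never guesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EvaluationConfig
from .errors import EmptyList, NoPairs, ShapeMismatch, ZeroFeet
from .types import CalibrationInfo


def feet_detection_accuracy(n_correct: int, n_feet: int) -> float:
    """Correctly identified feet blobs over total feet."""
    if n_feet <= 0:
        raise ZeroFeet("feet-detection accuracy needs at least one foot")
    if not 0 <= n_correct <= n_feet:
        raise ValueError("n_correct must be within [0, n_feet]")
    return n_correct / n_feet


def _check_shapes(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ShapeMismatch(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def mask_dissimilarity(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized Hamming distance: mean of the pixelwise XOR."""
    a, b = _check_shapes(a, b)
    return float(np.logical_xor(a, b).mean())


def edge_accuracy(distances, margin: float = 0.05) -> float:
    """Fraction of dissimilarity values at or under the error margin."""
    if not 0 < margin <= 1:
        raise ValueError("margin must be in (0, 1]")
    distances = np.asarray(list(distances), dtype=float)
    if distances.size == 0:
        raise EmptyList("edge accuracy over an empty list is undefined")
    return float(np.mean(distances <= margin))


def jaccard_index(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union; defined as 1 when both masks are empty
    (perfect agreement about absence, where the ratio is 0/0)."""
    a, b = _check_shapes(a, b)
    inter = int(np.logical_and(a, b).sum())
    union = int(a.sum()) + int(b.sum()) - inter
    return 1.0 if union == 0 else inter / union


def site_location_accuracy(
    estimates: dict,
    references: dict,
    cal: CalibrationInfo | None = None,
    evaluation: EvaluationConfig | None = None,
    site_ids=None,
) -> float:
    """``Acc_TSL`` over reference sites, with per-site radii.

    ``estimates`` and ``references`` map ``(image, side, site_id)`` keys to
    ``(x, y)`` pixel points.  Every reference forms a pair; a reference with
    no estimate is a miss.  A pair is a hit when the Euclidean pixel
    distance is *strictly* below the radius (a distance exactly equal to
    the radius is a miss).
    """
    evaluation = evaluation or EvaluationConfig()
    cal = cal or CalibrationInfo(mm_per_px=None, source="absent")
    keys = [k for k in references if site_ids is None or k[2] in site_ids]
    if not keys:
        raise NoPairs("no (estimate, reference) pairs to evaluate")
    hits = 0
    for key in keys:
        site_id = key[2]
        r_px = cal.to_px(evaluation.radius_mm(site_id), evaluation.radius_px_fallback(site_id))
        est = estimates.get(key)
        if est is None:
            continue
        rx, ry = references[key]
        if float(np.hypot(est[0] - rx, est[1] - ry)) < r_px:
            hits += 1
    return hits / len(keys)


def disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean disc (pixels whose centers lie within ``radius`` of ``center``)."""
    h, w = shape
    ys, xs = np.ogrid[:h, :w]
    cx, cy = center
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2


def point_pair_jaccard(
    estimate: tuple[float, float],
    reference: tuple[float, float],
    radius_px: float,
) -> float:
    """Jaccard index between two equal discs of the tolerance radius, one
    centered on the estimate and one on the reference.

    The pipeline outputs points, while region-overlap scoring compares
    areas; representing each point as a disc of its admissible-error radius
    makes the two comparable.  Computed on a local raster window.
    """
    r = max(1.0, float(radius_px))
    d = float(np.hypot(estimate[0] - reference[0], estimate[1] - reference[1]))
    if d > 2 * r:
        return 0.0
    pad = int(np.ceil(r)) + 2
    x0 = min(estimate[0], reference[0]) - pad
    y0 = min(estimate[1], reference[1]) - pad
    w = int(np.ceil(abs(estimate[0] - reference[0]))) + 2 * pad
    h = int(np.ceil(abs(estimate[1] - reference[1]))) + 2 * pad
    a = disc_mask((h, w), (estimate[0] - x0, estimate[1] - y0), r)
    b = disc_mask((h, w), (reference[0] - x0, reference[1] - y0), r)
    return jaccard_index(a, b)


def five_number_summary(values) -> dict[str, float]:
    """Box-plot statistics: min, first quartile, median, third quartile, max."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise EmptyList("five-number summary of an empty list")
    q25, q50, q75 = np.percentile(arr, [25, 50, 75])
    return {
        "min": float(arr.min()),
        "q25": float(q25),
        "median": float(q50),
        "q75": float(q75),
        "max": float(arr.max()),
    }


@dataclass
class EvaluationReport:
    """Aggregated scores over a set of images."""

    acc_fd: float | None = None
    edge_distances: list[float] = field(default_factory=list)
    edge_accuracy: float | None = None
    #: stratum -> site_id -> Acc_TSL
    acc_tsl: dict[str, dict[int, float]] = field(default_factory=dict)
    #: site_id -> list of Jaccard values (where the site was estimated)
    jsc: dict[int, list[float]] = field(default_factory=dict)
    #: site_id -> five-number summary of the Jaccard distribution
    jsc_summary: dict[int, dict[str, float]] = field(default_factory=dict)
    n_images: int = 0

    def to_dict(self) -> dict:
        return {
            "acc_fd": self.acc_fd,
            "edge_accuracy": self.edge_accuracy,
            "acc_tsl": {s: {str(k): v for k, v in d.items()} for s, d in self.acc_tsl.items()},
            "jsc_summary": {str(k): v for k, v in self.jsc_summary.items()},
            "n_images": self.n_images,
        }

    def acc_frame(self) -> pd.DataFrame:
        rows = [
            {"stratum": stratum, "site_id": site, "acc_tsl": acc}
            for stratum, per_site in self.acc_tsl.items()
            for site, acc in sorted(per_site.items())
        ]
        return pd.DataFrame(rows, columns=["stratum", "site_id", "acc_tsl"])


def plot_jsc_boxes(report: "EvaluationReport", path) -> None:
    """Box plot of the per-site Jaccard distributions (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sites = sorted(report.jsc)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.boxplot([report.jsc[s] for s in sites], tick_labels=[str(s) for s in sites])
    ax.set_xlabel("testing site")
    ax.set_ylabel("Jaccard similarity coefficient")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def summarize(
    records: pd.DataFrame,
    cal: CalibrationInfo | None = None,
    evaluation: EvaluationConfig | None = None,
    acc_fd: float | None = None,
    edge_distances=None,
) -> EvaluationReport:
    """Build an :class:`EvaluationReport` from paired site records.

    ``records`` needs columns ``image, side, site_id, true_x, true_y`` plus
    ``est_x, est_y`` (NaN where the pipeline emitted nothing) and optionally
    ``sex`` per image for the gender strata.  Strata: overall, per foot
    side, and per sex when present.
    """
    evaluation = evaluation or EvaluationConfig()
    cal = cal or CalibrationInfo(mm_per_px=None, source="absent")
    required = {"image", "side", "site_id", "true_x", "true_y", "est_x", "est_y"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if len(records) == 0:
        raise NoPairs("no records to summarize")

    def _accs(sub: pd.DataFrame) -> dict[int, float]:
        out: dict[int, float] = {}
        for site_id, grp in sub.groupby("site_id"):
            r_px = cal.to_px(
                evaluation.radius_mm(int(site_id)),
                evaluation.radius_px_fallback(int(site_id)),
            )
            d = np.hypot(grp.est_x - grp.true_x, grp.est_y - grp.true_y)
            hits = (d < r_px) & d.notna()
            out[int(site_id)] = float(hits.mean())
        return out

    report = EvaluationReport(n_images=records["image"].nunique(), acc_fd=acc_fd)
    report.acc_tsl["overall"] = _accs(records)
    for side, sub in records.groupby("side"):
        report.acc_tsl[str(side)] = _accs(sub)
    if "sex" in records.columns:
        for sex, sub in records.dropna(subset=["sex"]).groupby("sex"):
            report.acc_tsl[str(sex)] = _accs(sub)

    for row in records.dropna(subset=["est_x", "est_y"]).itertuples(index=False):
        r_px = cal.to_px(
            evaluation.radius_mm(int(row.site_id)),
            evaluation.radius_px_fallback(int(row.site_id)),
        )
        j = point_pair_jaccard((row.est_x, row.est_y), (row.true_x, row.true_y), r_px)
        report.jsc.setdefault(int(row.site_id), []).append(j)
    report.jsc_summary = {site: five_number_summary(v) for site, v in sorted(report.jsc.items())}

    if edge_distances is not None:
        report.edge_distances = [float(d) for d in edge_distances]
        report.edge_accuracy = edge_accuracy(report.edge_distances, evaluation.edge_margin)
    return report
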