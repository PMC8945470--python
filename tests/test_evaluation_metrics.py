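"""Metric implementations versus brute-force oracles and metric laws."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plantarsites.config import EvaluationConfig
from plantarsites.errors import EmptyList, NoPairs, ShapeMismatch, ZeroFeet
from plantarsites import evaluation_metrics as em
from plantarsites.types import CalibrationInfo


# --- naive double-loop oracles (kept independent of the implementations) --

def oracle_dissimilarity(a, b):
    total = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += int(bool(a[i, j]) ^ bool(b[i, j]))
    return total / (a.shape[0] * a.shape[1])


def oracle_jaccard(a, b):
    inter = union = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            inter += int(bool(a[i, j]) and bool(b[i, j]))
            union += int(bool(a[i, j]) or bool(b[i, j]))
    return 1.0 if union == 0 else inter / union


def _random_masks(rng, n=20, shape=(32, 32)):
    return [(rng.random(shape) > rng.uniform(0.2, 0.8),
             rng.random(shape) > rng.uniform(0.2, 0.8)) for _ in range(n)]


def test_feet_detection_accuracy_examples():
    assert em.feet_detection_accuracy(179, 180) == pytest.approx(179 / 180)
    assert em.feet_detection_accuracy(0, 10) == 0.0
    assert em.feet_detection_accuracy(10, 10) == 1.0
    with pytest.raises(ZeroFeet):
        em.feet_detection_accuracy(0, 0)


def test_dissimilarity_examples():
    rng = np.random.default_rng(0)
    a = rng.random((10, 10)) > 0.5
    assert em.mask_dissimilarity(a, a) == 0.0
    assert em.mask_dissimilarity(a, ~a) == 1.0
    b = a.copy()
    b[3, 4] ^= True
    assert em.mask_dissimilarity(a, b) == pytest.approx(0.01)
    with pytest.raises(ShapeMismatch):
        em.mask_dissimilarity(a, a[:5])


def test_dissimilarity_matches_oracle(rng):
    for a, b in _random_masks(rng):
        assert em.mask_dissimilarity(a, b) == oracle_dissimilarity(a, b)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_dissimilarity_is_a_metric(seed):
    """Identity, symmetry and the triangle inequality on random triples."""
    r = np.random.default_rng(seed)
    a, b, c = (r.random((12, 12)) > 0.5 for _ in range(3))
    assert em.mask_dissimilarity(a, a) == 0.0
    assert em.mask_dissimilarity(a, b) == em.mask_dissimilarity(b, a)
    assert em.mask_dissimilarity(a, c) <= (
        em.mask_dissimilarity(a, b) + em.mask_dissimilarity(b, c) + 1e-12
    )


def test_edge_accuracy_counting():
    assert em.edge_accuracy([0.01, 0.02, 0.9], margin=0.05) == pytest.approx(2 / 3)
    assert em.edge_accuracy([0.0] * 5, margin=0.05) == 1.0
    assert em.edge_accuracy([0.01] * 36 + [0.9], margin=0.05) == pytest.approx(36 / 37)
    with pytest.raises(EmptyList):
        em.edge_accuracy([], margin=0.05)


def test_jaccard_examples():
    rng = np.random.default_rng(1)
    a = rng.random((8, 8)) > 0.5
    assert em.jaccard_index(a, a) == 1.0
    left = np.zeros((4, 4), bool); left[:, :2] = True
    right = np.zeros((4, 4), bool); right[:, 2:] = True
    assert em.jaccard_index(left, right) == 0.0
    x = np.zeros((4, 4), bool); x[0, :4] = True
    y = np.zeros((4, 4), bool); y[0, 2:4] = True; y[1, 0:2] = True
    assert em.jaccard_index(x, y) == pytest.approx(1 / 3)
    empty = np.zeros((4, 4), bool)
    assert em.jaccard_index(empty, empty) == 1.0  # agreement about absence


def test_jaccard_matches_oracle_and_is_symmetric(rng):
    for a, b in _random_masks(rng):
        j = em.jaccard_index(a, b)
        assert j == oracle_jaccard(a, b)
        assert j == em.jaccard_index(b, a)
        assert 0.0 <= j <= 1.0
        denom = int(a.sum()) + int(b.sum())
        if denom:
            assert j >= int((a & b).sum()) / denom


def test_jaccard_monotone_under_containment(rng):
    """For nested masks A within B within C: J(A, C) <= J(B, C)."""
    for _ in range(50):
        c = rng.random((10, 10)) > 0.3
        b = c & (rng.random((10, 10)) > 0.3)
        a = b & (rng.random((10, 10)) > 0.3)
        assert em.jaccard_index(a, c) <= em.jaccard_index(b, c) + 1e-12


class TestSiteLocationAccuracy:
    def test_exact_estimates_score_one(self):
        refs = {("img", "left", s): (10.0 * s, 20.0) for s in range(1, 10)}
        assert em.site_location_accuracy(dict(refs), refs) == 1.0

    def test_distance_exactly_r_is_a_miss(self):
        """The admissible radius is a strict bound."""
        cfg = EvaluationConfig(toe_radius_px=10.0, central_radius_px=20.0)
        refs = {("img", "left", s): (100.0, 100.0) for s in range(1, 10)}
        ests = dict(refs)
        ests[("img", "left", 5)] = (120.0, 100.0)  # exactly r=20 away
        acc = em.site_location_accuracy(ests, refs, evaluation=cfg)
        assert acc == pytest.approx(8 / 9)

    def test_missing_estimate_counts_as_miss(self):
        refs = {("img", "left", 1): (0.0, 0.0), ("img", "left", 2): (5.0, 5.0)}
        ests = {("img", "left", 1): (0.0, 0.0)}
        assert em.site_location_accuracy(ests, refs) == pytest.approx(0.5)

    def test_known_offsets_with_millimetre_calibration(self):
        """Offsets of 3 mm and 7 mm at the 5 mm toe radius give 50%."""
        cal = CalibrationInfo(mm_per_px=0.5, source="markers")
        refs = {("a", "left", 1): (100.0, 100.0), ("b", "left", 1): (100.0, 100.0)}
        ests = {
            ("a", "left", 1): (100.0 + 3 / 0.5, 100.0),
            ("b", "left", 1): (100.0 + 7 / 0.5, 100.0),
        }
        assert em.site_location_accuracy(ests, refs, cal=cal) == pytest.approx(0.5)

    def test_matches_loop_oracle(self, rng):
        cal = CalibrationInfo(mm_per_px=0.8, source="markers")
        cfg = EvaluationConfig()
        refs, ests = {}, {}
        for i in range(60):
            key = (f"img{i % 7}", "left" if i % 2 else "right", 1 + i % 9)
            refs[key] = tuple(rng.uniform(0, 200, 2))
            if rng.random() < 0.8:
                ests[key] = tuple(refs[key] + rng.normal(0, 8, 2))
        hits = 0
        for key, (rx, ry) in refs.items():
            if key in ests:
                r_mm = 5.0 if key[2] <= 3 else 10.0
                d = ((ests[key][0] - rx) ** 2 + (ests[key][1] - ry) ** 2) ** 0.5
                hits += d < r_mm / 0.8
        assert em.site_location_accuracy(ests, refs, cal=cal, evaluation=cfg) == (
            pytest.approx(hits / len(refs))
        )

    def test_no_pairs_raises(self):
        with pytest.raises(NoPairs):
            em.site_location_accuracy({}, {})


def test_point_pair_jaccard_limits():
    assert em.point_pair_jaccard((10, 10), (10, 10), 6.0) == 1.0
    assert em.point_pair_jaccard((0, 0), (100, 0), 6.0) == 0.0
    mid = em.point_pair_jaccard((10, 10), (14, 10), 6.0)
    assert 0.0 < mid < 1.0


def test_five_number_summary_of_singleton():
    summary = em.five_number_summary([0.5])
    assert set(summary.values()) == {0.5}
    with pytest.raises(EmptyList):
        em.five_number_summary([])


class TestSummarize:
    @staticmethod
    def _records(perfect=True):
        rows = []
        for image, sex in (("a", "male"), ("b", "female")):
            for side in ("left", "right"):
                for sid in range(1, 10):
                    x, y = 50.0 * sid, 40.0
                    ex = x if perfect else x + 50.0
                    rows.append(dict(image=image, side=side, site_id=sid,
                                     true_x=x, true_y=y, est_x=ex, est_y=y, sex=sex))
        return pd.DataFrame(rows)

    def test_perfect_estimates_score_one_in_every_stratum(self):
        report = em.summarize(self._records())
        assert set(report.acc_tsl) == {"overall", "left", "right", "male", "female"}
        for per_site in report.acc_tsl.values():
            assert all(v == 1.0 for v in per_site.values())
        for summary in report.jsc_summary.values():
            assert summary["median"] == 1.0

    def test_matches_independent_recomputation(self, rng):
        records = self._records()
        jitter = rng.normal(0, 12, size=len(records))
        records["est_x"] = records["true_x"] + jitter
        records.loc[records.sample(6, random_state=1).index, ["est_x", "est_y"]] = np.nan
        cfg = EvaluationConfig()
        report = em.summarize(records, evaluation=cfg)
        for sid, grp in records.groupby("site_id"):
            r = cfg.radius_px_fallback(int(sid))
            d = np.hypot(grp.est_x - grp.true_x, grp.est_y - grp.true_y)
            expected = float(((d < r) & d.notna()).mean())
            assert report.acc_tsl["overall"][int(sid)] == pytest.approx(expected)

    def test_empty_records_raise(self):
        with pytest.raises(NoPairs):
            em.summarize(self._records().iloc[:0])
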