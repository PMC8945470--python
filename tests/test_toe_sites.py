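"""Contour profile, offset intensity track and toe-site placement."""

import numpy as np
import pytest

from plantarsites import FootGeometryParams, generate_foot
from plantarsites.config import ToesConfig
from plantarsites.errors import NoPeakFound
from plantarsites.foot_normalization import NormalizedFoot, TransformChain
from plantarsites import toe_sites as ts


def _normalized(inst):
    """Wrap a generated foot canvas as an already-normalized foot."""
    scene = np.zeros(inst.mask.shape + (3,), dtype=np.uint8)
    shade = np.clip(inst.valley[inst.mask, None] * np.array([205, 160, 135]), 0, 255)
    scene[inst.mask] = shade.astype(np.uint8)
    side_len = inst.mask.shape[0]
    return NormalizedFoot(
        image=scene, mask=inst.mask, side=inst.params.side, angle=0.0,
        chain=TransformChain(steps=[], scene_shape=(side_len, side_len)),
        crop_box=(0, 0, side_len, side_len),
    )


def _profile(y_top, foot_length):
    y = np.asarray(y_top, dtype=float)
    valid = ~np.isnan(y)
    cols = np.flatnonzero(valid)
    return ts.ContourProfile(
        y_top=y, valid=valid, foot_length=foot_length,
        col_range=(int(cols[0]), int(cols[-1]) + 1),
    )


class TestUpperContourProfile:
    def test_rectangle_gives_constant_profile(self):
        mask = np.zeros((40, 30), dtype=bool)
        mask[10:35, 5:25] = True
        foot = NormalizedFoot(
            image=np.zeros((40, 30, 3), np.uint8), mask=mask, side="left",
            angle=0.0, chain=TransformChain(), crop_box=(0, 0, 30, 40),
        )
        profile = ts.upper_contour_profile(foot)
        assert np.all(profile.y_top[5:25] == 10)
        assert not profile.valid[:5].any() and not profile.valid[25:].any()
        assert profile.col_range == (5, 25) and profile.foot_width == 20

    def test_profile_minima_sit_at_generated_toe_tips(self):
        """The prominent contour minima must land within 3 px of the
        generator's toe-site columns (hallux, third and fifth toes)."""
        inst = generate_foot(FootGeometryParams(side="left"), mm_per_px=0.76)
        profile = ts.upper_contour_profile(_normalized(inst))
        peaks = ts.contour_peaks(profile, ToesConfig())
        for sid in (1, 2, 3):
            x_true = inst.sites[sid][0]
            assert np.abs(peaks - x_true).min() <= 3


class TestLocateHallux:
    def test_first_medial_peak_wins_over_more_prominent_neighbor(self):
        """A second toe more prominent than the hallux must not steal site
        1: the scan takes the first peak from the medial edge."""
        cols = np.arange(100, dtype=float)
        y = np.full(100, 50.0)
        y -= 30 * np.exp(-((cols - 20) ** 2) / 18.0)  # hallux, shallower
        y -= 45 * np.exp(-((cols - 45) ** 2) / 18.0)  # second toe, deeper
        profile = _profile(y, foot_length=200)
        site = ts.locate_hallux(profile, "left")
        assert abs(site.x - 20) <= 2
        assert site.y == pytest.approx(profile.y_top[site.x] + 0.10 * 200, abs=1)
        assert site.evidence == frozenset({"contour"})

    def test_right_foot_scans_from_the_right(self):
        cols = np.arange(100, dtype=float)
        y = np.full(100, 50.0)
        y -= 30 * np.exp(-((cols - 80) ** 2) / 18.0)  # hallux near right edge
        y -= 45 * np.exp(-((cols - 55) ** 2) / 18.0)
        site = ts.locate_hallux(_profile(y, 200), "right")
        assert abs(site.x - 80) <= 2

    def test_monotonic_profile_has_no_peak(self):
        y = np.linspace(10, 60, 80)
        with pytest.raises(NoPeakFound):
            ts.locate_hallux(_profile(y, 200), "left")

    def test_generated_hallux_position_and_depth_rule(self):
        inst = generate_foot(FootGeometryParams(side="left"), mm_per_px=0.76)
        profile = ts.upper_contour_profile(_normalized(inst))
        site = ts.locate_hallux(profile, "left")
        tx, ty = inst.sites[1]
        assert abs(site.x - tx) <= 3 and abs(site.y - ty) <= 3

    def test_mirror_equivariance(self):
        """Left and right feet with identical anatomy give mirrored hallux
        estimates."""
        left = generate_foot(FootGeometryParams(side="left"), mm_per_px=0.76)
        right = generate_foot(FootGeometryParams(side="right"), mm_per_px=0.76)
        p_l = ts.upper_contour_profile(_normalized(left))
        p_r = ts.upper_contour_profile(_normalized(right))
        s_l = ts.locate_hallux(p_l, "left")
        s_r = ts.locate_hallux(p_r, "right")
        width = left.mask.shape[1]
        assert abs((width - 1 - s_l.x) - s_r.x) <= 2
        assert abs(s_l.y - s_r.y) <= 2


class TestToeTrack:
    def test_five_toes_give_five_bright_spans_at_toe_centers(self):
        inst = generate_foot(FootGeometryParams(side="left"), mm_per_px=0.76)
        profile = ts.upper_contour_profile(_normalized(inst))
        track = ts.analyze_toe_track(_normalized(inst), profile, ToesConfig())
        w_f = profile.foot_width
        spans = [s for s in track.bright_spans() if s.width > 0.04 * w_f]
        assert len(spans) == 5
        assert max(spans, key=lambda s: s.width) is spans[0]  # hallux widest
        # each generated toe tip column falls inside its own bright span
        toe_x = sorted(x for x, _ in inst.toe_tips)
        for span, tip in zip(spans, toe_x):
            assert span.start <= tip < span.stop

    def test_uniform_track_is_low_confidence_single_span(self):
        mask = np.zeros((60, 50), dtype=bool)
        mask[20:55, 5:45] = True
        image = np.full((60, 50, 3), 180, dtype=np.uint8)
        foot = NormalizedFoot(image=image, mask=mask, side="left", angle=0.0,
                              chain=TransformChain(), crop_box=(0, 0, 50, 60))
        track = ts.analyze_toe_track(foot, ts.upper_contour_profile(foot))
        assert track.low_confidence
        assert len(track.bright_spans()) == 1

    def test_fully_merged_toes_collapse_spans(self):
        inst = generate_foot(
            FootGeometryParams(side="left", toe_overlap=1.0), mm_per_px=0.76
        )
        profile = ts.upper_contour_profile(_normalized(inst))
        track = ts.analyze_toe_track(_normalized(inst), profile, ToesConfig())
        w_f = profile.foot_width
        spans = [s for s in track.bright_spans() if s.width > 0.04 * w_f]
        assert len(spans) <= 4

    def test_spans_partition_and_alternate(self):
        inst = generate_foot(FootGeometryParams(side="right"), mm_per_px=0.76)
        profile = ts.upper_contour_profile(_normalized(inst))
        track = ts.analyze_toe_track(_normalized(inst), profile)
        c0, c1 = profile.col_range
        assert track.spans[0].start == c0 and track.spans[-1].stop == c1
        for prev, cur in zip(track.spans, track.spans[1:]):
            assert prev.stop == cur.start and prev.bright != cur.bright


class TestPlaceSmallToeSites:
    @staticmethod
    def _track_from_spans(widths, w=100, bright_first=True):
        spans = []
        x = 0
        bright = bright_first
        for width in widths:
            spans.append(ts.Span(start=x, stop=x + width, bright=bright))
            x += width
            bright = not bright
        return ts.Span, spans

    def test_direct_rule_application(self):
        """Spans of widths 0.40/0.15/0.15/0.12/0.10 of the foot width emit
        site 2 from the second small span and site 3 from the fourth (0.10
        is within the 0.15 +- 0.10 proportion band)."""
        widths = [40, 2, 15, 2, 15, 2, 12, 2, 10]
        _, spans = self._track_from_spans(widths)
        y = np.full(100, 30.0)
        profile = _profile(y, foot_length=200)
        track = ts.ToeTrack(
            columns=np.arange(100), intensity=np.zeros(100), threshold=100.0,
            spans=spans, peaks=np.array([], dtype=int), low_confidence=False,
        )
        sites = ts.place_small_toe_sites(track, profile, "left")
        assert {s.site_id for s in sites} == {2, 3}
        site2 = next(s for s in sites if s.site_id == 2)
        assert site2.x == spans[4].center
        assert site2.y == pytest.approx(30 + 0.05 * 200, abs=1)
        for s in sites:
            assert "color" in s.evidence and "proportion" in s.evidence

    def test_no_hallux_like_span_emits_nothing(self):
        widths = [20, 2, 15, 2, 15, 2, 12, 2, 10]  # widest span far from 40%
        _, spans = self._track_from_spans(widths)
        track = ts.ToeTrack(
            columns=np.arange(100), intensity=np.zeros(100), threshold=100.0,
            spans=spans, peaks=np.array([], dtype=int), low_confidence=False,
        )
        assert ts.place_small_toe_sites(track, _profile(np.full(100, 30.0), 200), "left") == []

    def test_incomplete_small_toe_pattern_abstains(self):
        # three small spans only: a merged pair cannot be disambiguated
        widths = [40, 2, 17, 2, 12, 2, 10]
        _, spans = self._track_from_spans(widths)
        track = ts.ToeTrack(
            columns=np.arange(100), intensity=np.zeros(100), threshold=100.0,
            spans=spans, peaks=np.array([], dtype=int), low_confidence=False,
        )
        assert ts.place_small_toe_sites(track, _profile(np.full(100, 30.0), 200), "left") == []

    def test_emitted_sites_always_carry_evidence_and_proportion(self, benign_results):
        for _, result in benign_results:
            for site in result.sites:
                if site.site_id in (2, 3):
                    assert site.evidence & {"color", "contour"}
                    assert "proportion" in site.evidence
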