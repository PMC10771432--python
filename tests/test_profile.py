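"""Signed distances, ROI, area-adjusted binning, profile smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cordflow.datatypes import InjuryGeometry
from cordflow.profile import (
    area_adjusted_index,
    bin_profile,
    roi_mask,
    signed_distance_map,
    smooth_profile,
)
from tests.conftest import profile_from_values


def make_geometry(line, upper=10.0, lower=50.0, w=60, pixel_size=0.05, rostral_left=True):
    return InjuryGeometry(
        injury_line=np.asarray(line, dtype=float),
        upper_border=np.array([[0.0, upper], [w - 1.0, upper]]),
        lower_border=np.array([[0.0, lower], [w - 1.0, lower]]),
        pixel_size=pixel_size,
        rostral_left=rostral_left,
    )


def point_to_segment(p, a, b):
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
    return np.linalg.norm(p - (a + t * ab))


class TestSignedDistanceMap:
    def test_axis_aligned_case(self):
        geom = make_geometry([[20, 0], [20, 59]], pixel_size=0.05, w=60)
        d = signed_distance_map(geom, (60, 60))
        assert d[30, 30] == pytest.approx(+0.5)  # 10 columns right of the line
        assert d[30, 10] == pytest.approx(-0.5)

    def test_pixel_on_the_line_is_zero(self):
        geom = make_geometry([[20, 0], [20, 59]])
        d = signed_distance_map(geom, (60, 60))
        assert np.all(d[:, 20] == 0.0)

    def test_matches_brute_force_point_to_segment(self, rng):
        a, b = np.array([25.0, 5.0]), np.array([33.0, 55.0])  # slanted line
        geom = make_geometry([a, b])
        d = signed_distance_map(geom, (60, 60))
        for _ in range(100):
            i, j = rng.integers(0, 60, 2)
            p = np.array([j, i], dtype=float)
            assert abs(d[i, j]) == pytest.approx(
                point_to_segment(p, a, b) * geom.pixel_size, abs=1e-9
            )

    def test_rostral_flag_flips_sign(self):
        geom = make_geometry([[20, 0], [20, 59]])
        d1 = signed_distance_map(geom, (60, 60))
        d2 = signed_distance_map(geom.flipped(), (60, 60))
        assert np.allclose(d1, -d2)

    def test_translation_invariance(self):
        geom1 = make_geometry([[20, 10], [20, 50]])
        geom2 = make_geometry([[25, 10], [25, 50]])
        d1 = signed_distance_map(geom1, (60, 70))
        d2 = signed_distance_map(geom2, (60, 70))
        # joint translation of line and pixels leaves distances unchanged
        assert np.allclose(d1[:, :-5], d2[:, 5:])

    def test_rejects_degenerate_line(self):
        with pytest.raises(ValueError):
            make_geometry([[20, 30], [20, 30]])


class TestRoiMask:
    def test_horizontal_borders_strictly_between(self):
        geom = make_geometry([[20, 0], [20, 59]], upper=10, lower=50)
        m = roi_mask(geom, (60, 60))
        rows = np.nonzero(m.any(axis=1))[0]
        assert rows.min() == 11 and rows.max() == 49

    def test_touching_borders_give_zero_width_roi(self):
        geom = InjuryGeometry(
            injury_line=np.array([[20.0, 0.0], [20.0, 59.0]]),
            upper_border=np.array([[0.0, 30.0], [59.0, 10.0]]),
            lower_border=np.array([[0.0, 30.0], [59.0, 50.0]]),
            pixel_size=0.05,
        )
        m = roi_mask(geom, (60, 60))
        assert not m[:, 0].any()  # borders meet at column 0
        assert m[:, 59].any()

    def test_matches_per_column_scanline_oracle(self, rng):
        xs = np.array([0.0, 20.0, 40.0, 59.0])
        up = np.column_stack([xs, rng.uniform(5, 20, 4)])
        lo = np.column_stack([xs, rng.uniform(35, 55, 4)])
        geom = InjuryGeometry(
            injury_line=np.array([[20.0, 0.0], [20.0, 59.0]]),
            upper_border=up,
            lower_border=lo,
            pixel_size=0.05,
        )
        m = roi_mask(geom, (60, 60))
        for c in range(60):
            yu = np.interp(c, up[:, 0], up[:, 1])
            yl = np.interp(c, lo[:, 0], lo[:, 1])
            want = (np.arange(60) > yu) & (np.arange(60) < yl)
            assert np.array_equal(m[:, c], want)


class TestAreaAdjustedIndex:
    def test_all_zero_bin(self):
        assert area_adjusted_index(np.array([0.0, 0, 0, 0])) == 0.0

    def test_quarter_colored_bin(self):
        # v = 4, colored fraction = 1/4, I = 1
        assert area_adjusted_index(np.array([4.0, 0, 0, 0])) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 1000), n=st.integers(1, 200))
    def test_threshold_zero_equals_mean_including_zeros(self, seed, n):
        r = np.random.default_rng(seed)
        v = r.random(n) * (r.random(n) > 0.3)  # mix of zeros and positives
        assert area_adjusted_index(v) == pytest.approx(v.mean(), abs=1e-12)

    def test_empty_bin_is_an_error(self):
        with pytest.raises(ValueError):
            area_adjusted_index(np.array([]))


class TestBinProfile:
    def test_uniform_flow_gives_constant_profile(self):
        dist = np.linspace(-2, 2, 80)[None, :].repeat(40, axis=0)
        flow = np.full((40, 80), 0.4)
        mask = np.ones((40, 80), bool)
        prof = bin_profile(flow, dist, mask)
        ok = np.isfinite(prof.index_values)
        assert np.allclose(prof.index_values[ok], 0.4)

    def test_conservation_of_total_flow(self, rng):
        dist = rng.uniform(-3, 3, (30, 50))
        flow = rng.random((30, 50))
        mask = rng.random((30, 50)) > 0.4
        prof = bin_profile(flow, dist, mask)
        vals = np.where(np.isfinite(prof.index_values), prof.index_values, 0.0)
        total = float((vals * prof.bin_pixel_counts).sum())
        assert total == pytest.approx(float(flow[mask].sum()), abs=1e-9)

    def test_bin_edges_anchored_at_zero(self, rng):
        dist = rng.uniform(-1, 1, (20, 20))
        prof = bin_profile(rng.random((20, 20)), dist, np.ones((20, 20), bool))
        # every center is an odd multiple of half the bin width
        frac = prof.bin_centers / prof.bin_width - 0.5
        assert np.allclose(frac, np.round(frac))

    def test_shifting_injury_line_shifts_bins_by_one(self, rng):
        # with pixel_size == bin_width, a one-column line shift moves every
        # pixel's bin assignment by exactly one bin
        flow = rng.random((40, 60))
        mask = np.ones((40, 60), bool)
        # half-pixel line offset keeps every distance mid-bin (numerically robust)
        g1 = make_geometry([[30.5, 0], [30.5, 39]], upper=-1, lower=40, w=60, pixel_size=0.1)
        g2 = make_geometry([[31.5, 0], [31.5, 39]], upper=-1, lower=40, w=60, pixel_size=0.1)
        p1 = bin_profile(flow, signed_distance_map(g1, (40, 60)), mask)
        p2 = bin_profile(flow, signed_distance_map(g2, (40, 60)), mask)
        v1 = p1.index_values
        v2 = p2.index_values
        # p2's grid is one bin longer on the rostral side, shorter caudally
        assert np.allclose(p1.bin_centers - 0.1, p2.bin_centers[: v1.size])
        assert np.allclose(v1, v2[: v1.size], equal_nan=True)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            bin_profile(np.zeros((5, 5)), np.zeros((5, 5)), np.zeros((5, 5), bool))


class TestSmoothProfile:
    def test_constant_profile_unchanged(self):
        centers = np.arange(-20, 21) * 0.1
        prof = profile_from_values(centers, np.full(41, 0.3))
        assert np.allclose(smooth_profile(prof).index_values, 0.3)

    def test_impulse_becomes_eleven_bin_plateau(self):
        centers = np.arange(-20, 21) * 0.1
        v = np.zeros(41)
        v[20] = 1.0
        sm = smooth_profile(profile_from_values(centers, v), window=1.0)
        # 1 mm / 0.1 mm = 10 bins, rounded to the nearest odd count = 11
        covered = slice(15, 26)
        assert np.allclose(sm.index_values[covered], 1 / 11)
        assert np.allclose(sm.index_values[:15], 0)
        assert np.allclose(sm.index_values[26:], 0)

    def test_matches_naive_loop_with_missing_bins(self, rng):
        centers = np.arange(-30, 31) * 0.1
        v = rng.random(61)
        v[rng.random(61) < 0.2] = np.nan
        sm = smooth_profile(profile_from_values(centers, v), window=1.0)
        for i in range(61):
            lo, hi = max(i - 5, 0), min(i + 6, 61)
            w = v[lo:hi]
            w = w[np.isfinite(w)]
            if w.size:
                assert sm.index_values[i] == pytest.approx(w.mean(), abs=1e-12)
            else:
                assert np.isnan(sm.index_values[i])

    def test_support_extends_at_most_half_a_window(self):
        centers = np.arange(-20, 21) * 0.1
        v = np.full(41, np.nan)
        v[18:23] = 1.0
        sm = smooth_profile(profile_from_values(centers, v), window=1.0)
        filled = np.nonzero(np.isfinite(sm.index_values))[0]
        assert filled.min() >= 18 - 5 and filled.max() <= 22 + 5
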