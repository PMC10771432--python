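"""Peak detection, umbra localization, extent, distal means, pre-injury."""

import numpy as np
import pytest

from cordflow.datatypes import ZoneLabels
from cordflow.zones import (
    distal_flows,
    find_penumbra_peaks,
    injury_extent,
    label_zones,
    locate_umbra,
    pre_injury_parameters,
)
from tests.conftest import profile_from_values


def double_bump(centers, peak_height=0.3, baseline=0.1, sigma=0.25, sep=1.0):
    v = np.full(centers.size, baseline)
    for sign in (-1, 1):
        v = v + peak_height * np.exp(-0.5 * ((centers - sign * sep) / sigma) ** 2)
    return v


def exhaustive_prominences(v):
    """Textbook topographic prominence of every strict local maximum."""
    peaks, proms = [], []
    for i in range(1, v.size - 1):
        if v[i] > v[i - 1] and v[i] > v[i + 1]:
            left = v[:i][::-1]
            stop = np.nonzero(left > v[i])[0]
            lmin = left[: stop[0]].min() if stop.size else left.min()
            right = v[i + 1 :]
            stop = np.nonzero(right > v[i])[0]
            rmin = right[: stop[0]].min() if stop.size else right.min()
            peaks.append(i)
            proms.append(v[i] - max(lmin, rmin))
    return np.array(peaks), np.array(proms)


class TestFindPenumbraPeaks:
    def test_symmetric_double_bump_located(self):
        centers = np.arange(-30, 31) * 0.1
        prof = profile_from_values(centers, double_bump(centers))
        res = find_penumbra_peaks(prof, min_prominence=0.2)
        assert res["rostral"][0] == pytest.approx(-1.0)
        assert res["caudal"][0] == pytest.approx(1.0)

    def test_flat_profile_has_no_peaks(self):
        centers = np.arange(-20, 21) * 0.1
        prof = profile_from_values(centers, np.full(41, 0.2))
        res = find_penumbra_peaks(prof)
        assert res["rostral"] is None and res["caudal"] is None
        labels = label_zones(prof)
        assert not labels.labeling_ok

    def test_closest_of_several_peaks_chosen_per_side(self):
        centers = np.arange(-40, 41) * 0.1
        v = np.full(centers.size, 0.1)
        for loc in (-3.0, -2.0, -1.0, 1.2, 2.2, 3.2):
            v = v + 0.3 * np.exp(-0.5 * ((centers - loc) / 0.15) ** 2)
        prof = profile_from_values(centers, v)
        res = find_penumbra_peaks(prof, min_prominence=0.1)
        assert res["rostral"][0] == pytest.approx(-1.0)
        assert res["caudal"][0] == pytest.approx(1.2)

    def test_agrees_with_exhaustive_prominence_computation(self, rng):
        from scipy.signal import find_peaks

        for _ in range(20):
            n = int(rng.integers(30, 500))
            v = np.cumsum(rng.normal(0, 1, n))  # continuous: no ties
            pk, props = find_peaks(v, prominence=(None, None))
            opk, oproms = exhaustive_prominences(v)
            assert np.array_equal(pk, opk)
            assert np.allclose(props["prominences"], oproms, atol=1e-12)

    def test_interior_missing_bins_interpolated(self):
        centers = np.arange(-30, 31) * 0.1
        v = double_bump(centers)
        v[12] = np.nan
        prof = profile_from_values(centers, v)
        res = find_penumbra_peaks(prof, min_prominence=0.2)
        assert res["rostral"] is not None and res["caudal"] is not None


class TestLocateUmbra:
    def test_unique_minimum_found_off_center(self):
        centers = np.arange(-30, 31) * 0.1
        v = double_bump(centers) + 0.2 * (centers + 0.2) ** 2  # min near -0.2
        prof = profile_from_values(centers, v)
        loc, flow, _ = locate_umbra(prof, -1.0, 1.0)
        assert loc == pytest.approx(-0.2, abs=0.051)

    def test_consecutive_plateau_resolves_to_center(self):
        centers = np.arange(-10, 11) * 0.1
        v = 1.2 - np.exp(-0.5 * (centers / 0.5) ** 2)
        plateau = (centers >= -0.05) & (centers <= 0.45)  # bins 0.0 .. 0.4
        v[plateau] = v[plateau].min() - 0.1
        prof = profile_from_values(centers, v)
        loc, _, _ = locate_umbra(prof, -0.8, 0.8)
        assert loc == pytest.approx(0.2, abs=1e-12)

    def test_separate_ties_broken_toward_zero(self):
        centers = np.arange(-10, 11) * 0.1
        v = np.full(21, 0.5)
        v[np.argmin(np.abs(centers + 0.6))] = 0.1
        v[np.argmin(np.abs(centers - 0.2))] = 0.1
        prof = profile_from_values(centers, v)
        loc, _, notes = locate_umbra(prof, -0.9, 0.9)
        assert loc == pytest.approx(0.2)
        assert any("toward 0" in n for n in notes)

    def test_monotone_segment_flags_edge_minimum(self):
        centers = np.arange(-10, 11) * 0.1
        v = 0.1 + 0.05 * (centers + 1.0)
        prof = profile_from_values(centers, v)
        loc, _, notes = locate_umbra(prof, -0.9, 0.9)
        assert loc == pytest.approx(-0.8)
        assert any("edge" in n for n in notes)


def labels_for_extent(umbra_loc, umbra_flow, ro_loc, ro_flow, ca_loc, ca_flow):
    return ZoneLabels(
        umbra_location=umbra_loc,
        umbra_flow=umbra_flow,
        rostral_penumbra_location=ro_loc,
        rostral_penumbra_flow=ro_flow,
        caudal_penumbra_location=ca_loc,
        caudal_penumbra_flow=ca_flow,
        labeling_ok=True,
    )


class TestInjuryExtent:
    def test_triangular_dip_half_maximum_geometry(self):
        centers = np.arange(-20, 21) * 0.1
        v = np.clip(np.abs(centers), 0, 1)
        prof = profile_from_values(centers, v)
        labels = labels_for_extent(0.0, 0.0, -1.0, 1.0, 1.0, 1.0)
        assert injury_extent(prof, labels) == pytest.approx(1.0, abs=1e-9)

    def test_asymmetric_flanks_closed_form(self):
        centers = np.arange(-20, 21) * 0.1
        v = np.where(centers < 0, np.clip(2 * np.abs(centers), 0, 1), np.clip(np.abs(centers), 0, 1))
        prof = profile_from_values(centers, v)
        labels = labels_for_extent(0.0, 0.0, -0.5, 1.0, 1.0, 1.0)
        # thresholds 0.5: crossings at -0.25 and +0.5
        assert injury_extent(prof, labels) == pytest.approx(0.75, abs=1e-9)

    def test_gaussian_dip_matches_closed_form_fwhm(self):
        sigma = 0.4
        centers = np.arange(-40, 41) * 0.1
        v = 1.0 - np.exp(-0.5 * (centers / sigma) ** 2)
        prof = profile_from_values(centers, v)
        labels = labels_for_extent(0.0, 0.0, -3.0, 1.0, 3.0, 1.0)
        fwhm = 2 * sigma * np.sqrt(2 * np.log(2))
        assert injury_extent(prof, labels) == pytest.approx(fwhm, abs=0.1)

    def test_flat_profile_has_no_crossing(self):
        centers = np.arange(-10, 11) * 0.1
        prof = profile_from_values(centers, np.full(21, 0.5))
        labels = labels_for_extent(0.0, 0.5, -0.8, 0.5, 0.8, 0.5)
        assert np.isnan(injury_extent(prof, labels))


class TestDistalFlows:
    def test_flat_baseline_recovered_on_both_sides(self):
        centers = np.arange(-30, 31) * 0.1
        v = double_bump(centers, baseline=0.5)
        prof = profile_from_values(centers, v)
        labels = labels_for_extent(0.0, 0.1, -1.0, 0.8, 1.0, 0.8)
        ro, ca = distal_flows(prof, labels)
        # Gaussian tails decay: distal means sit near the 0.5 baseline
        assert ro == pytest.approx(np.mean(v[centers < -1.0]), abs=1e-12)
        assert ca == pytest.approx(np.mean(v[centers > 1.0]), abs=1e-12)

    def test_linear_trend_gives_analytic_mean(self):
        centers = np.arange(-30, 31) * 0.1
        v = 0.5 + 0.05 * centers + 3.0  # positive linear trend
        prof = profile_from_values(centers, v)
        labels = labels_for_extent(0.0, 0.1, -1.0, 0.8, 1.0, 0.8)
        ro, ca = distal_flows(prof, labels)
        ro_centers = centers[centers < -1.0]
        assert ro == pytest.approx(3.5 + 0.05 * ro_centers.mean(), abs=1e-12)

    def test_penumbra_at_edge_yields_missing_not_zero(self):
        centers = np.arange(-10, 11) * 0.1
        prof = profile_from_values(centers, np.full(21, 0.4))
        labels = labels_for_extent(0.0, 0.1, -1.0, 0.8, 0.8, 0.8)
        ro, ca = distal_flows(prof, labels)
        assert np.isnan(ro)  # no bins rostral of -1.0
        assert ca == pytest.approx(0.4)


class TestLabelZones:
    def test_prominence_invariant_to_constant_offset(self):
        centers = np.arange(-30, 31) * 0.1
        v = double_bump(centers)
        a = label_zones(profile_from_values(centers, v), min_prominence=0.1)
        b = label_zones(profile_from_values(centers, v + 0.5), min_prominence=0.1)
        assert b.rostral_prominence == pytest.approx(a.rostral_prominence, abs=1e-12)
        assert b.caudal_prominence == pytest.approx(a.caudal_prominence, abs=1e-12)

    def test_extent_invariant_to_positive_scaling(self):
        centers = np.arange(-30, 31) * 0.1
        v = double_bump(centers)
        a = label_zones(profile_from_values(centers, v), min_prominence=0.05)
        b = label_zones(profile_from_values(centers, 3.0 * v), min_prominence=0.05)
        assert b.injury_extent == pytest.approx(a.injury_extent, abs=1e-9)

    def test_requires_bins_on_both_sides(self):
        centers = np.arange(1, 30) * 0.1
        with pytest.raises(ValueError):
            label_zones(profile_from_values(centers, np.full(29, 0.2)))


class TestPreInjuryParameters:
    def test_identical_profiles_give_identical_parameters(self):
        centers = np.arange(-30, 31) * 0.1
        v = double_bump(centers)
        prof = profile_from_values(centers, v)
        post = label_zones(prof, min_prominence=0.1)
        pre = pre_injury_parameters(prof, post)
        assert pre.umbra_flow == pytest.approx(post.umbra_flow)
        assert pre.rostral_penumbra_flow == pytest.approx(post.rostral_penumbra_flow)
        assert pre.rostral_prominence == pytest.approx(post.rostral_prominence)

    def test_flat_pre_injury_profile_gives_constant_flows(self):
        centers = np.arange(-30, 31) * 0.1
        post = label_zones(profile_from_values(centers, double_bump(centers)), min_prominence=0.1)
        flat = profile_from_values(centers, np.full(61, 0.42))
        pre = pre_injury_parameters(flat, post)
        assert pre.umbra_flow == pytest.approx(0.42)
        assert pre.caudal_penumbra_flow == pytest.approx(0.42)
        assert pre.rostral_prominence == pytest.approx(0.0)
        assert np.isnan(pre.injury_extent)

    def test_values_match_manual_bin_lookup(self, rng):
        centers = np.arange(-30, 31) * 0.1
        post_v = double_bump(centers)
        pre_v = rng.random(61) + 0.1
        post = label_zones(profile_from_values(centers, post_v), min_prominence=0.1)
        pre = pre_injury_parameters(profile_from_values(centers, pre_v), post)
        i_um = int(np.argmin(np.abs(centers - post.umbra_location)))
        assert pre.umbra_flow == pytest.approx(pre_v[i_um])
        i_ca = int(np.argmin(np.abs(centers - post.caudal_penumbra_location)))
        assert pre.caudal_penumbra_flow == pytest.approx(pre_v[i_ca])
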