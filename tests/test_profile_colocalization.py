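"""Line profiles, signal peaks and the peak-overlap positivity rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_stack8
from oracles import classify_oracle
from vesicoloc.errors import ContractError, GeometryError
from vesicoloc.profile_colocalization import (
    ColocalizationCall,
    ProfileConfig,
    classify_marker_positive,
    extract_line_profile,
    find_signal_peaks,
    percent_marker_positive,
    principal_axis_direction,
    quantify_profile_intensity,
)


def random_profiles(rng, n, length=40):
    """Random 8-bit-valued profile pairs with spectrum around the cutoff."""
    for _ in range(n):
        v = np.zeros(length)
        m = np.zeros(length)
        for arr in (v, m):
            n_bumps = rng.integers(0, 4)
            for _ in range(n_bumps):
                c = rng.integers(0, length)
                wdt = rng.integers(1, 8)
                amp = rng.uniform(40, 255)
                ks = np.arange(length)
                arr += amp * np.exp(-((ks - c) ** 2) / (2 * (wdt / 2) ** 2))
        yield np.clip(np.round(v), 0, 255), np.clip(np.round(m), 0, 255)


class TestExtractLineProfile:
    def test_constant_image_gives_constant_samples(self):
        stack = make_stack8({"a": np.full((64, 64), 7)})
        prof = extract_line_profile(stack, (30, 30), (0.6, 0.8), 40)
        assert len(prof.samples["a"]) == 40
        np.testing.assert_allclose(prof.samples["a"], 7.0)

    def test_bilinear_interpolation_across_a_stripe(self):
        """Hand-computed bilinear values for a 1-px vertical stripe of 200."""
        img = np.zeros((12, 12), dtype=np.uint8)
        img[:, 5] = 200
        stack = make_stack8({"a": img})
        # anchor x=5.25: samples at x = 3.75, 4.75, 5.75, 6.75
        prof = extract_line_profile(stack, (5.25, 6.0), (1.0, 0.0), 4)
        np.testing.assert_allclose(prof.samples["a"], [0.0, 150.0, 50.0, 0.0])
        above = prof.samples["a"] > 100
        assert above.tolist() == [False, True, False, False]

    def test_direction_reversal_reverses_samples(self):
        rng = np.random.default_rng(3)
        stack = make_stack8({"a": rng.integers(0, 255, (64, 64))})
        fwd = extract_line_profile(stack, (31.5, 30.2), (0.8, 0.6), 21)
        rev = extract_line_profile(stack, (31.5, 30.2), (-0.8, -0.6), 21)
        np.testing.assert_allclose(fwd.samples["a"], rev.samples["a"][::-1],
                                   atol=1e-9)

    def test_edge_clipped_samples_are_missing(self):
        stack = make_stack8({"a": np.full((32, 32), 200)})
        prof = extract_line_profile(stack, (2.0, 16.0), (1.0, 0.0), 40)
        samples = prof.samples["a"]
        assert np.isnan(samples[0])  # extends past the left edge
        assert np.isfinite(samples[-1])
        # clipped samples never join a peak
        peaks = find_signal_peaks(samples, cutoff=100)
        assert all(p.start_idx >= np.argmax(np.isfinite(samples)) for p in peaks)

    def test_anchor_outside_image_rejected(self):
        stack = make_stack8({"a": np.zeros((16, 16))})
        with pytest.raises(GeometryError):
            extract_line_profile(stack, (40.0, 4.0), (1.0, 0.0), 10)

    def test_principal_axis_follows_elongated_structure(self):
        img = np.zeros((64, 64))
        img[30:33, 10:54] = 200.0  # horizontal bar
        dx, dy = principal_axis_direction(img, (32.0, 31.0))
        assert abs(dx) > 0.98 and abs(dy) < 0.2


class TestFindSignalPeaks:
    def test_all_zero_profile_has_no_peaks(self):
        assert find_signal_peaks(np.zeros(40), cutoff=100) == []

    def test_single_peak_area_and_max(self):
        samples = np.zeros(40)
        samples[18:21] = [120, 130, 120]
        (peak,) = find_signal_peaks(samples, cutoff=100)
        assert (peak.start_idx, peak.end_idx) == (18, 21)
        assert peak.area == 370
        assert peak.max_intensity == 130

    def test_run_at_exactly_cutoff_is_not_a_signal(self):
        samples = np.zeros(40)
        samples[10:15] = 100.0
        assert find_signal_peaks(samples, cutoff=100) == []

    def test_single_sample_runs_count(self):
        samples = np.zeros(40)
        samples[5] = 101.0
        (peak,) = find_signal_peaks(samples, cutoff=100)
        assert peak.length == 1 and peak.area == 101.0

    def test_area_satisfies_lower_bound(self, rng):
        for v, _ in random_profiles(rng, 20):
            for p in find_signal_peaks(v, cutoff=100):
                assert p.area >= p.length * 100


class TestClassifyMarkerPositive:
    CONFIG = ProfileConfig(length_px=40)

    def test_marker_nested_in_vesicle_is_fully_overlapping(self):
        v = np.zeros(40)
        m = np.zeros(40)
        v[15:25] = 200.0
        m[18:22] = 150.0
        call = classify_marker_positive(v, m, self.CONFIG)
        assert call.is_positive and call.overlap_share == 1.0

    def test_no_marker_signal_is_negative(self):
        v = np.zeros(40)
        v[15:25] = 200.0
        call = classify_marker_positive(v, np.full(40, 60.0), self.CONFIG)
        assert not call.is_positive and call.overlap_share == 0.0

    def test_no_vesicle_peak_is_negative(self):
        m = np.zeros(40)
        m[18:22] = 150.0
        call = classify_marker_positive(np.full(40, 50.0), m, self.CONFIG)
        assert not call.is_positive and call.overlap_share == 0.0

    def test_exact_half_overlap_is_negative(self):
        """'Greater than 50%' is strict: a share of exactly 0.5 fails."""
        v = np.zeros(40)
        m = np.zeros(40)
        v[16:22] = 200.0
        m[20:24] = 150.0  # area 600; overlap indices 20,21 -> 300
        call = classify_marker_positive(v, m, self.CONFIG)
        assert call.overlap_share == pytest.approx(0.5)
        assert not call.is_positive

    def test_positivity_flips_just_above_half(self):
        v = np.zeros(40)
        m = np.zeros(40)
        v[16:22] = 200.0
        m[20:24] = 150.0
        m[23] = 149.0  # marker area 599, overlap still 300 > 299.5
        call = classify_marker_positive(v, m, self.CONFIG)
        assert call.is_positive

    def test_mismatched_geometry_rejected(self):
        with pytest.raises(ContractError):
            classify_marker_positive(np.zeros(40), np.zeros(50), self.CONFIG)

    def test_agrees_with_brute_force_oracle_on_random_profiles(self, rng):
        for v, m in random_profiles(rng, 500):
            call = classify_marker_positive(v, m, self.CONFIG)
            want_pos, want_share = classify_oracle(v, m)
            assert call.is_positive == want_pos
            assert call.overlap_share == pytest.approx(want_share, abs=1e-12)

    def test_direction_reversal_invariance(self, rng):
        for v, m in random_profiles(rng, 100):
            fwd = classify_marker_positive(v, m, self.CONFIG)
            rev = classify_marker_positive(v[::-1].copy(), m[::-1].copy(),
                                           self.CONFIG)
            assert fwd.is_positive == rev.is_positive
            assert fwd.overlap_share == pytest.approx(rev.overlap_share)

    @settings(max_examples=200, deadline=None)
    @given(
        v=st.lists(st.sampled_from([0.0, 128.0, 200.0]), min_size=10, max_size=10),
        m=st.lists(st.sampled_from([0.0, 128.0, 200.0]), min_size=10, max_size=10),
    )
    def test_oracle_equivalence_on_three_level_profiles(self, v, m):
        call = classify_marker_positive(np.array(v), np.array(m),
                                        ProfileConfig(length_px=10))
        want_pos, want_share = classify_oracle(v, m)
        assert call.is_positive == want_pos
        assert call.overlap_share == pytest.approx(want_share, abs=1e-12)


class TestPercentMarkerPositive:
    def test_three_of_ten(self):
        calls = [ColocalizationCall(i, i < 3, 0.0) for i in range(10)]
        assert percent_marker_positive(calls) == 30.0

    def test_all_positive(self):
        calls = [ColocalizationCall(i, True, 1.0) for i in range(5)]
        assert percent_marker_positive(calls) == 100.0

    def test_empty_is_missing_not_zero(self):
        assert percent_marker_positive([]) is None


class TestQuantifyProfileIntensity:
    CONFIG = ProfileConfig(length_px=40)

    def test_flat_reporter_gives_zero(self):
        v = np.zeros(40)
        v[15:25] = 200.0
        assert quantify_profile_intensity(v, np.zeros(40), self.CONFIG) == (0.0, 0.0)

    def test_reporter_identical_to_vesicle_returns_vesicle_area(self):
        v = np.zeros(40)
        v[15:25] = 200.0
        area, peak_max = quantify_profile_intensity(v, v.copy(), self.CONFIG)
        assert area == 2000.0 and peak_max == 200.0

    def test_doubling_reporter_doubles_area(self):
        v = np.zeros(40)
        v[15:25] = 200.0
        r = np.zeros(40)
        r[17:20] = [110.0, 120.0, 110.0]
        area1, _ = quantify_profile_intensity(v, r, self.CONFIG)
        area2, _ = quantify_profile_intensity(v, 2 * r, self.CONFIG)
        assert area2 == 2 * area1
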