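"""IN/RD profile extraction and length normalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from profilecad.io import ChannelImage
from profilecad.profiles import (Profile1D, build_map, extract_in_profile,
                                 extract_rd_profiles, normalize_length)
from profilecad.synthetic import PhenotypeSpec, render_channels


class TestExtractIn:
    def test_constant_image_gives_constant_profile(self):
        img = ChannelImage(np.full((50, 50), 7.0))
        p = extract_in_profile(img, (10, 10), (40, 40))
        np.testing.assert_allclose(p.samples, 7.0)

    def test_horizontal_ramp_sampled_linearly(self):
        img = ChannelImage(np.tile(np.arange(50.0), (50, 1)))
        p = extract_in_profile(img, (25, 10), (25, 20), step_px=1.0)
        np.testing.assert_allclose(p.samples, np.arange(10.0, 21.0))

    def test_sample_count_formula(self):
        img = ChannelImage(np.zeros((50, 50)))
        p = extract_in_profile(img, (10, 10), (10, 25.7), step_px=1.0)
        assert p.samples.size == int(np.floor(15.7)) + 1

    def test_bilinear_sampling_exact_at_integer_pixels(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(0, 100, (30, 30))
        p = extract_in_profile(ChannelImage(arr), (5, 3), (5, 20), step_px=1.0)
        np.testing.assert_allclose(p.samples, arr[5, 3:21])

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(1)
        img = ChannelImage(rng.uniform(0, 50, (60, 60)))
        a = extract_in_profile(img, (10, 12), (45, 50))
        b = extract_in_profile(img, (45, 50), (10, 12))
        np.testing.assert_allclose(a.samples, b.samples[::-1], atol=1e-9)

    def test_out_of_bounds_endpoint_rejected(self):
        img = ChannelImage(np.zeros((50, 50)))
        with pytest.raises(ValueError, match="outside image"):
            extract_in_profile(img, (10, 10), (10, 60))

    def test_identical_points_rejected(self):
        img = ChannelImage(np.zeros((50, 50)))
        with pytest.raises(ValueError):
            extract_in_profile(img, (10, 10), (10, 10))

    def test_wt_pair_peak_at_membrane_crossing(self, scene49, wt_noiseless):
        from tests.conftest import membrane_crossing_fractions

        _, protein = wt_noiseless
        crossings = membrane_crossing_fractions(scene49)
        argmaxes = []
        for (i, j), m in zip(scene49.adjacency_pairs(), crossings):
            p = extract_in_profile(protein, scene49.cells[i].nucleus_center,
                                   scene49.cells[j].nucleus_center)
            norm = normalize_length(p)
            am = np.argmax(norm.samples) / 99
            assert abs(am - m) <= 2 / 99  # within 2 samples of the true crossing
            argmaxes.append(am)
        # for similar-size cells the membrane sits near the axis center
        assert 0.45 <= np.median(argmaxes) <= 0.55


class TestExtractRd:
    def test_ring_image_gives_identical_profiles_peaking_at_radius(self):
        rr, cc = np.mgrid[0:101, 0:101]
        dist = np.hypot(rr - 50, cc - 50)
        ring = ChannelImage(100 * np.exp(-((dist - 30) ** 2) / 2.0))
        profs = extract_rd_profiles(ring, (50, 50), n_angles=8, ray_length=45)
        assert len(profs) == 8
        for p in profs:
            assert np.argmax(p.samples) == 30
        stacked = np.vstack([p.samples for p in profs])
        assert np.abs(stacked - stacked[0]).max() < 0.08 * stacked.max()

    def test_ramp_symmetry_across_four_angles(self):
        ramp = ChannelImage(np.tile(np.arange(101.0), (101, 1)))
        profs = extract_rd_profiles(ramp, (50, 50), n_angles=4, ray_length=30)
        by_angle = {round(p.anchors["angle"], 2): p.samples for p in profs}
        assert by_angle[0.0][-1] > by_angle[0.0][0]  # +col: increasing
        assert by_angle[3.14][-1] < by_angle[3.14][0]  # -col: decreasing
        np.testing.assert_allclose(np.diff(by_angle[1.57]), 0, atol=1e-9)  # +row
        np.testing.assert_allclose(np.diff(by_angle[4.71]), 0, atol=1e-9)  # -row

    def test_clipped_rays_flagged_and_excluded(self):
        img = ChannelImage(np.zeros((60, 60)))
        with pytest.warns(UserWarning, match="excluded"):
            profs = extract_rd_profiles(img, (30, 5), n_angles=8, ray_length=20)
        assert 0 < len(profs) < 8

    def test_center_outside_image_rejected(self):
        img = ChannelImage(np.zeros((60, 60)))
        with pytest.raises(ValueError, match="outside"):
            extract_rd_profiles(img, (70, 30), n_angles=8, ray_length=10)


class TestNormalizeLength:
    def test_length_100_identity(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 10, 100)
        out = normalize_length(Profile1D(y, geometry="IN"))
        np.testing.assert_allclose(out.samples, y, atol=1e-12)

    def test_linear_ramp_preserved_with_endpoints(self):
        for n in (17, 250, 333):
            y = np.linspace(3.0, 47.0, n)
            out = normalize_length(Profile1D(y, geometry="IN"))
            assert out.samples.size == 100
            np.testing.assert_allclose(out.samples, np.linspace(3.0, 47.0, 100), atol=1e-9)

    def test_delta_peak_lands_at_expected_index(self):
        n, f = 333, 0.7
        y = np.zeros(n)
        y[int(round(f * (n - 1)))] = 100.0
        out = normalize_length(Profile1D(y, geometry="IN"))
        assert np.argmax(out.samples) == round(f * 99)

    def test_mean_preserved_on_smooth_profiles(self):
        x = np.linspace(0, 1, 73)
        y = 20 + 50 * np.exp(-((x - 0.4) ** 2) / 0.02)
        out = normalize_length(Profile1D(y, geometry="IN"))
        assert out.samples.mean() == pytest.approx(y.mean(), rel=0.01)

    @given(st.integers(min_value=2, max_value=400), st.integers(min_value=0, max_value=1000))
    def test_monotone_profiles_stay_monotone(self, n, seed):
        rng = np.random.default_rng(seed)
        y = np.cumsum(rng.uniform(0, 1, n))
        out = normalize_length(Profile1D(y, geometry="IN"))
        assert np.all(np.diff(out.samples) >= -1e-12)
        assert out.samples[0] == pytest.approx(y[0])
        assert out.samples[-1] == pytest.approx(y[-1])


class TestBuildMap:
    def test_single_profile_map(self):
        p = normalize_length(Profile1D(np.arange(50.0), geometry="IN"))
        m = build_map([p])
        assert m.values.shape == (100, 1)
        np.testing.assert_allclose(m.values[:, 0], p.samples)

    def test_identical_profiles_have_zero_row_variance(self):
        p = normalize_length(Profile1D(np.arange(50.0), geometry="IN"))
        m = build_map([p, p, p])
        np.testing.assert_allclose(m.values.var(axis=1), 0.0, atol=1e-20)

    def test_columns_in_input_order(self):
        ps = [normalize_length(Profile1D(np.full(10, float(v)), geometry="IN"))
              for v in (1, 2, 3)]
        m = build_map(ps)
        np.testing.assert_allclose(m.values.mean(axis=0), [1.0, 2.0, 3.0])

    def test_mixed_lengths_rejected(self):
        from profilecad.profiles import NormalizedProfile

        a = NormalizedProfile(np.zeros(100))
        b = NormalizedProfile(np.zeros(50))
        with pytest.raises(ValueError, match="mixed"):
            build_map([a, b])
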