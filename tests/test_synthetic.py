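"""Synthetic scene generation and channel rendering."""

import json

import numpy as np
import pytest

from profilecad.io import read_channel_tiff, read_selection_csv
from profilecad.synthetic import (PhenotypeSpec, make_scene, render_channels,
                                  write_fixture)


class TestMakeScene:
    def test_single_cell_is_centered_with_nucleus_at_centroid(self):
        scene = make_scene(1, (128, 128), shape_jitter=0.0, seed=0)
        assert scene.n_cells == 1
        cell = scene.cells[0]
        assert cell.nucleus_center == pytest.approx((63.5, 63.5))
        # convexity: polygon equals its own convex hull footprint
        from shapely.geometry import Polygon

        poly = Polygon(cell.polygon)
        assert poly.convex_hull.area == pytest.approx(poly.area)

    def test_deterministic_for_fixed_seed(self):
        a = make_scene(4, (256, 256), 0.2, seed=1)
        b = make_scene(4, (256, 256), 0.2, seed=1)
        for ca, cb in zip(a.cells, b.cells):
            assert ca.nucleus_center == cb.nucleus_center
            assert ca.nucleus_radius == cb.nucleus_radius
            np.testing.assert_array_equal(ca.polygon, cb.polygon)

    def test_tessellation_covers_image(self):
        scene = make_scene(9, (512, 512), 0.3, seed=7)
        assert scene.n_cells == 9
        lab = scene.label_map()
        # rasterized union of the cells covers at least 80% of the region
        assert (lab > 0).mean() >= 0.80

    def test_nucleus_inside_its_polygon(self):
        from shapely.geometry import Point, Polygon

        scene = make_scene(16, (384, 384), 0.4, seed=5)
        for cell in scene.cells:
            assert Polygon(cell.polygon).buffer(1e-6).contains(Point(*cell.nucleus_center))

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError, match="too small"):
            make_scene(100, (64, 64), 0.2, seed=0)

    def test_bad_jitter_rejected(self):
        with pytest.raises(ValueError):
            make_scene(4, (256, 256), 1.5, seed=0)


class TestRenderChannels:
    def test_zero_phenotype_renders_zero_protein(self):
        scene = make_scene(4, (256, 256), 0.2, seed=2)
        ph = PhenotypeSpec(membrane_amplitude=0, cytoplasm_baseline=0,
                           perinuclear_peak_amplitude=0, noise_model="none")
        _, protein = render_channels(scene, ph)
        assert np.all(protein.pixels == 0.0)

    def test_wt_boundary_and_interior_intensities(self, scene49):
        ph = PhenotypeSpec(membrane_amplitude=100, cytoplasm_baseline=20,
                           perinuclear_peak_amplitude=0, noise_model="none")
        _, protein = render_channels(scene49, ph)
        boundary = scene49.boundary_mask()
        assert protein.pixels[boundary].max() == pytest.approx(120.0, abs=1.0)
        # interior pixels far (> 4 sigma) from any boundary sit at the baseline
        from scipy import ndimage

        far = ndimage.distance_transform_edt(~boundary) > 8
        assert protein.pixels[far].max() == pytest.approx(20.0, abs=0.5)

    def test_perinuclear_peak_at_stated_radial_fraction(self):
        scene = make_scene(9, (384, 384), 0.15, seed=4)
        ph = PhenotypeSpec(membrane_amplitude=30, cytoplasm_baseline=20,
                           perinuclear_peak_amplitude=80, perinuclear_peak_position=0.8,
                           noise_model="none")
        _, protein = render_channels(scene, ph)
        lab = scene.label_map()
        # ray-sample from each interior nucleus center to its membrane crossing
        fractions = []
        for i in scene.interior_cells():
            c = np.array(scene.cells[i].nucleus_center)
            own = lab[int(round(c[0])), int(round(c[1]))]
            for theta in np.linspace(0, 2 * np.pi, 8, endpoint=False):
                step = np.array([np.sin(theta), np.cos(theta)])
                ts = np.arange(1, 200)
                pts = np.round(c + np.outer(ts, step)).astype(int)
                ok = ((pts[:, 0] >= 0) & (pts[:, 0] < 384) & (pts[:, 1] >= 0) & (pts[:, 1] < 384))
                labs = lab[pts[ok, 0], pts[ok, 1]]
                hits = np.where(labs != own)[0]
                if not hits.size:
                    continue
                d_mem = ts[ok][hits[0]]
                vals = protein.pixels[pts[ok, 0][: hits[0]], pts[ok, 1][: hits[0]]]
                # brightest non-membrane structure: exclude the last 3 px near membrane
                if vals.size < 6:
                    continue
                interior_vals = vals[:-3]
                fractions.append(ts[ok][np.argmax(interior_vals)] / d_mem)
        assert np.mean(fractions) == pytest.approx(0.8, abs=0.05)

    def test_membrane_amplitude_monotonicity(self):
        scene = make_scene(4, (256, 256), 0.2, seed=2)
        boundary = scene.boundary_mask()
        means = []
        for amp in (20.0, 60.0, 120.0):
            _, protein = render_channels(scene, PhenotypeSpec(membrane_amplitude=amp,
                                                              noise_model="none"))
            means.append(protein.pixels[boundary].mean())
        assert means[0] < means[1] < means[2]

    def test_poisson_noise_variance_matches_photon_scale(self):
        # variance of a constant region over repeated draws ~ mean / photon_scale
        from profilecad.synthetic import apply_poisson_noise

        mean, scale = 40.0, 5.0
        draws = np.stack([apply_poisson_noise(np.full((20, 20), mean), scale, seed=s)
                          for s in range(1000)])
        var = draws.var(axis=0).mean()
        assert var == pytest.approx(mean / scale, rel=0.10)

    def test_render_deterministic(self):
        scene = make_scene(4, (256, 256), 0.2, seed=3)
        ph = PhenotypeSpec(noise_model="poisson", photon_scale=10)
        n1, p1 = render_channels(scene, ph)
        n2, p2 = render_channels(scene, ph)
        np.testing.assert_array_equal(n1.pixels, n2.pixels)
        np.testing.assert_array_equal(p1.pixels, p2.pixels)

    def test_phenotype_validation(self):
        with pytest.raises(ValueError):
            PhenotypeSpec(membrane_amplitude=-1)
        with pytest.raises(ValueError):
            PhenotypeSpec(perinuclear_peak_position=1.0)
        with pytest.raises(ValueError):
            PhenotypeSpec(noise_model="gaussian")


class TestWriteFixture:
    def test_round_trip_and_determinism(self, tmp_path):
        scene = make_scene(9, (256, 256), 0.2, seed=6)
        ph = PhenotypeSpec(noise_model="poisson", photon_scale=10)
        m1 = write_fixture(scene, ph, tmp_path / "a")
        m2 = write_fixture(scene, ph, tmp_path / "b")
        man1 = json.loads(m1.read_text())
        man2 = json.loads(m2.read_text())
        assert man1["checksums"] == man2["checksums"]
        # bit-for-bit round trip through the TIFF writer/reader
        img = read_channel_tiff(tmp_path / "a" / "protein.tif")
        img2 = read_channel_tiff(tmp_path / "b" / "protein.tif")
        np.testing.assert_array_equal(img.pixels, img2.pixels)

    def test_selection_csv_counts_match_scene(self, tmp_path):
        scene = make_scene(9, (256, 256), 0.2, seed=6)
        write_fixture(scene, PhenotypeSpec(noise_model="none"), tmp_path)
        sels = read_selection_csv(tmp_path / "selections.csv")
        points = [s for s in sels if s.kind == "point"]
        pairs = [s for s in sels if s.kind == "pair"]
        assert len(points) == scene.n_cells
        assert len(pairs) == len(scene.adjacency_pairs())
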