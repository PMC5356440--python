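import numpy as np
import pytest

from mtcortex import InvalidParameterError
from mtcortex import synthetic as sy


class TestCellMosaic:
    def test_single_cell_has_no_internal_junctions(self):
        assert sy.make_cell_mosaic(1, (20, 20), 0) == []

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_two_cells_share_exactly_one_edge(self, seed):
        edges = sy.make_cell_mosaic(2, (20, 20), seed)
        assert len(edges) == 1
        assert edges[0].meta["cells"] == (0, 1)

    def test_deterministic_given_seed(self):
        a = sy.make_cell_mosaic(25, (50, 50), 7)
        b = sy.make_cell_mosaic(25, (50, 50), 7)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.vertices, pb.vertices)

    def test_edges_lie_inside_field(self, mosaic25):
        for e in mosaic25:
            assert np.all(e.vertices >= -1e-9)
            assert np.all(e.vertices[:, 0] <= 50 + 1e-9)
            assert np.all(e.vertices[:, 1] <= 50 + 1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            sy.make_cell_mosaic(0, (20, 20), 0)
        with pytest.raises(InvalidParameterError):
            sy.make_cell_mosaic(5, (0, 20), 0)


class TestRidgeRendering:
    def test_zero_amplitude_gives_uniform_background(self, straight_path):
        img = sy.render_junction_scene([straight_path], 0.3, 0.0, 7.0, 0.0,
                                       (20, 20), 0.1, 0)
        assert np.all(img.values == 7.0)

    def test_empty_path_list_gives_blank_image(self):
        img = sy.render_junction_scene([], 0.3, 50.0, 3.0, 0.0, (10, 10), 0.1, 0)
        assert np.all(img.values == 3.0)

    def test_ridge_matches_analytic_gaussian_cross_section(self, ridge_image):
        # oracle: background + A exp(-d^2 / 2 sigma^2) at pixel centres
        sigma, amp = 0.3, 100.0
        ys = (np.arange(ridge_image.shape[0]) + 0.5) * ridge_image.pixel_size
        col = 100  # x = 10.05 µm, mid-ridge
        d = ys - 10.0
        expected = amp * np.exp(-d**2 / (2 * sigma**2))
        np.testing.assert_allclose(ridge_image.values[:, col], expected, atol=1e-5)

    def test_seeded_noise_is_reproducible(self, straight_path):
        a = sy.render_junction_scene([straight_path], 0.3, 50, 5, 2.0, (20, 20), 0.1, 3)
        b = sy.render_junction_scene([straight_path], 0.3, 50, 5, 2.0, (20, 20), 0.1, 3)
        assert np.array_equal(a.values, b.values)

    def test_negative_amplitude_rejected(self, straight_path):
        with pytest.raises(InvalidParameterError):
            sy.render_junction_scene([straight_path], 0.3, -1.0, 0, 0, (20, 20))


class TestCorticalPuncta:
    def test_zero_enrichment_means_no_junctional_puncta(self, mosaic25):
        puncta, _ = sy.place_cortical_puncta(mosaic25, (50, 50), 0.05, 5.0,
                                             0.4, 0.0, pixel_size=1.0, seed=2)
        assert all(not p.on_junction for p in puncta)

    def test_junctional_count_matches_poisson_mean(self):
        # oracle: Poisson(junction_density * enrichment * total length)
        from mtcortex import PolyPath
        path = PolyPath([[0, 25], [100, 25]])  # 100 µm straight junction
        lam = 2.0 * 0.5 * 100.0  # = 100
        counts = []
        for s in range(200):
            puncta, _ = sy.place_cortical_puncta(
                [path], (100, 50), 0.0, 2.0, 0.4, 0.5, pixel_size=1.0, seed=s)
            counts.append(sum(p.on_junction for p in puncta))
        se = np.sqrt(lam / 200)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_deterministic_given_seed(self, mosaic25):
        a, _ = sy.place_cortical_puncta(mosaic25, (50, 50), 0.05, 3.0, 0.4, 1.0,
                                        pixel_size=1.0, seed=11)
        b, _ = sy.place_cortical_puncta(mosaic25, (50, 50), 0.05, 3.0, 0.4, 1.0,
                                        pixel_size=1.0, seed=11)
        assert [(p.x, p.y) for p in a] == [(p.x, p.y) for p in b]


class TestFilamentSet:
    def test_requested_count_returned(self, mosaic25):
        fils, _ = sy.draw_filament_set(mosaic25, (50, 50), 37, 60, 2.0,
                                       render=False, seed=0)
        assert len(fils) == 37
        assert all("angle_truth" in f.meta for f in fils)

    def test_degenerate_concentration_pins_target_angle(self, mosaic25):
        fils, _ = sy.draw_filament_set(mosaic25, (50, 50), 50, 90, 1e9,
                                       render=False, seed=1)
        angles = np.array([f.meta["angle_truth"] for f in fils])
        assert np.all(np.abs(angles - 90.0) < 0.5)

    def test_kappa_zero_is_uniform_on_acute_range(self, mosaic25):
        # oracle: uniform angles -> P(45-90) = 0.5
        fils, _ = sy.draw_filament_set(mosaic25, (50, 50), 1000, 45, 0.0,
                                       render=False, seed=3)
        angles = np.array([f.meta["angle_truth"] for f in fils])
        frac = np.mean((angles >= 45) & (angles <= 90))
        se = np.sqrt(0.25 / 1000)
        assert abs(frac - 0.5) < 3 * se

    def test_zero_filaments_allowed(self, mosaic25):
        fils, img = sy.draw_filament_set(mosaic25, (50, 50), 0, 45, 1.0,
                                         render=False, seed=0)
        assert fils == []


class TestCometFrames:
    def test_zero_density_blank_image(self):
        frames, img = sy.simulate_comet_frames((20, 20), 0.0, background=4.0, seed=0)
        assert frames == [[]]
        assert np.all(img.values == 4.0)

    def test_count_matches_poisson_mean(self):
        # oracle: Poisson(density * area / 100): field 100 µm² at 30/100 µm²
        counts = [len(sy.simulate_comet_frames((10, 10), 30.0, pixel_size=0.5,
                                               seed=s)[0][0])
                  for s in range(200)]
        se = np.sqrt(30.0 / 200)
        assert abs(np.mean(counts) - 30.0) < 3 * se

    def test_truth_areas_within_requested_range(self):
        frames, _ = sy.simulate_comet_frames((30, 30), 10.0, area_range=(0.4, 0.9),
                                             seed=5)
        for c in frames[0]:
            assert 0.4 <= c.area <= 0.9

    def test_area_range_validation(self):
        with pytest.raises(InvalidParameterError):
            sy.simulate_comet_frames((10, 10), 5.0, area_range=(0.0, 1.0))


class TestDynamicTracks:
    def test_absorbing_growth(self):
        tracks = sy.simulate_dynamic_tracks(5, 12, 1, p_gp=0.0, p_pg=0.3,
                                            n_frames=30, seed=0)
        for t in tracks:
            assert all(s == "growth" for s in t.meta["states"])

    def test_stationary_pause_fraction(self):
        # oracle: two-state chain stationary pause mass p_gp/(p_gp+p_pg)
        p_gp, p_pg = 0.2, 0.3
        tracks = sy.simulate_dynamic_tracks(50, 12, 1, p_gp, p_pg,
                                            n_frames=200, seed=4)
        states = [s for t in tracks for s in t.meta["states"][50:]]  # burn-in
        frac = states.count("pause") / len(states)
        expected = p_gp / (p_gp + p_pg)
        se = np.sqrt(expected * (1 - expected) / len(states))
        # autocorrelated samples: allow a generous multiple of the iid SE
        assert abs(frac - expected) < 10 * se

    def test_deterministic_given_seed(self):
        a = sy.simulate_dynamic_tracks(3, 10, 2, 0.1, 0.2, seed=9)
        b = sy.simulate_dynamic_tracks(3, 10, 2, 0.1, 0.2, seed=9)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.positions, tb.positions)
            assert ta.meta["states"] == tb.meta["states"]

    def test_too_few_frames_rejected(self):
        with pytest.raises(InvalidParameterError):
            sy.simulate_dynamic_tracks(1, 10, 1, 0.1, 0.2, n_frames=1)


def test_calibration_round_trip(straight_path, ridge_image):
    """Rendering then measuring a known distance agrees within one pixel."""
    vals = ridge_image.values
    col = 100
    row = int(np.argmax(vals[:, col]))
    y_measured = (row + 0.5) * ridge_image.pixel_size
    assert abs(y_measured - 10.0) <= ridge_image.pixel_size
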