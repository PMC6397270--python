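import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import gi_star_brute, semivariogram_brute
from pelthg.spatial import (
    SpatialError,
    empirical_semivariogram,
    fit_variogram_range,
    gi_star,
    hotspot_map,
)


def _grid_points(n=5):
    return np.array([(i, j) for i in range(n) for j in range(n)], dtype=float)


class TestEmpiricalSemivariogram:
    def test_two_points_hand_value(self):
        # gamma = (0 - 2)^2 / (2 * 1) = 2
        lags, gamma, counts = empirical_semivariogram(
            np.array([[0.0, 0.0], [1.0, 0.0]]), np.array([0.0, 2.0]), n_bins=1)
        assert gamma == pytest.approx([2.0])
        assert counts.tolist() == [1]

    def test_constant_field_zero_gamma(self):
        pts = _grid_points(4)
        _, gamma, _ = empirical_semivariogram(pts, np.ones(len(pts)), n_bins=5)
        assert np.allclose(gamma, 0.0)

    def test_scaling_quadruples_gamma(self, rng):
        pts = _grid_points(5)
        v = rng.normal(size=len(pts))
        _, g1, _ = empirical_semivariogram(pts, v, n_bins=6)
        _, g2, _ = empirical_semivariogram(pts, 2 * v, n_bins=6)
        assert np.allclose(g2, 4 * g1)

    def test_shift_invariance(self, rng):
        pts = _grid_points(5)
        v = rng.normal(size=len(pts))
        _, g1, _ = empirical_semivariogram(pts, v, n_bins=6)
        _, g2, _ = empirical_semivariogram(pts, v + 7.3, n_bins=6)
        assert np.allclose(g1, g2)

    def test_matches_brute_force_enumeration(self, rng):
        pts = rng.uniform(-1, 1, size=(30, 2))
        v = rng.normal(size=30)
        from scipy.spatial.distance import pdist
        dmax = pdist(pts).max()
        n_bins = 7
        lags, gamma, counts = empirical_semivariogram(pts, v, n_bins=n_bins)
        edges = np.linspace(0, dmax, n_bins + 1)
        g_ref, c_ref = semivariogram_brute(pts, v, edges)
        nonempty = c_ref > 0
        assert counts.tolist() == c_ref[nonempty].tolist()
        assert np.allclose(gamma, g_ref[nonempty])

    def test_coincident_points_error(self):
        with pytest.raises(SpatialError):
            empirical_semivariogram(np.zeros((4, 2)), np.arange(4.0))


def _spherical(h, nugget, sill, rng_):
    hr = np.minimum(h / rng_, 1.0)
    return nugget + (sill - nugget) * (1.5 * hr - 0.5 * hr ** 3)


class TestVariogramFit:
    def test_recovers_exact_spherical_range(self):
        lags = np.linspace(0.05, 1.0, 15)
        gamma = _spherical(lags, 0.0, 1.0, 0.5)
        vg = fit_variogram_range(lags, gamma, np.full(15, 100), "spherical")
        assert vg.range_ == pytest.approx(0.5, abs=1e-3)
        assert not vg.fallback

    def test_flat_gamma_falls_back_to_half_max_lag(self):
        lags = np.linspace(0.1, 1.0, 10)
        gamma = np.full(10, 0.7)  # pure nugget
        vg = fit_variogram_range(lags, gamma, np.full(10, 50), "spherical")
        assert vg.fallback
        assert vg.range_ == pytest.approx(0.5)

    def test_bin_order_invariance(self, rng):
        lags = np.linspace(0.05, 1.0, 12)
        gamma = _spherical(lags, 0.1, 1.0, 0.4) + 0.01 * rng.normal(size=12)
        counts = rng.integers(10, 100, size=12)
        vg1 = fit_variogram_range(lags, gamma, counts)
        perm = rng.permutation(12)
        vg2 = fit_variogram_range(lags[perm], gamma[perm], counts[perm])
        assert vg1.range_ == pytest.approx(vg2.range_, rel=1e-9)

    def test_too_few_bins_error(self):
        with pytest.raises(SpatialError, match="fallback"):
            fit_variogram_range([0.1, 0.2], [1.0, 1.0], [5, 5])


class TestGiStar:
    def test_hand_evaluated_center_point(self):
        # 1-D points 0..4 with a single spike: center z = 0.8165
        pts = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0], [4, 0]])
        vals = np.array([0.0, 0, 10, 0, 0])
        gi = gi_star(pts, vals, band_distance=1.0)
        assert gi.z[2] == pytest.approx(0.8165, abs=1e-4)

    def test_constant_field_nan_neutral(self):
        pts = _grid_points(3)
        with pytest.warns(RuntimeWarning, match="constant"):
            gi = gi_star(pts, np.full(len(pts), 2.0), band_distance=1.0)
        assert np.all(np.isnan(gi.z))
        assert set(gi.labels) == {"neutral"}

    def test_location_invariance(self, rng):
        pts = _grid_points(5)
        v = rng.normal(size=len(pts))
        z1 = gi_star(pts, v, 1.5).z
        z2 = gi_star(pts, v + 100.0, 1.5).z
        assert np.allclose(z1, z2, atol=1e-10)

    def test_weight_matrix_symmetric_band(self, rng):
        # w_ij = w_ji: the statistic computed on reversed point order matches
        pts = rng.uniform(0, 4, size=(40, 2))
        v = rng.normal(size=40)
        z1 = gi_star(pts, v, 1.0).z
        z2 = gi_star(pts[::-1], v[::-1], 1.0).z
        assert np.allclose(z1, z2[::-1], atol=1e-12)

    def test_labels_match_threshold(self, rng):
        pts = _grid_points(6)
        v = rng.normal(size=len(pts))
        gi = gi_star(pts, v, 1.2, threshold=1.0)
        assert np.all((gi.z >= 1.0) == (gi.labels == "hot"))
        assert np.all((gi.z <= -1.0) == (gi.labels == "cold"))

    def test_agrees_with_brute_force_oracle(self):
        # oracle equivalence to 1e-10 on random 5x5 grids
        rng = np.random.default_rng(2024)
        pts = _grid_points(5)
        for _ in range(50):
            v = rng.normal(size=len(pts))
            band = rng.uniform(0.8, 4.0)
            z = gi_star(pts, v, band).z
            z_ref = gi_star_brute(pts, v, band)
            assert np.allclose(z, z_ref, atol=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=9, max_size=9),
           st.floats(0.5, 3.0))
    def test_property_matches_oracle(self, vals, band):
        pts = _grid_points(3)
        v = np.asarray(vals)
        if np.std(v) == 0:
            return
        z = gi_star(pts, v, band).z
        assert np.allclose(z, gi_star_brute(pts, v, band), atol=1e-10)


class TestHotspotMap:
    def test_deterministic(self, grids):
        tc = grids[0]
        gi1, vg1 = hotspot_map(tc)
        gi2, vg2 = hotspot_map(tc)
        assert np.array_equal(gi1.z, gi2.z)
        assert list(gi1.labels) == list(gi2.labels)
        assert vg1.range_ == vg2.range_

    def test_band_distance_recorded(self, grids):
        gi, vg = hotspot_map(grids[0])
        assert gi.band_distance == vg.range_

    def test_iid_field_false_positive_ceiling(self):
        # no spatial structure: mean significant fraction <= 10%
        from pelthg.synthetic_pelts import SimConfig, generate_pelt
        fracs = []
        for seed in range(30):
            cfg = SimConfig(n_pelts=1, n_rows=10, n_cols=10, n_holes=0,
                            topcoat_mean=5.0, topcoat_sd=0.5,
                            hotspot_amplitude=0.0, coldspot_amplitude=0.0,
                            corr_length=1e-6, seed=seed)
            tc, _ = generate_pelt(cfg, 0)
            gi, _ = hotspot_map(tc)
            fracs.append(np.mean(gi.labels != "neutral"))
        assert np.mean(fracs) <= 0.10
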