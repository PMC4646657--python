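import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import correlate

import mgdfseg
from mgdfseg.config import RunConfig
from mgdfseg.level_set import heaviside_eps
from mgdfseg.mgdf import (
    SIGMA_FLOOR,
    LocalGaussianStats,
    ModelWeights,
    data_force,
    make_window_kernel,
    total_energy,
    truncation_half_width,
    update_local_stats,
    window_filter,
)
from mgdfseg.phantoms import two_phase_fixture


class TestWindowKernel:
    def test_sigma_3_gives_15x15(self):
        assert truncation_half_width(3.0) == 7
        assert make_window_kernel(3.0).shape == (15, 15)

    def test_sigma_half_gives_3x3_center_peaked(self):
        k = make_window_kernel(0.5)
        assert k.shape == (3, 3)
        assert k[1, 1] == k.max()

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.2, 8.0))
    def test_kernel_conservation(self, sigma):
        assert make_window_kernel(sigma).sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            make_window_kernel(0.0)

    def test_separable_filter_matches_dense_correlation(self, rng):
        img = rng.uniform(0, 255, (24, 24))
        dense = correlate(img, make_window_kernel(2.0), mode="reflect")
        np.testing.assert_allclose(window_filter(img, 2.0), dense, rtol=1e-12)


def _exact_phi(truth, c0=2.0):
    return np.where(truth == 1, -c0, c0)


def _far_masks(truth, margin):
    """Pixels farther (Euclidean) than ``margin`` from the region boundary;
    the 15x15 window reaches tau * sqrt(2) ~ 9.9 px diagonally."""
    from scipy.ndimage import distance_transform_edt

    inner = distance_transform_edt(truth) > margin
    outer = distance_transform_edt(1 - truth) > margin
    return inner, outer


class TestLocalStats:
    def test_piecewise_constant_means_recovered_away_from_boundary(self):
        pair = two_phase_fixture((128, 128), 100.0, 20.0, radius=40.0)
        phi = _exact_phi(pair.truth)
        st_ = update_local_stats(pair.image, np.zeros_like(pair.image), phi, 3.0, 0.1)
        inner, outer = _far_masks(pair.truth, 10.5)
        np.testing.assert_allclose(st_.u1I[inner], 100.0, rtol=1e-3)
        np.testing.assert_allclose(st_.u2I[outer], 20.0, rtol=1e-3)
        # zero within-region variance clamps at the floor
        np.testing.assert_allclose(st_.s1I[inner], SIGMA_FLOOR, rtol=1e-2)
        np.testing.assert_allclose(st_.s2I[outer], SIGMA_FLOOR, rtol=1e-2)

    def test_noise_std_recovered_inside_region(self, rng):
        pair = two_phase_fixture((128, 128), 100.0, 20.0, radius=40.0)
        img = pair.image.copy()
        img[pair.truth == 1] += 5.0 * rng.standard_normal(int(pair.truth.sum()))
        phi = _exact_phi(pair.truth)
        st_ = update_local_stats(img, np.zeros_like(img), phi, 3.0, 0.1)
        inner, _ = _far_masks(pair.truth, 10.5)
        assert abs(st_.s1I[inner].mean() - 5.0) < 0.5  # within 10 %

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            update_local_stats(
                np.zeros((4, 4)), np.zeros((5, 5)), np.zeros((4, 4)), 3.0, 0.1
            )

    def test_shift_covariance(self, rng):
        img = rng.uniform(0, 255, (48, 48))
        ves = rng.uniform(-0.9, 0.9, (48, 48))
        phi = rng.standard_normal((48, 48))
        dy, dx = 3, 5
        st0 = update_local_stats(img, ves, phi, 2.0, 0.1)
        st1 = update_local_stats(
            np.roll(img, (dy, dx), (0, 1)),
            np.roll(ves, (dy, dx), (0, 1)),
            np.roll(phi, (dy, dx), (0, 1)),
            2.0,
            0.1,
        )
        tau = truncation_half_width(2.0)
        b = tau + max(dy, dx)  # exclude the reflective-boundary band
        np.testing.assert_allclose(
            np.roll(st0.u1I, (dy, dx), (0, 1))[b:-b, b:-b],
            st1.u1I[b:-b, b:-b],
            rtol=1e-10,
        )


def _reference_lgdf_force(image, u1, u2, s1, s2, sigma, lam1, lam2):
    """Independent dense-correlation implementation of the single-feature
    local Gaussian data force (oracle for the separable fast path)."""
    k = make_window_kernel(sigma)
    conv = lambda a: correlate(a, k, mode="reflect")
    log2pi = np.log(2 * np.pi)

    def e(u, s):
        inv2 = 0.5 / s**2
        return (
            log2pi
            + conv(np.log(s))
            + image**2 * conv(inv2)
            - 2 * image * conv(u * inv2)
            + conv(u**2 * inv2)
        )

    return lam1 * e(u1, s1) - lam2 * e(u2, s2)


class TestDataForce:
    def test_symmetric_statistics_give_zero_force(self, rng):
        img = rng.uniform(0, 255, (20, 20))
        ves = rng.uniform(-0.9, 0.9, (20, 20))
        u = rng.uniform(0, 255, (20, 20))
        s = rng.uniform(1, 10, (20, 20))
        uv = rng.uniform(-0.5, 0.5, (20, 20))
        sv = rng.uniform(0.1, 0.5, (20, 20))
        stats = LocalGaussianStats(u, u, uv, uv, s, s, sv, sv)
        w = ModelWeights(1.0, 1.0, 1.0, 1.0)
        F = data_force(img, ves, stats, 3.0, w)
        np.testing.assert_array_equal(F, np.zeros_like(F))

    def test_force_reinforces_correct_partition_near_boundary(self):
        # the local statistics only discriminate within the window's reach
        # of the contour; there the force must point with the sign of phi
        from scipy.ndimage import distance_transform_edt

        pair = two_phase_fixture((96, 96), 100.0, 20.0, radius=30.0)
        phi = _exact_phi(pair.truth)
        ves = np.zeros_like(pair.image)
        stats = update_local_stats(pair.image, ves, phi, 3.0, 0.1)
        F = data_force(pair.image, ves, stats, 3.0, ModelWeights())
        d_in = distance_transform_edt(pair.truth)
        d_out = distance_transform_edt(1 - pair.truth)
        inner_band = (d_in >= 1) & (d_in <= 6)
        outer_band = (d_out >= 1) & (d_out <= 6)
        assert F[inner_band].mean() < 0  # boundary interior pulled inward
        assert F[outer_band].mean() > 0  # boundary background pushed out

    def test_vesselness_nulling_reduces_to_reference_lgdf_force(self, rng):
        img = rng.uniform(0, 255, (24, 24))
        ves = rng.uniform(-0.9, 0.9, (24, 24))
        phi = rng.standard_normal((24, 24)) * 2
        stats = update_local_stats(img, ves, phi, 3.0, 0.1)
        F = data_force(img, ves, stats, 3.0, ModelWeights(1.05, 1.0, 0.0, 0.0))
        ref = _reference_lgdf_force(
            img, stats.u1I, stats.u2I, stats.s1I, stats.s2I, 3.0, 1.05, 1.0
        )
        np.testing.assert_allclose(F, ref, rtol=1e-9, atol=1e-9)


class TestTotalEnergy:
    def test_plane_signed_distance_has_no_interior_distance_penalty(self):
        cfg = RunConfig()
        h = w = 40
        phi = np.tile(np.arange(w, dtype=float) - w / 2, (h, 1))  # |grad| = 1
        img = np.full((h, w), 50.0)
        ves = np.zeros((h, w))
        stats = update_local_stats(img, ves, phi, cfg.sigma, cfg.epsilon)
        e = total_energy(img, ves, phi, stats, cfg)
        # only the one-pixel reflective border can contribute
        assert e.distance_term <= cfg.mu * 2 * h * 0.2
        assert e.distance_term >= 0

    def test_gamma_term_limits(self):
        cfg = RunConfig()
        img = np.full((16, 16), 50.0)
        ves = np.zeros_like(img)
        deep = np.full((16, 16), 1e6)
        stats = update_local_stats(img, ves, deep, cfg.sigma, cfg.epsilon)
        assert total_energy(img, ves, deep, stats, cfg).gamma_term == pytest.approx(
            0.0, abs=1e-3
        )
        flat = np.zeros((16, 16))
        stats = update_local_stats(img, ves, flat, cfg.sigma, cfg.epsilon)
        assert total_energy(img, ves, flat, stats, cfg).gamma_term == pytest.approx(
            cfg.eta * 256
        )

    def test_correct_partition_has_lower_energy_than_inverted(self):
        pair = two_phase_fixture((96, 96), 100.0, 20.0, radius=30.0, noise_std=3.0, seed=4)
        cfg = RunConfig()
        ves = np.zeros_like(pair.image)
        phi = _exact_phi(pair.truth)
        e_ok = total_energy(
            pair.image, ves, phi, update_local_stats(pair.image, ves, phi, cfg.sigma, cfg.epsilon), cfg
        )
        e_bad = total_energy(
            pair.image, ves, -phi, update_local_stats(pair.image, ves, -phi, cfg.sigma, cfg.epsilon), cfg
        )
        assert e_ok.total < e_bad.total

    def test_breakdown_total_is_sum_of_components(self):
        pair = two_phase_fixture((48, 48), 100.0, 20.0, radius=14.0)
        cfg = RunConfig()
        ves = np.zeros_like(pair.image)
        phi = _exact_phi(pair.truth)
        e = total_energy(
            pair.image, ves, phi, update_local_stats(pair.image, ves, phi, cfg.sigma, cfg.epsilon), cfg
        )
        assert e.total == pytest.approx(
            e.data_intensity + e.data_vesselness + e.length_term + e.distance_term + e.gamma_term
        )
        assert e.length_term >= 0 and e.distance_term >= 0
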