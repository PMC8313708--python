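"""Mutual information metric, optimizer, resampling and evaluation metrics."""

import numpy as np
import pytest

from bps.doppler import DopplerVolume, ParameterError
from bps.geometry import AffineTransform3D, SingularTransformError, rotation_angle_deg
from bps.registration import (DegenerateOverlapError, ESParams, GridSpec,
                              LandmarkSet, MIConfig, landmark_discrepancy,
                              mattes_mi, normalized_xcorr3, one_plus_one_es,
                              resample_volume, xcorr_metrics)


def hard_binned_mi(a, b, n_bins=50):
    """Brute-force joint-histogram MI oracle (box kernels on both axes)."""
    def bins(v):
        if np.ptp(v) == 0:
            return np.zeros(v.size, int)
        return np.round((v - v.min()) / np.ptp(v) * (n_bins - 1)).astype(int)
    ua, ub = bins(a.ravel()), bins(b.ravel())
    h = np.bincount(ua * n_bins + ub, minlength=n_bins * n_bins).reshape(n_bins, n_bins)
    p = h / h.sum()
    pf, pm = p.sum(1), p.sum(0)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / np.outer(pf, pm)[nz])))


class TestAffineTransform:
    def test_compose_and_inverse_roundtrip(self, rng):
        t = AffineTransform3D(np.eye(3) + 0.1 * rng.standard_normal((3, 3)),
                              rng.standard_normal(3), rng.standard_normal(3))
        pts = rng.standard_normal((50, 3))
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-10)

    def test_rejects_flipping_linear_part(self):
        with pytest.raises(SingularTransformError):
            AffineTransform3D(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))

    def test_from_params_rotation_angle(self):
        t = AffineTransform3D.from_params([0.1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        assert rotation_angle_deg(t.linear) == pytest.approx(np.degrees(0.1))

    def test_json_roundtrip_maps_points_identically(self, rng, tmp_path):
        t = AffineTransform3D(np.eye(3) + 0.05 * rng.standard_normal((3, 3)),
                              rng.standard_normal(3), rng.standard_normal(3))
        path = tmp_path / "t.json"
        t.save_json(path)
        t2 = AffineTransform3D.load_json(path)
        pts = rng.standard_normal((100, 3))
        np.testing.assert_allclose(t2.apply(pts), t.apply(pts), atol=1e-12)


class TestMattesMI:
    def test_constant_volumes_zero_mi(self):
        vol = DopplerVolume(np.full((6, 6, 4), 0.5), (1, 1, 1))
        assert mattes_mi(vol, vol) == pytest.approx(0.0, abs=1e-12)

    def test_identical_50_level_volume_ln50(self, rng):
        """A volume whose intensities uniformly occupy all 50 bins has
        self-MI equal to the entropy ln 50 of the uniform histogram."""
        vals = rng.permutation(np.repeat(np.arange(50), 20))[:1000] / 49.0
        vol = DopplerVolume(vals.reshape(10, 10, 10), (0.1, 0.1, 0.1))
        assert mattes_mi(vol, vol) == pytest.approx(np.log(50), abs=0.05)

    def test_matches_hand_counted_toy_histogram(self):
        """4×4×1 integer-valued toy volumes against the enumerated joint
        histogram."""
        a = np.array([[0, 0, 1, 1], [2, 2, 3, 3], [0, 1, 2, 3], [3, 2, 1, 0]],
                     float).reshape(4, 4, 1)
        b = np.array([[0, 1, 1, 0], [2, 2, 3, 3], [0, 1, 2, 3], [0, 1, 2, 3]],
                     float).reshape(4, 4, 1)
        va = DopplerVolume(a / 3, (1, 1, 1))
        vb = DopplerVolume(b / 3, (1, 1, 1))
        assert mattes_mi(va, vb, config=MIConfig(n_bins=4)) == pytest.approx(
            hard_binned_mi(a, b, 4), abs=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_on_random_volumes(self, seed):
        r = np.random.default_rng(seed)
        a = r.integers(0, 50, (8, 8, 4)) / 49.0
        b = r.integers(0, 50, (8, 8, 4)) / 49.0
        mi = mattes_mi(DopplerVolume(a, (1, 1, 1)), DopplerVolume(b, (1, 1, 1)))
        assert mi == pytest.approx(hard_binned_mi(a, b), abs=0.05)

    def test_symmetry_within_parzen_tolerance(self, rng):
        a = DopplerVolume(rng.random((10, 8, 6)), (1, 1, 1))
        b = DopplerVolume(rng.random((10, 8, 6)), (1, 1, 1))
        assert mattes_mi(a, b) == pytest.approx(mattes_mi(b, a), abs=0.05)

    def test_data_processing_bound(self, rng):
        """MI never exceeds the smaller marginal entropy (hard-binned check)."""
        a = rng.integers(0, 50, (12, 10, 6)) / 49.0
        b = rng.integers(0, 50, (12, 10, 6)) / 49.0
        mi = mattes_mi(DopplerVolume(a, (1, 1, 1)), DopplerVolume(b, (1, 1, 1)))
        def entropy(v):
            counts = np.bincount(np.round(v.ravel() * 49).astype(int), minlength=50)
            p = counts[counts > 0] / counts.sum()
            return -np.sum(p * np.log(p))
        assert mi <= min(entropy(a), entropy(b)) + 0.05

    def test_degenerate_overlap_raises(self, rng):
        vol = DopplerVolume(rng.random((8, 8, 8)), (0.1, 0.1, 0.1))
        far = AffineTransform3D.from_translation((100.0, 0.0, 0.0))
        with pytest.raises(DegenerateOverlapError):
            mattes_mi(vol, vol, transform=far)


class TestOnePlusOneES:
    def test_converges_on_convex_quadratic(self):
        target = np.array([1.0, 2.0, 3.0])
        best, trace = one_plus_one_es(
            lambda x: -np.sum((x - target) ** 2), np.zeros(3),
            ESParams(initial_radius=0.5, growth_factor=1.1, max_iterations=500),
            seed=0)
        assert np.linalg.norm(best - target) <= 1e-3
        assert len(trace) <= 500

    def test_zero_iterations_returns_start(self):
        x0 = np.array([4.0, 5.0])
        best, trace = one_plus_one_es(lambda x: -x @ x, x0,
                                      ESParams(max_iterations=0), seed=0)
        np.testing.assert_array_equal(best, x0)
        assert trace == []

    def test_deterministic_trace_for_fixed_seed(self):
        obj = lambda x: -np.sum(np.abs(x - 1.5))
        p = ESParams(initial_radius=0.3, max_iterations=100)
        a = one_plus_one_es(obj, np.zeros(4), p, seed=9)
        b = one_plus_one_es(obj, np.zeros(4), p, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_nonfinite_start_rejected(self):
        with pytest.raises(ParameterError):
            one_plus_one_es(lambda x: np.nan, np.zeros(2), seed=0)

    def test_monotone_best_objective(self):
        obj = lambda x: -np.sum((x - 2.0) ** 4)
        _, trace = one_plus_one_es(obj, np.zeros(3),
                                   ESParams(initial_radius=0.5, max_iterations=200),
                                   seed=1)
        best = [f for (_, f, _) in trace]
        assert np.all(np.diff(best) >= 0)


class TestResample:
    def test_identity_same_grid_exact(self, small_volume):
        for interp in ("trilinear", "nearest"):
            out = resample_volume(small_volume, AffineTransform3D.identity(),
                                  interp=interp)
            np.testing.assert_allclose(out.intensity, small_volume.intensity,
                                       atol=1e-12)

    def test_integer_voxel_translation_nearest(self, small_volume):
        t = AffineTransform3D.from_translation((2 * 0.1, 0, 0))
        out = resample_volume(small_volume, t, interp="nearest")
        np.testing.assert_allclose(out.intensity[2:], small_volume.intensity[:-2],
                                   atol=1e-12)
        assert np.all(out.intensity[:2] == 0)

    def test_subvoxel_shift_matches_hand_interpolation(self, rng):
        vol = DopplerVolume(rng.random((10, 10, 10)), (0.1, 0.1, 0.1))
        t = AffineTransform3D.from_translation((0.05, 0, 0))
        out = resample_volume(vol, t)
        expected = 0.5 * (vol.intensity[:-1] + vol.intensity[1:])
        np.testing.assert_allclose(out.intensity[1:], expected, atol=1e-10)

    def test_forward_then_inverse_recovers_interior(self, phantom_volume):
        from scipy import ndimage
        from bps.doppler import normalize_for_registration
        vol = normalize_for_registration(phantom_volume)
        # band-limit so that the invariant is about the resampler, not about
        # aliasing of voxel-thin vessels
        vol = DopplerVolume(ndimage.gaussian_filter(vol.intensity, 1.5),
                            vol.spacing_mm, vol.origin_mm)
        t = AffineTransform3D.from_params([0.05, 0, 0.03, 0, 0, 0, 0, 0, 0,
                                           0.21, -0.13, 0.17],
                                          center=(6.4, 3.0, 3.0))
        back = resample_volume(resample_volume(vol, t), t.inverse())
        inner = (slice(8, -8), slice(8, -8), slice(3, -3))
        a = vol.intensity[inner].ravel()
        b = back.intensity[inner].ravel()
        r = np.corrcoef(a, b)[0, 1]
        assert r >= 0.99


class TestXCorr:
    def test_autocorrelation_peak_is_unity_at_zero_lag(self, small_volume):
        xc = normalized_xcorr3(small_volume, small_volume)
        m = xcorr_metrics(xc)
        assert m.peak_value == pytest.approx(1.0)
        assert m.peak_lag_mm == (0.0, 0.0, 0.0)

    def test_shifted_copy_peak_lag(self, rng):
        a = np.zeros((24, 20, 10))
        a[8:16, 6:14, 3:7] = rng.random((8, 8, 4))
        va = DopplerVolume(a, (0.1, 0.1, 0.1))
        vb = DopplerVolume(np.roll(a, 4, axis=0), (0.1, 0.1, 0.1))
        m = xcorr_metrics(normalized_xcorr3(va, vb))
        assert m.peak_lag_mm[0] == pytest.approx(0.4)
        assert m.peak_lag_mm[1:] == (0.0, 0.0)
        # slightly below 1: the shifted support loses a few background planes
        assert m.peak_value == pytest.approx(1.0, abs=0.02)

    def test_uncorrelated_noise_low_peak(self):
        r1, r2 = np.random.default_rng(1), np.random.default_rng(2)
        a = DopplerVolume(r1.random((64, 64, 64)), (1, 1, 1))
        b = DopplerVolume(r2.random((64, 64, 64)), (1, 1, 1))
        m = xcorr_metrics(normalized_xcorr3(a, b))
        assert abs(m.peak_value) < 0.2

    def test_gaussian_blob_autocorrelation_fwhm(self):
        """Autocorrelation of an isotropic Gaussian blob of σ=0.3 mm has
        FWHM 2√(2 ln 2)·σ·√2 ≈ 0.999 mm on each axis."""
        spacing = 0.05
        n = 81
        x = (np.arange(n) - n // 2) * spacing
        gx, gy, gz = np.meshgrid(x, x, x, indexing="ij")
        blob = np.exp(-(gx**2 + gy**2 + gz**2) / (2 * 0.3**2))
        vol = DopplerVolume(blob, (spacing,) * 3)
        m = xcorr_metrics(normalized_xcorr3(vol, vol))
        expected = 2 * np.sqrt(2 * np.log(2)) * 0.3 * np.sqrt(2)
        for w in m.fwhm_mm:
            assert w == pytest.approx(expected, rel=0.03)

    def test_single_voxel_delta_fwhm_at_resolution_floor(self):
        a = np.zeros((15, 15, 15))
        a[7, 7, 7] = 1.0
        vol = DopplerVolume(a, (0.1, 0.1, 0.1))
        m = xcorr_metrics(normalized_xcorr3(vol, vol))
        for w in m.fwhm_mm:
            assert w <= 2 * 0.1 + 1e-9

    def test_constant_volume_rejected(self):
        vol = DopplerVolume(np.ones((6, 6, 6)), (1, 1, 1))
        with pytest.raises(ParameterError):
            normalized_xcorr3(vol, vol)


class TestLandmarks:
    def test_identical_sets_zero_distance(self):
        lm = LandmarkSet({"VL1": (1, 2, 3), "VL2": (-1, 0, 2)})
        d = landmark_discrepancy(lm, lm)
        assert d.mean_um == 0.0
        assert all(v == 0 for v in d.distances_um.values())

    def test_three_four_five_triangle(self):
        a = LandmarkSet({"VL1": (0.0, 0.0, 0.0)})
        b = LandmarkSet({"VL1": (0.030, 0.040, 0.0)})
        d = landmark_discrepancy(a, b)
        assert d.distances_um["VL1"] == pytest.approx(50.0)

    def test_four_offset_mean(self):
        a = LandmarkSet({f"VL{i}": (0, 0, 0) for i in range(1, 5)})
        b = LandmarkSet({"VL1": (0.1, 0, 0), "VL2": (0, 0.1, 0),
                         "VL3": (0, 0, 0.1), "VL4": (0.1, 0.1, 0.1)})
        d = landmark_discrepancy(a, b)
        expected = (3 * 100 + 100 * np.sqrt(3)) / 4
        assert d.mean_um == pytest.approx(expected, abs=0.1)

    def test_disjoint_names_rejected(self):
        with pytest.raises(ParameterError):
            landmark_discrepancy(LandmarkSet({"A": (0, 0, 0)}),
                                 LandmarkSet({"B": (0, 0, 0)}))
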