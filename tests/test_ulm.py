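"""Localization microscopy: detection, linking, rendering, misalignment."""

import itertools

import numpy as np
import pytest

from bps.doppler import ParameterError
from bps.phantom import generate_vessel_tree, simulate_bubble_movie
from bps.ulm import (ConvergenceWarning, Detection, Track, TrackSet,
                     _gated_assignment, demons_displacement, detect_bubbles,
                     link_tracks, mean_misalignment, refine_track,
                     render_ulm_maps)


def gaussian_spot(shape, cx, cz, sigma=1.5, amp=1.0):
    gx, gz = np.mgrid[: shape[0], : shape[1]]
    return amp * np.exp(-((gx - cx) ** 2 + (gz - cz) ** 2) / (2 * sigma**2))


class TestDetection:
    def test_empty_frame_no_detections(self):
        assert detect_bubbles(np.zeros((32, 32)), threshold=0.1, psf_radius=2) == []

    def test_subpixel_centroid_accuracy(self):
        frame = gaussian_spot((40, 40), 20.3, 15.7)
        (det,) = detect_bubbles(frame, threshold=0.2, psf_radius=3)
        assert det.x_mm == pytest.approx(20.3, abs=0.05)
        assert det.z_mm == pytest.approx(15.7, abs=0.05)

    def test_well_separated_spots_both_found(self):
        frame = gaussian_spot((64, 64), 12, 12) + gaussian_spot((64, 64), 42, 42)
        dets = detect_bubbles(frame, threshold=0.2, psf_radius=3)
        assert len(dets) == 2

    def test_close_spots_merge_to_brighter(self):
        frame = gaussian_spot((40, 40), 20, 20, amp=1.0) + \
            gaussian_spot((40, 40), 21, 20, amp=0.5)
        dets = detect_bubbles(frame, threshold=0.2, psf_radius=4)
        assert len(dets) == 1

    def test_pixel_size_converts_to_mm(self):
        frame = gaussian_spot((40, 40), 20, 10)
        (det,) = detect_bubbles(frame, threshold=0.2, psf_radius=3,
                                pixel_size_mm=(0.05, 0.05))
        assert det.x_mm == pytest.approx(1.0, abs=0.01)
        assert det.z_mm == pytest.approx(0.5, abs=0.01)


class TestLinking:
    def test_two_by_two_assignment(self):
        cost = np.array([[1.0, 2.0], [2.0, 1.0]])
        pairs = _gated_assignment(cost, gate=10.0)
        assert sorted(pairs) == [(0, 0), (1, 1)]

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_assignment_matches_permutation_minimum(self, n):
        """Hungarian solution equals the brute-force minimum over all n!
        permutations for random cost matrices."""
        rng = np.random.default_rng(n)
        for _ in range(20):
            cost = rng.random((n, n))
            pairs = _gated_assignment(cost, gate=1e6)
            total = sum(cost[r, c] for r, c in pairs)
            brute = min(sum(cost[i, p[i]] for i in range(n))
                        for p in itertools.permutations(range(n)))
            assert total == pytest.approx(brute)

    def test_parallel_bubbles_no_identity_swap(self):
        gate = 1.0
        frames = []
        for f in range(8):
            x = 0.5 * gate * f
            frames.append([Detection(f, x, 0.0, 1.0),
                           Detection(f, x, 3.0 * gate, 1.0)])
        ts = link_tracks(frames, max_link_dist=gate, min_track_length=4)
        assert len(ts) == 2
        for tr in ts.tracks:
            assert len(tr) == 8
            assert np.ptp(tr.positions_mm[:, 1]) < 1e-12  # stayed in its lane

    def test_gating_splits_distant_detections(self):
        frames = [[Detection(0, 0.0, 0.0, 1.0)], [Detection(1, 5.0, 0.0, 1.0)]]
        ts = link_tracks(frames, max_link_dist=1.0, min_track_length=1)
        assert len(ts) == 2  # jump above gate: two singleton tracks

    def test_short_tracks_discarded(self):
        frames = [[Detection(f, 0.1 * f, 0.0, 1.0)] for f in range(3)]
        ts = link_tracks(frames, max_link_dist=1.0, min_track_length=4)
        assert len(ts) == 0

    def test_gap_linking_bridges_missed_detection(self):
        frames = [[Detection(0, 0.0, 0.0, 1.0)], [],
                  [Detection(2, 0.2, 0.0, 1.0)], [Detection(3, 0.3, 0.0, 1.0)]]
        ts = link_tracks(frames, max_link_dist=0.15, max_gap=1, min_track_length=3)
        assert len(ts) == 1
        assert list(ts.tracks[0].frames) == [0, 2, 3]


class TestRefine:
    def test_identity_when_window_one(self):
        tr = Track(np.arange(5), np.random.default_rng(0).random((5, 2)))
        out = refine_track(tr, smooth_window=1, upsample=1)
        np.testing.assert_allclose(out.positions_mm, tr.positions_mm)

    def test_straight_line_collinearity_preserved(self):
        """Sliding-average smoothing maps collinear points to collinear points
        (interior points are exactly unchanged; edge points slide along the
        line under their shrinking windows)."""
        t = np.arange(10)
        pos = np.column_stack([0.1 * t, 0.05 * t])
        out = refine_track(Track(t, pos), smooth_window=5, upsample=1)
        d = np.array([0.1, 0.05])
        d = d / np.linalg.norm(d)
        resid = out.positions_mm - np.outer(out.positions_mm @ d, d)
        assert np.abs(resid).max() < 1e-10
        np.testing.assert_allclose(out.positions_mm[2:-2], pos[2:-2], atol=1e-12)

    def test_window3_hand_average(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 0.0]])
        out = refine_track(Track(np.arange(3), pos), smooth_window=3, upsample=1)
        assert out.positions_mm[1, 0] == pytest.approx(2.0)
        # edges use shrinking windows
        assert out.positions_mm[0, 0] == pytest.approx(0.5)

    def test_upsample_multiplies_density(self):
        tr = Track(np.arange(4), np.column_stack([np.arange(4.0), np.zeros(4)]))
        out = refine_track(tr, smooth_window=1, upsample=10)
        assert len(out) == 31  # (n-1)*upsample + 1


class TestRenderMaps:
    def test_straight_track_constant_velocity(self):
        n = 50
        speed = 10.0  # mm/s at 1000 Hz: 10 µm per frame
        pos = np.column_stack([np.linspace(0, speed * (n - 1) / 1000.0, n),
                               np.full(n, 0.05)])
        ts = TrackSet([Track(np.arange(n), pos)], frame_rate_hz=1000.0)
        maps = render_ulm_maps(ts, pixel_size_mm=0.005, extent_mm=(0.6, 0.1),
                               smooth_window=1, upsample=10)
        visited = maps.density > 0
        assert visited.any()
        np.testing.assert_allclose(maps.velocity[visited], speed, rtol=1e-6)

    def test_density_counts_conserved(self):
        rng = np.random.default_rng(5)
        tracks = [Track(np.arange(6), 0.2 + 0.02 * rng.random((6, 2)))
                  for _ in range(4)]
        ts = TrackSet(tracks, frame_rate_hz=1000.0)
        maps = render_ulm_maps(ts, pixel_size_mm=0.005, extent_mm=(0.5, 0.5),
                               smooth_window=1, upsample=10)
        expected = sum(5 * 10 + 1 for _ in tracks)
        assert maps.density.sum() == pytest.approx(expected)

    def test_permutation_invariant_to_track_order(self):
        rng = np.random.default_rng(6)
        tracks = [Track(np.arange(5), 0.1 + 0.05 * rng.random((5, 2)))
                  for _ in range(5)]
        a = render_ulm_maps(TrackSet(tracks, 1000.0), 0.005, (0.3, 0.3))
        b = render_ulm_maps(TrackSet(tracks[::-1], 1000.0), 0.005, (0.3, 0.3))
        np.testing.assert_allclose(a.density, b.density)


class TestEndToEnd:
    def test_noise_free_track_recovery(self):
        """On clean synthetic movies ≥95% of ground-truth tracks are recovered
        with sub-0.2-pixel localization error."""
        tree = generate_vessel_tree(2)
        stack, truth = simulate_bubble_movie(tree, n_bubbles=12, seed=2,
                                             n_frames=60, psf_sigma_px=1.2)
        px = stack.pixel_size_mm
        dets = [detect_bubbles(stack.data[:, :, f], threshold=0.3, psf_radius=3,
                               pixel_size_mm=px, frame_index=f)
                for f in range(stack.n_frames)]
        found = link_tracks(dets, max_link_dist=0.05, min_track_length=4,
                            frame_rate_hz=stack.compound_rate_hz)
        from bps.ulm import track_recovery_stats
        frac, loc_err = track_recovery_stats(truth, found, match_tol_mm=px[0])
        assert frac >= 0.95
        assert loc_err <= 0.2 * px[0]


class TestEndToEndNoisy:
    def test_noisy_movie_localization_within_half_pixel(self):
        """At 20 dB SNR (noise amplitude 1/10 of the bubble peak) recovered
        tracks still localize within 0.5 pixel."""
        from bps.phantom import BranchingConfig
        from bps.ulm import track_recovery_stats
        tree = generate_vessel_tree(3, BranchingConfig(depth=5, n_roots=2))
        stack, truth = simulate_bubble_movie(tree, n_bubbles=10, seed=3,
                                             n_frames=60, noise_sd=0.1,
                                             slab_thickness_mm=2.5)
        px = stack.pixel_size_mm
        dets = [detect_bubbles(stack.data[:, :, f], threshold=0.35, psf_radius=2,
                               pixel_size_mm=px, frame_index=f)
                for f in range(stack.n_frames)]
        found = link_tracks(dets, max_link_dist=0.05, min_track_length=4,
                            frame_rate_hz=stack.compound_rate_hz)
        frac, loc_err = track_recovery_stats(truth, found, match_tol_mm=2 * px[0],
                                             resolution_mm=0.15)
        assert frac >= 0.8
        assert loc_err <= 0.5 * px[0]


class TestDemonsMisalignment:
    def _vessel_map(self, shift_px=0):
        img = np.zeros((128, 128))
        gx, gz = np.mgrid[0:128, 0:128]
        for (a, b, w) in [(30, 0.5, 2.0), (70, -0.3, 2.5), (100, 0.1, 1.5)]:
            center = a + b * gz
            img += np.exp(-((gx - center - shift_px) ** 2) / (2 * w**2))
        return img

    def test_identical_images_zero_field(self):
        img = self._vessel_map()
        field = demons_displacement(img, img, n_iter=30)
        assert np.abs(field).mean() < 0.05

    def test_known_shift_recovered(self):
        a = self._vessel_map(0)
        b = self._vessel_map(3)
        field = demons_displacement(a, b)
        mask = (a > 0.1) | (b > 0.1)
        assert abs(field[0][mask].mean() - 3.0) < 0.3

    def test_rotation_beyond_capture_warns(self):
        rng = np.random.default_rng(0)
        a = rng.random((64, 64))
        b = np.rot90(a).copy()
        with pytest.warns(ConvergenceWarning):
            demons_displacement(a, b, n_iter=5, n_levels=1)

    def test_uniform_field_unit_conversion(self):
        field = np.full((2, 16, 16), 3.0)
        mask = np.ones((16, 16), bool)
        res = mean_misalignment(field, mask, mask, pixel_size_mm=0.005)
        assert res.mean_shift_um == (pytest.approx(15.0), pytest.approx(15.0))

    def test_disjoint_masks_rejected(self):
        field = np.zeros((2, 16, 16))
        ma = np.zeros((16, 16), bool)
        mb = np.zeros((16, 16), bool)
        ma[0, 0] = True
        mb[15, 15] = True
        with pytest.raises(ParameterError):
            mean_misalignment(field, ma, mb, 0.005, dilate_px=1)

    def test_constructed_40um_offset_recovered(self):
        """A vessel-map pair offset by 40 µm (8 px at 5 µm) is recovered
        within 10 µm by the demons displacement average."""
        a = self._vessel_map(0)
        b = self._vessel_map(8)
        field = demons_displacement(a, b)
        res = mean_misalignment(field, a > 0.1, b > 0.1, pixel_size_mm=0.005)
        assert abs(res.mean_shift_um[0] - 40.0) <= 10.0
        assert abs(res.mean_shift_um[1]) <= 10.0
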