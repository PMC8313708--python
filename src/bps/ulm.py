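"""Ultrasound Localization Microscopy: bubble detection, tracking, map rendering.

Intravascular microbubbles are localized frame by frame with sub-pixel
precision, linked into trajectories by minimum-cost bipartite assignment,
smoothed and interpolated, then projected onto a fine (5 µm) grid to build
super-resolved density and velocity maps.  Pairs of such maps acquired after
probe repositioning quantify residual misalignment through a non-rigid
(demons) displacement field averaged over the vasculature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .doppler import ParameterError


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class Detection:
    frame: int
    x_mm: float
    z_mm: float
    intensity: float


@dataclass
class Track:
    frames: np.ndarray          # strictly increasing frame indices
    positions_mm: np.ndarray    # (n, 2) columns x, z

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.positions_mm = np.asarray(self.positions_mm, dtype=float).reshape(-1, 2)
        if len(self.frames) != len(self.positions_mm):
            raise ParameterError("frames and positions length mismatch")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ParameterError("track frames must be strictly increasing")

    def __len__(self):
        return len(self.frames)


@dataclass
class TrackSet:
    tracks: list
    frame_rate_hz: float

    def __len__(self):
        return len(self.tracks)

    def velocities_mm_s(self, track: Track) -> np.ndarray:
        """Per-point velocity by central finite differences × frame rate."""
        p = track.positions_mm
        if len(p) < 2:
            return np.zeros_like(p)
        dt = np.gradient(track.frames.astype(float)) / self.frame_rate_hz
        return np.gradient(p, axis=0) / dt[:, None]


@dataclass
class ULMMaps:
    density: np.ndarray      # counts of interpolated track points per pixel
    velocity: np.ndarray     # mean speed mm/s where density > 0, else 0
    pixel_size_mm: float
    origin_mm: tuple = (0.0, 0.0)


@dataclass
class MisalignmentResult:
    mean_shift_um: tuple     # (Δlateral, Δaxial), shift of B relative to A
    mask_voxel_count: int


# --- detection --------------------------------------------------------------

def detect_bubbles(frame: np.ndarray, threshold: float, psf_radius: int,
                   pixel_size_mm=(1.0, 1.0), frame_index: int = 0) -> list:
    """Sub-pixel bubble localization on one clutter-filtered frame.

    Local maxima above ``threshold`` are refined by intensity-weighted centroid
    in a (2·psf_radius+1)² window; maxima closer than psf_radius collapse onto
    the brighter one.  With the default unit pixel size, positions are in
    pixels of the (x, z) grid.
    """
    if threshold <= 0:
        raise ParameterError("detection threshold must be positive")
    img = np.abs(np.asarray(frame, dtype=float))
    r = int(psf_radius)
    size = 2 * r + 1
    local_max = ndimage.maximum_filter(img, size=size, mode="constant") == img
    peaks = np.argwhere(local_max & (img > threshold))
    # plateau / near-duplicate suppression: keep brighter of any pair closer than r
    order = np.argsort(img[tuple(peaks.T)])[::-1] if len(peaks) else []
    kept = []
    for idx in order:
        p = peaks[idx]
        if all(np.hypot(*(p - q)) >= r for q in kept):
            kept.append(p)
    out = []
    sx, sz = pixel_size_mm
    for ix, iz in kept:
        x0, x1 = max(0, ix - r), min(img.shape[0], ix + r + 1)
        z0, z1 = max(0, iz - r), min(img.shape[1], iz + r + 1)
        win = img[x0:x1, z0:z1]
        gx, gz = np.mgrid[x0:x1, z0:z1]
        w = win.sum()
        cx = float((gx * win).sum() / w)
        cz = float((gz * win).sum() / w)
        out.append(Detection(frame=frame_index, x_mm=cx * sx, z_mm=cz * sz,
                             intensity=float(img[ix, iz])))
    return out


# --- linking ----------------------------------------------------------------

def _gated_assignment(cost: np.ndarray, gate: float):
    """Min-cost assignment with birth/death at cost ``gate`` (augmented matrix).

    Returns list of (row, col) pairs with cost below the gate; unmatched rows
    terminate and unmatched columns are births.
    """
    n, m = cost.shape
    big = gate  # a pairing is only worthwhile below the birth+death alternative
    aug = np.full((n + m, n + m), 0.0)
    aug[:n, :m] = cost
    aug[:n, m:] = np.where(np.eye(n, dtype=bool), big, 1e9)
    aug[n:, :m] = np.where(np.eye(m, dtype=bool), big, 1e9)
    rows, cols = linear_sum_assignment(aug)
    return [(r, c) for r, c in zip(rows, cols) if r < n and c < m and cost[r, c] <= gate]


def link_tracks(detections_per_frame: list, max_link_dist: float,
                max_gap: int = 0, min_track_length: int = 4,
                frame_rate_hz: float = 1000.0) -> TrackSet:
    """Frame-to-frame Hungarian linking of detections into bubble tracks.

    Each consecutive assignment minimizes total Euclidean cost, gated at
    ``max_link_dist`` (per-frame-step); a track unmatched for more than
    ``max_gap`` frames terminates; tracks shorter than ``min_track_length``
    points are discarded.
    """
    active = []   # dicts: frames (list), pos (list), last_frame
    done = []
    for fi, dets in enumerate(detections_per_frame):
        pts = np.array([[d.x_mm, d.z_mm] for d in dets], dtype=float).reshape(-1, 2)
        # retire stale tracks
        still = []
        for tr in active:
            if fi - tr["last"] > max_gap + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        matched_cols = set()
        if active and len(pts):
            last_pos = np.array([tr["pos"][-1] for tr in active])
            gaps = np.array([fi - tr["last"] for tr in active], dtype=float)
            dist = np.linalg.norm(last_pos[:, None, :] - pts[None, :, :], axis=2)
            gate_per_row = max_link_dist * gaps  # allow proportionally longer jumps over gaps
            cost = dist / gaps[:, None]          # per-frame-step distance
            pairs = _gated_assignment(cost, max_link_dist)
            for r, c in pairs:
                if dist[r, c] <= gate_per_row[r]:
                    active[r]["frames"].append(fi)
                    active[r]["pos"].append(pts[c])
                    active[r]["last"] = fi
                    matched_cols.add(c)
        for c in range(len(pts)):
            if c not in matched_cols:
                active.append({"frames": [fi], "pos": [pts[c]], "last": fi})
    done.extend(active)
    tracks = [Track(np.array(t["frames"]), np.array(t["pos"]))
              for t in done if len(t["frames"]) >= min_track_length]
    return TrackSet(tracks=tracks, frame_rate_hz=frame_rate_hz)


# --- refinement and rendering ----------------------------------------------

def refine_track(track: Track, smooth_window: int = 3, upsample: int = 10) -> Track:
    """Sliding-average smoothing (shrinking windows at the edges) then linear
    interpolation to ``upsample``× temporal density."""
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ParameterError("smooth_window must be odd and >= 1")
    if upsample < 1:
        raise ParameterError("upsample must be >= 1")
    p = track.positions_mm
    n = len(p)
    h = smooth_window // 2
    csum = np.vstack([np.zeros((1, 2)), np.cumsum(p, axis=0)])
    lo = np.maximum(0, np.arange(n) - h)
    hi = np.minimum(n, np.arange(n) + h + 1)
    sm = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    if upsample == 1 or n < 2:
        return Track(track.frames.copy(), sm)
    t_old = track.frames.astype(float)
    t_new = np.arange(t_old[0], t_old[-1] + 1e-9, 1.0 / upsample)
    out = np.column_stack([np.interp(t_new, t_old, sm[:, k]) for k in range(2)])
    return Track(np.round(t_new * upsample).astype(int), out)


def render_ulm_maps(trackset: TrackSet, pixel_size_mm: float = 0.005,
                    extent_mm=None, origin_mm=(0.0, 0.0),
                    smooth_window: int = 3, upsample: int = 10) -> ULMMaps:
    """Project refined tracks onto a fine grid as density and mean-speed maps.

    Density counts interpolated track points per pixel; velocity is the
    density-weighted mean bubble speed (finite differences × frame rate).
    """
    if pixel_size_mm <= 0:
        raise ParameterError("pixel size must be positive")
    refined = [refine_track(t, smooth_window, upsample) for t in trackset.tracks]
    if extent_mm is None:
        allp = np.vstack([t.positions_mm for t in refined]) if refined else np.zeros((1, 2))
        extent_mm = (allp[:, 0].max() - origin_mm[0] + pixel_size_mm,
                     allp[:, 1].max() - origin_mm[1] + pixel_size_mm)
    nx = max(1, int(np.ceil(extent_mm[0] / pixel_size_mm - 1e-9)))
    nz = max(1, int(np.ceil(extent_mm[1] / pixel_size_mm - 1e-9)))
    density = np.zeros((nx, nz))
    vsum = np.zeros((nx, nz))
    for tr in refined:
        p = tr.positions_mm
        if len(p) < 2:
            speeds = np.zeros(len(p))
        else:
            dt = np.gradient(tr.frames.astype(float)) / (upsample * trackset.frame_rate_hz)
            vel = np.gradient(p, axis=0) / dt[:, None]
            speeds = np.linalg.norm(vel, axis=1)
        ix = np.floor((p[:, 0] - origin_mm[0]) / pixel_size_mm).astype(int)
        iz = np.floor((p[:, 1] - origin_mm[1]) / pixel_size_mm).astype(int)
        ok = (ix >= 0) & (ix < nx) & (iz >= 0) & (iz < nz)
        np.add.at(density, (ix[ok], iz[ok]), 1.0)
        np.add.at(vsum, (ix[ok], iz[ok]), speeds[ok])
    with np.errstate(invalid="ignore"):
        velocity = np.where(density > 0, vsum / np.maximum(density, 1), 0.0)
    return ULMMaps(density=density, velocity=velocity,
                   pixel_size_mm=pixel_size_mm, origin_mm=tuple(origin_mm))


def track_recovery_stats(truth: TrackSet, found: TrackSet, match_tol_mm: float,
                         min_coverage: float = 0.8, min_truth_length: int = 4,
                         resolution_mm: float | None = None):
    """Score recovered tracks against ground truth.

    A truth-track point is covered when some found track holds a point at the
    same frame within ``match_tol_mm``; a truth track is recovered when at
    least ``min_coverage`` of its points are covered (splits at bubble
    crossings are tolerated — coverage is over the union of found tracks).
    With ``resolution_mm`` given, truth points with another truth emitter
    inside that radius are excluded as unresolvable — two sources within the
    point-spread function render as one spot, which no localizer separates —
    and tracks left with fewer than ``min_truth_length`` resolvable points
    drop out of the denominator.  Returns (recovered_fraction,
    mean_localization_error_mm) over the evaluated truth tracks.
    """
    by_frame = {}
    for ft in found.tracks:
        for fr, pos in zip(ft.frames, ft.positions_mm):
            by_frame.setdefault(int(fr), []).append(pos)
    truth_by_frame = {}
    if resolution_mm is not None:
        for ti, tt in enumerate(truth.tracks):
            for fr, pos in zip(tt.frames, tt.positions_mm):
                truth_by_frame.setdefault(int(fr), []).append((ti, pos))
    n_eval = 0
    n_recovered = 0
    errs = []
    for ti, tt in enumerate(truth.tracks):
        if len(tt) < min_truth_length:
            continue
        points = list(zip(tt.frames, tt.positions_mm))
        if resolution_mm is not None:
            points = [
                (fr, pos) for fr, pos in points
                if not any(tj != ti and np.hypot(*(pos - q)) < resolution_mm
                           for tj, q in truth_by_frame.get(int(fr), ()))
            ]
            if len(points) < min_truth_length:
                continue
        n_eval += 1
        dists = []
        for fr, pos in points:
            cands = by_frame.get(int(fr))
            if not cands:
                continue
            d = min(np.hypot(*(pos - c)) for c in cands)
            if d <= match_tol_mm:
                dists.append(d)
        if len(dists) >= min_coverage * len(points):
            n_recovered += 1
            errs.append(np.mean(dists))
    if n_eval == 0:
        raise ParameterError("no resolvable ground-truth tracks to evaluate")
    return n_recovered / n_eval, float(np.mean(errs)) if errs else np.nan


# --- misalignment quantification -------------------------------------------

def _demons_step(fixed, moving, disp, reg_sigma, n_iter):
    gx, gz = np.gradient(fixed)
    grid = np.mgrid[0:fixed.shape[0], 0:fixed.shape[1]].astype(float)
    for _ in range(n_iter):
        coords = grid + disp
        warped = ndimage.map_coordinates(moving, coords, order=1, mode="nearest")
        diff = fixed - warped
        denom = gx**2 + gz**2 + diff**2
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(denom > 1e-12, diff * gx / denom, 0.0)
            uz = np.where(denom > 1e-12, diff * gz / denom, 0.0)
        disp[0] += ux
        disp[1] += uz
        disp[0] = ndimage.gaussian_filter(disp[0], reg_sigma)
        disp[1] = ndimage.gaussian_filter(disp[1], reg_sigma)
    return disp


def demons_displacement(img_a: np.ndarray, img_b: np.ndarray, n_iter: int = 100,
                        reg_sigma: float = 2.0, pre_blur_sigma: float = 2.0,
                        n_levels: int | None = None) -> np.ndarray:
    """Thirion-style demons displacement field warping ``img_b`` toward ``img_a``.

    Both images are Gaussian pre-blurred (near-binary super-resolution maps
    carry no usable gradients otherwise) and a coarse-to-fine pyramid extends
    the capture range.  Returns a (2, nx, nz) field ``d`` in pixels such that
    B(x + d(x)) ≈ A(x); ``d`` directly measures the displacement of B's
    structures relative to A's (B = A shifted by +s gives d ≈ +s).
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("images must share a shape")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ParameterError("non-finite input image")
    if n_levels is None:
        # pyramid depth scales with image size so the coarsest level sees
        # structure at the tens-of-pixels scale (super-res maps are huge)
        n_levels = max(3, int(np.ceil(np.log2(max(min(a.shape) / 32, 1)))))
    scale = max(a.max(), b.max())
    if scale > 0:
        a, b = a / scale, b / scale
    a = ndimage.gaussian_filter(a, pre_blur_sigma)
    b = ndimage.gaussian_filter(b, pre_blur_sigma)
    initial_mse = float(np.mean((a - b) ** 2))
    disp = None
    for lev in range(n_levels - 1, -1, -1):
        f = 2**lev
        af = ndimage.zoom(ndimage.gaussian_filter(a, f / 2.0), 1.0 / f, order=1)
        bf = ndimage.zoom(ndimage.gaussian_filter(b, f / 2.0), 1.0 / f, order=1)
        if disp is None:
            disp = np.zeros((2,) + af.shape)
        else:
            disp = np.stack([
                ndimage.zoom(disp[k], np.array(af.shape) / np.array(disp[k].shape), order=1) * 2.0
                for k in range(2)
            ])
            disp = disp[:, : af.shape[0], : af.shape[1]]
        disp = _demons_step(af, bf, disp, reg_sigma, n_iter)
    grid = np.mgrid[0:a.shape[0], 0:a.shape[1]].astype(float)
    warped = ndimage.map_coordinates(b, grid + disp, order=1, mode="nearest")
    final_mse = float(np.mean((a - warped) ** 2))
    if initial_mse > 0 and final_mse > 0.8 * initial_mse:
        warnings.warn("demons registration did not converge (residual barely reduced); "
                      "misalignment may exceed the capture range", ConvergenceWarning)
    return disp


def mean_misalignment(field: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray,
                      pixel_size_mm: float, dilate_px: int = 2) -> MisalignmentResult:
    """Average the displacement field over the shared vasculature, in µm.

    The support is the intersection of the (dilated) nonzero-density masks of
    the two maps; the reported shift is that of map B relative to map A.
    """
    da = ndimage.binary_dilation(np.asarray(mask_a, bool), iterations=dilate_px)
    db = ndimage.binary_dilation(np.asarray(mask_b, bool), iterations=dilate_px)
    mask = da & db
    if not mask.any():
        raise ParameterError("vasculature masks do not overlap")
    shift_px = (field[0][mask].mean(), field[1][mask].mean())
    um = pixel_size_mm * 1000.0
    return MisalignmentResult(
        mean_shift_um=(float(shift_px[0] * um), float(shift_px[1] * um)),
        mask_voxel_count=int(mask.sum()),
    )
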