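"""Seeded generators for every synthetic input the pipeline consumes.

The generators emulate the study's data shapes — tree-like vascular intensity
volumes (the "vascular fingerprint" registration keys on), rank-structured
tissue+blood frame stacks for clutter filtering, sparse moving point-scatterer
movies for localization microscopy, and stimulus-locked / correlated CBV time
series — and always return the latent ground truth (applied transforms, exact
bubble tracks, effect sizes, correlation structure) that downstream accuracy
tests measure against.  Every generator is a pure function of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .doppler import DopplerVolume, FrameStack, ParameterError
from .functional import StimulusPattern
from .geometry import AffineTransform3D
from .ulm import Track, TrackSet


@dataclass(frozen=True)
class Segment:
    start_mm: np.ndarray
    end_mm: np.ndarray
    radius_mm: float
    branch_depth: int

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.asarray(self.end_mm) - np.asarray(self.start_mm)))


@dataclass
class VesselTree:
    segments: list
    domain_box_mm: tuple

    def __post_init__(self):
        box = np.asarray(self.domain_box_mm, dtype=float)
        for s in self.segments:
            for p in (s.start_mm, s.end_mm):
                if np.any(np.asarray(p) < -1e-9) or np.any(np.asarray(p) > box + 1e-9):
                    raise ParameterError("segment endpoint outside domain box")
            if s.radius_mm <= 0:
                raise ParameterError("segment radius must be positive")

    def span_mm(self) -> np.ndarray:
        pts = np.vstack([[s.start_mm, s.end_mm] for s in self.segments]).reshape(-1, 3)
        return pts.max(axis=0) - pts.min(axis=0)


@dataclass(frozen=True)
class BranchingConfig:
    """Binary-branching vascular tree parameters.

    ``depth`` counts bifurcation levels below the root trunk; a full binary
    tree yields 2^(depth+1) − 1 segments.  Radii and segment lengths decay
    geometrically down the tree so child radius ≤ parent radius always holds.
    """

    domain_extents_mm: tuple = (12.8, 6.0, 6.0)
    depth: int = 4
    n_roots: int = 1
    root_radius_mm: float = 0.15
    radius_decay: float = 0.8
    length_decay: float = 0.72
    branch_angle_deg: float = 35.0
    angle_jitter_deg: float = 10.0

    def __post_init__(self):
        if any(e <= 0 for e in self.domain_extents_mm):
            raise ParameterError("domain extents must be positive")
        if self.depth < 0:
            raise ParameterError("depth must be non-negative")
        if self.root_radius_mm <= 0:
            raise ParameterError("root radius must be positive")


@dataclass
class GroundTruth:
    applied_transform: AffineTransform3D | None = None
    bubble_tracks: TrackSet | None = None
    roi_effect_sizes: dict = field(default_factory=dict)
    correlation_structure: np.ndarray | None = None


def _rotate_about(v, axis, angle):
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def generate_vessel_tree(seed: int, params: BranchingConfig | None = None) -> VesselTree:
    """Grow a deterministic binary vascular tree spanning the domain.

    The first root trunk runs along the box diagonal (guaranteeing the tree
    spans well over half of every axis); additional roots (``n_roots`` > 1)
    start from other corners along crossing diagonals, emulating the several
    major vessel systems of a real angiogram.  Each segment bifurcates into
    two children deflected by ~``branch_angle_deg`` with seeded jitter, with
    geometrically decaying length and radius.  Endpoints are clipped to the
    domain box.
    """
    p = params or BranchingConfig()
    rng = np.random.default_rng(seed)
    ext = np.asarray(p.domain_extents_mm, dtype=float)
    corners = [np.array([0.08, 0.08, 0.08]), np.array([0.92, 0.08, 0.12]),
               np.array([0.08, 0.92, 0.12]), np.array([0.92, 0.92, 0.08])]
    segments = []
    frontier = []
    for r in range(p.n_roots):
        c = corners[r % len(corners)]
        start = c * ext
        end = (1.0 - c + np.array([0, 0, 0.6]) * (c[2] - 0.1)) * ext
        end = np.clip(end, 0.02 * ext, 0.98 * ext)
        radius = p.root_radius_mm * (1.0 if r == 0 else 0.85)
        segments.append(Segment(start, end, radius, 0))
        frontier.append((start, end, radius, np.linalg.norm(end - start)))
    for level in range(1, p.depth + 1):
        new_frontier = []
        for (s0, e0, r0, l0) in frontier:
            d0 = e0 - s0
            if np.linalg.norm(d0) < 1e-9:  # parent collapsed onto the box wall
                d0 = 0.5 * ext - e0
            if np.linalg.norm(d0) < 1e-9:
                d0 = np.array([1.0, 0.0, 0.0])
            d0 = d0 / np.linalg.norm(d0)
            # an arbitrary normal to the parent direction seeds the branching plane
            ref = np.array([0.0, 0.0, 1.0]) if abs(d0[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            n0 = np.cross(d0, ref)
            n0 /= np.linalg.norm(n0)
            azimuth = rng.uniform(0, 2 * np.pi)
            plane_n = _rotate_about(n0, d0, azimuth)
            for sign in (+1.0, -1.0):
                ang = np.radians(p.branch_angle_deg + rng.normal(0, p.angle_jitter_deg))
                d = _rotate_about(d0, plane_n, sign * ang)
                length = l0 * p.length_decay * (1 + rng.normal(0, 0.05))
                radius = r0 * p.radius_decay
                e = np.clip(e0 + d * length, 0.02 * ext, 0.98 * ext)
                if np.linalg.norm(e - e0) < 1e-6:  # fully clipped: grow inward
                    d_in = 0.5 * ext - e0
                    d_in /= max(np.linalg.norm(d_in), 1e-9)
                    e = np.clip(e0 + d_in * length, 0.02 * ext, 0.98 * ext)
                segments.append(Segment(e0.copy(), e, radius, level))
                new_frontier.append((e0, e, radius, length))
        frontier = new_frontier
    return VesselTree(segments=segments, domain_box_mm=tuple(ext))


def rasterize_doppler_volume(tree: VesselTree, spacing_mm=(0.1, 0.1, 0.4),
                             snr: float = np.inf, seed: int = 0,
                             psf_sigma_voxels: float = 0.6) -> DopplerVolume:
    """Render a vessel tree as a Power Doppler intensity volume.

    Grid dimension per axis is floor(extent/spacing)+1 with values sampled at
    voxel centres.  Voxels within a segment radius carry intensity ∝ radius²
    (blood-volume proxy) with a narrow Gaussian falloff at the wall; the
    rendered volume is then convolved with a Gaussian of ``psf_sigma_voxels``
    emulating the system point-spread function (the device resolves ~1 voxel
    per axis), and additive Gaussian noise with sd = (mean vessel
    intensity)/snr is applied and clipped at zero.
    """
    from scipy import ndimage
    spacing = np.asarray(spacing_mm, dtype=float)
    if np.any(spacing <= 0):
        raise ParameterError("spacing must be positive")
    ext = np.asarray(tree.domain_box_mm, dtype=float)
    dims = (np.floor(ext / spacing + 1e-9).astype(int) + 1)
    vol = np.zeros(tuple(dims))
    edge = 0.35 * float(spacing.min())  # wall softening scale, sub-voxel
    for seg in tree.segments:
        a = np.asarray(seg.start_mm, float)
        b = np.asarray(seg.end_mm, float)
        r_eff = max(seg.radius_mm, 0.6 * float(spacing.min()))
        pad = r_eff + 4 * edge
        lo = np.maximum(np.floor((np.minimum(a, b) - pad) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((np.maximum(a, b) + pad) / spacing).astype(int) + 1, dims)
        if np.any(lo >= hi):
            continue
        grids = np.meshgrid(*[np.arange(lo[k], hi[k]) * spacing[k] for k in range(3)],
                            indexing="ij")
        pts = np.stack(grids, axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip(((pts - a) @ ab) / max(denom, 1e-12), 0.0, 1.0)
        closest = a + t[..., None] * ab
        dist = np.linalg.norm(pts - closest, axis=-1)
        inten = seg.radius_mm**2 * np.where(
            dist <= r_eff, 1.0, np.exp(-((dist - r_eff) / edge) ** 2)
        )
        sl = tuple(slice(lo[k], hi[k]) for k in range(3))
        np.maximum(vol[sl], inten, out=vol[sl])
    if psf_sigma_voxels > 0:
        vol = ndimage.gaussian_filter(vol, psf_sigma_voxels)
    if np.isfinite(snr):
        if snr <= 0:
            raise ParameterError("snr must be positive")
        rng = np.random.default_rng(seed)
        vessel_mean = vol[vol > 0].mean() if np.any(vol > 0) else 1.0
        vol = np.clip(vol + rng.normal(0, vessel_mean / snr, vol.shape), 0.0, None)
    return DopplerVolume(vol, tuple(spacing), origin_mm=(0.0, 0.0, 0.0))


def random_rigid_scale_transform(seed: int, center, max_translation_mm: float = 1.0,
                                 max_rotation_deg: float = 10.0,
                                 scale_range=(0.95, 1.05)) -> AffineTransform3D:
    """Seeded random rigid+scale perturbation about ``center`` (uniform draws)."""
    rng = np.random.default_rng(seed)
    t = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rng.uniform(-max_rotation_deg, max_rotation_deg))
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    rot = np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)
    scale = np.diag(rng.uniform(*scale_range, 3))
    return AffineTransform3D(rot @ scale, t, np.asarray(center, dtype=float))


def make_registration_phantom(seed: int, extents_mm=(6.3, 4.7, 6.2),
                              spacing_mm=(0.1, 0.1, 0.2), snr: float = 10.0,
                              depth: int = 5, n_roots: int = 3,
                              max_translation_mm: float = 1.0,
                              max_rotation_deg: float = 10.0,
                              scale_range=(0.95, 1.05)):
    """Fixed/moving Doppler volume pair with a known applied transform.

    Two independently noisy acquisitions of the same vascular tree; the moving
    one is additionally carried through a seeded random rigid+scale transform
    about the volume centre.  Returns (fixed, moving, applied_transform); a
    perfect registration recovers the applied transform's inverse.
    """
    from .registration import GridSpec, resample_volume

    tree = generate_vessel_tree(seed, BranchingConfig(domain_extents_mm=extents_mm,
                                                      depth=depth, n_roots=n_roots))
    fixed = rasterize_doppler_volume(tree, spacing_mm, snr=snr, seed=seed * 2 + 1)
    moving0 = rasterize_doppler_volume(tree, spacing_mm, snr=snr, seed=seed * 2 + 2)
    center = (np.asarray(extents_mm) / 2.0)
    applied = random_rigid_scale_transform(seed + 10_000, center,
                                           max_translation_mm, max_rotation_deg,
                                           scale_range)
    moving = resample_volume(moving0, applied, GridSpec.from_volume(moving0))
    return fixed, moving, applied


def simulate_frame_stack(n_frames: int, grid=(64, 64), tissue_rank: int = 3,
                         blood_mask: np.ndarray | None = None, blood_power: float = 1.0,
                         seed: int = 0, tissue_power: float = 100.0,
                         noise_power: float = 0.0, compound_rate_hz: float = 500.0,
                         prf_hz: float = 5500.0, n_angles: int = 11) -> FrameStack:
    """Rank-structured tissue + fast blood + white-noise compounded frame stack.

    Tissue is an exact sum of ``tissue_rank`` outer products of smooth spatial
    modes with slow temporal oscillations (so its Casorati rank is exactly
    ``tissue_rank``); blood is temporally white signal confined to
    ``blood_mask``; noise is white everywhere.  Powers are per-pixel variances.
    """
    from scipy import ndimage

    if tissue_rank >= n_frames:
        raise ParameterError("tissue_rank must be smaller than n_frames")
    rng = np.random.default_rng(seed)
    nx, nz = grid
    t = np.arange(n_frames) / compound_rate_hz
    data = np.zeros((nx, nz, n_frames))
    for k in range(tissue_rank):
        spatial = ndimage.gaussian_filter(rng.standard_normal((nx, nz)), min(nx, nz) / 8)
        spatial /= max(np.abs(spatial).max(), 1e-12)
        f_k = 0.5 + 1.5 * k
        temporal = np.cos(2 * np.pi * f_k * t + rng.uniform(0, 2 * np.pi))
        amp = np.sqrt(tissue_power) * 2.0 ** (-k)
        data += amp * spatial[:, :, None] * temporal[None, None, :]
    if blood_mask is not None and blood_power > 0 and np.any(blood_mask):
        m = np.asarray(blood_mask, bool)
        blood = rng.normal(0, np.sqrt(blood_power), (int(m.sum()), n_frames))
        data[m] += blood
    if noise_power > 0:
        data += rng.normal(0, np.sqrt(noise_power), data.shape)
    angles = tuple(np.linspace(-(n_angles // 2) * 2, (n_angles // 2) * 2, n_angles))
    return FrameStack(data, compound_rate_hz=compound_rate_hz, prf_hz=prf_hz,
                      angles_deg=angles)


def simulate_bubble_movie(tree: VesselTree, n_bubbles: int = 20,
                          frame_rate_hz: float = 1000.0, psf_sigma_px: float = 1.2,
                          seed: int = 0, n_frames: int = 100,
                          pixel_size_mm: float = 0.05,
                          speed_range_mm_s=(5.0, 20.0),
                          noise_sd: float = 0.0,
                          stagger_entry: bool = False,
                          slab_thickness_mm: float | None = None) -> tuple:
    """Render microbubbles flowing along vessel centerlines, with exact truth.

    Each bubble travels along one segment's centerline (projected onto the
    (x, z) imaging plane) at a constant seeded speed; frames carry a Gaussian
    point-spread blob per bubble.  The returned TrackSet is the exact
    ground-truth trajectory set (positions in mm, one point per frame while
    the bubble remains inside its segment).

    With ``slab_thickness_mm`` set, only vessels whose midpoint lies within
    an elevation slab of that thickness around the domain centre feed
    bubbles — emulating the finite slice thickness of a 2D acquisition,
    where out-of-plane vessels do not project onto the image and pile up.
    """
    if n_bubbles < 1:
        raise ParameterError("need at least one bubble")
    rng = np.random.default_rng(seed)
    ext = np.asarray(tree.domain_box_mm, dtype=float)
    # bubbles are seeded only on vessels inside the usable field of view:
    # a PSF window clipped by the image border biases the centroid, so real
    # processing crops edge detections rather than localizing them
    margin = (4.0 * psf_sigma_px + 1.0) * pixel_size_mm

    def in_fov(p):
        return (margin <= p[0] <= ext[0] - margin
                and margin <= p[1] <= ext[2] - margin)

    segments = [s for s in tree.segments
                if in_fov(((s.start_mm[0] + s.end_mm[0]) / 2.0,
                           (s.start_mm[2] + s.end_mm[2]) / 2.0))]
    if slab_thickness_mm is not None:
        y0 = ext[1] / 2.0
        segments = [s for s in segments
                    if abs((s.start_mm[1] + s.end_mm[1]) / 2.0 - y0)
                    <= slab_thickness_mm / 2.0]
    if not segments:
        raise ParameterError("no vessel lies inside the usable field of view")
    nx = int(np.floor(ext[0] / pixel_size_mm + 1e-9)) + 1
    nz = int(np.floor(ext[2] / pixel_size_mm + 1e-9)) + 1
    frames = np.zeros((nx, nz, n_frames))
    tracks = []
    # bubbles occupy distinct vessels when possible: two bubbles sharing one
    # centerline for a whole movie would be a single unresolvable spot
    if n_bubbles <= len(segments):
        seg_idx = rng.choice(len(segments), size=n_bubbles, replace=False)
    else:
        seg_idx = rng.integers(0, len(segments), n_bubbles)
    for b in range(n_bubbles):
        seg = segments[seg_idx[b]]
        a2 = np.asarray(seg.start_mm, float)[[0, 2]]
        b2 = np.asarray(seg.end_mm, float)[[0, 2]]
        seg_len = np.linalg.norm(b2 - a2)
        if seg_len < 1e-6:
            continue
        d = (b2 - a2) / seg_len
        speed = rng.uniform(*speed_range_mm_s)
        start_arc = rng.uniform(0, 0.5 * seg_len)
        start_frame = int(rng.integers(0, max(1, n_frames // 4))) if stagger_entry else 0
        fr, pos = [], []
        for f in range(start_frame, n_frames):
            arc = start_arc + speed * (f - start_frame) / frame_rate_hz
            if arc > seg_len:
                break
            p = a2 + arc * d
            if not in_fov(p):  # bubble leaves the usable field of view
                break
            pos.append(p)
            fr.append(f)
        if not fr:
            continue
        pos = np.array(pos)
        tracks.append(Track(np.array(fr), pos))
        px = pos / pixel_size_mm
        for f, (cx, cz) in zip(fr, px):
            x0, x1 = max(0, int(cx - 4 * psf_sigma_px)), min(nx, int(cx + 4 * psf_sigma_px) + 2)
            z0, z1 = max(0, int(cz - 4 * psf_sigma_px)), min(nz, int(cz + 4 * psf_sigma_px) + 2)
            gx, gz = np.mgrid[x0:x1, z0:z1]
            frames[x0:x1, z0:z1, f] += np.exp(
                -((gx - cx) ** 2 + (gz - cz) ** 2) / (2 * psf_sigma_px**2)
            )
    if noise_sd > 0:
        frames += rng.normal(0, noise_sd, frames.shape)
    stack = FrameStack(frames, compound_rate_hz=frame_rate_hz, prf_hz=9 * frame_rate_hz,
                       angles_deg=tuple(np.arange(-8, 9, 2)),
                       pixel_size_mm=(pixel_size_mm, pixel_size_mm))
    return stack, TrackSet(tracks=tracks, frame_rate_hz=frame_rate_hz)


def simulate_functional_timeseries(label_map: np.ndarray, stimulus: StimulusPattern,
                                   effects: dict, noise_sd: float = 0.02,
                                   rate_hz: float = 2.5,
                                   corr: np.ndarray | None = None,
                                   seed: int = 0, baseline: float = 100.0,
                                   voxel_noise_sd: float = 0.0,
                                   n_samples: int | None = None) -> np.ndarray:
    """CBV time series per voxel: baseline·(1 + effect·regressor) + noise.

    ``effects`` maps region ids of ``label_map`` to fractional CBV changes.
    With ``corr`` given, the noise is drawn at ROI level with that (PSD,
    unit-diagonal) correlation across the regions listed in sorted id order;
    ``voxel_noise_sd`` optionally adds independent per-voxel noise on top.
    Noise sd values are fractions of baseline.
    """
    labels = np.asarray(label_map)
    region_ids = sorted(int(v) for v in np.unique(labels) if v != 0)
    if any(k not in region_ids for k in effects):
        raise ParameterError("effects keys must be labels present in the map")
    reg = stimulus.boxcar(rate_hz)
    if n_samples is not None:
        reg = np.resize(reg, n_samples)
    nt = reg.size
    rng = np.random.default_rng(seed)
    out = np.zeros(labels.shape + (nt,))
    if corr is not None:
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (len(region_ids), len(region_ids)):
            raise ParameterError("corr must be ROI×ROI over the non-zero labels")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ParameterError("corr must be symmetric")
        w, v = np.linalg.eigh(corr)
        if w.min() < -1e-10:
            raise ParameterError("corr must be positive semi-definite")
        chol = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
        roi_noise = (chol @ rng.standard_normal((len(region_ids), nt)))
    for i, rid in enumerate(region_ids):
        mask = labels == rid
        effect = effects.get(rid, 0.0)
        sig = baseline * (1.0 + effect * reg)
        if noise_sd > 0:
            if corr is not None:
                noise = baseline * noise_sd * roi_noise[i]  # shared within the ROI
            else:
                noise = baseline * noise_sd * rng.standard_normal((int(mask.sum()), nt))
            out[mask] = sig + noise
        else:
            out[mask] = sig
    if voxel_noise_sd > 0:
        out[labels != 0] += baseline * voxel_noise_sd * rng.standard_normal(
            (int((labels != 0).sum()), nt))
    return out
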