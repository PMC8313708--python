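"""Vascular volume registration: Mattes mutual information + (1+1) evolution strategy.

The positioning system registers a subject's 3D Power Doppler volume to a
pre-aligned Doppler reference by maximizing the mutual information of the
joint intensity histogram (Parzen-smoothed, 50 bins by default, all spatial
samples) over a 12-parameter affine map, searched by an adaptive-radius (1+1)
evolution strategy on a multiresolution pyramid.  The module also carries the
evaluation metrics used to characterize registration quality: 3D normalized
cross-correlation peak value / location / width, and 3D landmark distance
statistics.

Transform convention: ``register_affine(moving, fixed)`` returns the affine
map taking *moving-space points into fixed space*; resampling a volume through
a transform pulls intensities through the transform's inverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal

from .doppler import DopplerVolume, ParameterError
from .geometry import AffineTransform3D

log = logging.getLogger(__name__)


class DegenerateOverlapError(RuntimeError):
    """Overlap between fixed and transformed moving support fell below threshold."""


class RegistrationFailureError(RuntimeError):
    pass


@dataclass(frozen=True)
class MIConfig:
    """Metric and optimizer settings for MI-driven affine registration.

    The (1+1)-ES search is conditioned per parameter (a unit optimizer step
    moves a translation ~10× further in mm than a rotation in radians — 1 rad
    of rotation ≈ 10 mm of motion at brain scale); ``register_affine`` stages
    the per-parameter scales internally, rigid-first then full affine.
    """

    n_bins: int = 50
    sampling: float = 1.0
    pyramid_levels: int = 3
    initial_radius: float = 0.25
    growth_factor: float = 1.05
    epsilon: float = 1.5e-6
    max_iterations: int = 600
    seed: int = 0
    min_overlap: float = 0.1

    def __post_init__(self):
        if self.n_bins < 2:
            raise ParameterError("need at least 2 histogram bins")
        if not 0 < self.sampling <= 1:
            raise ParameterError("sampling fraction must be in (0, 1]")


# --- Parzen mutual information ---------------------------------------------

def _bspline3(t):
    """Cubic B-spline kernel values for |t| ≤ 2 (vectorized)."""
    at = np.abs(t)
    out = np.zeros_like(at)
    m1 = at <= 1
    out[m1] = 2.0 / 3.0 - at[m1] ** 2 + at[m1] ** 3 / 2.0
    m2 = (at > 1) & (at < 2)
    out[m2] = (2.0 - at[m2]) ** 3 / 6.0
    return out


def _narrow_kernel(d):
    """B3(2d) for d ∈ [0, 1]: 2/3 − 4d² + 4d³ below d=0.5, 4(1−d)³/3 above."""
    return np.where(d <= 0.5, 2.0 / 3.0 - 4.0 * d * d * (1.0 - d),
                    4.0 / 3.0 * (1.0 - d) ** 3)


def _bin_coords(values, vmin, vmax, n_bins):
    """Continuous bin coordinates: vmin/vmax sit at the centres of the end bins."""
    if vmax - vmin <= 0:
        return np.zeros_like(values)
    return (values - vmin) / (vmax - vmin) * (n_bins - 1)


def _joint_histogram(uf, um, n_bins):
    """Parzen joint histogram: box kernel on the fixed axis, cubic B-spline
    rescaled to one-bin support on the moving axis."""
    f = np.clip(np.round(uf).astype(int), 0, n_bins - 1)
    j0 = np.floor(um).astype(int)
    j1 = j0 + 1
    w0 = _bspline3(2.0 * (um - j0))
    w1 = _bspline3(2.0 * (um - j1))
    wsum = np.maximum(w0 + w1, 1e-12)
    idx = np.concatenate([f * n_bins + np.clip(j0, 0, n_bins - 1),
                          f * n_bins + np.clip(j1, 0, n_bins - 1)])
    w = np.concatenate([w0 / wsum, w1 / wsum])
    hist = np.bincount(idx, weights=w, minlength=n_bins * n_bins)
    return hist.reshape(n_bins, n_bins) / len(uf)


def _mi_from_joint(p):
    pf = p.sum(axis=1)
    pm = p.sum(axis=0)
    nz = p > 0
    outer = pf[:, None] * pm[None, :]
    return float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))


class _MIEngine:
    """Repeated MI evaluation of one fixed/moving pair at one pyramid level.

    Precomputes the fixed-volume sample positions, their hard bin offsets and
    the moving-volume bin range so each candidate transform costs one matmul,
    one trilinear interpolation and one weighted bincount.
    """

    def __init__(self, fixed: DopplerVolume, moving: DopplerVolume, config: MIConfig):
        self.cfg = config
        # float32 keeps the interpolation memory-bound path fast; intensities
        # live in [0,1] so the precision loss is ~1e-7, far below bin width
        self.moving = np.ascontiguousarray(moving.intensity, dtype=np.float32)
        self.m_origin = np.array(moving.origin_mm)
        self.m_spacing = np.array(moving.spacing_mm)
        pts = fixed.voxel_centers_world()
        vf = fixed.intensity.reshape(-1)
        if config.sampling < 1.0:
            rng = np.random.default_rng(config.seed)
            keep = rng.random(len(pts)) < config.sampling
            pts, vf = pts[keep], vf[keep]
        self.points = pts
        fmin, fmax = float(fixed.intensity.min()), float(fixed.intensity.max())
        uf = _bin_coords(vf, fmin, fmax, config.n_bins)
        nb = config.n_bins
        self.f_base = np.clip(np.round(uf).astype(np.int64), 0, nb - 1) * nb
        self.mmin, self.mmax = float(self.moving.min()), float(self.moving.max())

    def evaluate(self, pull: AffineTransform3D, strict: bool = True) -> float:
        """MI in nats for the fixed→moving pull map; −inf (or raise) on
        degenerate overlap."""
        nb = self.cfg.n_bins
        # fold world→voxel scaling of the moving grid into the pull map
        lin = pull.linear / self.m_spacing[:, None]
        off = (pull.center + pull.translation - pull.linear @ pull.center
               - self.m_origin) / self.m_spacing
        coords = np.asarray((self.points @ lin.T + off).T, dtype=np.float32)
        vm = ndimage.map_coordinates(self.moving, coords, order=1,
                                     mode="constant", cval=np.nan)
        mask = ~np.isnan(vm)
        frac = mask.mean()
        if frac < self.cfg.min_overlap:
            if strict:
                raise DegenerateOverlapError(
                    f"overlap {frac:.1%} below {self.cfg.min_overlap:.0%}")
            return -np.inf
        um = _bin_coords(vm[mask], self.mmin, self.mmax, nb)
        f_base = self.f_base[mask]
        j0 = np.floor(um).astype(np.int64)
        d = um - j0
        # cubic B-spline rescaled to one-bin support: weight f(d) on the left
        # bin and f(1-d) on the right, renormalized
        w0 = _narrow_kernel(d)
        w1 = _narrow_kernel(1.0 - d)
        wsum = w0 + w1
        w0 /= wsum
        w1 /= wsum
        idx = np.concatenate([f_base + np.clip(j0, 0, nb - 1),
                              f_base + np.clip(j0 + 1, 0, nb - 1)])
        hist = np.bincount(idx, weights=np.concatenate([w0, w1]),
                           minlength=nb * nb)
        joint = hist.reshape(nb, nb) / mask.sum()
        return _mi_from_joint(joint)


def mattes_mi(fixed: DopplerVolume, moving: DopplerVolume,
              transform: AffineTransform3D | None = None,
              config: MIConfig | None = None) -> float:
    """Mattes mutual information (nats) between ``fixed`` and the moving volume
    seen through ``transform`` (a moving→fixed map; identity by default).

    Volumes should be normalized to [0, 1] upstream; all fixed-volume voxels
    are sampled unless ``config.sampling`` < 1.
    """
    cfg = config or MIConfig()
    engine = _MIEngine(fixed, moving, cfg)
    pull = (transform or AffineTransform3D.identity()).inverse()
    return engine.evaluate(pull, strict=True)


# --- (1+1) evolution strategy ----------------------------------------------

@dataclass(frozen=True)
class ESParams:
    initial_radius: float = 0.25
    growth_factor: float = 1.05
    epsilon: float = 1.5e-6
    max_iterations: int = 600
    scales: tuple | None = None


def one_plus_one_es(objective, x0, params: ESParams | None = None, seed: int = 0):
    """(1+1) evolution strategy maximizing ``objective``.

    One parent, one offspring: perturb the current best by an isotropic
    Gaussian scaled per-parameter, accept only improvements, expand the search
    radius by ``growth_factor`` on success and shrink it by
    growth_factor^(−1/4) on failure; stop when the radius drops below
    ``epsilon`` or ``max_iterations`` offspring have been tried.  Deterministic
    for a fixed seed.  Returns (best_x, trace) where the trace records
    (iteration, best_objective, radius) per iteration.
    """
    p = params or ESParams()
    x = np.asarray(x0, dtype=float).copy()
    scales = np.ones_like(x) if p.scales is None else np.asarray(p.scales, dtype=float)
    f = objective(x)
    if not np.isfinite(f):
        raise ParameterError("objective is not finite at the starting point")
    rng = np.random.default_rng(seed)
    radius = p.initial_radius
    shrink = p.growth_factor ** (-0.25)
    trace = []
    for it in range(p.max_iterations):
        if radius < p.epsilon:
            break
        cand = x + radius * scales * rng.standard_normal(x.size)
        fc = objective(cand)
        if fc > f:
            x, f = cand, fc
            radius *= p.growth_factor
        else:
            radius *= shrink
        trace.append((it, f, radius))
    return x, trace


# --- affine registration ----------------------------------------------------

def _downsample(vol: DopplerVolume, factor: int) -> DopplerVolume:
    if factor == 1:
        return vol
    data = ndimage.gaussian_filter(vol.intensity, sigma=factor / 2.0)
    data = data[::factor, ::factor, ::factor]
    return DopplerVolume(np.clip(data, 0, None),
                         tuple(s * factor for s in vol.spacing_mm),
                         vol.origin_mm, vol.axes)


def register_affine(moving: DopplerVolume, fixed: DopplerVolume,
                    config: MIConfig | None = None):
    """Affine registration of ``moving`` onto ``fixed`` by MI maximization.

    Coarse-to-fine over a Gaussian pyramid; at each level a (1+1)-ES searches
    the 12-parameter affine family (rotations, log-scales, shears,
    translations; rotation centre at the fixed-volume centroid).  Returns
    ``(transform, mi)`` with the moving→fixed transform and the final metric
    value; the result never scores below the identity transform.
    """
    cfg = config or MIConfig()
    center = np.array(fixed.origin_mm) + (np.array(fixed.shape) - 1) / 2.0 * np.array(fixed.spacing_mm)

    def pull_from(p):
        return AffineTransform3D.from_params(p, center=center)

    # rigid-first staging: the coarse levels and the first fine pass freeze
    # scales/shears (zero step scale), so the search cannot settle into a
    # rotation/shear-compensated optimum before the rigid pose is right;
    # full-affine passes then refine with annealed step scales
    rigid = (0.05,) * 3 + (0.0,) * 6 + (1.0,) * 3
    affine_1 = (0.05,) * 9 + (0.5,) * 3
    affine_2 = (0.02,) * 9 + (0.2,) * 3
    fine_schedule = [(rigid, cfg.initial_radius / 3.0),
                     (affine_1, cfg.initial_radius / 3.0),
                     (affine_2, cfg.initial_radius / 5.0)]

    x = np.zeros(12)
    factors = [2**k for k in range(cfg.pyramid_levels - 1, -1, -1)]
    engine = None
    started = False
    for li, f in enumerate(factors):
        fx = _downsample(fixed, f)
        mv = _downsample(moving, f)
        engine = _MIEngine(fx, mv, cfg)
        try:
            engine.evaluate(pull_from(x), strict=True)
            started = True
        except DegenerateOverlapError:
            if li == len(factors) - 1 and not started:
                raise RegistrationFailureError(
                    "degenerate overlap at every pyramid level") from None
            continue

        def objective(p, _e=engine):
            try:
                return _e.evaluate(pull_from(p), strict=False)
            except Exception:  # pragma: no cover - defensive
                return -np.inf

        if f > 1:
            passes = [(rigid, cfg.initial_radius / (li + 1))]
        else:
            passes = fine_schedule
        for r, (scales, radius) in enumerate(passes):
            es = ESParams(initial_radius=radius, growth_factor=cfg.growth_factor,
                          epsilon=cfg.epsilon, max_iterations=cfg.max_iterations,
                          scales=scales)
            x, _ = one_plus_one_es(objective, x, es, seed=cfg.seed + 7 * li + r)
    if engine is None:
        raise RegistrationFailureError("empty pyramid")
    mi_final = engine.evaluate(pull_from(x), strict=False)
    mi_identity = engine.evaluate(pull_from(np.zeros(12)), strict=False)
    if mi_identity > mi_final:
        log.warning("registration did not improve on identity; returning identity")
        x, mi_final = np.zeros(12), mi_identity
    return pull_from(x).inverse(), float(mi_final)


# --- resampling -------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    shape: tuple
    spacing_mm: tuple
    origin_mm: tuple = (0.0, 0.0, 0.0)

    @classmethod
    def from_volume(cls, vol: DopplerVolume) -> "GridSpec":
        return cls(tuple(vol.shape), tuple(vol.spacing_mm), tuple(vol.origin_mm))


def resample_volume(vol: DopplerVolume, transform: AffineTransform3D,
                    target_grid: GridSpec | None = None,
                    interp: str = "trilinear") -> DopplerVolume:
    """Resample ``vol`` through ``transform`` onto ``target_grid``.

    The output voxel at world position x receives ``vol(transform⁻¹(x))``
    (i.e. the volume is carried forward by the transform); voxels that map
    outside the source support are zero.
    """
    if interp not in ("trilinear", "nearest"):
        raise ParameterError("interp must be 'trilinear' or 'nearest'")
    grid = target_grid or GridSpec.from_volume(vol)
    inv = transform.inverse()
    idx = np.indices(grid.shape).reshape(3, -1).T.astype(float)
    world = idx * np.array(grid.spacing_mm) + np.array(grid.origin_mm)
    src = inv.apply(world)
    coords = ((src - np.array(vol.origin_mm)) / np.array(vol.spacing_mm)).T
    order = 1 if interp == "trilinear" else 0
    out = ndimage.map_coordinates(np.asarray(vol.intensity, float), coords,
                                  order=order, mode="constant", cval=0.0)
    return DopplerVolume(np.clip(out.reshape(grid.shape), 0, None),
                         grid.spacing_mm, grid.origin_mm, vol.axes)


# --- cross-correlation metrics ----------------------------------------------

@dataclass
class XCorrVolume:
    corr: np.ndarray
    zero_lag_index: tuple
    spacing_mm: tuple

    def lag_mm(self, index) -> np.ndarray:
        return (np.asarray(index) - np.asarray(self.zero_lag_index)) * np.asarray(self.spacing_mm)


@dataclass
class XCorrMetrics:
    peak_value: float
    peak_lag_mm: tuple
    fwhm_mm: tuple  # per-axis full width at half maximum; nan where undefined


def normalized_xcorr3(a: DopplerVolume, b: DopplerVolume) -> XCorrVolume:
    """Zero-mean, unit-normalized 3D cross-correlation over all integer lags.

    The peak lag reports the displacement of ``b`` relative to ``a``: if b is
    a copy of a shifted by +0.4 mm in x, the peak sits at lag (+0.4, 0, 0).
    """
    if tuple(a.spacing_mm) != tuple(b.spacing_mm):
        raise ParameterError("volumes must share voxel spacing")
    a0 = a.intensity - a.intensity.mean()
    b0 = b.intensity - b.intensity.mean()
    na, nb = np.linalg.norm(a0), np.linalg.norm(b0)
    if na == 0 or nb == 0:
        raise ParameterError("constant volume has undefined normalized correlation")
    corr = signal.correlate(b0, a0, mode="full", method="fft") / (na * nb)
    zero = tuple(n - 1 for n in a.shape)
    return XCorrVolume(corr=corr, zero_lag_index=zero, spacing_mm=tuple(a.spacing_mm))


def _fwhm_profile(profile: np.ndarray, peak_idx: int, spacing: float) -> float:
    pk = profile[peak_idx]
    half = pk / 2.0
    left = np.nan
    for i in range(peak_idx, 0, -1):
        if profile[i - 1] <= half:
            frac = (profile[i] - half) / (profile[i] - profile[i - 1])
            left = i - frac
            break
    right = np.nan
    for i in range(peak_idx, len(profile) - 1):
        if profile[i + 1] <= half:
            frac = (profile[i] - half) / (profile[i] - profile[i + 1])
            right = i + frac
            break
    return float((right - left) * spacing)


def xcorr_metrics(xc: XCorrVolume) -> XCorrMetrics:
    """Peak value, peak lag (mm) and per-axis FWHM of a correlation volume.

    The FWHM is measured on the axis profiles through the peak with linear
    interpolation of the half-maximum crossings; an axis whose profile never
    crosses half maximum inside the lag range reports nan.  Ties in the peak
    break to the first occurrence in scan order.
    """
    corr = xc.corr
    peak_flat = int(np.argmax(corr))
    peak_idx = np.unravel_index(peak_flat, corr.shape)
    value = float(corr[peak_idx])
    lag = tuple(float(v) for v in xc.lag_mm(peak_idx))
    fwhm = []
    for ax in range(3):
        sl = list(peak_idx)
        sl[ax] = slice(None)
        fwhm.append(_fwhm_profile(corr[tuple(sl)], peak_idx[ax], xc.spacing_mm[ax]))
    return XCorrMetrics(peak_value=value, peak_lag_mm=lag, fwhm_mm=tuple(fwhm))


# --- landmark statistics ----------------------------------------------------

@dataclass
class LandmarkSet:
    entries: dict  # name -> (x, y, z) mm

    def __post_init__(self):
        self.entries = {str(k): np.asarray(v, dtype=float).reshape(3)
                        for k, v in self.entries.items()}
        for name, p in self.entries.items():
            if not np.all(np.isfinite(p)):
                raise ParameterError(f"non-finite coordinates for landmark {name}")


@dataclass
class LandmarkDiscrepancy:
    distances_um: dict
    mean_um: float
    sd_um: float


def landmark_discrepancy(a: LandmarkSet, b: LandmarkSet) -> LandmarkDiscrepancy:
    """3D distance shift per shared landmark, with mean ± SD across landmarks (µm)."""
    shared = sorted(set(a.entries) & set(b.entries))
    if not shared:
        raise ParameterError("no shared landmark names")
    d = {n: float(np.linalg.norm(a.entries[n] - b.entries[n]) * 1000.0) for n in shared}
    vals = np.array(list(d.values()))
    return LandmarkDiscrepancy(distances_um=d, mean_um=float(vals.mean()),
                               sd_um=float(vals.std()))
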