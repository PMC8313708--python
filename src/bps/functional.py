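"""Task-evoked activation mapping and resting-state connectivity.

Activation: per-voxel ordinary least squares of the Doppler (CBV) signal on a
stimulus regressor, with the regression t statistic mapped through the exact
t→z distribution correspondence and thresholded under Bonferroni control.
Connectivity: 0.1 Hz low-pass filtered signals, Pearson correlation matrices
over atlas ROIs and seed-based correlation maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .doppler import ParameterError

Z_MAX = 38.0  # |z| cap: beyond this Φ underflows to 0/1 in float64


@dataclass(frozen=True)
class StimulusPattern:
    """Block stimulation protocol: a baseline then ``n_trials`` of ON/OFF."""

    baseline_s: float
    n_trials: int
    on_s: float
    off_s: float

    def __post_init__(self):
        if min(self.baseline_s, self.on_s, self.off_s) < 0 or self.n_trials < 0:
            raise ParameterError("stimulus durations and trial count must be non-negative")

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.n_trials * (self.on_s + self.off_s)

    def boxcar(self, rate_hz: float) -> np.ndarray:
        """0/1 regressor sampled at frame times t_i = i / rate."""
        if rate_hz <= 0:
            raise ParameterError("sampling rate must be positive")
        if self.total_s <= 0:
            raise ParameterError("zero-duration stimulus")
        n = int(round(self.total_s * rate_hz))
        t = np.arange(n) / rate_hz
        reg = np.zeros(n)
        period = self.on_s + self.off_s
        if self.n_trials > 0 and period > 0:
            rel = t - self.baseline_s
            in_trials = (rel >= 0) & (rel < self.n_trials * period)
            reg[in_trials & (np.mod(rel, period) < self.on_s)] = 1.0
        return reg


def gamma_hrf(rate_hz: float, peak_s: float = 1.5, fwhm_s: float = 1.5) -> np.ndarray:
    """Gamma-variate hemodynamic kernel, unit area, sampled at ``rate_hz``."""
    shape = 8.0 * np.log(2.0) * peak_s**2 / fwhm_s**2
    scale = peak_s / shape
    t = np.arange(0, peak_s + 5 * fwhm_s, 1.0 / rate_hz)
    h = stats.gamma.pdf(t, a=shape + 1, scale=scale)
    return h / h.sum()


def build_design(stimulus: StimulusPattern, rate_hz: float, convolve_hrf: bool = False) -> np.ndarray:
    """(time × 2) design matrix: intercept column and stimulus regressor."""
    reg = stimulus.boxcar(rate_hz)
    if convolve_hrf:
        reg = np.convolve(reg, gamma_hrf(rate_hz))[: reg.size]
    return np.column_stack([np.ones(reg.size), reg])


@dataclass
class ActivationMap:
    z: np.ndarray
    p_threshold: float
    significant: np.ndarray


def glm_zscores(series: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Per-voxel OLS z-scores for the stimulus regressor.

    ``series`` is (..., time); the t statistic β̂₁/SE(β̂₁) is mapped to a
    z-score through the exact t→normal quantile correspondence (not relabelled),
    capped at ±Z_MAX.  Zero-variance voxels report z = 0.
    """
    y = np.asarray(series, dtype=float)
    x = np.asarray(design, dtype=float)
    nt = x.shape[0]
    if y.shape[-1] != nt:
        raise ParameterError("time axis of series must match design rows")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ParameterError("rank-deficient design matrix")
    spatial = y.shape[:-1]
    yf = y.reshape(-1, nt)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = yf @ x @ xtx_inv.T              # (nvox, 2)
    resid = yf - beta @ x.T
    dof = nt - x.shape[1]
    sigma2 = np.sum(resid**2, axis=1) / dof
    se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[1, 1])
    z = np.zeros(yf.shape[0])
    flat = np.ptp(yf, axis=1) == 0
    ok = (se > 0) & ~flat
    t = beta[ok, 1] / se[ok]
    # two-tailed-symmetric mapping via the survival function keeps precision in the tails
    z[ok] = np.sign(t) * np.clip(stats.norm.isf(stats.t.sf(np.abs(t), dof)), -Z_MAX, Z_MAX)
    z[~ok & ~flat] = np.sign(beta[~ok & ~flat, 1]) * Z_MAX  # perfect fit, nonzero effect
    return z.reshape(spatial)


def bonferroni_threshold(alpha: float, n_voxels: int) -> float:
    """Per-voxel p-value threshold alpha / n_voxels."""
    if n_voxels < 1:
        raise ParameterError("need at least one voxel")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    return alpha / n_voxels


def activation_map(series: np.ndarray, design: np.ndarray, alpha: float = 0.05) -> ActivationMap:
    """GLM z-map with Bonferroni-corrected two-sided significance mask."""
    z = glm_zscores(series, design)
    p_thr = bonferroni_threshold(alpha, z.size)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return ActivationMap(z=z, p_threshold=p_thr, significant=p < p_thr)


def lowpass(series: np.ndarray, cutoff_hz: float, rate_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last (time) axis, DC gain 1."""
    if cutoff_hz >= rate_hz / 2:
        raise ParameterError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(series, dtype=float), axis=-1)


def seed_correlation_map(series: np.ndarray, seed_mask: np.ndarray) -> np.ndarray:
    """Pearson r between the seed-mean signal and every voxel.

    ``series`` is (..., time); ``seed_mask`` is boolean over the spatial axes.
    """
    y = np.asarray(series, dtype=float)
    mask = np.asarray(seed_mask, dtype=bool)
    if mask.shape != y.shape[:-1]:
        raise ParameterError("seed mask shape must match series spatial shape")
    if not mask.any():
        raise ParameterError("empty seed mask")
    seed = y[mask].mean(axis=0)
    if np.ptp(seed) == 0:
        raise ParameterError("seed signal has zero variance")
    yc = y - y.mean(axis=-1, keepdims=True)
    sc = seed - seed.mean()
    denom = np.sqrt(np.sum(yc**2, axis=-1) * np.sum(sc**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, np.sum(yc * sc, axis=-1) / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


@dataclass
class ConnectivityMatrix:
    r: np.ndarray
    roi_ids: list

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape[0] != self.r.shape[1] or len(self.roi_ids) != self.r.shape[0]:
            raise ParameterError("connectivity matrix must be square over roi_ids")


def connectivity_matrix(roi_signals: np.ndarray, roi_ids=None) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of (ROI × time) signals."""
    y = np.asarray(roi_signals, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2:
        raise ParameterError("need at least two ROI signals")
    flat = np.ptp(y, axis=1) == 0
    if flat.any():
        bad = [roi_ids[i] if roi_ids is not None else i for i in np.flatnonzero(flat)]
        raise ParameterError(f"constant ROI signal(s): {bad}")
    r = np.corrcoef(y)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    if roi_ids is None:
        roi_ids = list(range(y.shape[0]))
    return ConnectivityMatrix(r=r, roi_ids=list(roi_ids))


def fisher_ci_halfwidth(n_samples: int, confidence: float = 0.99) -> float:
    """Half-width of the Fisher-z confidence interval for a Pearson r."""
    if n_samples <= 3:
        raise ParameterError("need more than 3 samples")
    zq = stats.norm.isf((1.0 - confidence) / 2.0)
    return zq / np.sqrt(n_samples - 3)
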