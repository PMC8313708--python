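"""Power Doppler processing: SVD clutter filtering, block arithmetic, volume assembly.

An ultrafast acquisition produces a stack of compounded frames (each coherently
summed from several tilted plane-wave transmits).  Slow tissue motion dominates
the largest spatiotemporal singular components of the space×time (Casorati)
matrix; discarding them isolates the blood signal, whose per-pixel temporal
power is the Power Doppler image — the cerebral-blood-volume proxy every later
stage consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


@dataclass
class FrameStack:
    """Beamformed compounded frame ensemble, ``data`` shaped (nx, nz, nt).

    ``compound_rate_hz`` is the frame rate after angle compounding; when both
    ``prf_hz`` and ``angles_deg`` are given it must equal prf / n_angles.
    """

    data: np.ndarray
    compound_rate_hz: float | None = None
    prf_hz: float | None = None
    angles_deg: tuple = ()
    pixel_size_mm: tuple = (0.1, 0.1)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ParameterError("frame stack must be (nx, nz, nt)")
        if self.data.shape[2] < 2:
            raise ParameterError("frame stack needs at least 2 frames")
        if self.prf_hz and self.angles_deg and self.compound_rate_hz:
            expected = self.prf_hz / len(self.angles_deg)
            if abs(expected - self.compound_rate_hz) > 1e-6 * expected:
                raise ParameterError(
                    f"compound_rate {self.compound_rate_hz} Hz inconsistent with "
                    f"prf/n_angles = {expected} Hz"
                )

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def duration_s(self) -> float | None:
        if self.compound_rate_hz:
            return self.n_frames / self.compound_rate_hz
        return None


@dataclass
class DopplerVolume:
    """3D Power Doppler intensity grid on a Bregma-referenced mm lattice.

    World coordinate of voxel (i, j, k) is ``origin_mm + (i, j, k) * spacing_mm``
    (voxel centres); axes follow the package convention x lateral, y AP
    (posterior negative), z depth downward.
    """

    intensity: np.ndarray
    spacing_mm: tuple
    origin_mm: tuple = (0.0, 0.0, 0.0)
    axes: str = "x:lateral y:ap z:depth"

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ParameterError("volume must be 3D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ParameterError("spacing must be positive")
        if np.any(self.intensity < 0):
            raise ParameterError("Power Doppler intensity must be non-negative")

    @property
    def shape(self):
        return self.intensity.shape

    def voxel_centers_world(self) -> np.ndarray:
        """(N, 3) array of world coordinates of all voxel centres, x-fastest."""
        idx = np.indices(self.shape).reshape(3, -1).T.astype(float)
        return idx * np.array(self.spacing_mm) + np.array(self.origin_mm)

    def world_extent_mm(self):
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing_mm))


# --- acquisition arithmetic -------------------------------------------------

def compound_frame_rate(prf_hz: float, n_angles: int) -> float:
    """Compounded frame rate: PRF divided by the number of tilted plane waves."""
    if n_angles < 1:
        raise ParameterError("need at least one transmit angle")
    return prf_hz / n_angles


def doppler_frame_rate(block_frames: int, compound_rate_hz: float) -> tuple[float, float]:
    """(Doppler rate Hz, block duration s) for blocks of ``block_frames`` frames."""
    if block_frames < 1:
        raise ParameterError("block must contain at least one frame")
    return compound_rate_hz / block_frames, block_frames / compound_rate_hz


# --- clutter filtering ------------------------------------------------------

def casorati(stack_data: np.ndarray) -> np.ndarray:
    """Reshape (nx, nz, nt) to the (nx*nz, nt) Casorati matrix, x-fastest rows."""
    nx, nz, nt = stack_data.shape
    return stack_data.reshape(nx * nz, nt)


def svd_clutter_filter(stack: FrameStack, cutoff_rank: int) -> FrameStack:
    """Remove the ``cutoff_rank`` largest singular components (tissue clutter).

    The stack is reshaped space×time, decomposed by SVD with singular values
    sorted descending, and reconstructed from components of index ≥ cutoff_rank.
    """
    nt = stack.n_frames
    if not 0 <= cutoff_rank < nt:
        raise ParameterError(f"cutoff_rank must be in [0, {nt}), got {cutoff_rank}")
    if cutoff_rank == 0:
        return replace(stack, data=stack.data.copy())
    c = casorati(stack.data)
    u, s, vt = np.linalg.svd(c, full_matrices=False)
    s_f = s.copy()
    s_f[:cutoff_rank] = 0.0
    filtered = (u * s_f) @ vt
    return replace(stack, data=filtered.reshape(stack.data.shape))


def power_doppler(stack: FrameStack) -> np.ndarray:
    """Per-pixel mean squared magnitude over time of a clutter-filtered stack."""
    if stack.data.shape[2] == 0:
        raise ParameterError("empty stack")
    return np.mean(np.abs(stack.data) ** 2, axis=2)


# --- volume assembly and conditioning --------------------------------------

def assemble_volume(slices, step_mm: float, in_plane_spacing_mm,
                    first_slice_y_mm: float = 0.0) -> DopplerVolume:
    """Stack ordered 2D Power Doppler slices into a 3D volume.

    The first slice is the most anterior; successive slices step toward the
    posterior, so the elevation (y) axis runs anterior→posterior with spacing
    ``step_mm`` and decreasing Bregma coordinate.  Internally the volume is
    stored with y increasing, so the slice order is reversed into the grid.
    """
    if step_mm <= 0:
        raise ParameterError("slice step must be positive")
    slices = [np.asarray(s, dtype=float) for s in slices]
    shape0 = slices[0].shape
    if any(s.shape != shape0 for s in slices):
        raise ParameterError("all slices must share the same shape")
    # slice i lives at y = first_slice_y_mm - i*step; grid stores ascending y
    stacked = np.stack(slices[::-1], axis=1)  # (nx, ny, nz)
    ny = len(slices)
    origin_y = first_slice_y_mm - (ny - 1) * step_mm
    sx, sz = in_plane_spacing_mm
    return DopplerVolume(
        stacked,
        spacing_mm=(sx, step_mm, sz),
        origin_mm=(0.0, origin_y, 0.0),
    )


def coronal_slice(vol: DopplerVolume, y_index: int) -> np.ndarray:
    """The stored (x, z) section at elevation index ``y_index``."""
    return vol.intensity[:, y_index, :]


def normalize_for_registration(vol: DopplerVolume, clip_percentiles=(1.0, 99.0)) -> DopplerVolume:
    """Log-compress, percentile-clip and rescale a volume to [0, 1].

    Histogram-based similarity metrics are dominated by the huge dynamic range
    of Power Doppler; log compression plus clipping spreads vascular intensity
    over the histogram. A constant volume maps to all-zeros (logged).
    """
    low, high = clip_percentiles
    if not (0 <= low < high <= 100):
        raise ParameterError("percentiles must satisfy 0 <= low < high <= 100")
    data = np.log1p(vol.intensity)
    lo, hi = np.percentile(data, [low, high])
    if hi - lo <= 0:
        log.warning("normalize_for_registration: constant volume, returning zeros")
        out = np.zeros_like(data)
    else:
        out = (np.clip(data, lo, hi) - lo) / (hi - lo)
    return DopplerVolume(out, vol.spacing_mm, vol.origin_mm, vol.axes)
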