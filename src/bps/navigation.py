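"""Atlas-guided neuronavigation: label propagation, ROI extraction, probe planes.

Once the subject volume is registered, composing the subject→reference and
reference→atlas transforms lets atlas labels be overlaid on the live Doppler
frame, ROI signals be extracted automatically, and new imaging planes be
defined from two user markers and converted into motor positions of the
4-DOF motorized probe stage (x, y, z translations + yaw about the vertical).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .doppler import DopplerVolume, ParameterError
from .geometry import AffineTransform3D
from .registration import GridSpec


class UnsupportedOrientationError(ValueError):
    """The requested plane is outside the stage's reachable (vertical) family."""


@dataclass
class AtlasVolume:
    """Integer label grid plus ontology table (id, acronym, name, parent_id, group)."""

    labels: np.ndarray
    spacing_mm: tuple
    origin_mm: tuple
    ontology: pd.DataFrame

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ParameterError("atlas labels must be integers")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        known = set(int(i) for i in self.ontology["id"])
        if not present <= known:
            raise ParameterError(f"labels missing from ontology: {sorted(present - known)}")
        # parent links must be acyclic
        parent = dict(zip(self.ontology["id"], self.ontology["parent_id"]))
        for start in parent:
            node, seen = start, set()
            while node in parent and parent[node] != 0:
                if node in seen:
                    raise ParameterError("ontology parent links contain a cycle")
                seen.add(node)
                node = parent[node]

    def region_ids(self) -> list:
        return [int(i) for i in self.ontology["id"] if int(i) in
                set(int(v) for v in np.unique(self.labels))]


def make_synthetic_atlas(shape=(64, 48, 32), spacing_mm=(0.1, 0.125, 0.2),
                         origin_mm=(0.0, 0.0, 0.0), n_cortex: int = 40,
                         n_thalamus: int = 20, n_hypothalamus: int = 10) -> AtlasVolume:
    """Deterministic geometric mini-atlas standing in for a real reference atlas
    (synthetic; labelled as such).

    A brain-shaped ellipsoid is split into an outer cortical shell and deep
    nuclei; each group is tiled into regions by angular sector and
    antero-posterior slab, producing ~70 regions grouped into isocortex,
    thalamus and hypothalamus with a two-level ontology.
    """
    nx, ny, nz = shape
    sp = np.asarray(spacing_mm)
    grid = np.indices(shape).astype(float)
    world = grid * sp[:, None, None, None]
    c = (np.array(shape) - 1) * sp / 2.0
    r = (np.array(shape) - 1) * sp / 2.0 * np.array([0.9, 0.95, 0.9])
    u = (world - c[:, None, None, None]) / r[:, None, None, None]
    rho = np.sqrt((u**2).sum(axis=0))
    brain = rho <= 1.0
    labels = np.zeros(shape, dtype=np.int32)
    theta = np.arctan2(u[2], u[0])          # angle in the coronal (x, z) plane
    ap = np.clip((u[1] + 1) / 2, 0, 1 - 1e-9)  # normalized AP position

    def tile(mask, n_regions, base_id):
        n_sector = max(1, int(np.round(np.sqrt(n_regions))))
        n_slab = max(1, int(np.ceil(n_regions / n_sector)))
        sector = np.floor((theta + np.pi) / (2 * np.pi) * n_sector).astype(int)
        slab = np.floor(ap * n_slab).astype(int)
        rid = base_id + (slab * n_sector + np.clip(sector, 0, n_sector - 1))
        labels[mask] = np.clip(rid[mask], base_id, base_id + n_regions - 1)

    cortex = brain & (rho > 0.62)
    thal = brain & (rho <= 0.62) & (u[2] < 0.15)
    hypo = brain & (rho <= 0.62) & (u[2] >= 0.15)  # most ventral (z down)
    tile(cortex, n_cortex, 100)
    tile(thal, n_thalamus, 300)
    tile(hypo, n_hypothalamus, 500)
    rows = [{"id": 1, "acronym": "ISO", "name": "isocortex", "parent_id": 0, "group": "isocortex"},
            {"id": 2, "acronym": "TH", "name": "thalamus", "parent_id": 0, "group": "thalamus"},
            {"id": 3, "acronym": "HY", "name": "hypothalamus", "parent_id": 0, "group": "hypothalamus"}]
    for base, n, parent, grp, tag in ((100, n_cortex, 1, "isocortex", "CTX"),
                                      (300, n_thalamus, 2, "thalamus", "THA"),
                                      (500, n_hypothalamus, 3, "hypothalamus", "HYP")):
        for k in range(n):
            rows.append({"id": base + k, "acronym": f"{tag}{k:02d}",
                         "name": f"synthetic {grp} region {k}", "parent_id": parent,
                         "group": grp})
    return AtlasVolume(labels, tuple(spacing_mm), tuple(origin_mm), pd.DataFrame(rows))


# --- transform composition and label propagation ----------------------------

def compose_transforms(ref_to_atlas: AffineTransform3D,
                       subject_to_ref: AffineTransform3D) -> AffineTransform3D:
    """Subject→atlas map: apply subject→reference, then reference→atlas."""
    return ref_to_atlas.compose(subject_to_ref)


def propagate_labels(atlas: AtlasVolume, subject_to_atlas: AffineTransform3D,
                     subject_grid: GridSpec) -> np.ndarray:
    """Nearest-neighbour atlas labels sampled at subject voxel centres.

    Each subject voxel centre is mapped into atlas space through
    ``subject_to_atlas``; voxels falling outside the atlas get label 0.
    Labels are never interpolated, so no new ids can appear.
    """
    idx = np.indices(subject_grid.shape).reshape(3, -1).T.astype(float)
    world = idx * np.array(subject_grid.spacing_mm) + np.array(subject_grid.origin_mm)
    in_atlas = subject_to_atlas.apply(world)
    coords = ((in_atlas - np.array(atlas.origin_mm)) / np.array(atlas.spacing_mm)).T
    out = ndimage.map_coordinates(atlas.labels, coords, order=0,
                                  mode="constant", cval=0)
    return out.reshape(subject_grid.shape).astype(atlas.labels.dtype)


def extract_roi_signals(series: np.ndarray, labels: np.ndarray,
                        ontology: pd.DataFrame, min_voxels: int = 1):
    """Per-ROI spatially averaged time series.

    Returns (signals, meta): ``signals`` is ROI×time in ontology row order
    restricted to labels present in the grid; ROIs smaller than
    ``min_voxels`` are dropped (and listed in the meta table with kept=False).
    """
    series = np.asarray(series, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != series.shape[:-1]:
        raise ParameterError("labels grid must match series spatial shape")
    present = set(int(v) for v in np.unique(labels)) - {0}
    rows, signals = [], []
    for _, rec in ontology.iterrows():
        rid = int(rec["id"])
        if rid not in present:
            continue
        mask = labels == rid
        n = int(mask.sum())
        kept = n >= min_voxels
        rows.append({"id": rid, "acronym": rec.get("acronym", str(rid)),
                     "group": rec.get("group", ""), "n_voxels": n, "kept": kept})
        if kept:
            signals.append(series[mask].mean(axis=0))
    if not signals:
        raise ParameterError("no ROI meets the minimum voxel count")
    meta = pd.DataFrame(rows)
    return np.array(signals), meta


# --- plane definition and stage kinematics ----------------------------------

@dataclass(frozen=True)
class PlaneSpec:
    """Imaging plane: point on plane, in-plane unit vectors u (probe lateral)
    and v (probe axial/depth), and normal = u × v."""

    point_mm: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        for name in ("point_mm", "u", "v"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        if abs(np.linalg.norm(self.u) - 1) > 1e-9 or abs(np.linalg.norm(self.v) - 1) > 1e-9:
            raise ParameterError("u and v must be unit vectors")
        if abs(self.u @ self.v) > 1e-9:
            raise ParameterError("u and v must be orthogonal")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u, self.v)

    def contains(self, point, tol=1e-10) -> bool:
        return abs(float(self.normal @ (np.asarray(point, float) - self.point_mm))) < tol


@dataclass(frozen=True)
class StagePose:
    """4-DOF motor position: mm translations and yaw (degrees) about vertical."""

    x_mm: float
    y_mm: float
    z_mm: float
    yaw_deg: float

    def __post_init__(self):
        if not -180.0 < self.yaw_deg <= 180.0:
            raise ParameterError("yaw must lie in (-180, 180]")


def plane_from_markers(m1, m2, min_horizontal_mm: float = 0.1) -> PlaneSpec:
    """Vertical imaging plane through two user markers.

    The plane contains both markers and the vertical (z) direction: u is the
    normalized horizontal component of (m2 − m1), v is +z, and the plane point
    is the midpoint of the markers.  Markers that are (nearly) vertically
    stacked leave the plane under-determined.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    horiz = (m2 - m1) * np.array([1.0, 1.0, 0.0])
    if np.linalg.norm(horiz) < min_horizontal_mm:
        raise ParameterError(
            "markers are vertically stacked: horizontal separation "
            f"{np.linalg.norm(horiz):.3g} mm under-determines the plane")
    u = horiz / np.linalg.norm(horiz)
    v = np.array([0.0, 0.0, 1.0])
    return PlaneSpec(point_mm=(m1 + m2) / 2.0, u=u, v=v)


def forward_kinematics(pose: StagePose) -> PlaneSpec:
    """Plane produced by the stage at ``pose``: the probe's lateral axis is
    +x rotated by yaw about the vertical, its axial axis is +z (depth)."""
    psi = np.radians(pose.yaw_deg)
    u = np.array([np.cos(psi), np.sin(psi), 0.0])
    return PlaneSpec(point_mm=np.array([pose.x_mm, pose.y_mm, pose.z_mm]),
                     u=u, v=np.array([0.0, 0.0, 1.0]))


def solve_stage_pose(plane: PlaneSpec, tol: float = 1e-8) -> StagePose:
    """Invert the stage kinematics for a vertical plane.

    Only planes containing the vertical direction (normal ⊥ z) are reachable
    by the 4-DOF stage; anything else raises UnsupportedOrientationError.
    The solved pose reproduces the plane's point and normal exactly.
    """
    n = plane.normal
    if abs(n[2]) > 1e-6:
        raise UnsupportedOrientationError(
            f"plane normal has vertical component {n[2]:.3g}; only vertical "
            "planes are reachable by the 4-DOF stage")
    u = plane.u
    if abs(u[2]) > 1e-6:
        # rebuild the in-plane frame with v = +z
        u = np.cross(np.array([0.0, 0.0, 1.0]), n)
        u /= np.linalg.norm(u)
    yaw = float(np.degrees(np.arctan2(u[1], u[0])))
    if yaw <= -180.0:
        yaw += 360.0
    px, py, pz = plane.point_mm
    return StagePose(x_mm=float(px), y_mm=float(py), z_mm=float(pz), yaw_deg=yaw)


# --- oblique slicing ---------------------------------------------------------

def slice_volume(vol: DopplerVolume, plane: PlaneSpec, out_spacing_mm=(0.1, 0.1),
                 extent_mm=(12.8, 6.0), labels: np.ndarray | None = None,
                 center_offset_mm=(0.0, 0.0)):
    """Trilinear oblique slice of a volume on the plane's (u, v) grid.

    The grid is centred on the plane point (optionally offset along u, v);
    ``labels``, when given, is sliced with nearest-neighbour sampling and the
    function returns (slice, label_slice).  Raises if the plane misses the
    volume entirely.
    """
    su, sv = out_spacing_mm
    if su <= 0 or sv <= 0:
        raise ParameterError("slice spacing must be positive")
    nu = int(np.floor(extent_mm[0] / su + 1e-9)) + 1
    nv = int(np.floor(extent_mm[1] / sv + 1e-9)) + 1
    iu = (np.arange(nu) - (nu - 1) / 2.0) * su + center_offset_mm[0]
    iv = (np.arange(nv) - (nv - 1) / 2.0) * sv + center_offset_mm[1]
    uu, vv = np.meshgrid(iu, iv, indexing="ij")
    pts = (plane.point_mm[None, None, :] + uu[..., None] * plane.u[None, None, :]
           + vv[..., None] * plane.v[None, None, :])
    coords = ((pts - np.array(vol.origin_mm)) / np.array(vol.spacing_mm))
    inside = np.all((coords >= -0.5) & (coords <= np.array(vol.shape) - 0.5), axis=-1)
    if not inside.any():
        raise ParameterError("plane does not intersect the volume")
    cT = coords.reshape(-1, 3).T
    img = ndimage.map_coordinates(vol.intensity, cT, order=1,
                                  mode="constant", cval=0.0).reshape(nu, nv)
    if labels is None:
        return img
    lab = ndimage.map_coordinates(np.asarray(labels), cT, order=0,
                                  mode="constant", cval=0).reshape(nu, nv)
    return img, lab
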