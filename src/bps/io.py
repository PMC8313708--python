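"""Readers and writers for the formats shared across the pipeline.

Volumes travel as NIfTI (voxel spacing and the Bregma-referenced origin in the
affine), frame stacks and bubble movies as HDF5 (`frames` dataset with
acquisition attributes), tracks/landmarks/ontologies as CSV, transforms,
poses and stimulus protocols as JSON, and super-resolution maps as 32-bit
TIFF with a JSON sidecar.  Write-then-read round-trips preserve array data
bit-exactly and metadata to float tolerance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .doppler import DopplerVolume, FrameStack
from .functional import StimulusPattern
from .navigation import AtlasVolume, StagePose
from .registration import LandmarkSet
from .ulm import Track, TrackSet, ULMMaps


def provenance(config: dict | None = None, seed: int | None = None) -> dict:
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return {"package": "bps-neuronav", "version": __version__, "seed": seed,
            "config_sha256": hashlib.sha256(blob).hexdigest()[:16]}


# --- volumes (NIfTI) --------------------------------------------------------

def save_volume(path, vol: DopplerVolume) -> None:
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    affine[:3, 3] = vol.origin_mm
    img = nib.Nifti1Image(np.asarray(vol.intensity, dtype=np.float64), affine)
    img.header["descrip"] = vol.axes.encode()[:79]
    nib.save(img, str(path))


def load_volume(path) -> DopplerVolume:
    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(float(affine[i, i]) for i in range(3))
    origin = tuple(float(v) for v in affine[:3, 3])
    axes = img.header["descrip"].tobytes().split(b"\x00")[0].decode() or "x:lateral y:ap z:depth"
    return DopplerVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin, axes)


def save_labels(path, labels: np.ndarray, spacing_mm, origin_mm=(0, 0, 0)) -> None:
    affine = np.diag(list(spacing_mm) + [1.0])
    affine[:3, 3] = origin_mm
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int32), affine), str(path))


def load_atlas(label_path, ontology_path) -> AtlasVolume:
    img = nib.load(str(label_path))
    spacing = tuple(float(img.affine[i, i]) for i in range(3))
    origin = tuple(float(v) for v in img.affine[:3, 3])
    ontology = pd.read_csv(ontology_path)
    return AtlasVolume(np.asarray(img.dataobj, dtype=np.int32), spacing, origin, ontology)


def save_atlas(label_path, ontology_path, atlas: AtlasVolume) -> None:
    save_labels(label_path, atlas.labels, atlas.spacing_mm, atlas.origin_mm)
    atlas.ontology.to_csv(ontology_path, index=False)


# --- frame stacks (HDF5) ----------------------------------------------------

def save_frame_stack(path, stack: FrameStack) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("frames", data=stack.data)
        if stack.compound_rate_hz:
            d.attrs["frame_rate_hz"] = stack.compound_rate_hz
        if stack.prf_hz:
            d.attrs["prf_hz"] = stack.prf_hz
        if stack.angles_deg:
            d.attrs["angles_deg"] = list(stack.angles_deg)
        d.attrs["pixel_size_mm"] = list(stack.pixel_size_mm)


def load_frame_stack(path) -> FrameStack:
    with h5py.File(path, "r") as f:
        d = f["frames"]
        return FrameStack(
            data=d[()],
            compound_rate_hz=float(d.attrs.get("frame_rate_hz", 0)) or None,
            prf_hz=float(d.attrs.get("prf_hz", 0)) or None,
            angles_deg=tuple(d.attrs.get("angles_deg", ())),
            pixel_size_mm=tuple(d.attrs.get("pixel_size_mm", (0.1, 0.1))),
        )


# --- tracks and landmarks (CSV) ---------------------------------------------

def save_tracks(path, ts: TrackSet, with_velocity: bool = True) -> None:
    rows = []
    for tid, tr in enumerate(ts.tracks):
        vel = ts.velocities_mm_s(tr) if with_velocity else np.zeros_like(tr.positions_mm)
        for k in range(len(tr)):
            rows.append({"track_id": tid, "frame": int(tr.frames[k]),
                         "x_mm": tr.positions_mm[k, 0], "z_mm": tr.positions_mm[k, 1],
                         "vx_mm_s": vel[k, 0], "vz_mm_s": vel[k, 1]})
    pd.DataFrame(rows, columns=["track_id", "frame", "x_mm", "z_mm",
                                "vx_mm_s", "vz_mm_s"]).to_csv(path, index=False)


def load_tracks(path, frame_rate_hz: float = 1000.0) -> TrackSet:
    df = pd.read_csv(path)
    tracks = []
    for _, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        tracks.append(Track(g["frame"].to_numpy(),
                            g[["x_mm", "z_mm"]].to_numpy()))
    return TrackSet(tracks=tracks, frame_rate_hz=frame_rate_hz)


def save_landmarks(path, lm: LandmarkSet) -> None:
    rows = [{"name": n, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]}
            for n, p in lm.entries.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_landmarks(path) -> LandmarkSet:
    df = pd.read_csv(path)
    return LandmarkSet({r["name"]: (r["x_mm"], r["y_mm"], r["z_mm"])
                        for _, r in df.iterrows()})


# --- maps, poses, stimuli ---------------------------------------------------

def save_ulm_maps(prefix, maps: ULMMaps) -> None:
    """Write `<prefix>_density.tif`, `<prefix>_velocity.tif` and a JSON sidecar."""
    prefix = str(prefix)
    tifffile.imwrite(prefix + "_density.tif", maps.density.astype(np.float32))
    tifffile.imwrite(prefix + "_velocity.tif", maps.velocity.astype(np.float32))
    Path(prefix + "_maps.json").write_text(json.dumps({
        "pixel_size_mm": maps.pixel_size_mm, "origin_mm": list(maps.origin_mm)}))


def load_ulm_maps(prefix) -> ULMMaps:
    prefix = str(prefix)
    meta = json.loads(Path(prefix + "_maps.json").read_text())
    return ULMMaps(density=tifffile.imread(prefix + "_density.tif").astype(float),
                   velocity=tifffile.imread(prefix + "_velocity.tif").astype(float),
                   pixel_size_mm=float(meta["pixel_size_mm"]),
                   origin_mm=tuple(meta["origin_mm"]))


def save_pose(path, pose: StagePose, provenance_block: dict | None = None) -> None:
    payload = {"x_mm": pose.x_mm, "y_mm": pose.y_mm, "z_mm": pose.z_mm,
               "yaw_deg": pose.yaw_deg}
    if provenance_block:
        payload["provenance"] = provenance_block
    Path(path).write_text(json.dumps(payload, indent=2))


def load_pose(path) -> StagePose:
    d = json.loads(Path(path).read_text())
    return StagePose(d["x_mm"], d["y_mm"], d["z_mm"], d["yaw_deg"])


def save_stimulus(path, stim: StimulusPattern) -> None:
    Path(path).write_text(json.dumps({
        "baseline_s": stim.baseline_s, "n_trials": stim.n_trials,
        "on_s": stim.on_s, "off_s": stim.off_s}))


def load_stimulus(path) -> StimulusPattern:
    d = json.loads(Path(path).read_text())
    return StimulusPattern(d["baseline_s"], d["n_trials"], d["on_s"], d["off_s"])
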