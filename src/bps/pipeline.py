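"""End-to-end positioning session on one subject volume.

Chains the online workflow: normalize both volumes → affine MI registration
of the subject to the Doppler reference → composition with the pre-computed
reference→atlas transform → atlas label propagation into the subject grid —
and writes the session bundle (transform JSON, labelled NIfTI, markdown QC
report with the MI trace and cross-correlation metrics).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .doppler import DopplerVolume, normalize_for_registration
from .geometry import AffineTransform3D
from .navigation import AtlasVolume, compose_transforms, propagate_labels
from .registration import (GridSpec, MIConfig, RegistrationFailureError,
                           normalized_xcorr3, register_affine, resample_volume,
                           xcorr_metrics)

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


def _save_overlay_png(path, reference: DopplerVolume, moved: DopplerVolume) -> None:
    """Green/magenta mid-coronal overlay: aligned vasculature renders white."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = reference.shape[1] // 2
    g = reference.intensity[:, y, :].T
    m = moved.intensity[:, y, :].T
    scale = max(g.max(), m.max(), 1e-12)
    rgb = np.stack([m / scale, g / scale, m / scale], axis=-1)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.imshow(np.clip(rgb, 0, 1), origin="upper", aspect="auto")
    ax.set_title(f"coronal overlay at y-index {y} (green: ref, magenta: moved)")
    ax.set_xlabel("x (lateral)")
    ax.set_ylabel("z (depth)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


@dataclass
class PipelineConfig:
    reference_path: str | None = None
    atlas_labels_path: str | None = None
    atlas_ontology_path: str | None = None
    ref_to_atlas_path: str | None = None
    mi: MIConfig = field(default_factory=MIConfig)
    clip_percentiles: tuple = (1.0, 99.0)
    seed: int = 0

    def validate(self):
        for name in ("reference_path", "atlas_labels_path", "atlas_ontology_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} does not exist: {p}")


@dataclass
class SessionBundle:
    subject_to_ref: AffineTransform3D
    subject_to_atlas: AffineTransform3D
    final_mi: float
    labels: np.ndarray
    xcorr: object
    outputs: dict


def run_bps(config: PipelineConfig, subject: DopplerVolume,
            reference: DopplerVolume | None = None,
            atlas: AtlasVolume | None = None,
            ref_to_atlas: AffineTransform3D | None = None,
            out_dir=None) -> SessionBundle:
    """Run the full positioning chain on one subject volume.

    Reference, atlas and the reference→atlas transform may be passed directly
    or through paths in ``config`` (checked before any computation).  On
    registration failure the QC artifacts written so far are kept and the
    error propagates.
    """
    config.validate()
    if reference is None:
        if config.reference_path is None:
            raise ConfigurationError("no reference volume given")
        reference = io.load_volume(config.reference_path)
    if atlas is None:
        if config.atlas_labels_path is None or config.atlas_ontology_path is None:
            raise ConfigurationError("no atlas given")
        atlas = io.load_atlas(config.atlas_labels_path, config.atlas_ontology_path)
    if ref_to_atlas is None:
        if config.ref_to_atlas_path is not None:
            ref_to_atlas = AffineTransform3D.load_json(config.ref_to_atlas_path)
        else:
            ref_to_atlas = AffineTransform3D.identity()

    outputs = {}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    prov = io.provenance({"mi": str(config.mi)}, config.seed)

    t0 = time.perf_counter()
    ref_n = normalize_for_registration(reference, config.clip_percentiles)
    sub_n = normalize_for_registration(subject, config.clip_percentiles)
    try:
        subject_to_ref, final_mi = register_affine(sub_n, ref_n, config.mi)
    except RegistrationFailureError:
        if out_dir is not None:
            (out_dir / "qc_report.md").write_text(
                "# BPS session QC\n\nRegistration FAILED: degenerate overlap.\n")
        raise
    log.info("stage=register elapsed=%.1fs final_mi=%.4f", time.perf_counter() - t0, final_mi)

    moved = resample_volume(sub_n, subject_to_ref, GridSpec.from_volume(ref_n))
    xc = xcorr_metrics(normalized_xcorr3(ref_n, moved))
    subject_to_atlas = compose_transforms(ref_to_atlas, subject_to_ref)
    labels = propagate_labels(atlas, subject_to_atlas, GridSpec.from_volume(subject))
    log.info("stage=propagate n_labels=%d", len(np.unique(labels)) - 1)

    if out_dir is not None:
        tpath = out_dir / "subject_to_ref.json"
        subject_to_ref.save_json(tpath, provenance=prov)
        outputs["transform"] = str(tpath)
        apath = out_dir / "subject_to_atlas.json"
        subject_to_atlas.save_json(apath, provenance=prov)
        outputs["atlas_transform"] = str(apath)
        lpath = out_dir / "subject_labels.nii.gz"
        io.save_labels(lpath, labels, subject.spacing_mm, subject.origin_mm)
        outputs["labels"] = str(lpath)
        overlay = out_dir / "qc_overlay.png"
        _save_overlay_png(overlay, ref_n, moved)
        outputs["overlay"] = str(overlay)
        report = out_dir / "qc_report.md"
        report.write_text("\n".join([
            "# BPS session QC",
            "",
            f"- provenance: `{json.dumps(prov)}`",
            f"- final mutual information: **{final_mi:.4f} nats**",
            f"- NCC peak value: **{xc.peak_value:.3f}**",
            f"- NCC peak lag (mm): {tuple(round(v, 3) for v in xc.peak_lag_mm)}",
            f"- NCC FWHM (mm): {tuple(round(v, 3) for v in xc.fwhm_mm)}",
            f"- atlas regions propagated: {len(np.unique(labels)) - 1}",
            "",
            "![green: reference, magenta: moved subject](qc_overlay.png)",
            "",
        ]))
        outputs["report"] = str(report)
    return SessionBundle(subject_to_ref=subject_to_ref, subject_to_atlas=subject_to_atlas,
                         final_mi=final_mi, labels=labels, xcorr=xc, outputs=outputs)
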