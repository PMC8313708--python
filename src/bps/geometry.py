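"""World-space affine transforms used throughout the positioning pipeline.

All transforms act on points given in millimetres in the common stereotaxic
frame (x lateral left→right, y antero-posterior with Bregma at 0 and posterior
negative, z depth positive downward).  A transform is stored as a 3×3 linear
part, a translation and a rotation centre, and maps a point ``p`` to

    linear @ (p - center) + center + translation
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class SingularTransformError(ValueError):
    """Raised when a transform with non-positive determinant is built or inverted."""


@dataclass(frozen=True)
class AffineTransform3D:
    linear: np.ndarray
    translation: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "linear", np.asarray(self.linear, dtype=float).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        if not np.all(np.isfinite(self.linear)) or not np.all(np.isfinite(self.translation)):
            raise SingularTransformError("non-finite transform entries")
        if np.linalg.det(self.linear) <= 0:
            raise SingularTransformError(
                f"transform must be orientation-preserving (det={np.linalg.det(self.linear):g})"
            )

    @classmethod
    def identity(cls) -> "AffineTransform3D":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t) -> "AffineTransform3D":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    @classmethod
    def from_params(cls, params, center=(0.0, 0.0, 0.0)) -> "AffineTransform3D":
        """Build from the 12-vector (rx, ry, rz, log-scales, shears, translations).

        Rotations are intrinsic about x, y, z (radians, applied as Rz·Ry·Rx),
        scales enter as exp(log_scale), shears fill the upper triangle, and
        translations are in mm.  This is the parameterization the registration
        optimizer searches.
        """
        p = np.asarray(params, dtype=float).reshape(12)
        rx, ry, rz = p[0:3]
        sx, sy, sz = np.exp(p[3:6])
        hxy, hxz, hyz = p[6:9]
        cx, cy = np.cos(rx), np.cos(ry)
        sx_, sy_ = np.sin(rx), np.sin(ry)
        cz, sz_ = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx_], [0, sx_, cx]])
        Ry = np.array([[cy, 0, sy_], [0, 1, 0], [-sy_, 0, cy]])
        Rz = np.array([[cz, -sz_, 0], [sz_, cz, 0], [0, 0, 1]])
        S = np.diag([sx, sy, sz])
        H = np.array([[1, hxy, hxz], [0, 1, hyz], [0, 0, 1]])
        return cls(Rz @ Ry @ Rx @ S @ H, p[9:12], np.asarray(center, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (..., 3) array of mm points through the transform."""
        pts = np.asarray(points, dtype=float)
        return (pts - self.center) @ self.linear.T + self.center + self.translation

    def compose(self, other: "AffineTransform3D") -> "AffineTransform3D":
        """Return the transform ``x ↦ self(other(x))`` (centre folded into translation)."""
        lin = self.linear @ other.linear
        # each factor acts as L p + off with off = c + t - L c
        off_other = other.center + other.translation - other.linear @ other.center
        off_self = self.center + self.translation - self.linear @ self.center
        off = self.linear @ off_other + off_self
        return AffineTransform3D(lin, off, np.zeros(3))

    def inverse(self) -> "AffineTransform3D":
        inv = np.linalg.inv(self.linear)
        off = self.center + self.translation - self.linear @ self.center
        return AffineTransform3D(inv, -inv @ off, np.zeros(3))

    # --- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "linear": self.linear.tolist(),
            "translation_mm": self.translation.tolist(),
            "center_mm": self.center.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform3D":
        return cls(np.array(d["linear"]), np.array(d["translation_mm"]), np.array(d.get("center_mm", [0, 0, 0])))

    def save_json(self, path, provenance: dict | None = None) -> None:
        payload = self.to_dict()
        if provenance:
            payload["provenance"] = provenance
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load_json(cls, path) -> "AffineTransform3D":
        return cls.from_dict(json.loads(Path(path).read_text()))


def rotation_angle_deg(linear: np.ndarray) -> float:
    """Rotation magnitude (degrees) of the orthogonal polar factor of ``linear``.

    Strips scale/shear via polar decomposition, then reads the angle from the
    trace of the rotation matrix.
    """
    u, _, vt = np.linalg.svd(np.asarray(linear, dtype=float))
    r = u @ vt
    if np.linalg.det(r) < 0:  # keep a proper rotation
        u[:, -1] *= -1
        r = u @ vt
    c = (np.trace(r) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
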