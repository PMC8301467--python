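"""Rigid (6-parameter) transforms in physical (mm) coordinates.

Convention
----------
A :class:`RigidTransform` maps *moving* physical coordinates to *fixed*
physical coordinates as::

    y = R @ (x - center) + center + translation

where ``R`` is built from intrinsic rotations about the x, y and z axes
applied in that order (``R = Rz @ Ry @ Rx``) and ``center`` is the rotation
center in mm.  Angles are stored in degrees, translations in mm.  This is
the convention written to transform JSON files (key ``convention``:
``"intrinsic-xyz-deg-about-center"``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

CONVENTION = "intrinsic-xyz-deg-about-center"


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation mapping moving -> fixed physical coordinates."""

    angles_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("angles_deg", "translation_mm", "center_mm"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be 3 finite numbers, got {v!r}")
            object.__setattr__(self, name, tuple(float(x) for x in v))

    @property
    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix."""
        return _rotation_matrix(np.asarray(self.angles_deg))

    def as_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(A, b)`` such that ``y = A @ x + b``."""
        r = self.matrix
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return r, c + t - r @ c

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) or (3,) array of mm points."""
        a, b = self.as_affine()
        pts = np.asarray(points, dtype=float)
        return pts @ a.T + b

    def invert(self) -> "RigidTransform":
        """Exact inverse with the same rotation center."""
        a, b = self.as_affine()
        ai = a.T  # orthonormal
        c = np.asarray(self.center_mm)
        # y = ai @ x + bi ; express with same center:  t' = ai@b_total...
        bi = -ai @ b
        t = bi - (c - ai @ c)
        angles = _matrix_to_angles(ai)
        return RigidTransform(tuple(angles), tuple(t), self.center_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        a1, b1 = other.as_affine()
        a2, b2 = self.as_affine()
        a = a2 @ a1
        b = a2 @ b1 + b2
        c = np.asarray(self.center_mm)
        t = b - (c - a @ c)
        return RigidTransform(tuple(_matrix_to_angles(a)), tuple(t), self.center_mm)

    @property
    def is_identity(self) -> bool:
        return (
            np.allclose(self.angles_deg, 0, atol=1e-12)
            and np.allclose(self.translation_mm, 0, atol=1e-12)
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "angles_deg": list(self.angles_deg),
            "translation_mm": list(self.translation_mm),
            "center_mm": list(self.center_mm),
            "convention": CONVENTION,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        conv = d.get("convention", CONVENTION)
        if conv != CONVENTION:
            raise ValueError(f"unsupported transform convention {conv!r}")
        return cls(
            tuple(d["angles_deg"]), tuple(d["translation_mm"]), tuple(d["center_mm"])
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _matrix_to_angles(r: np.ndarray) -> np.ndarray:
    """Inverse of ``_rotation_matrix`` (intrinsic x-y-z order), degrees."""
    sy = -r[2, 0]
    sy = np.clip(sy, -1.0, 1.0)
    ay = np.arcsin(sy)
    if abs(sy) < 1.0 - 1e-12:
        ax = np.arctan2(r[2, 1], r[2, 2])
        az = np.arctan2(r[1, 0], r[0, 0])
    else:  # gimbal lock: put all the remaining rotation into x
        ax = np.arctan2(-r[1, 2], r[1, 1])
        az = 0.0
    return np.rad2deg(np.array([ax, ay, az]))


def from_matrix(a: np.ndarray, t: np.ndarray, center=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Build a RigidTransform from rotation matrix plus translation.

    ``t`` is the net translation in ``y = A @ (x - c) + c + t``.
    """
    return RigidTransform(tuple(_matrix_to_angles(np.asarray(a))), tuple(t), tuple(center))
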