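"""Rigid transforms (rotation + translation) in millimetres.

Rotations are stored as unit quaternions in scalar-last order ``(x, y, z, w)``,
the convention of :class:`scipy.spatial.transform.Rotation`.  Composition is
written ``A @ B`` and means "apply ``B`` first, then ``A``", matching matrix
multiplication of the corresponding homogeneous transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform"]


@dataclass(frozen=True)
class RigidTransform:
    quaternion: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0])
    )
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        q = np.asarray(self.quaternion, dtype=float).reshape(4)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        n = np.linalg.norm(q)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-9:
            if n <= 0 or not np.isfinite(n):
                raise ValueError("quaternion must be nonzero and finite")
            q = q / n
        object.__setattr__(self, "quaternion", q)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_rotation(cls, rotation: Rotation, translation=(0.0, 0.0, 0.0)):
        return cls(rotation.as_quat(), np.asarray(translation, dtype=float))

    @classmethod
    def from_rotvec_deg(cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)):
        """Rotation of ``angle_deg`` about ``axis`` (through the origin)."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis)
        return cls.from_rotation(rot, translation)

    @classmethod
    def rotation_about_point(cls, rotation: Rotation, point) -> "RigidTransform":
        """Rotation about an arbitrary fixed point instead of the origin."""
        point = np.asarray(point, dtype=float)
        return cls.from_rotation(rotation, point - rotation.apply(point))

    # -- algebra -----------------------------------------------------------
    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.rotation.apply(pts) + self.translation

    def apply_direction(self, direction: np.ndarray) -> np.ndarray:
        return self.rotation.apply(np.asarray(direction, dtype=float))

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        rot = self.rotation * other.rotation
        return RigidTransform(
            rot.as_quat(), self.rotation.apply(other.translation) + self.translation
        )

    def inverse(self) -> "RigidTransform":
        inv = self.rotation.inv()
        return RigidTransform(inv.as_quat(), -inv.apply(self.translation))

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation.as_matrix()
        m[:3, 3] = self.translation
        return m

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            self.rotation.magnitude() <= tol
            and float(np.abs(self.translation).max(initial=0.0)) <= tol
        )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "quaternion_xyzw": [float(x) for x in self.quaternion],
            "translation_mm": [float(x) for x in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            np.asarray(d["quaternion_xyzw"], dtype=float),
            np.asarray(d["translation_mm"], dtype=float),
        )
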