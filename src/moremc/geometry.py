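"""Rigid-body transforms for ligand pose degrees of freedom."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "random_rotation_matrix", "rotation_about_axis"]


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Proper rotation matrix about ``axis`` (need not be normalised) by ``angle_rad``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        return np.eye(3)
    x, y, z = axis / n
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Rotation uniform over SO(3) (random unit quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform: rotation (3x3, det +1) followed by translation (A).

    The rotation is applied about the point ``center`` supplied to :meth:`apply`
    (the ligand centroid), so translation and rotation degrees of freedom stay
    decoupled during sampling.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, coords: np.ndarray, center: np.ndarray) -> np.ndarray:
        """Rotate ``coords`` about ``center`` and translate."""
        return (coords - center) @ self.rotation.T + center + self.translation

    def then(self, delta_rotation: np.ndarray, delta_translation: np.ndarray) -> "RigidTransform":
        """Compose a further rotation (about the moving centroid) and translation."""
        return RigidTransform(
            rotation=np.asarray(delta_rotation) @ self.rotation,
            translation=self.translation + np.asarray(delta_translation, dtype=float),
        )

    def translated(self, delta: np.ndarray) -> "RigidTransform":
        return RigidTransform(self.rotation, self.translation + np.asarray(delta, dtype=float))
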