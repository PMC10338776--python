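"""Rigid/affine world-space transforms and their composition.

All transforms act on world coordinates (mm).  Rotations use intrinsic
XYZ Euler angles in radians: the linear part is ``R = Rx @ Ry @ Rz``.
A transform may carry a rotation ``center`` (world mm) so that rotation,
scale and shear pivot about a meaningful point (typically the fixed
image's center) rather than the world origin:

    y = L @ (x - c) + c + t

with ``L`` the linear part, ``c`` the center and ``t`` the translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidParams", "AffineParams", "TransformChain", "as_matrix"]


def _euler_xyz(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


def _about_center(L: np.ndarray, t: np.ndarray, c: np.ndarray) -> np.ndarray:
    m = np.eye(4)
    m[:3, :3] = L
    m[:3, 3] = t + c - L @ c
    return m


@dataclass
class RigidParams:
    """Six-parameter rigid-body transform: translations (mm) and intrinsic
    XYZ Euler rotations (radians)."""

    translations: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotations: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.translations = np.asarray(self.translations, dtype=float).reshape(3)
        self.rotations = np.asarray(self.rotations, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    def matrix(self) -> np.ndarray:
        R = _euler_xyz(*self.rotations)
        m = _about_center(R, self.translations, self.center)
        # orthonormality guard: R is exactly a rotation by construction
        assert abs(np.linalg.det(m[:3, :3]) - 1.0) < 1e-9
        return m

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.translations, self.rotations])

    @classmethod
    def from_vector(cls, v, center=(0.0, 0.0, 0.0)) -> "RigidParams":
        v = np.asarray(v, float)
        return cls(translations=v[:3], rotations=v[3:6], center=np.asarray(center, float))

    def to_dict(self) -> dict:
        return {
            "type": "rigid",
            "translations_mm": self.translations.tolist(),
            "rotations_rad": self.rotations.tolist(),
            "center_mm": self.center.tolist(),
            "matrix": self.matrix().tolist(),
        }


@dataclass
class AffineParams:
    """Twelve-parameter affine: 3 translations (mm), 3 rotations (rad),
    3 scales (unitless, > 0), 3 shears (xy, xz, yz).

    Linear part is ``R @ Shear @ diag(scales)`` applied about ``center``.
    """

    translations: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotations: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scales: np.ndarray = field(default_factory=lambda: np.ones(3))
    shears: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.translations = np.asarray(self.translations, float).reshape(3)
        self.rotations = np.asarray(self.rotations, float).reshape(3)
        self.scales = np.asarray(self.scales, float).reshape(3)
        self.shears = np.asarray(self.shears, float).reshape(3)
        self.center = np.asarray(self.center, float).reshape(3)
        if np.any(self.scales <= 0):
            raise ValueError("scales must be positive")

    def matrix(self) -> np.ndarray:
        R = _euler_xyz(*self.rotations)
        Sh = np.array(
            [[1, self.shears[0], self.shears[1]], [0, 1, self.shears[2]], [0, 0, 1]], dtype=float
        )
        L = R @ Sh @ np.diag(self.scales)
        m = _about_center(L, self.translations, self.center)
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("affine matrix is singular")
        return m

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.translations, self.rotations, self.scales, self.shears])

    @classmethod
    def from_vector(cls, v, center=(0.0, 0.0, 0.0)) -> "AffineParams":
        v = np.asarray(v, float)
        return cls(v[:3], v[3:6], v[6:9], v[9:12], center=np.asarray(center, float))

    def to_dict(self) -> dict:
        return {
            "type": "affine",
            "translations_mm": self.translations.tolist(),
            "rotations_rad": self.rotations.tolist(),
            "scales": self.scales.tolist(),
            "shears": self.shears.tolist(),
            "center_mm": self.center.tolist(),
            "matrix": self.matrix().tolist(),
        }


class TransformChain:
    """Ordered world->world mappings composed into one matrix.

    ``chain = TransformChain([A, B])`` applies A first, then B:
    ``y = B(A(x))``, i.e. ``matrix = B.matrix() @ A.matrix()``.  Used as a
    pull-back in :func:`centiz.volume_io.resample`, so the whole chain
    costs a single interpolation.
    """

    def __init__(self, transforms=()):
        self.transforms = list(transforms)
        for t in self.transforms:
            as_matrix(t)  # validate composability early

    def append(self, t):
        as_matrix(t)
        self.transforms.append(t)

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        for t in self.transforms:
            m = as_matrix(t) @ m
        return m

    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix())

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply the chain to (N, 3) world points."""
        pts = np.atleast_2d(np.asarray(points, float))
        m = self.matrix()
        return pts @ m[:3, :3].T + m[:3, 3]

    def to_dict(self) -> dict:
        return {
            "type": "chain",
            "matrix": self.matrix().tolist(),
            "components": [
                t.to_dict() if hasattr(t, "to_dict") else {"type": "matrix", "matrix": as_matrix(t).tolist()}
                for t in self.transforms
            ],
        }


def as_matrix(transform) -> np.ndarray:
    """Coerce None / 4x4 array / params object / chain to a 4x4 matrix."""
    if transform is None:
        return np.eye(4)
    if isinstance(transform, np.ndarray):
        m = np.asarray(transform, float)
        if m.shape != (4, 4):
            raise ValueError("matrix transform must be 4x4")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-9):
            raise ValueError("last row of a transform matrix must be [0,0,0,1]")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("transform matrix is singular")
        return m
    if hasattr(transform, "matrix"):
        return np.asarray(transform.matrix(), float)
    raise TypeError(f"cannot interpret {type(transform).__name__} as a transform")
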