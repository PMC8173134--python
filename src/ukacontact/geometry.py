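"""Rigid-body poses and low-level mesh geometry kernels.

All lengths are millimetres, all angles degrees unless stated otherwise.
The pose parameterisation used for optimisation and for noise injection is
(rx, ry, rz, tx, ty, tz): intrinsic Z-X-Y Euler angles in degrees followed
by a translation in mm.  The middle (X) angle is the gimbal axis, so the
Euler round-trip is only guaranteed for ``|rx| < 89 deg``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidPose",
    "closest_point_on_triangles",
    "triangle_normals",
    "orthonormality_error",
]

# scipy euler convention: uppercase = intrinsic, applied left to right.
# We store angles in (rx, ry, rz) order but the rotation sequence is Z, X, Y.
_EULER_SEQ = "ZXY"


def _angles_to_scipy(rx: float, ry: float, rz: float) -> list[float]:
    return [rz, rx, ry]


def _angles_from_scipy(a: np.ndarray) -> tuple[float, float, float]:
    return float(a[1]), float(a[2]), float(a[0])


@dataclass(frozen=True)
class RigidPose:
    """Rotation + translation mapping component coordinates to world (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("pose contains non-finite entries")
        err = orthonormality_error(R)
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (error {err:.2e})")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidPose":
        return cls()

    @classmethod
    def from_params(cls, params: np.ndarray) -> "RigidPose":
        """Build from (rx, ry, rz, tx, ty, tz), angles in degrees."""
        p = np.asarray(params, dtype=float).reshape(6)
        R = Rotation.from_euler(
            _EULER_SEQ, _angles_to_scipy(p[0], p[1], p[2]), degrees=True
        ).as_matrix()
        return cls(R, p[3:6])

    @classmethod
    def from_euler_xyz(cls, rx: float, ry: float, rz: float, t=(0.0, 0.0, 0.0)) -> "RigidPose":
        return cls.from_params([rx, ry, rz, *t])

    # -- conversions --------------------------------------------------
    def as_params(self) -> np.ndarray:
        a = Rotation.from_matrix(self.rotation).as_euler(_EULER_SEQ, degrees=True)
        rx, ry, rz = _angles_from_scipy(a)
        return np.array([rx, ry, rz, *self.translation])

    # -- algebra ------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidPose") -> "RigidPose":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidPose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidPose":
        Rt = self.rotation.T
        return RigidPose(Rt, -Rt @ self.translation)

    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def almost_equal(self, other: "RigidPose", rot_tol=1e-9, trans_tol=1e-9) -> bool:
        return (
            np.abs(self.rotation - other.rotation).max() < rot_tol
            and np.abs(self.translation - other.translation).max() < trans_tol
        )


def orthonormality_error(R: np.ndarray) -> float:
    """max(|R^T R - I|, |det R - 1|)."""
    R = np.asarray(R, dtype=float)
    return float(
        max(np.abs(R.T @ R - np.eye(3)).max(), abs(np.linalg.det(R) - 1.0))
    )


def triangle_normals(vertices: np.ndarray, faces: np.ndarray, normalize: bool = True) -> np.ndarray:
    tri = vertices[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    if normalize:
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        n = n / norm
    return n


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray):
    """Closest point on each candidate triangle for each query point.

    points : (N, 3); triangles : (N, K, 3, 3) candidate triangles per point
    (broadcastable).  Returns (closest (N, K, 3), squared distance (N, K)).

    Region-based clamping after Ericson, vectorised over both axes.
    """
    p = np.asarray(points, dtype=float)[:, None, :]          # (N,1,3)
    tri = np.asarray(triangles, dtype=float)                 # (N,K,3,3)
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)

    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)

    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    denom_ab = d1 - d3
    denom_ab = np.where(denom_ab == 0, 1.0, denom_ab)
    v_ab = np.clip(d1 / denom_ab, 0.0, 1.0)

    denom_ac = d2 - d6
    denom_ac = np.where(denom_ac == 0, 1.0, denom_ac)
    w_ac = np.clip(d2 / denom_ac, 0.0, 1.0)

    denom_bc = (d4 - d3) + (d5 - d6)
    denom_bc = np.where(denom_bc == 0, 1.0, denom_bc)
    w_bc = np.clip((d4 - d3) / denom_bc, 0.0, 1.0)

    denom_in = va + vb + vc
    denom_in = np.where(denom_in == 0, 1.0, denom_in)
    v_in = vb / denom_in
    w_in = vc / denom_in

    close = a + v_in[..., None] * ab + w_in[..., None] * ac  # interior default

    # edge BC region
    cond_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    close = np.where(cond_bc[..., None], b + w_bc[..., None] * (c - b), close)
    # edge AC region
    cond_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    close = np.where(cond_ac[..., None], a + w_ac[..., None] * ac, close)
    # edge AB region
    cond_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    close = np.where(cond_ab[..., None], a + v_ab[..., None] * ab, close)
    # vertex regions
    cond_c = (d6 >= 0) & (d5 <= d6)
    close = np.where(cond_c[..., None], c, close)
    cond_b = (d3 >= 0) & (d4 <= d3)
    close = np.where(cond_b[..., None], b, close)
    cond_a = (d1 <= 0) & (d2 <= 0)
    close = np.where(cond_a[..., None], a, close)

    diff = p - close
    d2_ = np.einsum("...i,...i->...", diff, diff)
    return close, d2_
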