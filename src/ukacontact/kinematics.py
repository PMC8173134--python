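"""Joint coordinate frames and 6-DOF kinematic decomposition.

Convention (right knee): x = anterior(+), y = medial(+), z = proximal(+).
Rotations follow the knee joint coordinate system of Grood and Suntay:
flexion about the femoral mediolateral axis (e1), internal-external
rotation about the tibial long axis (e3), ab/adduction about the floating
axis e2 = e3 x e1.  With the axis conventions above this is exactly the
intrinsic Y-X-Z Euler decomposition of the tibia-in-femur rotation.

Signs: flexion(+), adduction(+), tibial internal rotation(+); translations
of the femoral frame origin relative to the tibial origin are expressed
along the tibial axes: anterior(+), proximal(+), medial(+).  Left knees are
mirrored to the right-knee convention before pooling, which preserves
medial(+) as medial(+).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GimbalDegenerateError, InvalidInputError
from .geometry import RigidPose
from .phantom import MotionTrajectory, SurfaceMesh

__all__ = [
    "ComponentFrame",
    "KinematicsSample",
    "KinematicsSeries",
    "decompose_6dof",
    "compose_6dof",
    "decompose_trajectory",
    "mirror_left_to_right",
    "resample_to_phase",
    "split_flexion_limbs",
]

_MIRROR = np.diag([1.0, -1.0, 1.0])  # reflection across the sagittal plane


@dataclass(frozen=True)
class ComponentFrame:
    """Right-handed orthonormal component frame (origin in mm)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        M = np.column_stack([self.x_axis, self.y_axis, self.z_axis])
        if np.abs(M.T @ M - np.eye(3)).max() > 1e-9:
            raise InvalidInputError("frame axes must be orthonormal")
        if np.cross(self.x_axis, self.y_axis) @ self.z_axis < 1.0 - 1e-9:
            raise InvalidInputError("frame must be right-handed")

    @classmethod
    def from_pose(cls, pose: RigidPose) -> "ComponentFrame":
        R = pose.rotation
        return cls(pose.translation, R[:, 0], R[:, 1], R[:, 2])

    def as_pose(self) -> RigidPose:
        return RigidPose(
            np.column_stack([self.x_axis, self.y_axis, self.z_axis]), self.origin
        )


@dataclass(frozen=True)
class KinematicsSample:
    """One frame of joint kinematics: angles in degrees, translations mm."""

    flexion: float
    adduction: float
    internal_rotation: float
    ap: float
    pd: float
    ml: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.flexion, self.adduction, self.internal_rotation, self.ap, self.pd, self.ml]
        )


@dataclass
class KinematicsSeries:
    activity: str
    phase_axis: str
    phase_keys: np.ndarray
    flexion: np.ndarray
    adduction: np.ndarray
    internal_rotation: np.ndarray
    ap: np.ndarray
    pd: np.ndarray
    ml: np.ndarray

    _CHANNELS = ("flexion", "adduction", "internal_rotation", "ap", "pd", "ml")

    def __post_init__(self) -> None:
        self.phase_keys = np.asarray(self.phase_keys, dtype=float)
        n = len(self.phase_keys)
        for ch in self._CHANNELS:
            arr = np.asarray(getattr(self, ch), dtype=float)
            if len(arr) != n:
                raise InvalidInputError(f"channel {ch} length != phase keys")
            setattr(self, ch, arr)


def decompose_6dof(femur_pose: RigidPose, tibia_pose: RigidPose) -> KinematicsSample:
    """Decompose the femur-tibia relative pose into the six joint DOF."""
    e1 = femur_pose.rotation[:, 1]  # femoral ML
    e3 = tibia_pose.rotation[:, 2]  # tibial long axis
    if abs(float(e1 @ e3)) > 0.999:
        raise GimbalDegenerateError("femoral ML axis nearly parallel to tibial long axis")
    r_rel = femur_pose.rotation.T @ tibia_pose.rotation
    a, b, c = Rotation.from_matrix(r_rel).as_euler("YXZ", degrees=True)
    d = femur_pose.translation - tibia_pose.translation
    Rt = tibia_pose.rotation
    return KinematicsSample(
        flexion=float(a),
        adduction=float(-b),
        internal_rotation=float(c),
        ap=float(d @ Rt[:, 0]),
        ml=float(d @ Rt[:, 1]),
        pd=float(d @ Rt[:, 2]),
    )


def compose_6dof(
    sample: KinematicsSample, tibia_pose: RigidPose = RigidPose.identity()
) -> RigidPose:
    """Inverse of :func:`decompose_6dof`: femur pose from the six DOF."""
    r_rel = Rotation.from_euler(
        "YXZ", [sample.flexion, -sample.adduction, sample.internal_rotation], degrees=True
    ).as_matrix()
    R_f = tibia_pose.rotation @ r_rel.T
    t_f = tibia_pose.translation + tibia_pose.rotation @ np.array(
        [sample.ap, sample.ml, sample.pd]
    )
    return RigidPose(R_f, t_f)


def decompose_trajectory(trajectory: MotionTrajectory) -> KinematicsSeries:
    samples = [
        decompose_6dof(f, t) for f, t in zip(trajectory.femur_poses, trajectory.tibia_poses)
    ]
    arr = np.array([s.as_array() for s in samples])
    return KinematicsSeries(
        activity=trajectory.activity,
        phase_axis=trajectory.phase_axis,
        phase_keys=trajectory.phase_keys,
        flexion=arr[:, 0],
        adduction=arr[:, 1],
        internal_rotation=arr[:, 2],
        ap=arr[:, 3],
        pd=arr[:, 4],
        ml=arr[:, 5],
    )


def mirror_left_to_right(obj: Union[SurfaceMesh, RigidPose]):
    """Reflect a left-knee mesh or pose into the right-knee convention.

    Meshes are reflected across the sagittal (ML-normal) plane with a
    winding-order repair; poses are conjugated by the reflection.  Applying
    the operation twice is the identity, bit for bit.
    """
    if isinstance(obj, SurfaceMesh):
        verts = obj.vertices.copy()
        verts[:, 1] = -verts[:, 1]
        faces = obj.faces[:, [0, 2, 1]].copy()
        return SurfaceMesh(verts, faces, obj.frame_label, dict(obj.metadata))
    if isinstance(obj, RigidPose):
        return RigidPose(_MIRROR @ obj.rotation @ _MIRROR, _MIRROR @ obj.translation)
    raise InvalidInputError(f"cannot mirror object of type {type(obj).__name__}")


def resample_to_phase(
    phase_keys: np.ndarray, values: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Linear resampling onto ``grid``; points outside the observed phase
    range are NaN (flagged missing), never extrapolated."""
    pk = np.asarray(phase_keys, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(pk) < 2:
        raise InvalidInputError("need at least 2 source samples to resample")
    if np.any(np.diff(pk) <= 0):
        raise InvalidInputError("phase keys must be strictly monotone")
    g = np.asarray(grid, dtype=float)
    out = np.interp(g, pk, v)
    out[(g < pk[0]) | (g > pk[-1])] = np.nan
    return out


def split_flexion_limbs(flexion: np.ndarray, values: np.ndarray):
    """Split a non-monotone flexion series at peak flexion.

    Returns ((flexion_up, values_up), (flexion_down, values_down)) with each
    limb strictly monotone increasing in flexion (the descent limb is
    reversed).  Duplicate flexion samples within a limb are dropped.
    """
    f = np.asarray(flexion, dtype=float)
    v = np.asarray(values, dtype=float)
    apex = int(np.argmax(f))
    limbs = []
    for fl, vl in ((f[: apex + 1], v[: apex + 1]), (f[apex:][::-1], v[apex:][::-1])):
        if len(fl) >= 2:
            keep = np.concatenate([[True], np.diff(fl) > 0])
            limbs.append((fl[keep], vl[keep]))
    return limbs


def resample_series(series: KinematicsSeries, grid: np.ndarray) -> KinematicsSeries:
    """Resample every channel of a kinematics series onto ``grid``."""
    kwargs = {
        ch: resample_to_phase(series.phase_keys, getattr(series, ch), grid)
        for ch in KinematicsSeries._CHANNELS
    }
    return KinematicsSeries(
        activity=series.activity,
        phase_axis=series.phase_axis,
        phase_keys=np.asarray(grid, dtype=float),
        **kwargs,
    )
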