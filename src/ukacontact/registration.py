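"""Rigid registration: trimmed ICP and dual-view silhouette pose estimation.

Two registration problems appear in the pipeline:

* mesh-to-mesh alignment (the preoperative-to-postoperative bone surrogate),
  solved by point-to-point iterative closest point with optional trimming of
  the worst correspondences for partial-overlap robustness;
* 2D-to-3D pose recovery of an implant component from its silhouette
  outlines in two approximately orthogonal fluoroscopic views (the virtual
  dual fluoroscopic imaging system), solved by derivative-free minimisation
  of the contour-to-projected-silhouette distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, InvalidInputError, InvalidParameterError
from .geometry import RigidPose
from .meshquery import MeshDistanceQuery
from .phantom import CameraModel, Contour2D, SilhouetteProjector, SurfaceMesh

__all__ = [
    "RegistrationResult",
    "OptimizerConfig",
    "icp_align",
    "surface_deviation",
    "estimate_pose_dfis",
]


@dataclass
class RegistrationResult:
    pose: RigidPose
    residual_rms: float
    n_iterations: int
    converged: bool
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.residual_rms < 0:
            raise InvalidParameterError("residual_rms must be >= 0")


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidPose:
    """Closed-form least-squares rigid transform src -> dst (SVD of the
    cross-covariance)."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1.0):
        raise DegenerateGeometryError("rank-deficient cross-covariance in ICP update")
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ D @ U.T
    return RigidPose(R, mu_d - R @ mu_s)


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, SurfaceMesh):
        return obj.vertices
    return np.asarray(obj, dtype=float).reshape(-1, 3)


def icp_align(
    source,
    target: SurfaceMesh,
    max_iter: int = 100,
    tol: float = 1e-8,
    trim_fraction: float = 0.0,
    initial_pose: Optional[RigidPose] = None,
) -> RegistrationResult:
    """Point-to-point ICP aligning ``source`` onto ``target``.

    Per iteration: nearest-neighbour correspondences against the target
    vertices (KD-tree), rejection of the worst ``trim_fraction`` of
    correspondences by distance, then the closed-form rigid update.  Stops
    when the trimmed RMS changes by less than ``tol`` (mm) or at
    ``max_iter``.  Returns the source-to-target pose; the trimmed residual
    RMS is non-increasing across iterations.
    """
    src = _as_points(source)
    if len(src) < 100:
        raise InvalidInputError("ICP needs at least 100 source points")
    if not (0.0 <= trim_fraction < 0.5):
        raise InvalidParameterError("trim_fraction must be in [0, 0.5)")
    tgt = _as_points(target)
    tree = cKDTree(tgt)
    pose = initial_pose or RigidPose.identity()
    n_keep = max(3, int(round(len(src) * (1.0 - trim_fraction))))

    history: list[float] = []
    rms = np.inf
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        moved = pose.apply(src)
        dist, idx = tree.query(moved)
        if trim_fraction > 0:
            keep = np.argsort(dist)[:n_keep]
        else:
            keep = slice(None)
        new_rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        history.append(new_rms)
        if abs(rms - new_rms) < tol:
            rms = new_rms
            converged = True
            break
        rms = new_rms
        pose = _kabsch(src[keep] if trim_fraction > 0 else src, tgt[idx[keep]])
    return RegistrationResult(pose, rms, it, converged, history)


def surface_deviation(mesh_a: SurfaceMesh, mesh_b: SurfaceMesh) -> tuple[float, float]:
    """Unsigned vertex-to-surface deviation of A against B: (mean, SD) in mm.

    Distances are point-to-triangle (nearest point anywhere on B's surface),
    not point-to-vertex.
    """
    if len(mesh_a.vertices) == 0 or len(mesh_b.vertices) == 0:
        raise InvalidInputError("empty mesh")
    q = MeshDistanceQuery(mesh_b.vertices, mesh_b.faces)
    dist, _, _ = q.query(mesh_a.vertices)
    return float(dist.mean()), float(dist.std())


# ---------------------------------------------------------------------------
# dual-view silhouette pose estimation
# ---------------------------------------------------------------------------


@dataclass
class OptimizerConfig:
    """Nelder-Mead settings for silhouette matching.

    The cost is non-smooth (nearest-segment assignments switch as the pose
    moves), so a simplex method with restarts at the incumbent best point is
    used.  ``initial_step`` sets the initial simplex size in degrees / mm.
    """

    max_fev: int = 1500
    restarts: int = 2
    xatol: float = 1e-6
    fatol: float = 1e-12
    initial_step: float = 0.5
    converged_rms: float = 1e-3  # mm on the detector
    # deterministic fallback starts (tried only while unconverged): the
    # initial pose is re-perturbed one parameter at a time by this amount
    multistart_offsets: tuple = (1.0, -1.0, 2.0, -2.0)


def _point_segment_sqdist(points: np.ndarray, segments: np.ndarray) -> np.ndarray:
    """Min squared distance from each 2D point to a set of 2D segments."""
    a = segments[:, 0]  # (m, 2)
    ab = segments[:, 1] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    ap = points[:, None, :] - a[None, :, :]  # (n, m, 2)
    t = np.clip(np.einsum("nmi,mi->nm", ap, ab) / denom, 0.0, 1.0)
    diff = ap - t[..., None] * ab[None, :, :]
    return np.einsum("nmi,nmi->nm", diff, diff).min(axis=1)


def silhouette_cost(
    projector: SilhouetteProjector,
    pose: RigidPose,
    contours: Sequence[Contour2D],
    cameras: Sequence[CameraModel],
) -> float:
    """Mean squared contour-point-to-model-silhouette distance (mm^2).

    Asymmetric by design: measured outline points are matched to the
    complete projected model silhouette, never the reverse, because a
    measured outline may be partial.
    """
    total = 0.0
    n = 0
    for contour, cam in zip(contours, cameras):
        segs = projector.silhouette_segments(pose, cam)
        d2 = _point_segment_sqdist(contour.points, segs)
        total += float(d2.sum())
        n += len(d2)
    return total / n


def estimate_pose_dfis(
    mesh: SurfaceMesh,
    contours: Sequence[Contour2D],
    cameras: Sequence[CameraModel],
    initial_pose: RigidPose,
    optimizer_config: Optional[OptimizerConfig] = None,
    projector: Optional[SilhouetteProjector] = None,
) -> RegistrationResult:
    """Recover a component's 6-DOF pose from dual-view silhouette contours.

    Minimises the summed squared distance from every measured contour point
    to the nearest point of the model's projected silhouette in both views,
    over the six Euler + translation parameters, starting from
    ``initial_pose`` (which must lie within the local basin, roughly 5 deg /
    10 mm of the truth).  Non-convergence is flagged in the result, never
    silent.
    """
    if len(contours) < 2 or len(cameras) < 2:
        raise InvalidInputError(
            "at least two views are required (single-view depth is unconstrained)"
        )
    cfg = optimizer_config or OptimizerConfig()
    proj = projector or SilhouetteProjector(mesh)

    def cost(params: np.ndarray) -> float:
        pose = RigidPose.from_params(params)
        return silhouette_cost(proj, pose, contours, cameras)

    x0 = initial_pose.as_params()
    best_x = x0
    best_f = cost(x0)
    total_fev = 0

    def local_search(start: np.ndarray):
        nonlocal best_x, best_f, total_fev
        x, step = start, cfg.initial_step
        for _ in range(cfg.restarts + 1):
            simplex = np.vstack([x, x + np.eye(6) * step])
            res = minimize(
                cost,
                x,
                method="Nelder-Mead",
                options={
                    "maxfev": cfg.max_fev,
                    "xatol": cfg.xatol,
                    "fatol": cfg.fatol,
                    "initial_simplex": simplex,
                },
            )
            total_fev += res.nfev
            if res.fun < best_f:
                best_x, best_f = res.x, res.fun
            x = res.x if res.fun <= best_f else best_x
            step = max(step * 0.2, 10 * cfg.xatol)
            if np.sqrt(best_f) <= cfg.converged_rms:
                return

    local_search(x0)
    if np.sqrt(best_f) > cfg.converged_rms:
        # deterministic multi-start: re-perturb one parameter at a time
        for delta in cfg.multistart_offsets:
            for axis in range(6):
                start = x0.copy()
                start[axis] += delta
                local_search(start)
                if np.sqrt(best_f) <= cfg.converged_rms:
                    break
            if np.sqrt(best_f) <= cfg.converged_rms:
                break
    x = best_x
    rms = float(np.sqrt(best_f))
    return RegistrationResult(
        pose=RigidPose.from_params(x),
        residual_rms=rms,
        n_iterations=total_fev,
        converged=rms <= cfg.converged_rms,
    )
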