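"""Synthetic phantom: implant geometry, virtual fluoroscopes and motions.

The phantom emulates a medial fixed-bearing UKA: a low-congruence
cobalt-chrome femoral condyle articulating on a flat (or shallowly dished)
polyethylene insert seated on a tibial baseplate, imaged by two
approximately orthogonal fluoroscopes.  Every stochastic operation takes an
explicit seed; there is no global RNG state.

Component frame convention (right knee): x = anterior(+), y = medial(+),
z = proximal(+), units mm.  The femoral component frame sits at the centre
of its sagittal arc; the tibial component frame sits at the centre of the
insert footprint with z = 0 on the baseplate plane, so the insert centroid
projects to the frame origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.spatial import ConvexHull

from .errors import (
    InvalidParameterError,
    InvalidInputError,
    OutOfFootprintError,
    ProjectionGeometryError,
)
from .geometry import RigidPose, triangle_normals

__all__ = [
    "SurfaceMesh",
    "ImplantSet",
    "CameraModel",
    "Contour2D",
    "MotionTrajectory",
    "make_femoral_component",
    "make_tibial_insert",
    "make_tibial_baseplate",
    "make_implant_set",
    "make_camera_pair",
    "project_silhouette",
    "SilhouetteProjector",
    "generate_activity_trajectory",
    "default_keyframes",
    "DEFAULT_INSERT_LENGTH",
    "DEFAULT_INSERT_WIDTH",
]

# Representative insert dimensions (mm).  43 mm is the anteroposterior
# length of the representative polyethylene insert onto which all contact
# trajectories are mapped; 26.5 mm is the mediolateral width reconstructed
# so that the millimetre and percentage summaries of the reference contact
# table are mutually consistent.
DEFAULT_INSERT_LENGTH = 43.0
DEFAULT_INSERT_WIDTH = 26.5


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Triangulated surface in a named coordinate frame (mm)."""

    vertices: np.ndarray
    faces: np.ndarray
    frame_label: str = "unknown"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.validate()

    def validate(self) -> None:
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise InvalidInputError("empty mesh")
        if not np.all(np.isfinite(self.vertices)):
            raise InvalidInputError("mesh has non-finite vertices")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise InvalidInputError("face index out of range")
        areas = 0.5 * np.linalg.norm(
            triangle_normals(self.vertices, self.faces, normalize=False), axis=1
        )
        if np.any(areas <= 0):
            raise InvalidInputError("mesh contains degenerate (zero-area) triangles")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def transformed(self, pose: RigidPose, frame_label: Optional[str] = None) -> "SurfaceMesh":
        return SurfaceMesh(
            pose.apply(self.vertices),
            self.faces.copy(),
            frame_label or self.frame_label,
            dict(self.metadata),
        )

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(), self.faces.copy(), self.frame_label, dict(self.metadata)
        )


@dataclass
class ImplantSet:
    """The three UKA components plus the insert dimensions used downstream."""

    femoral_condyle: SurfaceMesh
    insert: SurfaceMesh
    baseplate: SurfaceMesh
    insert_length: float = DEFAULT_INSERT_LENGTH
    insert_width: float = DEFAULT_INSERT_WIDTH
    insert_centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.insert_length <= 0 or self.insert_width <= 0:
            raise InvalidParameterError("insert dimensions must be positive")
        self.insert_centroid = np.asarray(self.insert_centroid, dtype=float).reshape(3)


@dataclass
class CameraModel:
    """Point-source central projection onto a flat detector (mm)."""

    source_position: np.ndarray
    detector_center: np.ndarray
    detector_axes: np.ndarray  # (2, 3) in-plane orthonormal unit vectors
    source_detector_distance: float

    def __post_init__(self) -> None:
        self.source_position = np.asarray(self.source_position, dtype=float).reshape(3)
        self.detector_center = np.asarray(self.detector_center, dtype=float).reshape(3)
        self.detector_axes = np.asarray(self.detector_axes, dtype=float).reshape(2, 3)
        d = self.detector_center - self.source_position
        dist = np.linalg.norm(d)
        if abs(dist - self.source_detector_distance) > 1e-6:
            raise InvalidParameterError(
                "source_detector_distance inconsistent with source/detector positions"
            )
        u, v = self.detector_axes
        if (
            abs(np.linalg.norm(u) - 1) > 1e-9
            or abs(np.linalg.norm(v) - 1) > 1e-9
            or abs(u @ v) > 1e-9
            or abs(u @ d / dist) > 1e-9
            or abs(v @ d / dist) > 1e-9
        ):
            raise InvalidParameterError("detector axes must be orthonormal and in-plane")

    @property
    def view_direction(self) -> np.ndarray:
        d = self.detector_center - self.source_position
        return d / np.linalg.norm(d)

    def project(self, points: np.ndarray) -> np.ndarray:
        """Centrally project 3D world points onto detector (u, v) in mm."""
        p = np.asarray(points, dtype=float).reshape(-1, 3)
        n = self.view_direction
        rel = p - self.source_position
        depth = rel @ n
        if np.any(depth <= 1e-9):
            raise ProjectionGeometryError("point at or behind the source plane")
        q = self.source_position + rel * (self.source_detector_distance / depth)[:, None]
        rel_det = q - self.detector_center
        return np.column_stack([rel_det @ self.detector_axes[0], rel_det @ self.detector_axes[1]])


@dataclass
class Contour2D:
    """Sampled silhouette outline in detector-plane coordinates (mm)."""

    view_id: str
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) < 20:
            raise InvalidInputError("contour needs at least 20 points")
        if not np.all(np.isfinite(self.points)):
            raise InvalidInputError("contour has non-finite points")


@dataclass
class MotionTrajectory:
    """Per-frame component poses with phantom ground truth attached.

    ``phase_axis`` is ``percent_stance`` for gait and ``flexion_angle``
    (degrees) for lunge / sit-to-stand.  ``truth`` holds the noise-free
    keyframe-interpolated contact AP/ML (mm, insert frame), flexion and
    internal rotation per frame, for oracle use downstream.
    """

    activity: str
    phase_axis: str
    phase_keys: np.ndarray
    femur_poses: list
    tibia_poses: list
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase_keys = np.asarray(self.phase_keys, dtype=float)
        if np.any(np.diff(self.phase_keys) <= 0):
            raise InvalidInputError("phase keys must be strictly increasing")
        if not (len(self.phase_keys) == len(self.femur_poses) == len(self.tibia_poses)):
            raise InvalidInputError("pose lists must match phase keys")

    @property
    def n_frames(self) -> int:
        return len(self.phase_keys)


# ---------------------------------------------------------------------------
# implant geometry
# ---------------------------------------------------------------------------


def _oriented_convex_hull(points: np.ndarray):
    """Convex hull with outward winding; returns (vertices, faces, source_idx)."""
    hull = ConvexHull(points)
    verts = points[hull.vertices]
    remap = np.full(len(points), -1, dtype=np.int64)
    remap[hull.vertices] = np.arange(len(hull.vertices))
    faces = remap[hull.simplices]
    centroid = verts.mean(axis=0)
    tri = verts[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    outward = np.einsum("ij,ij->i", normals, tri.mean(axis=1) - centroid) < 0
    faces[outward] = faces[outward][:, [0, 2, 1]]
    return verts, faces, hull.vertices


def make_femoral_component(
    sagittal_radius: float = 24.0,
    coronal_radius: float = 11.0,
    arc_span: float = 160.0,
    mesh_resolution: int = 28,
    coronal_span: float = 140.0,
) -> SurfaceMesh:
    """Toroidal-section femoral condyle closed into a watertight convex solid.

    The articular surface is the outer band of a torus: a coronal circular
    arc of radius ``coronal_radius`` swept along a sagittal circular arc of
    radius ``sagittal_radius``.  The component frame origin is the sagittal
    arc centre; the articular surface faces distally (-z) with the lowest
    point at (0, 0, -sagittal_radius) and the sweep (tube) axis along y.
    Vertices on the outer band satisfy the torus implicit equation

        (sqrt(x^2 + z^2) - (Rs - Rc))^2 + y^2 = Rc^2.

    ``mesh_resolution`` counts samples along the sagittal arc; coronal
    sampling is scaled to keep facets roughly isotropic.  In the limit
    ``coronal_radius == sagittal_radius`` the surface is a sphere.
    """
    if sagittal_radius <= 0 or coronal_radius <= 0:
        raise InvalidParameterError("radii must be positive")
    if coronal_radius > sagittal_radius:
        raise InvalidParameterError("coronal radius cannot exceed sagittal radius")
    if not (90.0 <= arc_span <= 180.0):
        raise InvalidParameterError("arc_span must be within [90, 180] degrees")
    if mesh_resolution < 8:
        raise InvalidParameterError("mesh_resolution must be >= 8")

    ring_radius = sagittal_radius - coronal_radius
    theta = np.deg2rad(np.linspace(-arc_span / 2, arc_span / 2, mesh_resolution))
    n_phi = max(8, int(round(mesh_resolution * coronal_span / arc_span)))
    phi = np.deg2rad(np.linspace(-coronal_span / 2, coronal_span / 2, n_phi))

    th, ph = np.meshgrid(theta, phi, indexing="ij")
    # direction of the sagittal sweep in the x-z plane; theta=0 points distally
    d = np.stack([np.sin(th), np.zeros_like(th), -np.cos(th)], axis=-1)
    y_hat = np.array([0.0, 1.0, 0.0])
    radial = ring_radius + coronal_radius * np.cos(ph)
    pts = radial[..., None] * d + (coronal_radius * np.sin(ph))[..., None] * y_hat
    grid = pts.reshape(-1, 3)

    # closure points: pull the patch boundary toward the arc centre so the
    # hull closes into a compact solid without shadowing articular vertices
    cap = np.array(
        [
            [0.0, 0.0, 0.2 * sagittal_radius],
            [0.3 * sagittal_radius, 0.0, 0.1 * sagittal_radius],
            [-0.3 * sagittal_radius, 0.0, 0.1 * sagittal_radius],
        ]
    )
    cloud = np.vstack([grid, cap])
    verts, faces, source_idx = _oriented_convex_hull(cloud)
    # articular vertices = hull vertices originating from the torus grid
    articular = source_idx < len(grid)

    mesh = SurfaceMesh(
        verts,
        faces,
        frame_label="femoral_component",
        metadata={
            "component": "femoral_condyle",
            "sagittal_radius": sagittal_radius,
            "coronal_radius": coronal_radius,
            "arc_span": arc_span,
            "coronal_span": coronal_span,
            "articular_mask": articular,
        },
    )
    return mesh


def _insert_height_fn(dish_radius: Optional[float], thickness: float) -> Callable:
    """Closed-form superior-surface height field z = h(x, y)."""
    if dish_radius is None or np.isinf(dish_radius):
        return lambda x, y: np.broadcast_to(np.float64(thickness), np.shape(x)).copy()

    def h(x, y):
        r2 = np.asarray(x) ** 2 + np.asarray(y) ** 2
        return thickness + dish_radius - np.sqrt(dish_radius**2 - r2)

    return h


def _block_mesh(length, width, thickness, height_fn, nx, ny, frame_label, metadata):
    """Watertight block: gridded superior surface, flat bottom, side walls."""
    x = np.linspace(-length / 2, length / 2, nx)
    y = np.linspace(-width / 2, width / 2, ny)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    top = np.column_stack([xx.ravel(), yy.ravel(), height_fn(xx, yy).ravel()])
    bot = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(nx * ny)])
    verts = np.vstack([top, bot])
    n = nx * ny

    def vid(i, j, layer):  # layer 0 = top, 1 = bottom
        return layer * n + i * ny + j

    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b, c, d = vid(i, j, 0), vid(i + 1, j, 0), vid(i + 1, j + 1, 0), vid(i, j + 1, 0)
            faces += [[a, b, c], [a, c, d]]  # top, +z outward (ccw seen from above)
            a, b, c, d = vid(i, j, 1), vid(i + 1, j, 1), vid(i + 1, j + 1, 1), vid(i, j + 1, 1)
            faces += [[a, c, b], [a, d, c]]  # bottom, -z outward
    # walls along the four boundary strips
    for i in range(nx - 1):
        for (j, flip) in ((0, False), (ny - 1, True)):
            a, b = vid(i, j, 0), vid(i + 1, j, 0)
            a2, b2 = vid(i, j, 1), vid(i + 1, j, 1)
            quad = [[a, a2, b2], [a, b2, b]] if not flip else [[a, b2, a2], [a, b, b2]]
            faces += quad
    for j in range(ny - 1):
        for (i, flip) in ((0, True), (nx - 1, False)):
            a, b = vid(i, j, 0), vid(i, j + 1, 0)
            a2, b2 = vid(i, j, 1), vid(i, j + 1, 1)
            quad = [[a, a2, b2], [a, b2, b]] if not flip else [[a, b2, a2], [a, b, b2]]
            faces += quad

    md = dict(metadata)
    md["superior_vertex_indices"] = np.arange(n)
    return SurfaceMesh(verts, np.asarray(faces), frame_label=frame_label, metadata=md)


def make_tibial_insert(
    length: float = DEFAULT_INSERT_LENGTH,
    width: float = DEFAULT_INSERT_WIDTH,
    dish_radius: Optional[float] = None,
    thickness: float = 8.0,
    mesh_resolution: int = 40,
) -> SurfaceMesh:
    """Polyethylene insert: block with a flat or shallow spherical-dish top.

    ``dish_radius=None`` (or inf) gives the low-congruence flat superior
    surface; otherwise the top is a spherical dish of that radius, lowest at
    the footprint centre, height rising toward the edges as
    ``h(x, y) = thickness + R - sqrt(R^2 - x^2 - y^2)``.  The frame origin is
    the footprint centre on the baseplate plane, x anterior along the
    length, y medial along the width.
    """
    if length <= 0 or width <= 0 or thickness <= 0:
        raise InvalidParameterError("insert dimensions must be positive")
    if dish_radius is not None and not np.isinf(dish_radius) and dish_radius <= 0:
        raise InvalidParameterError("dish_radius must be positive, inf, or None")
    if mesh_resolution < 4:
        raise InvalidParameterError("mesh_resolution must be >= 4")
    if dish_radius is not None and not np.isinf(dish_radius):
        if dish_radius**2 <= (length / 2) ** 2 + (width / 2) ** 2:
            raise InvalidParameterError("dish_radius too small for the footprint")

    nx = mesh_resolution
    ny = max(4, int(round(mesh_resolution * width / length)))
    hfn = _insert_height_fn(dish_radius, thickness)
    return _block_mesh(
        length,
        width,
        thickness,
        hfn,
        nx,
        ny,
        frame_label="tibial_component",
        metadata={
            "component": "insert",
            "length": length,
            "width": width,
            "thickness": thickness,
            "dish_radius": None if dish_radius is None or np.isinf(dish_radius) else dish_radius,
        },
    )


def make_tibial_baseplate(
    length: float = 45.0, width: float = 28.0, thickness: float = 3.5, mesh_resolution: int = 8
) -> SurfaceMesh:
    """Flat tibial baseplate block seated below the insert (top at z = 0)."""
    if length <= 0 or width <= 0 or thickness <= 0:
        raise InvalidParameterError("baseplate dimensions must be positive")
    mesh = _block_mesh(
        length,
        width,
        thickness,
        _insert_height_fn(None, thickness),
        mesh_resolution,
        max(4, int(round(mesh_resolution * width / length))),
        frame_label="tibial_component",
        metadata={"component": "baseplate", "length": length, "width": width,
                  "thickness": thickness},
    )
    mesh.vertices[:, 2] -= thickness  # top face flush with the insert underside
    return mesh


def make_implant_set(
    sagittal_radius: float = 24.0,
    coronal_radius: float = 11.0,
    arc_span: float = 160.0,
    insert_length: float = DEFAULT_INSERT_LENGTH,
    insert_width: float = DEFAULT_INSERT_WIDTH,
    insert_thickness: float = 8.0,
    dish_radius: Optional[float] = None,
    femoral_resolution: int = 28,
    insert_resolution: int = 40,
) -> ImplantSet:
    """Assemble the default phantom implant set."""
    return ImplantSet(
        femoral_condyle=make_femoral_component(
            sagittal_radius, coronal_radius, arc_span, femoral_resolution
        ),
        insert=make_tibial_insert(
            insert_length, insert_width, dish_radius, insert_thickness, insert_resolution
        ),
        baseplate=make_tibial_baseplate(),
        insert_length=insert_length,
        insert_width=insert_width,
        insert_centroid=np.array([0.0, 0.0, insert_thickness / 2]),
    )


# ---------------------------------------------------------------------------
# virtual fluoroscopes
# ---------------------------------------------------------------------------


def make_camera_pair(
    iso_center=(0.0, 0.0, 0.0),
    source_iso_distance: float = 700.0,
    source_detector_distance: float = 1000.0,
    angle_between: float = 90.0,
) -> tuple[CameraModel, CameraModel]:
    """Two fluoroscopes with horizontal view axes separated by ~90 degrees."""
    if not (80.0 <= angle_between <= 100.0):
        raise InvalidParameterError("view separation must be 80-100 degrees")
    iso = np.asarray(iso_center, dtype=float)
    cams = []
    for k, ang in enumerate((0.0, np.deg2rad(angle_between))):
        view = np.array([np.cos(ang), np.sin(ang), 0.0])
        source = iso - source_iso_distance * view
        center = source + source_detector_distance * view
        u = np.array([-np.sin(ang), np.cos(ang), 0.0])
        v = np.array([0.0, 0.0, 1.0])
        cams.append(
            CameraModel(
                source_position=source,
                detector_center=center,
                detector_axes=np.stack([u, v]),
                source_detector_distance=source_detector_distance,
            )
        )
    return cams[0], cams[1]


class SilhouetteProjector:
    """Occluding-contour extraction + central projection for one mesh.

    Precomputes edge/face adjacency once so that repeated evaluation at
    candidate poses (the inner loop of silhouette registration) is cheap.
    The facing test is perspective-correct: each face is classified by the
    sign of its normal against the ray from the face centroid to the source.
    """

    def __init__(self, mesh: SurfaceMesh):
        tm = mesh.to_trimesh()
        if not tm.is_watertight:
            raise InvalidInputError("silhouette projection requires a watertight mesh")
        self.vertices = mesh.vertices.copy()
        self.faces = mesh.faces.copy()
        self.adjacency = tm.face_adjacency.astype(np.int64)
        self.adjacency_edges = tm.face_adjacency_edges.astype(np.int64)

    def silhouette_segments(self, pose: RigidPose, camera: CameraModel) -> np.ndarray:
        """Projected silhouette edges as 2D segments, shape (m, 2, 2)."""
        vw = self.vertices @ pose.rotation.T + pose.translation
        tri = vw[self.faces]
        centroids = tri.mean(axis=1)
        normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        to_source = camera.source_position - centroids
        facing = np.einsum("ij,ij->i", normals, to_source) > 0.0
        sil = facing[self.adjacency[:, 0]] != facing[self.adjacency[:, 1]]
        edges = self.adjacency_edges[sil]
        if len(edges) == 0:
            raise ProjectionGeometryError("no silhouette edges (source inside mesh?)")
        n = camera.view_direction
        depths = (vw - camera.source_position) @ n
        if depths.min() <= 1e-6:
            raise ProjectionGeometryError("mesh at or behind the X-ray source")
        p0 = camera.project(vw[edges[:, 0]])
        p1 = camera.project(vw[edges[:, 1]])
        return np.stack([p0, p1], axis=1)


def project_silhouette(
    mesh: SurfaceMesh,
    pose: RigidPose,
    camera: CameraModel,
    n_samples: int = 200,
    view_id: str = "view",
    projector: Optional[SilhouetteProjector] = None,
) -> Contour2D:
    """Sample the projected occluding contour to exactly ``n_samples`` points.

    Points are placed uniformly by cumulative arc length along the projected
    silhouette edge segments (segment order is arbitrary; the contour is a
    point set, not an ordered polyline).
    """
    if n_samples < 20:
        raise InvalidParameterError("n_samples must be >= 20")
    proj = projector or SilhouetteProjector(mesh)
    segs = proj.silhouette_segments(pose, camera)
    lengths = np.linalg.norm(segs[:, 1] - segs[:, 0], axis=1)
    keep = lengths > 1e-12
    segs, lengths = segs[keep], lengths[keep]
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    total = cum[-1]
    s = (np.arange(n_samples) + 0.5) * total / n_samples
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(lengths) - 1)
    frac = (s - cum[idx]) / lengths[idx]
    pts = segs[idx, 0] + frac[:, None] * (segs[idx, 1] - segs[idx, 0])
    return Contour2D(view_id=view_id, points=pts)


# ---------------------------------------------------------------------------
# activity trajectories
# ---------------------------------------------------------------------------

# Keyframes: (phase_key, contact_AP mm, contact_ML mm, flexion deg, internal
# rotation deg).  Contact keys encode the reference in vivo medial contact
# trajectories: gait stance keyed by percent stance, lunge and sit-to-stand
# keyed by knee flexion angle.
_STANCE_KEYFRAMES = [
    (0.0, 7.4, 0.8, 5.0, 0.0),
    (20.0, 3.1, 2.2, 15.0, 2.0),
    (50.0, 4.8, 2.7, 8.0, 3.0),
    (80.0, 6.6, 2.0, 8.0, 2.0),
    (100.0, 4.5, 0.8, 30.0, 1.0),
]
_LUNGE_KEYFRAMES = [
    (0.0, 5.8, -0.2, 0.0, 0.0),
    (36.0, -0.2, 1.4, 36.0, 3.0),
    (70.0, -0.3, 2.2, 70.0, 6.0),
    (100.0, -0.2, 0.2, 100.0, 8.0),
]
_SIT_TO_STAND_KEYFRAMES = [
    (0.0, 7.3, 2.5, 0.0, 0.0),
    (44.0, 0.9, 0.4, 44.0, 4.0),
    (76.0, 0.7, 1.2, 76.0, 6.0),
    (90.0, -0.6, 2.1, 90.0, 7.0),
]

_DEFAULT_KEYFRAMES = {
    "stance": _STANCE_KEYFRAMES,
    "lunge": _LUNGE_KEYFRAMES,
    "sit_to_stand": _SIT_TO_STAND_KEYFRAMES,
}
_PHASE_AXES = {
    "stance": "percent_stance",
    "lunge": "flexion_angle",
    "sit_to_stand": "flexion_angle",
}


def default_keyframes(activity: str) -> list[tuple]:
    try:
        return [tuple(k) for k in _DEFAULT_KEYFRAMES[activity]]
    except KeyError:
        raise InvalidParameterError(
            f"unknown activity {activity!r}; expected one of {sorted(_DEFAULT_KEYFRAMES)}"
        ) from None


def generate_activity_trajectory(
    activity: str,
    implant_set: ImplantSet,
    keyframes: Optional[Sequence[tuple]] = None,
    n_frames: int = 21,
    noise_sd: Optional[tuple[float, float]] = None,
    seed: Optional[int] = None,
) -> MotionTrajectory:
    """Smooth pose sequence whose ground-truth contact follows the keyframes.

    The tibial component is held at the identity (world frame = tibial
    component frame).  The femoral component is rotated by the keyframed
    flexion (about its ML/tube axis) and internal rotation, and translated
    so that the lowest point of its toroidal articular surface sits exactly
    over the keyframed contact AP/ML on the insert superior surface.  By
    torus symmetry the lowest articular point is always directly below the
    femoral frame origin while the needed patch angle stays inside the arc
    span, so on a flat insert the analytic contact equals the keyframe
    interpolant at every frame.

    Channels are interpolated with monotone (PCHIP) cubics: no overshoot
    between key values.  ``noise_sd = (rot_sd_deg, trans_sd_mm)`` adds
    per-frame i.i.d. Gaussian jitter to all six pose parameters of both
    components (seeded).
    """
    if activity not in _DEFAULT_KEYFRAMES:
        raise InvalidParameterError(f"unknown activity {activity!r}")
    keys = [tuple(map(float, k)) for k in (keyframes or _DEFAULT_KEYFRAMES[activity])]
    if len(keys) < 2:
        raise InvalidParameterError("need at least two keyframes")
    arr = np.asarray(keys, dtype=float)
    if np.any(np.diff(arr[:, 0]) <= 0):
        raise InvalidParameterError("keyframes must be sorted by phase key")
    if n_frames < len(keys):
        raise InvalidParameterError("n_frames must be >= number of keyframes")

    half_l = implant_set.insert_length / 2
    half_w = implant_set.insert_width / 2
    if np.any(np.abs(arr[:, 1]) > half_l) or np.any(np.abs(arr[:, 2]) > half_w):
        raise OutOfFootprintError("keyframed contact lies outside the insert footprint")

    phases = np.linspace(arr[0, 0], arr[-1, 0], n_frames)
    interp = {
        name: PchipInterpolator(arr[:, 0], arr[:, col])
        for name, col in (("ap", 1), ("ml", 2), ("flexion", 3), ("internal_rotation", 4))
    }
    ap = interp["ap"](phases)
    ml = interp["ml"](phases)
    flexion = interp["flexion"](phases)
    ir = interp["internal_rotation"](phases)

    fem_meta = implant_set.femoral_condyle.metadata
    r_sag = float(fem_meta.get("sagittal_radius", 24.0))
    arc_span = float(fem_meta.get("arc_span", 160.0))
    usable = arc_span / 2 - 10.0  # keep the contact away from the patch edge
    f_lo, f_hi = float(flexion.min()), float(flexion.max())
    mount = 0.0
    if f_hi > usable or f_lo < -usable:
        mount = (f_lo + f_hi) / 2.0
        if f_hi - mount > usable:
            raise InvalidParameterError(
                "flexion range exceeds the femoral articular arc span"
            )

    ins_meta = implant_set.insert.metadata
    hfn = _insert_height_fn(ins_meta.get("dish_radius"), float(ins_meta.get("thickness", 8.0)))
    z_top = np.asarray(hfn(ap, ml), dtype=float)

    rng = np.random.default_rng(seed)
    femur_poses, tibia_poses = [], []
    for i in range(n_frames):
        # flexion / internal rotation are of the tibia relative to the femur;
        # with the tibia fixed the femoral component rotates by -flexion
        # about its (medial) tube axis and -ir about the proximal axis
        params = np.array(
            [0.0, -(flexion[i] - mount), -ir[i], ap[i], ml[i], z_top[i] + r_sag]
        )
        tib = np.zeros(6)
        if noise_sd is not None:
            rot_sd, trans_sd = noise_sd
            params[:3] += rng.normal(0.0, rot_sd, 3)
            params[3:] += rng.normal(0.0, trans_sd, 3)
            tib[:3] += rng.normal(0.0, rot_sd, 3)
            tib[3:] += rng.normal(0.0, trans_sd, 3)
        femur_poses.append(RigidPose.from_params(params))
        tibia_poses.append(RigidPose.from_params(tib))

    return MotionTrajectory(
        activity=activity,
        phase_axis=_PHASE_AXES[activity],
        phase_keys=phases,
        femur_poses=femur_poses,
        tibia_poses=tibia_poses,
        truth={
            "contact_ap": ap,
            "contact_ml": ml,
            "flexion": flexion,
            "internal_rotation": ir,
            "mount_offset": mount,
        },
    )
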