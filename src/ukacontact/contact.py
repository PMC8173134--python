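"""Medial articular contact tracking on the polyethylene insert.

The contact point is defined on the insert superior surface (wear accrues
on the insert): the sample point of minimal signed distance to the femoral
articular surface, or of maximal penetration depth when the noisy
registration leaves the surfaces slightly interpenetrating.  Coordinates
are reported relative to the insert centroid along the tibial component
anteroposterior / mediolateral axes, in mm and as a percentage of the
insert length (AP) and width (ML), and can be mapped onto the
representative 43-mm insert for cross-subject averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import InvalidInputError, InvalidParameterError
from .geometry import RigidPose
from .meshquery import MeshDistanceQuery
from .phantom import (
    DEFAULT_INSERT_LENGTH,
    DEFAULT_INSERT_WIDTH,
    ImplantSet,
    SurfaceMesh,
    _insert_height_fn,
)

__all__ = [
    "ContactRecord",
    "ContactSeries",
    "ActivitySummary",
    "WearReferenceCenter",
    "DEFAULT_WEAR_REFERENCE",
    "ContactEngine",
    "closest_point_contact",
    "normalize_contact",
    "map_to_representative",
    "excursion_summary",
    "offset_vs_reference",
]

GAP_CEILING_MM = 6.0  # beyond plausible joint distraction -> registration failure
TIE_TOL_MM = 1e-6
MAX_PENETRATION_MM = 3.0  # deeper interpenetration falls back to full search


@dataclass(frozen=True)
class ContactRecord:
    """Medial contact location for one frame (insert-centroid coordinates)."""

    ap: float  # mm, anterior +
    ml: float  # mm, medial +
    gap: float  # mm, signed closest distance; negative = penetration
    phase_key: Optional[float] = None
    ap_pct: Optional[float] = None
    ml_pct: Optional[float] = None
    flags: tuple = ()

    @property
    def no_contact(self) -> bool:
        return "no_contact" in self.flags


@dataclass
class ContactSeries:
    activity: str
    phase_axis: str
    records: list

    def __len__(self) -> int:
        return len(self.records)

    def channel(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.records], dtype=float)


@dataclass(frozen=True)
class WearReferenceCenter:
    """Centre of an in vitro wear / stress region on the representative insert."""

    source_label: str
    ap_pct: float
    ml_pct: float
    ap_mm: Optional[float] = None  # printed mm on the representative insert
    ml_mm: Optional[float] = None

    def as_mm(
        self,
        rep_length: float = DEFAULT_INSERT_LENGTH,
        rep_width: float = DEFAULT_INSERT_WIDTH,
    ) -> tuple[float, float]:
        ap = self.ap_mm if self.ap_mm is not None else self.ap_pct * rep_length / 100.0
        ml = self.ml_mm if self.ml_mm is not None else self.ml_pct * rep_width / 100.0
        return float(ap), float(ml)


# Aggregate centre of published in vitro wear-region / stress-distribution
# centres mapped onto the representative 43-mm insert: 0.5 mm posterior,
# 0.7 mm medial of the insert centroid.
DEFAULT_WEAR_REFERENCE = WearReferenceCenter(
    source_label="in_vitro_aggregate", ap_pct=-1.1, ml_pct=2.6, ap_mm=-0.5, ml_mm=0.7
)


# ---------------------------------------------------------------------------
# closest-point contact
# ---------------------------------------------------------------------------


def _superior_samples(insert: SurfaceMesh) -> np.ndarray:
    idx = insert.metadata.get("superior_vertex_indices")
    if idx is not None:
        return insert.vertices[np.asarray(idx, dtype=np.int64)]
    # fallback: vertices belonging to upward-facing triangles
    from .geometry import triangle_normals

    normals = triangle_normals(insert.vertices, insert.faces)
    up = normals[:, 2] > 0.5
    verts = np.unique(insert.faces[up].ravel())
    if len(verts) == 0:
        raise InvalidInputError("insert has no upward-facing superior surface")
    return insert.vertices[verts]


class ContactEngine:
    """Repeated contact queries for one femoral component / insert pair.

    The femoral mesh is indexed once in its own component frame; per query
    the insert superior sample points are mapped into that frame, so the
    KD-tree never needs rebuilding as the femur moves.  With ``refine`` the
    discrete sample-point minimum is polished by a continuous 2D simplex
    search over the insert superior height field (available for phantom
    inserts), removing the sample-grid quantisation.
    """

    def __init__(
        self,
        femoral_mesh: SurfaceMesh,
        insert: SurfaceMesh,
        insert_centroid: Optional[np.ndarray] = None,
        gap_ceiling: float = GAP_CEILING_MM,
        exact: bool = True,
    ):
        self.query = MeshDistanceQuery(femoral_mesh.vertices, femoral_mesh.faces)
        self.samples = _superior_samples(insert)
        self.gap_ceiling = float(gap_ceiling)
        self.exact = exact
        c = insert_centroid
        if c is None:
            c = np.array([0.0, 0.0, 0.0])
        self.centroid_xy = np.asarray(c, dtype=float).reshape(3)[:2]
        md = insert.metadata
        self._height_fn = None
        self._half_l = self._half_w = None
        if "thickness" in md:
            self._height_fn = _insert_height_fn(md.get("dish_radius"), float(md["thickness"]))
            self._half_l = float(md.get("length", np.inf)) / 2
            self._half_w = float(md.get("width", np.inf)) / 2

    def _signed_gap(self, points_tibial: np.ndarray, femur_pose: RigidPose) -> np.ndarray:
        local = femur_pose.inverse().apply(points_tibial)
        gap, _, _ = self.query.signed_query(local, exact=self.exact)
        return gap

    def contact_at(
        self,
        femur_pose: RigidPose,
        phase_key: Optional[float] = None,
        refine: bool = True,
        start_xy: Optional[np.ndarray] = None,
    ) -> ContactRecord:
        """Contact record for the femur at ``femur_pose`` in the tibial frame.

        The discrete stage prunes with a nearest-vertex lower bound: a
        sample whose nearest femoral vertex is farther than the incumbent
        best distance plus the mesh bounding radius cannot be the closest
        sample, so only near-minimal samples get an exact point-to-triangle
        evaluation.  The surviving argmin (with ties resolved to the most
        posterior sample) is identical to exhaustive search.

        ``start_xy`` (with ``refine=True``) warm-starts the continuous
        polish from a known nearby contact and skips the discrete stage —
        used when tracking small pose perturbations of a solved frame.
        """
        if refine and start_xy is not None and self._height_fn is not None:
            # start_xy is centroid-relative (AP, ML), like ContactRecord
            x = float(start_xy[0]) + self.centroid_xy[0]
            y = float(start_xy[1]) + self.centroid_xy[1]
            p0 = np.array([x, y, float(self._height_fn(x, y))])
            point, gap = self._refine(p0, femur_pose, step=0.3)
            flags = [] if gap <= self.gap_ceiling else ["no_contact"]
            return ContactRecord(
                ap=float(point[0] - self.centroid_xy[0]),
                ml=float(point[1] - self.centroid_xy[1]),
                gap=gap,
                phase_key=phase_key,
                flags=tuple(flags),
            )
        local = femur_pose.inverse().apply(self.samples)
        dv, _ = self.query.vertex_tree.query(local)
        r = self.query.radius
        # near-minimal outside samples, plus anything shallow enough to be
        # interpenetrating (an inside sample at depth t has dv <= t + r)
        mask = (dv - r <= dv.min() + TIE_TOL_MM) | (dv <= MAX_PENETRATION_MM + r)
        shortlist = np.flatnonzero(mask)
        gaps, _, _ = self.query.signed_query(local[shortlist], exact=self.exact)
        if gaps.min() < -MAX_PENETRATION_MM:  # deeper than the prune allows
            shortlist = np.arange(len(self.samples))
            gaps, _, _ = self.query.signed_query(local, exact=self.exact)
        best = float(gaps.min())
        flags: list[str] = []
        cand = shortlist[np.flatnonzero(gaps <= best + TIE_TOL_MM)]
        if len(cand) > 1:
            flags.append("tie")
        # deterministic tie-break: most posterior (lowest AP) candidate
        i = cand[np.argmin(self.samples[cand, 0])]
        point = self.samples[i]
        gap = float(gaps[np.searchsorted(shortlist, i)])

        if refine and self._height_fn is not None:
            point, gap = self._refine(point, femur_pose)

        if gap > self.gap_ceiling:
            flags.append("no_contact")
        return ContactRecord(
            ap=float(point[0] - self.centroid_xy[0]),
            ml=float(point[1] - self.centroid_xy[1]),
            gap=gap,
            phase_key=phase_key,
            flags=tuple(flags),
        )

    def _refine(self, start: np.ndarray, femur_pose: RigidPose, step: float = 0.6):
        hfn = self._height_fn
        half_l, half_w = self._half_l, self._half_w

        def objective(xy):
            x, y = xy
            penalty = 0.0
            if abs(x) > half_l:
                penalty += (abs(x) - half_l) ** 2
            if abs(y) > half_w:
                penalty += (abs(y) - half_w) ** 2
            x = np.clip(x, -half_l, half_l)
            y = np.clip(y, -half_w, half_w)
            p = np.array([[x, y, float(hfn(x, y))]])
            return float(self._signed_gap(p, femur_pose)[0]) + penalty

        simplex = np.vstack([start[:2], start[:2] + np.eye(2) * step])
        res = minimize(
            objective,
            start[:2],
            method="Nelder-Mead",
            options={
                "xatol": 1e-4,
                "fatol": 1e-9,
                "maxfev": 150,
                "initial_simplex": simplex,
            },
        )
        x = np.clip(res.x[0], -half_l, half_l)
        y = np.clip(res.x[1], -half_w, half_w)
        point = np.array([x, y, float(hfn(x, y))])
        gap = float(self._signed_gap(point[None], femur_pose)[0])
        if gap > float(self._signed_gap(start[None], femur_pose)[0]):
            point = start
            gap = float(self._signed_gap(start[None], femur_pose)[0])
        return point, gap


def closest_point_contact(
    femoral_mesh_in_tibial_frame: SurfaceMesh,
    insert: SurfaceMesh,
    insert_centroid: Optional[np.ndarray] = None,
    gap_ceiling: float = GAP_CEILING_MM,
    refine: bool = False,
) -> ContactRecord:
    """One-shot closest-point contact between femoral surface and insert.

    Both meshes must be expressed in the tibial component frame.  With the
    default ``refine=False`` the result is the exact discrete minimum over
    the insert superior sample points (identical to exhaustive
    vertex-triangle search); ``refine=True`` adds the continuous polish.
    """
    engine = ContactEngine(
        femoral_mesh_in_tibial_frame, insert, insert_centroid, gap_ceiling
    )
    return engine.contact_at(RigidPose.identity(), refine=refine)


# ---------------------------------------------------------------------------
# normalisation / mapping / summaries
# ---------------------------------------------------------------------------


def normalize_contact(
    record: ContactRecord,
    insert_length: float = DEFAULT_INSERT_LENGTH,
    insert_width: float = DEFAULT_INSERT_WIDTH,
) -> ContactRecord:
    """Fill the percentage twins: AP by insert length, ML by insert width."""
    if insert_length <= 0 or insert_width <= 0:
        raise InvalidParameterError("insert dimensions must be positive")
    return replace(
        record,
        ap_pct=record.ap / insert_length * 100.0,
        ml_pct=record.ml / insert_width * 100.0,
    )


def map_to_representative(
    record: ContactRecord,
    source_length: float,
    source_width: float,
    rep_length: float = DEFAULT_INSERT_LENGTH,
    rep_width: float = DEFAULT_INSERT_WIDTH,
) -> ContactRecord:
    """Percentage-preserving rescale onto the representative insert."""
    if min(source_length, source_width, rep_length, rep_width) <= 0:
        raise InvalidParameterError("insert dimensions must be positive")
    norm = normalize_contact(record, source_length, source_width)
    return replace(
        norm,
        ap=norm.ap_pct * rep_length / 100.0,
        ml=norm.ml_pct * rep_width / 100.0,
    )


@dataclass
class ActivitySummary:
    """Cross-subject contact excursion summary (mean, SD) per quantity."""

    activity: str
    ap_avg_mm: tuple
    ap_range_mm: tuple
    ml_avg_mm: tuple
    ml_range_mm: tuple
    ap_avg_pct: tuple
    ap_range_pct: tuple
    ml_avg_pct: tuple
    ml_range_pct: tuple
    n_subjects: int
    n_skipped_trials: int = 0
    per_subject: dict = field(default_factory=dict)


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return float(np.mean(v)), sd


def excursion_summary(
    trials_by_subject: dict,
    activity: str = "",
    insert_length: float = DEFAULT_INSERT_LENGTH,
    insert_width: float = DEFAULT_INSERT_WIDTH,
) -> ActivitySummary:
    """Per-trial average and range of the contact coordinates, pooled.

    ``trials_by_subject`` maps subject id -> list of trials, each trial a
    sequence of :class:`ContactRecord`.  Per trial: average = frame mean of
    the coordinate, range = max - min over frames.  Trials of one subject
    are averaged, then mean +/- sample SD is taken across subjects.  Empty
    or single-frame trials are skipped (counted).  Normalised twins divide
    by the insert length (AP) / width (ML), times 100.
    """
    per_subject = {}
    skipped = 0
    for subject, trials in trials_by_subject.items():
        rows = []
        for trial in trials:
            recs = [r for r in trial if not r.no_contact]
            if len(recs) < 2:
                skipped += 1
                continue
            ap = np.array([r.ap for r in recs])
            ml = np.array([r.ml for r in recs])
            rows.append([ap.mean(), ap.max() - ap.min(), ml.mean(), ml.max() - ml.min()])
        if rows:
            per_subject[subject] = np.mean(np.asarray(rows), axis=0)
    if not per_subject:
        raise InvalidInputError("no usable trials in excursion summary")
    table = np.array(list(per_subject.values()))  # (s, 4)
    stats = [_mean_sd(table[:, j]) for j in range(4)]
    scale = [100.0 / insert_length, 100.0 / insert_length, 100.0 / insert_width, 100.0 / insert_width]
    pct = [(m * s, sd * s) for (m, sd), s in zip(stats, scale)]
    return ActivitySummary(
        activity=activity,
        ap_avg_mm=stats[0],
        ap_range_mm=stats[1],
        ml_avg_mm=stats[2],
        ml_range_mm=stats[3],
        ap_avg_pct=pct[0],
        ap_range_pct=pct[1],
        ml_avg_pct=pct[2],
        ml_range_pct=pct[3],
        n_subjects=len(per_subject),
        n_skipped_trials=skipped,
        per_subject=per_subject,
    )


def offset_vs_reference(
    ap_mm,
    ml_mm,
    reference: WearReferenceCenter = DEFAULT_WEAR_REFERENCE,
    rep_length: float = DEFAULT_INSERT_LENGTH,
    rep_width: float = DEFAULT_INSERT_WIDTH,
):
    """Signed offsets (in vivo - in vitro reference), anterior + / medial +.

    ``ap_mm`` / ``ml_mm`` may be scalars (group means) or per-subject
    arrays; returns matching offsets plus the group (mean, SD) when arrays
    are given.
    """
    ref_ap, ref_ml = reference.as_mm(rep_length, rep_width)
    ap = np.asarray(ap_mm, dtype=float)
    ml = np.asarray(ml_mm, dtype=float)
    ap_off = ap - ref_ap
    ml_off = ml - ref_ml
    if ap_off.ndim == 0:
        return float(ap_off), float(ml_off)
    return (ap_off, ml_off), (_mean_sd(ap_off), _mean_sd(ml_off))
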