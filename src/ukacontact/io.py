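"""File formats: meshes (STL/PLY), pose/contour/contact tables (CSV),
configuration and wear references (YAML).

Every CSV written here carries a comment header stating units and the
coordinate convention (right knee, anterior+/medial+/proximal+), because
sign-flip mistakes are the dominant failure mode when exchanging joint
kinematics data.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .contact import ContactRecord, ContactSeries, WearReferenceCenter
from .errors import ParseError, UnsupportedFormatError
from .geometry import RigidPose
from .kinematics import KinematicsSeries
from .phantom import Contour2D, MotionTrajectory, SurfaceMesh

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_trajectory",
    "write_trajectory",
    "read_contours",
    "write_contours",
    "write_kinematics",
    "write_contacts",
    "read_table",
    "write_table",
    "read_wear_references",
    "packaged_wear_references",
    "packaged_reference_summary",
    "CONVENTION_HEADER",
]

_MESH_FORMATS = {".stl", ".ply"}
CONVENTION_HEADER = (
    "# convention: right knee; x=anterior(+), y=medial(+), z=proximal(+); "
    "angles deg, lengths mm"
)


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def read_mesh(path: Union[str, Path], frame_label: str = "unknown") -> SurfaceMesh:
    """Read an STL or PLY mesh (ASCII or binary) into a SurfaceMesh."""
    import trimesh

    path = Path(path)
    if path.suffix.lower() not in _MESH_FORMATS:
        raise UnsupportedFormatError(f"unsupported mesh format: {path.suffix!r}")
    try:
        tm = trimesh.load_mesh(str(path), process=False)
    except Exception as exc:  # noqa: BLE001 - normalise loader failures
        raise ParseError(f"cannot parse mesh file {path}: {exc}") from exc
    if not hasattr(tm, "faces") or len(getattr(tm, "faces", [])) == 0:
        raise ParseError(f"no triangles parsed from {path}")
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), frame_label)


def write_mesh(mesh: SurfaceMesh, path: Union[str, Path], binary: bool = True) -> Path:
    path = Path(path)
    if path.suffix.lower() not in _MESH_FORMATS:
        raise UnsupportedFormatError(f"unsupported mesh format: {path.suffix!r}")
    tm = mesh.to_trimesh()
    if path.suffix.lower() == ".stl":
        tm.export(str(path), file_type="stl" if binary else "stl_ascii")
    else:
        tm.export(str(path), file_type="ply", encoding="binary" if binary else "ascii")
    return path


# ---------------------------------------------------------------------------
# trajectories / poses
# ---------------------------------------------------------------------------

_POSE_COLS = [
    f"{comp}_{p}" for comp in ("femur", "tibia") for p in ("rx", "ry", "rz", "tx", "ty", "tz")
]


def write_trajectory(traj: MotionTrajectory, path: Union[str, Path]) -> Path:
    path = Path(path)
    rows = []
    for i in range(traj.n_frames):
        rows.append(
            np.concatenate(
                [[traj.phase_keys[i]], traj.femur_poses[i].as_params(), traj.tibia_poses[i].as_params()]
            )
        )
    df = pd.DataFrame(rows, columns=["phase_key"] + _POSE_COLS)
    with open(path, "w") as fh:
        fh.write(CONVENTION_HEADER + "\n")
        fh.write(
            f"# activity={traj.activity} phase_axis={traj.phase_axis}; "
            "pose params: intrinsic Z-X-Y Euler (rx,ry,rz) deg + translation mm\n"
        )
        df.to_csv(fh, index=False)
    return path


def read_trajectory(path: Union[str, Path]) -> MotionTrajectory:
    path = Path(path)
    meta = {"activity": "unknown", "phase_axis": "unknown"}
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#") and "activity=" in line:
            for tok in line.lstrip("# ").split(";")[0].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    try:
        df = pd.read_csv(_io.StringIO(text), comment="#")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot parse trajectory CSV {path}: {exc}") from exc
    missing = [c for c in ["phase_key"] + _POSE_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"trajectory CSV {path} missing columns {missing}")
    fem = [RigidPose.from_params(row) for row in df[_POSE_COLS[:6]].to_numpy()]
    tib = [RigidPose.from_params(row) for row in df[_POSE_COLS[6:]].to_numpy()]
    return MotionTrajectory(
        activity=meta["activity"],
        phase_axis=meta["phase_axis"],
        phase_keys=df["phase_key"].to_numpy(),
        femur_poses=fem,
        tibia_poses=tib,
    )


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------


def write_contours(contours: Sequence[Contour2D], path: Union[str, Path]) -> Path:
    path = Path(path)
    frames = []
    for c in contours:
        frames.append(
            pd.DataFrame({"view_id": c.view_id, "u_mm": c.points[:, 0], "v_mm": c.points[:, 1]})
        )
    with open(path, "w") as fh:
        fh.write("# silhouette contour samples; detector-plane coordinates, mm\n")
        pd.concat(frames, ignore_index=True).to_csv(fh, index=False)
    return path


def read_contours(path: Union[str, Path]) -> list[Contour2D]:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot parse contour CSV {path}: {exc}") from exc
    if not {"view_id", "u_mm", "v_mm"} <= set(df.columns):
        raise ParseError(f"contour CSV {path} must have view_id,u_mm,v_mm columns")
    out = []
    for vid, grp in df.groupby("view_id", sort=False):
        out.append(Contour2D(view_id=str(vid), points=grp[["u_mm", "v_mm"]].to_numpy()))
    return out


# ---------------------------------------------------------------------------
# kinematics / contact tables
# ---------------------------------------------------------------------------


def write_kinematics(series: KinematicsSeries, path: Union[str, Path]) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "phase_key": series.phase_keys,
            "flexion_deg": series.flexion,
            "adduction_deg": series.adduction,
            "internal_rotation_deg": series.internal_rotation,
            "ap_mm": series.ap,
            "pd_mm": series.pd,
            "ml_mm": series.ml,
        }
    )
    with open(path, "w") as fh:
        fh.write(CONVENTION_HEADER + "\n")
        fh.write(f"# activity={series.activity} phase_axis={series.phase_axis}\n")
        df.to_csv(fh, index=False)
    return path


def write_contacts(series: ContactSeries, path: Union[str, Path]) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "phase_key": [r.phase_key for r in series.records],
            "ap_mm": [r.ap for r in series.records],
            "ml_mm": [r.ml for r in series.records],
            "ap_pct": [r.ap_pct for r in series.records],
            "ml_pct": [r.ml_pct for r in series.records],
            "gap_mm": [r.gap for r in series.records],
            "flags": ["|".join(r.flags) for r in series.records],
        }
    )
    with open(path, "w") as fh:
        fh.write(CONVENTION_HEADER + "\n")
        fh.write(
            f"# activity={series.activity} phase_axis={series.phase_axis}; "
            "contact relative to insert centroid\n"
        )
        df.to_csv(fh, index=False)
    return path


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot parse table {path}: {exc}") from exc


def write_table(df: pd.DataFrame, path: Union[str, Path], header: Optional[str] = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write((header or CONVENTION_HEADER) + "\n")
        df.to_csv(fh, index=False)
    return path


# ---------------------------------------------------------------------------
# wear references / packaged data
# ---------------------------------------------------------------------------


def read_wear_references(path: Union[str, Path]) -> list[WearReferenceCenter]:
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ParseError(f"cannot parse wear-reference YAML {path}: {exc}") from exc
    out = []
    for entry in doc.get("centers", []):
        out.append(
            WearReferenceCenter(
                source_label=str(entry["label"]),
                ap_pct=float(entry["ap_pct"]),
                ml_pct=float(entry["ml_pct"]),
                ap_mm=None if entry.get("ap_mm") is None else float(entry["ap_mm"]),
                ml_mm=None if entry.get("ml_mm") is None else float(entry["ml_mm"]),
            )
        )
    if not out:
        raise ParseError(f"no wear-reference centers found in {path}")
    return out


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def packaged_wear_references() -> list[WearReferenceCenter]:
    """The in vitro wear-region reference centers shipped with the package."""
    return read_wear_references(_data_path("wear_reference.yaml"))


def packaged_reference_summary() -> pd.DataFrame:
    """Published in vivo contact-excursion summary on the 43-mm insert."""
    return read_table(_data_path("reference_contact_summary.csv"))
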