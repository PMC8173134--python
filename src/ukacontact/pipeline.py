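"""End-to-end orchestration: phantom -> projection -> registration ->
kinematics -> contact -> summaries -> sensitivity -> statistics.

The pipeline is deterministic under a fixed top-level seed: every
stochastic stage draws its own seed from a :class:`numpy.random.SeedSequence`
spawned from the configured seed, and the run manifest records SHA-256
hashes of every artifact so that reruns can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contact import (
    ContactEngine,
    ContactSeries,
    excursion_summary,
    normalize_contact,
    offset_vs_reference,
)
from .errors import ConfigError
from .geometry import RigidPose
from .io import (
    packaged_reference_summary,
    packaged_wear_references,
    write_contacts,
    write_kinematics,
    write_mesh,
    write_table,
    write_trajectory,
)
from .kinematics import decompose_trajectory, resample_series
from .phantom import (
    MotionTrajectory,
    SilhouetteProjector,
    generate_activity_trajectory,
    make_camera_pair,
    make_femoral_component,
    make_implant_set,
    project_silhouette,
)
from .registration import OptimizerConfig, estimate_pose_dfis
from .sensitivity import NoiseSpec, propagate_pose_noise
from .stats import duncan_posthoc, ks_normality, one_way_anova, rank_sum_test

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]


_SCHEMA = {
    "seed": int,
    "output_dir": str,
    "save_meshes": bool,
    "phantom": {
        "sagittal_radius": float,
        "coronal_radius": float,
        "arc_span": float,
        "insert_length": float,
        "insert_width": float,
        "insert_thickness": float,
        "dish_radius": (float, type(None)),
        "registration_resolution": int,
        "contact_resolution": int,
    },
    "cameras": {
        "source_iso_distance": float,
        "source_detector_distance": float,
        "angle_between": float,
    },
    "activities": dict,  # name -> {n_frames: int}
    "registration": {
        "n_contour_samples": int,
        "init_rot_perturb": float,
        "init_trans_perturb": float,
        "max_fev": int,
        "restarts": int,
    },
    "contact": {"refine": bool, "gap_ceiling": float},
    "sensitivity": {
        "enabled": bool,
        "n_replicates": int,
        "frames": list,
        "femur_rot_sd": float,
        "femur_trans_sd": float,
        "tibia_rot_sd": float,
        "tibia_trans_sd": float,
    },
    "stats": {"alpha": float},
}

_DEFAULTS = {
    "seed": 0,
    "output_dir": "ukacontact_out",
    "save_meshes": False,
    "phantom": {
        "sagittal_radius": 24.0,
        "coronal_radius": 11.0,
        "arc_span": 160.0,
        "insert_length": 43.0,
        "insert_width": 26.5,
        "insert_thickness": 8.0,
        "dish_radius": None,
        "registration_resolution": 28,
        "contact_resolution": 240,
    },
    "cameras": {
        "source_iso_distance": 700.0,
        "source_detector_distance": 1000.0,
        "angle_between": 90.0,
    },
    "activities": {"stance": {"n_frames": 11}},
    "registration": {
        "n_contour_samples": 150,
        "init_rot_perturb": 2.0,
        "init_trans_perturb": 2.0,
        "max_fev": 1500,
        "restarts": 2,
    },
    "contact": {"refine": True, "gap_ceiling": 6.0},
    "sensitivity": {
        "enabled": False,
        "n_replicates": 100,
        "frames": [5],
        "femur_rot_sd": 0.27,
        "femur_trans_sd": 0.10,
        "tibia_rot_sd": 0.39,
        "tibia_trans_sd": 0.18,
    },
    "stats": {"alpha": 0.05},
}


def _merge_validate(user: dict, schema: dict, defaults: dict, path: str = "") -> dict:
    out = {}
    for key, default in defaults.items():
        sub_schema = schema.get(key)
        if key in user:
            val = user[key]
            if isinstance(default, dict) and isinstance(sub_schema, dict):
                if not isinstance(val, dict):
                    raise ConfigError(f"{path}{key} must be a mapping")
                out[key] = _merge_validate(val, sub_schema, default, f"{path}{key}.")
            else:
                out[key] = val
        else:
            out[key] = default if not isinstance(default, dict) else dict(default)
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(path + k for k in unknown)}")
    return out


@dataclass
class PipelineConfig:
    raw: dict

    @classmethod
    def from_dict(cls, d: Optional[dict] = None) -> "PipelineConfig":
        return cls(_merge_validate(d or {}, _SCHEMA, _DEFAULTS))

    def __getitem__(self, key):
        return self.raw[key]

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_yaml().encode()).hexdigest()[:16]


def load_config(path: Union[str, Path, None] = None) -> PipelineConfig:
    if path is None:
        return PipelineConfig.from_dict({})
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(doc)


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    stages: dict = field(default_factory=dict)  # stage -> {files, seconds, warnings}
    summary: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "package_version": self.package_version,
                "seed": self.seed,
                "stages": self.stages,
                "summary": self.summary,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage(manifest: RunManifest, name: str, t0: float, files: list, **extra) -> None:
    manifest.stages[name] = {
        "seconds": round(time.time() - t0, 3),
        "files": {str(Path(f).name): _sha256(Path(f)) for f in files},
        **extra,
    }


def run_pipeline(config: Optional[PipelineConfig] = None) -> RunManifest:
    """Execute the full phantom study; returns the run manifest.

    Stages: build the phantom implants and cameras; generate each activity's
    motion; render dual-view silhouette contours per frame; recover both
    component poses by silhouette registration (first frame initialised at a
    seeded perturbation of the truth, later frames tracked from the previous
    estimate); decompose the 6-DOF kinematics; track, normalise and
    summarise the medial contact point; compare against the packaged in
    vitro wear-region center; optionally run the pose-noise sensitivity
    analysis; and run the statistical battery across activities.
    """
    cfg = config or PipelineConfig.from_dict({})
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg.hash(), __version__, cfg["seed"])
    seeds = np.random.SeedSequence(cfg["seed"]).generate_state(32) & 0x7FFFFFFF

    # --- phantom ------------------------------------------------------
    t0 = time.time()
    ph_cfg = cfg["phantom"]
    iset = make_implant_set(
        sagittal_radius=ph_cfg["sagittal_radius"],
        coronal_radius=ph_cfg["coronal_radius"],
        arc_span=ph_cfg["arc_span"],
        insert_length=ph_cfg["insert_length"],
        insert_width=ph_cfg["insert_width"],
        insert_thickness=ph_cfg["insert_thickness"],
        dish_radius=ph_cfg["dish_radius"],
        femoral_resolution=ph_cfg["registration_resolution"],
    )
    fem_contact = make_femoral_component(
        ph_cfg["sagittal_radius"],
        ph_cfg["coronal_radius"],
        ph_cfg["arc_span"],
        mesh_resolution=ph_cfg["contact_resolution"],
    )
    cams = make_camera_pair(
        source_iso_distance=cfg["cameras"]["source_iso_distance"],
        source_detector_distance=cfg["cameras"]["source_detector_distance"],
        angle_between=cfg["cameras"]["angle_between"],
    )
    files = []
    if cfg["save_meshes"]:
        files.append(write_mesh(iset.femoral_condyle, out_dir / "femoral_condyle.stl"))
        files.append(write_mesh(iset.insert, out_dir / "insert.stl"))
        files.append(write_mesh(iset.baseplate, out_dir / "baseplate.stl"))
    _stage(manifest, "phantom", t0, files)

    # --- per-activity loop -------------------------------------------
    reg_cfg = cfg["registration"]
    opt_cfg = OptimizerConfig(max_fev=reg_cfg["max_fev"], restarts=reg_cfg["restarts"])
    engine = ContactEngine(
        fem_contact,
        iset.insert,
        insert_centroid=iset.insert_centroid,
        gap_ceiling=cfg["contact"]["gap_ceiling"],
        exact=False,
    )
    fem_proj = SilhouetteProjector(iset.femoral_condyle)
    tib_proj = SilhouetteProjector(iset.baseplate)
    contact_by_activity: dict[str, ContactSeries] = {}
    truth_by_activity: dict[str, MotionTrajectory] = {}

    for a_idx, (activity, a_cfg) in enumerate(sorted(cfg["activities"].items())):
        t0 = time.time()
        traj = generate_activity_trajectory(
            activity, iset, n_frames=int(a_cfg.get("n_frames", 11)), seed=int(seeds[a_idx])
        )
        truth_by_activity[activity] = traj
        files = [write_trajectory(traj, out_dir / f"{activity}_truth_poses.csv")]

        rng = np.random.default_rng(int(seeds[8 + a_idx]))
        fem_est, tib_est, residuals = [], [], []
        for i in range(traj.n_frames):
            frame_est = []
            for truth_pose, proj, mesh in (
                (traj.femur_poses[i], fem_proj, iset.femoral_condyle),
                (traj.tibia_poses[i], tib_proj, iset.baseplate),
            ):
                contours = [
                    project_silhouette(
                        mesh, truth_pose, cam, reg_cfg["n_contour_samples"],
                        view_id=v, projector=proj,
                    )
                    for v, cam in zip("AB", cams)
                ]
                if i == 0:
                    perturb = np.concatenate(
                        [
                            rng.choice([-1.0, 1.0], 3) * reg_cfg["init_rot_perturb"],
                            rng.choice([-1.0, 1.0], 3) * reg_cfg["init_trans_perturb"],
                        ]
                    )
                    init = RigidPose.from_params(truth_pose.as_params() + perturb)
                else:
                    init = (fem_est if proj is fem_proj else tib_est)[i - 1]
                res = estimate_pose_dfis(mesh, contours, cams, init, opt_cfg, projector=proj)
                frame_est.append(res.pose)
                residuals.append(res.residual_rms)
            fem_est.append(frame_est[0])
            tib_est.append(frame_est[1])

        est_traj = MotionTrajectory(
            activity=activity,
            phase_axis=traj.phase_axis,
            phase_keys=traj.phase_keys,
            femur_poses=fem_est,
            tibia_poses=tib_est,
        )
        files.append(write_trajectory(est_traj, out_dir / f"{activity}_registered_poses.csv"))

        series = decompose_trajectory(est_traj)
        files.append(write_kinematics(series, out_dir / f"{activity}_kinematics.csv"))
        if traj.phase_axis == "percent_stance":
            grid = np.arange(0.0, 100.5, 1.0)
        else:
            grid = np.arange(0.0, series.flexion.max() + 1e-9, 2.0)
            grid = grid[(grid >= series.phase_keys.min()) & (grid <= series.phase_keys.max())]
        files.append(
            write_kinematics(
                resample_series(series, grid), out_dir / f"{activity}_kinematics_resampled.csv"
            )
        )

        records = []
        for i in range(traj.n_frames):
            rel = tib_est[i].inverse().compose(fem_est[i])
            rec = engine.contact_at(
                rel, phase_key=float(traj.phase_keys[i]), refine=cfg["contact"]["refine"]
            )
            records.append(
                normalize_contact(rec, iset.insert_length, iset.insert_width)
            )
        cseries = ContactSeries(activity=activity, phase_axis=traj.phase_axis, records=records)
        contact_by_activity[activity] = cseries
        files.append(write_contacts(cseries, out_dir / f"{activity}_contact.csv"))
        _stage(
            manifest, f"activity:{activity}", t0, files,
            mean_registration_rms=float(np.mean(residuals)),
        )

    # --- excursion summary + offsets ---------------------------------
    t0 = time.time()
    rows = []
    for activity, cseries in contact_by_activity.items():
        summ = excursion_summary(
            {"phantom_subject": [cseries.records]},
            activity=activity,
            insert_length=iset.insert_length,
            insert_width=iset.insert_width,
        )
        rows.append(
            {
                "activity": activity,
                "ap_avg_mm": summ.ap_avg_mm[0],
                "ap_range_mm": summ.ap_range_mm[0],
                "ml_avg_mm": summ.ml_avg_mm[0],
                "ml_range_mm": summ.ml_range_mm[0],
                "ap_avg_pct": summ.ap_avg_pct[0],
                "ap_range_pct": summ.ap_range_pct[0],
                "ml_avg_pct": summ.ml_avg_pct[0],
                "ml_range_pct": summ.ml_range_pct[0],
            }
        )
    summary_df = pd.DataFrame(rows)
    files = [
        write_table(
            summary_df,
            out_dir / "contact_summary.csv",
            header="# phantom contact excursion summary (single synthetic subject)",
        )
    ]

    reference = packaged_wear_references()[0]
    ref_summary = packaged_reference_summary()
    offset_rows = []
    for _, row in ref_summary.iterrows():
        ap_off, ml_off = offset_vs_reference(row["ap_avg_mm"], row["ml_avg_mm"], reference)
        offset_rows.append(
            {"activity": row["activity"], "ap_offset_mm": ap_off, "ml_offset_mm": ml_off}
        )
    offsets_df = pd.DataFrame(offset_rows)
    files.append(
        write_table(
            offsets_df,
            out_dir / "offsets_vs_in_vitro.csv",
            header="# in vivo average contact minus in vitro wear-region center "
            "(anterior+/medial+), representative insert",
        )
    )
    manifest.summary["offsets_vs_in_vitro"] = {
        r["activity"]: [round(r["ap_offset_mm"], 3), round(r["ml_offset_mm"], 3)]
        for r in offset_rows
    }
    _stage(manifest, "summary", t0, files)

    # --- sensitivity ---------------------------------------------------
    sens_cfg = cfg["sensitivity"]
    if sens_cfg["enabled"]:
        t0 = time.time()
        activity = sorted(cfg["activities"])[0]
        noise = NoiseSpec(
            sens_cfg["femur_rot_sd"],
            sens_cfg["femur_trans_sd"],
            sens_cfg["tibia_rot_sd"],
            sens_cfg["tibia_trans_sd"],
        )
        report = propagate_pose_noise(
            truth_by_activity[activity],
            iset,
            noise,
            n_replicates=sens_cfg["n_replicates"],
            seed=int(seeds[16]),
            engine=engine,
            frame_indices=np.asarray(sens_cfg["frames"], dtype=int),
        )
        sens_path = out_dir / "sensitivity.json"
        sens_path.write_text(json.dumps(asdict(report), indent=2, sort_keys=True))
        manifest.summary["sensitivity"] = {
            "ap": [round(report.ap_error_mean, 4), round(report.ap_error_sd, 4)],
            "ml": [round(report.ml_error_mean, 4), round(report.ml_error_sd, 4)],
        }
        _stage(manifest, "sensitivity", t0, [sens_path])

    # --- statistics ----------------------------------------------------
    if len(contact_by_activity) >= 2:
        t0 = time.time()
        labels = sorted(contact_by_activity)
        groups = [contact_by_activity[a].channel("ap") for a in labels]
        anova = one_way_anova(groups, labels)
        duncan = duncan_posthoc(groups, alpha=cfg["stats"]["alpha"], labels=labels)
        stats_out = {
            "anova": {"F": anova.F, "p": anova.p_value, "df": [anova.df_between, anova.df_within]},
            "duncan_subsets": [list(s) for s in duncan.homogeneous_subsets],
            "ks_normality": {
                a: list(ks_normality(contact_by_activity[a].channel("ap"))) for a in labels
            },
            "rank_sum_first_vs_last": list(rank_sum_test(groups[0], groups[-1])),
        }
        stats_path = out_dir / "stats.json"
        stats_path.write_text(json.dumps(stats_out, indent=2, sort_keys=True))
        manifest.summary["anova_p"] = anova.p_value
        _stage(manifest, "stats", t0, [stats_path])

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    return manifest
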