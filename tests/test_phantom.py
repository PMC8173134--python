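"""Phantom geometry, virtual fluoroscopes and activity trajectories."""

import numpy as np
import pytest

from ukacontact import phantom as ph
from ukacontact.errors import (
    InvalidParameterError,
    OutOfFootprintError,
    ProjectionGeometryError,
)
from ukacontact.geometry import RigidPose


# ---------------------------------------------------------------------------
# femoral component
# ---------------------------------------------------------------------------


class TestFemoralComponent:
    def test_watertight_outward_no_degenerate(self, femoral_component):
        tm = femoral_component.to_trimesh()
        assert tm.is_watertight
        assert tm.is_winding_consistent
        assert tm.volume > 0  # outward orientation

    def test_articular_vertices_on_torus(self):
        mesh = ph.make_femoral_component(22.0, 18.0, 120.0, 24)
        m = mesh.metadata
        art = mesh.vertices[m["articular_mask"]]
        ring = m["sagittal_radius"] - m["coronal_radius"]
        resid = (
            (np.sqrt(art[:, 0] ** 2 + art[:, 2] ** 2) - ring) ** 2
            + art[:, 1] ** 2
            - m["coronal_radius"] ** 2
        )
        assert np.abs(resid).max() < 1e-9

    def test_sphere_limit(self):
        mesh = ph.make_femoral_component(20.0, 20.0, 180.0, 24)
        art = mesh.vertices[mesh.metadata["articular_mask"]]
        assert np.allclose(np.linalg.norm(art, axis=1), 20.0, atol=1e-9)

    def test_refinement_reduces_chord_deviation(self):
        def max_torus_deviation(res):
            mesh = ph.make_femoral_component(24.0, 11.0, 160.0, res)
            # midpoint of each face vs the analytic torus surface
            mid = mesh.vertices[mesh.faces].mean(axis=1)
            ring = 24.0 - 11.0
            d = np.abs(
                np.sqrt((np.sqrt(mid[:, 0] ** 2 + mid[:, 2] ** 2) - ring) ** 2 + mid[:, 1] ** 2)
                - 11.0
            )
            # only faces whose vertices are all articular
            art = mesh.metadata["articular_mask"]
            keep = art[mesh.faces].all(axis=1)
            return d[keep].max()

        assert max_torus_deviation(32) < max_torus_deviation(16)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sagittal_radius": -1.0},
            {"coronal_radius": 0.0},
            {"arc_span": 60.0},
            {"arc_span": 200.0},
            {"mesh_resolution": 4},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ph.make_femoral_component(**kwargs)


# ---------------------------------------------------------------------------
# tibial insert / baseplate
# ---------------------------------------------------------------------------


class TestTibialInsert:
    def test_flat_superior_surface(self):
        ins = ph.make_tibial_insert(43.0, 26.5, None, 8.0, 24)
        sup = ins.vertices[ins.metadata["superior_vertex_indices"]]
        assert np.allclose(sup[:, 2], 8.0)
        assert ins.to_trimesh().is_watertight

    def test_infinite_dish_equals_flat(self):
        flat = ph.make_tibial_insert(dish_radius=None)
        inf = ph.make_tibial_insert(dish_radius=np.inf)
        assert np.allclose(flat.vertices, inf.vertices)

    def test_dish_spherical_cap_closed_form(self):
        R = 100.0
        ins = ph.make_tibial_insert(dish_radius=R, thickness=8.0)
        sup = ins.vertices[ins.metadata["superior_vertex_indices"]]
        r2 = sup[:, 0] ** 2 + sup[:, 1] ** 2
        assert np.allclose(sup[:, 2], 8.0 + R - np.sqrt(R**2 - r2), atol=1e-9)
        center = sup[np.argmin(r2)]
        assert np.isclose(center[2], sup[:, 2].min())

    def test_dish_radius_validation(self):
        with pytest.raises(InvalidParameterError):
            ph.make_tibial_insert(dish_radius=-5.0)
        with pytest.raises(InvalidParameterError):
            ph.make_tibial_insert(dish_radius=10.0)  # smaller than footprint

    def test_baseplate_top_flush_with_zero(self, baseplate):
        assert np.isclose(baseplate.vertices[:, 2].max(), 0.0)
        assert baseplate.to_trimesh().is_watertight


# ---------------------------------------------------------------------------
# cameras and silhouettes
# ---------------------------------------------------------------------------


class TestProjection:
    def test_camera_pair_geometry(self, camera_pair):
        a, b = camera_pair
        ang = np.degrees(np.arccos(np.clip(a.view_direction @ b.view_direction, -1, 1)))
        assert 80.0 <= ang <= 100.0

    def test_sphere_contour_closed_form(self, icosphere, camera_pair):
        cam = camera_pair[0]
        c = ph.project_silhouette(icosphere, RigidPose.identity(), cam, 300)
        r, d, D = 20.0, 700.0, 1000.0
        expected = D * r / np.sqrt(d * d - r * r)
        assert np.abs(np.linalg.norm(c.points, axis=1) - expected).max() < 0.15

    def test_translation_magnification(self, icosphere, camera_pair):
        cam = camera_pair[0]
        c0 = ph.project_silhouette(icosphere, RigidPose.identity(), cam, 300)
        c1 = ph.project_silhouette(icosphere, RigidPose(np.eye(3), [0, 3.0, 0]), cam, 300)
        shift = c1.points.mean(axis=0) - c0.points.mean(axis=0)
        assert np.isclose(shift[0], 3.0 * 1000.0 / 700.0, atol=0.05)

    def test_doubling_source_detector_distance_doubles_extent(self, icosphere):
        camD, _ = ph.make_camera_pair(source_detector_distance=1000.0)
        cam2D, _ = ph.make_camera_pair(source_detector_distance=2000.0)
        e1 = np.linalg.norm(
            ph.project_silhouette(icosphere, RigidPose.identity(), camD, 200).points, axis=1
        ).mean()
        e2 = np.linalg.norm(
            ph.project_silhouette(icosphere, RigidPose.identity(), cam2D, 200).points, axis=1
        ).mean()
        assert np.isclose(e2 / e1, 2.0, atol=1e-9)

    def test_exact_sample_count(self, femoral_component, camera_pair):
        c = ph.project_silhouette(femoral_component, RigidPose.identity(), camera_pair[0], 200)
        assert c.points.shape == (200, 2)

    def test_mesh_behind_source_rejected(self, icosphere, camera_pair):
        pose = RigidPose(np.eye(3), [-1500.0, 0.0, 0.0])  # behind camera A's source
        with pytest.raises(ProjectionGeometryError):
            ph.project_silhouette(icosphere, pose, camera_pair[0], 100)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


class TestTrajectory:
    def test_default_stance_keyframes_encoded(self, implant_set):
        traj = ph.generate_activity_trajectory("stance", implant_set, n_frames=11)
        idx = {0.0: 0, 20.0: 2, 80.0: 8, 100.0: 10}
        for phase, i in idx.items():
            assert np.isclose(traj.phase_keys[i], phase)
        assert np.allclose(
            traj.truth["contact_ap"][[0, 2, 8, 10]], [7.4, 3.1, 6.6, 4.5]
        )

    def test_default_sit_to_stand_keyframes_encoded(self, implant_set):
        traj = ph.generate_activity_trajectory("sit_to_stand", implant_set, n_frames=46)
        for phase, ap in [(0.0, 7.3), (44.0, 0.9), (76.0, 0.7), (90.0, -0.6)]:
            i = int(np.argmin(np.abs(traj.phase_keys - phase)))
            assert np.isclose(traj.phase_keys[i], phase)
            assert np.isclose(traj.truth["contact_ap"][i], ap)

    def test_monotone_interpolation_no_overshoot(self, implant_set):
        traj = ph.generate_activity_trajectory("stance", implant_set, n_frames=101)
        ap = traj.truth["contact_ap"]
        assert ap.max() <= 7.4 + 1e-9
        assert ap.min() >= 3.1 - 1e-9

    def test_seeded_determinism(self, implant_set):
        a = ph.generate_activity_trajectory(
            "stance", implant_set, n_frames=11, noise_sd=(0.3, 0.2), seed=7
        )
        b = ph.generate_activity_trajectory(
            "stance", implant_set, n_frames=11, noise_sd=(0.3, 0.2), seed=7
        )
        for pa, pb in zip(a.femur_poses, b.femur_poses):
            assert np.array_equal(pa.rotation, pb.rotation)
            assert np.array_equal(pa.translation, pb.translation)

    def test_out_of_footprint_rejected(self, implant_set):
        keys = [(0.0, 30.0, 0.0, 0.0, 0.0), (100.0, 0.0, 0.0, 10.0, 0.0)]
        with pytest.raises(OutOfFootprintError):
            ph.generate_activity_trajectory("stance", implant_set, keyframes=keys)

    def test_lowest_articular_point_tracks_keyframes(self, implant_set):
        """With zero noise, the analytic lowest point of the condyle equals
        the keyframe interpolant at every frame (flat insert)."""
        traj = ph.generate_activity_trajectory("stance", implant_set, n_frames=21)
        r_sag = implant_set.femoral_condyle.metadata["sagittal_radius"]
        for i, pose in enumerate(traj.femur_poses):
            lowest = pose.translation + np.array([0.0, 0.0, -r_sag])
            assert np.isclose(lowest[0], traj.truth["contact_ap"][i], atol=1e-9)
            assert np.isclose(lowest[1], traj.truth["contact_ml"][i], atol=1e-9)
            assert np.isclose(lowest[2], 8.0, atol=1e-9)  # insert thickness
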