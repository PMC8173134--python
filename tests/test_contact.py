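"""Closest-point contact, normalisation, summaries and offsets."""

import numpy as np
import pytest
import trimesh

from ukacontact import contact as ct
from ukacontact import phantom as ph
from ukacontact.errors import InvalidInputError
from ukacontact.geometry import RigidPose


@pytest.fixture(scope="module")
def flat_insert():
    return ph.make_tibial_insert(43.0, 26.5, None, 8.0, 30)


def sphere_at(center, radius=20.0, subdivisions=3):
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return ph.SurfaceMesh(np.asarray(tm.vertices) + np.asarray(center), tm.faces, "tibial_component")


class TestClosestPoint:
    def test_sphere_over_flat_insert(self, flat_insert):
        rec = ct.closest_point_contact(sphere_at([3.0, -2.0, 28.5]), flat_insert, refine=True)
        assert np.isclose(rec.ap, 3.0, atol=1e-6)
        assert np.isclose(rec.ml, -2.0, atol=1e-6)
        assert np.isclose(rec.gap, 0.5, atol=1e-3)

    def test_sphere_touching_zero_gap(self, flat_insert):
        rec = ct.closest_point_contact(sphere_at([3.0, -2.0, 28.0]), flat_insert, refine=True)
        assert np.isclose(rec.gap, 0.0, atol=1e-3)

    def test_penetration_negative_gap(self, flat_insert):
        rec = ct.closest_point_contact(sphere_at([0.0, 0.0, 27.6]), flat_insert, refine=True)
        assert rec.gap < 0.0
        assert np.isclose(rec.gap, -0.4, atol=5e-3)

    def test_no_contact_flag_beyond_gap_ceiling(self, flat_insert):
        rec = ct.closest_point_contact(sphere_at([0.0, 0.0, 40.0]), flat_insert)
        assert rec.no_contact

    def test_accelerated_equals_brute_force(self, flat_insert, rng):
        """Discrete contact equals an exhaustive sample-by-triangle search
        (independent trimesh kernel) on small meshes."""
        fem = ph.make_femoral_component(mesh_resolution=14)  # small mesh
        assert fem.n_faces <= 2000
        samples = flat_insert.vertices[flat_insert.metadata["superior_vertex_indices"]]
        tm = fem.to_trimesh()
        for _ in range(20):
            pose = RigidPose.from_params(
                np.concatenate(
                    [rng.uniform(-8, 8, 3), rng.uniform(-3, 3, 2), [32.0 + rng.uniform(0, 2)]]
                )
            )
            moved = fem.transformed(pose)
            rec = ct.closest_point_contact(moved, flat_insert, refine=False)
            # oracle: trimesh naive closest point over all triangles
            _, dist, _ = trimesh.proximity.closest_point_naive(
                trimesh.Trimesh(moved.vertices, moved.faces, process=False), samples
            )
            j = np.flatnonzero(dist <= dist.min() + 1e-6)
            j = j[np.argmin(samples[j, 0])]
            assert np.isclose(rec.gap, dist[j], atol=1e-9)
            assert np.isclose(rec.ap, samples[j, 0], atol=1e-12)
            assert np.isclose(rec.ml, samples[j, 1], atol=1e-12)

    def test_sphere_over_dish_matches_brute_force(self):
        dish = ph.make_tibial_insert(dish_radius=100.0, mesh_resolution=24)
        sph = sphere_at([2.0, 1.0, 28.7], subdivisions=3)
        rec = ct.closest_point_contact(sph, dish, refine=False)
        samples = dish.vertices[dish.metadata["superior_vertex_indices"]]
        _, dist, _ = trimesh.proximity.closest_point_naive(
            trimesh.Trimesh(sph.vertices, sph.faces, process=False), samples
        )
        j = np.flatnonzero(dist <= dist.min() + 1e-6)
        j = j[np.argmin(samples[j, 0])]
        assert np.isclose(rec.gap, dist[j], atol=1e-9)
        assert np.isclose(rec.ap, samples[j, 0], atol=1e-12)

    def test_resolution_convergence_to_analytic_contact(self):
        """Sphere-over-dish contact converges to the analytic point: the
        dish point on the line joining the dish centre of curvature to the
        sphere centre."""
        R = 100.0
        center = np.array([2.0, 0.5, 29.0])
        dish_center = np.array([0.0, 0.0, 8.0 + R])
        d = center - dish_center
        analytic = dish_center + R * d / np.linalg.norm(d)
        # discrete error shrinks with the sample grid ...
        errors = []
        for res in (12, 36):
            dish = ph.make_tibial_insert(dish_radius=R, mesh_resolution=res)
            rec = ct.closest_point_contact(
                sphere_at(center, subdivisions=4), dish, refine=False
            )
            errors.append(np.hypot(rec.ap - analytic[0], rec.ml - analytic[1]))
        assert errors[1] < errors[0]
        # each error is bounded by the superior-surface sample spacing
        assert errors[0] <= 43.0 / 11  # res 12 -> 11 intervals
        assert errors[1] <= 43.0 / 35
        # the continuous refinement improves on the coarse discrete grid
        # (residual error is set by the faceted test sphere, not the grid)
        dish = ph.make_tibial_insert(dish_radius=R, mesh_resolution=24)
        rec = ct.closest_point_contact(sphere_at(center, subdivisions=4), dish, refine=True)
        assert np.hypot(rec.ap - analytic[0], rec.ml - analytic[1]) <= 43.0 / 23 / 2


class TestNormalisation:
    def test_zero_maps_to_zero(self):
        rec = ct.normalize_contact(ct.ContactRecord(ap=0.0, ml=0.0, gap=0.0))
        assert rec.ap_pct == 0.0

    def test_half_length_is_fifty_percent(self):
        rec = ct.normalize_contact(ct.ContactRecord(ap=21.5, ml=0.0, gap=0.0), 43.0, 26.5)
        assert np.isclose(rec.ap_pct, 50.0)

    def test_printed_normalisation_reproduced(self):
        rec = ct.normalize_contact(ct.ContactRecord(ap=2.1, ml=0.0, gap=0.0), 43.0, 26.5)
        assert round(rec.ap_pct, 1) == 4.9

    def test_map_identity_when_dims_match(self):
        rec = ct.ContactRecord(ap=5.0, ml=-1.0, gap=0.0)
        mapped = ct.map_to_representative(rec, 43.0, 26.5, 43.0, 26.5)
        assert np.isclose(mapped.ap, 5.0) and np.isclose(mapped.ml, -1.0)

    def test_percentage_preserved_under_rescale(self):
        rec = ct.ContactRecord(ap=3.8, ml=1.2, gap=0.0)
        mapped = ct.map_to_representative(rec, 38.0, 24.0, 43.0, 26.5)
        assert np.isclose(mapped.ap_pct, 3.8 / 38.0 * 100.0)
        assert np.isclose(mapped.ml_pct, 1.2 / 24.0 * 100.0)

    def test_literature_center_maps_to_printed_mm(self):
        rec = ct.ContactRecord(ap=-1.1 * 38.0 / 100.0, ml=0.0, gap=0.0)
        mapped = ct.map_to_representative(rec, 38.0, 24.0, 43.0, 26.5)
        assert round(mapped.ap, 1) == -0.5

    def test_normalization_roundtrip_identity_in_percent(self):
        rec = ct.normalize_contact(ct.ContactRecord(ap=4.2, ml=-0.9, gap=0.0), 40.0, 25.0)
        mapped = ct.map_to_representative(rec, 40.0, 25.0)
        back = ct.normalize_contact(mapped)
        assert np.isclose(back.ap_pct, rec.ap_pct, atol=1e-12)
        assert np.isclose(back.ml_pct, rec.ml_pct, atol=1e-12)


class TestSummary:
    def _trial(self, ap_values):
        return [ct.ContactRecord(ap=a, ml=0.5, gap=0.0) for a in ap_values]

    def test_single_trial_average_and_range(self):
        summ = ct.excursion_summary({"s1": [self._trial([3.0, 5.0, 7.0])]})
        assert np.isclose(summ.ap_avg_mm[0], 5.0)
        assert np.isclose(summ.ap_range_mm[0], 4.0)

    def test_constant_series_zero_range(self):
        summ = ct.excursion_summary({"s1": [self._trial([2.0, 2.0, 2.0])]})
        assert summ.ap_range_mm[0] == 0.0

    def test_two_subject_sample_sd(self):
        summ = ct.excursion_summary(
            {"s1": [self._trial([3.0, 5.0])], "s2": [self._trial([5.0, 7.0])]}
        )
        assert np.isclose(summ.ap_avg_mm[0], 5.0)
        assert np.isclose(summ.ap_avg_mm[1], np.sqrt(2.0))  # sample SD of {4, 6}

    def test_empty_trials_skipped_and_counted(self):
        summ = ct.excursion_summary({"s1": [self._trial([3.0, 5.0]), []]})
        assert summ.n_skipped_trials == 1

    def test_all_empty_raises(self):
        with pytest.raises(InvalidInputError):
            ct.excursion_summary({"s1": [[]]})

    def test_normalized_twins_exact_scaling(self):
        summ = ct.excursion_summary(
            {"s1": [self._trial([4.3, 8.6])]}, insert_length=43.0, insert_width=26.5
        )
        assert np.isclose(summ.ap_avg_pct[0], summ.ap_avg_mm[0] / 43.0 * 100.0)
        assert np.isclose(summ.ml_avg_pct[0], summ.ml_avg_mm[0] / 26.5 * 100.0)


class TestOffsets:
    def test_printed_stance_offsets(self):
        ap, ml = ct.offset_vs_reference(5.2, 1.8)
        assert np.isclose(ap, 5.7) and np.isclose(ml, 1.1)

    def test_zero_offset_at_reference(self):
        ref = ct.DEFAULT_WEAR_REFERENCE
        ap, ml = ct.offset_vs_reference(*ref.as_mm())
        assert ap == 0.0 and ml == 0.0

    def test_per_subject_group_stats(self):
        (ap_off, _), ((mean, sd), _) = ct.offset_vs_reference(
            np.array([4.5, 5.5]), np.array([1.0, 2.0])
        )
        assert np.allclose(ap_off, [5.0, 6.0])
        assert np.isclose(mean, 5.5) and np.isclose(sd, np.sqrt(0.5))
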