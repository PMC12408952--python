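import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from occlucontact.jaw_alignment import AlignedJawPair
from occlucontact.mesh_io import MeshContentError, SurfaceMesh
from occlucontact.oca_core import (
    DEFAULT_OFFSETS_UM,
    OffsetProfile,
    compute_oca_profile,
    extract_contact_patch,
    patch_area_2d,
    patch_area_2d_sum,
    points_within_distance,
    surface_distance,
    surface_distance_bruteforce,
)
from occlucontact.synthetic_data import (
    JawPhantomParams,
    make_analytic_fixture,
    make_jaw_pair,
    sample_surface_points,
)


class TestOffsetProfile:
    def test_default_is_the_nine_standard_offsets(self):
        assert OffsetProfile().offsets_um == DEFAULT_OFFSETS_UM
        assert len(OffsetProfile()) == 9

    @pytest.mark.parametrize("bad", [(), (0.0, 100.0), (200.0, 100.0),
                                     (100.0, 100.0)])
    def test_invalid_profiles_rejected(self, bad):
        with pytest.raises(ValueError):
            OffsetProfile(bad)


class TestSurfaceDistance:
    def test_perpendicular_point_above_triangle(self):
        tri = SurfaceMesh(np.array([[-1.0, -1, 0], [2, -1, 0], [0, 2, 0]]),
                          np.array([[0, 1, 2]]))
        d = surface_distance(np.array([[0.0, 0.0, 1.0]]), tri)
        assert d[0] == pytest.approx(1.0, abs=1e-12)

    def test_point_on_surface_is_zero(self, tetrahedron):
        d = surface_distance(tetrahedron.vertices[:2], tetrahedron)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_matches_bruteforce_including_edge_vertex_cases(self, bumpy_phantom):
        """The accelerated query must equal the exhaustive all-triangle
        minimum, also for points whose closest feature is an edge/vertex."""
        rng = np.random.default_rng(12)
        pts = rng.uniform([-2, -2, -2], [16, 16, 6], size=(200, 3))
        fast = surface_distance(pts, bumpy_phantom.maxilla)
        slow = surface_distance_bruteforce(pts, bumpy_phantom.maxilla)
        np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_membership_helper_agrees_with_distances(self, bumpy_phantom):
        rng = np.random.default_rng(5)
        pts = sample_surface_points(bumpy_phantom.mandible, 2000, rng)
        d = surface_distance(pts, bumpy_phantom.maxilla)
        inside = points_within_distance(pts, bumpy_phantom.maxilla, 0.2)
        np.testing.assert_array_equal(inside, d <= 0.2)

    def test_empty_mesh_rejected(self):
        mesh = SurfaceMesh(np.zeros((3, 3)), np.empty((0, 3), dtype=int))
        with pytest.raises(MeshContentError):
            surface_distance(np.zeros((1, 3)), mesh)


class TestAnalyticFixtures:
    def test_parallel_plates_step_function(self, plate_pair):
        pair, exact = plate_pair
        above = extract_contact_patch(pair, 100.0)
        assert above.area_3d == pytest.approx(exact(100.0)[0], rel=0.01)
        assert above.area_2d == pytest.approx(exact(100.0)[1], rel=0.01)
        below = extract_contact_patch(pair, 40.0)
        assert below.area_3d == 0.0 and below.area_2d == 0.0
        assert below.is_empty()

    def test_sphere_on_plane_cap_area(self):
        pair, exact = make_analytic_fixture("sphere_on_plane", radius=5.0,
                                            gap=0.1)
        patch = extract_contact_patch(pair, 200.0, refine_max_edge_mm=0.05)
        want = np.pi * (5.2 ** 2 - 5.1 ** 2)  # 3.236 mm^2
        assert exact(200.0)[1] == pytest.approx(want, rel=1e-12)
        assert patch.area_2d == pytest.approx(want, rel=0.02)
        assert patch.area_3d == pytest.approx(want, rel=0.02)

    def test_tilted_patch_cosine_ratio(self):
        pair, exact = make_analytic_fixture("tilted_patch", theta_deg=60.0)
        patch = extract_contact_patch(pair, 100.0)
        assert patch.area_3d == pytest.approx(exact(100.0)[0], rel=0.01)
        assert patch.area_2d / patch.area_3d == pytest.approx(0.5, rel=0.01)

    def test_overhang_union_not_sum(self):
        """Two stacked congruent facets project onto one footprint: the 2D
        union must equal one facet area while the naive sum doubles it."""
        pair, exact = make_analytic_fixture("overhang", side=4.0, dz=0.1,
                                            gap=0.05)
        patch = extract_contact_patch(pair, 200.0)
        a3, a2 = exact(200.0)
        assert patch.area_3d == pytest.approx(a3, rel=0.01)
        assert patch.area_2d == pytest.approx(a2, rel=0.01)
        assert patch_area_2d_sum(patch) == pytest.approx(2 * a2, rel=0.01)


class TestPatchArea2D:
    def test_horizontal_fragments_project_one_to_one(self, plate_pair):
        pair, _ = plate_pair
        patch = extract_contact_patch(pair, 100.0)
        assert patch.area_2d == pytest.approx(patch.area_3d, rel=0.005)

    def test_raster_converges_to_exact_union(self, bumpy_phantom):
        patch = extract_contact_patch(bumpy_phantom, 400.0)
        exact = patch_area_2d(patch, method="exact_union")
        for px_mm, tol in [(25.0, 0.02), (100.0, 0.005)]:
            raster = patch_area_2d(patch, raster_px_mm=px_mm)
            assert raster == pytest.approx(exact, rel=tol)

    def test_zero_resolution_rejected(self, plate_pair):
        pair, _ = plate_pair
        patch = extract_contact_patch(pair, 100.0)
        with pytest.raises(ValueError):
            patch_area_2d(patch, raster_px_mm=0.0)


class TestContactPatch:
    def test_area_3d_is_sum_of_fragment_areas(self, bumpy_phantom):
        patch = extract_contact_patch(bumpy_phantom, 300.0)
        total = 0.0
        for poly in patch.fragments:
            center = poly.mean(axis=0)
            s = np.zeros(3)
            for i in range(len(poly)):
                s += np.cross(poly[i] - center, poly[(i + 1) % len(poly)] - center)
            total += 0.5 * np.linalg.norm(s)
        assert patch.area_3d == pytest.approx(total, rel=1e-9)

    def test_patch_bounded_by_mandible_area(self, bumpy_phantom):
        patch = extract_contact_patch(bumpy_phantom, 2000.0)
        assert 0 < patch.area_3d <= bumpy_phantom.mandible.area()

    def test_nesting_across_offsets(self, bumpy_phantom):
        """Membership sampling: every surface point inside the 200 um patch
        region is inside the 400 um region (iso-regions are nested)."""
        rng = np.random.default_rng(8)
        pts = sample_surface_points(bumpy_phantom.mandible, 3000, rng)
        inner = points_within_distance(pts, bumpy_phantom.maxilla, 0.2)
        outer = points_within_distance(pts, bumpy_phantom.maxilla, 0.4)
        assert np.all(outer[inner])


class TestComputeProfile:
    def test_eighteen_evaluations_and_monotonicity(self, bumpy_phantom):
        prof = compute_oca_profile(bumpy_phantom, subject_id="s1")
        assert prof.evaluation_count == 18
        assert np.all(np.diff(prof.areas_3d_mm2) >= 0)
        assert np.all(np.diff(prof.areas_2d_mm2) >= 0)
        raster_tol = 0.05
        assert np.all(prof.areas_2d_mm2 <= prof.areas_3d_mm2 + raster_tol)

    def test_refinement_convergence(self, bumpy_phantom):
        coarse = extract_contact_patch(bumpy_phantom, 200.0,
                                       refine_max_edge_mm=0.2)
        fine = extract_contact_patch(bumpy_phantom, 200.0,
                                     refine_max_edge_mm=0.1)
        assert fine.area_3d == pytest.approx(coarse.area_3d, rel=0.01)

    def test_rigid_invariance_of_area(self, jaw_phantom):
        """Rotating both jaws by the same rigid motion (keeping the pair in
        an aligned frame via re-orientation) leaves area_3d unchanged."""
        pair, lm = jaw_phantom
        from occlucontact.jaw_alignment import orient_pair

        base = extract_contact_patch(pair, 300.0).area_3d
        R = Rotation.from_euler("xyz", [12, -25, 40], degrees=True).as_matrix()
        t = np.array([4.0, -2.0, 7.0])
        moved = orient_pair(pair.mandible.transformed(R, t),
                            pair.maxilla.transformed(R, t),
                            lm.transformed(R, t))
        assert extract_contact_patch(moved, 300.0).area_3d == pytest.approx(
            base, rel=1e-6)

    def test_face_order_independence(self, plate_pair):
        pair, _ = plate_pair
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pair.mandible.faces))
        shuffled = AlignedJawPair(
            mandible=SurfaceMesh(pair.mandible.vertices.copy(),
                                 pair.mandible.faces[perm], "mandible"),
            maxilla=pair.maxilla)
        a = compute_oca_profile(pair, OffsetProfile((100.0, 800.0)))
        b = compute_oca_profile(shuffled, OffsetProfile((100.0, 800.0)))
        np.testing.assert_allclose(a.areas_3d_mm2, b.areas_3d_mm2, rtol=1e-9)

    def test_negative_offset_rejected(self, plate_pair):
        pair, _ = plate_pair
        with pytest.raises(ValueError):
            extract_contact_patch(pair, -100.0)

    def test_tighter_intercuspation_increases_contact(self):
        areas = []
        for gap in (0.15, 0.05):
            pair, _ = make_jaw_pair(JawPhantomParams(gap=gap, seed=9))
            areas.append(extract_contact_patch(pair, 200.0).area_3d)
        assert areas[1] > areas[0]
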