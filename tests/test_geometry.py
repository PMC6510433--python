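"""Grains, capacities, distortion and embeddings of the tensor geometry."""

import math

import numpy as np
import pytest

import catmetric as cm
from catmetric.geometry import (
    ConstantTensorField,
    G1,
    G2,
    G3,
    spd_geometric_mean,
)


class TestGrainUnits:
    def test_unit_definitions(self):
        # enclosures of 0-, 1- and 2-spheres of radius pi/4
        assert G1 == pytest.approx(2 * (math.pi / 4))
        assert G2 == pytest.approx(math.pi * (math.pi / 4) ** 2)
        assert G3 == pytest.approx(4 * math.pi * (math.pi / 4) ** 3 / 3)


class TestPathLength:
    def test_identity_field_straight_segment(self):
        seg = cm.PathSpec(np.array([[0.1, 0.1, 0.1], [0.7, 0.5, 0.1]]))
        res = cm.path_length(cm.identity_field(), seg)
        assert res["raw"] == pytest.approx(seg.euclidean_length(), rel=1e-9)

    def test_scaling_homogeneity(self):
        f1 = ConstantTensorField(np.diag([2.0, 3.0, 5.0]))
        f2 = ConstantTensorField(9.0 * np.diag([2.0, 3.0, 5.0]))
        seg = cm.PathSpec(np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]]))
        l1 = cm.path_length(f1, seg)["raw"]
        l2 = cm.path_length(f2, seg)["raw"]
        assert l2 == pytest.approx(3.0 * l1, rel=1e-9)

    def test_convergence_with_density(self, grid13):
        axis = cm.achromatic_axis()
        l1 = cm.path_length(grid13, axis, density=100)["raw"]
        l2 = cm.path_length(grid13, axis, density=200)["raw"]
        assert abs(l2 - l1) / l2 < 0.005

    def test_complete_handover_measures_one_grain(self, handover_field):
        seg = cm.PathSpec(np.array([[0.0, 0.5, 0.5], [1.0, 0.5, 0.5]]))
        for delta in (0.1, 0.05):
            bf = cm.blur_field(handover_field, delta=delta)
            tf = cm.CallableTensorField(
                lambda pts, d=delta: cm.metric_tensor(bf, pts, d))
            grains = cm.path_length(tf, seg, density=200)["grains"]
            assert grains == pytest.approx(1.0, abs=0.01)

    def test_handover_invariant_to_speed_profile(self):
        def warped(pts):
            t = pts[:, 0] + 0.15 * np.sin(2 * np.pi * pts[:, 0])
            s = np.clip((t - 0.2) / 0.6, 0.0, 1.0)
            p1 = np.cos(np.pi * s / 2) ** 2
            return np.column_stack([p1, 1 - p1])

        bf = cm.blur_field(cm.CallableDistributionField(warped, ["a", "b"]))
        tf = cm.CallableTensorField(lambda pts: cm.metric_tensor(bf, pts, 0.1))
        seg = cm.PathSpec(np.array([[0.0, 0.5, 0.5], [1.0, 0.5, 0.5]]))
        grains = cm.path_length(tf, seg, density=200)["grains"]
        assert grains == pytest.approx(1.0, abs=0.01)

    def test_reparameterization_invariance(self, handover_field):
        # measuring the same sRGB segment at several sampling densities
        # (different discrete parameterizations) gives the same length
        bf = cm.blur_field(handover_field)
        tf = cm.CallableTensorField(lambda pts: cm.metric_tensor(bf, pts, 0.1))
        seg = cm.PathSpec(np.array([[0.0, 0.5, 0.5], [1.0, 0.5, 0.5]]))
        lengths = [cm.path_length(tf, seg, density=d)["raw"]
                   for d in (50, 100, 200)]
        assert max(lengths) - min(lengths) < 0.01 * lengths[-1]

    def test_cie76_path_length_converges_to_lab_length(self):
        from catmetric.colour import srgb_to_lab
        seg = cm.PathSpec(np.array([[0.2, 0.3, 0.4], [0.7, 0.6, 0.5]]))
        f = cm.cie_tensor_field("CIE76", delta=0.02)
        got = cm.path_length(f, seg, density=400)["raw"]
        pts = seg.vertices[0] + np.linspace(0, 1, 2001)[:, None] * (
            seg.vertices[1] - seg.vertices[0])
        lab = srgb_to_lab(pts)
        want = np.linalg.norm(np.diff(lab, axis=0), axis=1).sum()
        assert got == pytest.approx(want, rel=0.01)


class TestAreaVolume:
    def test_identity_cube_volume(self):
        res = cm.cube_volume(cm.identity_field(), resolution=4)
        assert res["raw"] == pytest.approx(1.0, abs=1e-12)
        assert res["grains"] == pytest.approx(48 / math.pi ** 4, rel=1e-9)

    def test_constant_diagonal_volume(self):
        f = ConstantTensorField(np.diag([4.0, 9.0, 16.0]))
        res = cm.cube_volume(f, resolution=3)
        assert res["raw"] == pytest.approx(math.sqrt(4 * 9 * 16), rel=1e-12)

    def test_scaling_homogeneity_area_volume(self):
        mesh = cm.hue_triangle("red", subdivisions=4)
        base = np.diag([2.0, 1.0, 3.0])
        f1, f2 = ConstantTensorField(base), ConstantTensorField(4.0 * base)
        a1 = cm.mesh_area(f1, mesh)["raw"]
        a2 = cm.mesh_area(f2, mesh)["raw"]
        v1 = cm.cube_volume(f1, resolution=2)["raw"]
        v2 = cm.cube_volume(f2, resolution=2)["raw"]
        assert a2 == pytest.approx(4.0 * a1, rel=1e-9)  # s^2 for areas
        assert v2 == pytest.approx(8.0 * v1, rel=1e-9)  # s^3 for volumes


class TestCapacity:
    def test_worked_example(self):
        assert cm.capacity(1.7, boundary_grains=2, dim=1) == pytest.approx(2.7)

    def test_closed_loop_has_no_boundary_term(self):
        assert cm.capacity(9.4, boundary_grains=0, dim=1) == pytest.approx(9.4)

    def test_additive_under_concatenation(self):
        l1, l2 = 1.3, 2.2
        merged = cm.capacity(l1 + l2, boundary_grains=2, dim=1)
        split = (cm.capacity(l1, boundary_grains=2, dim=1)
                 + cm.capacity(l2, boundary_grains=2, dim=1))
        # the shared interior endpoint contributes 2 * 1/2 that cancels
        assert split - merged == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cm.capacity(-1.0, 0.0, 1)

    def test_identity_cube_capacity(self):
        res = cm.cube_capacity(cm.identity_field(), resolution=4)
        assert res["volume_grains"] == pytest.approx(1 / G3, rel=1e-9)
        assert res["boundary_area_grains"] == pytest.approx(6 / G2, rel=1e-9)
        assert res["capacity"] == pytest.approx(1 / G3 + 3 / G2, rel=1e-9)


class TestRestrictTensor:
    def test_identity(self):
        t2 = cm.restrict_tensor(np.eye(3), [1, 0, 0], [0, 1, 0])
        assert np.allclose(t2, np.eye(2))

    def test_axis_aligned_diagonal(self):
        t2 = cm.restrict_tensor(np.diag([4.0, 9.0, 25.0]),
                                [1, 0, 0], [0, 1, 0])
        assert np.allclose(t2, np.diag([4.0, 9.0]))

    def test_quadratic_form_preserved_in_plane(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=(3, 3))
        t = a @ a.T + np.eye(3)
        x = np.array([1.0, 1.0, 0.0]) / math.sqrt(2)
        y = np.array([1.0, -1.0, 0.0]) / math.sqrt(2)
        t2 = cm.restrict_tensor(t, x, y)
        for _ in range(10):
            c = rng.normal(size=2)
            v = c[0] * x + c[1] * y
            assert v @ t @ v == pytest.approx(c @ t2 @ c, rel=1e-9)

    def test_non_orthonormal_frame_rejected(self):
        with pytest.raises(ValueError):
            cm.restrict_tensor(np.eye(3), [1, 0, 0], [1, 1, 0])


class TestDistortion:
    def test_identical_fields_zero(self):
        f = ConstantTensorField(np.diag([2.0, 1.0, 3.0]))
        assert cm.global_distortion(f, f, n_samples=500, seed=0) == pytest.approx(
            0.0, abs=1e-12)

    def test_uniform_rescaling_gives_constant_local_distortion(self):
        a = ConstantTensorField(4.0 * np.eye(3))
        b = cm.identity_field()
        assert cm.local_distortion(4.0 * np.eye(3), np.eye(3),
                                   [1, 0, 0]) == pytest.approx(1.0)
        sd = cm.global_distortion(a, b, n_samples=500, seed=0)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_95_percent_range_formula(self):
        lo, hi = cm.distortion_range(0.50)
        assert round(100 * lo) == 51 and round(100 * hi) == 197

    def test_symmetry_under_field_exchange(self):
        a = cm.cie_tensor_field("CIE76")
        b = cm.identity_field()
        s1 = cm.global_distortion(a, b, n_samples=5000, seed=4)
        s2 = cm.global_distortion(b, a, n_samples=5000, seed=4)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_geometric_mean_properties(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(3, 3))
        a = x @ x.T + np.eye(3)
        y = rng.normal(size=(3, 3))
        b = y @ y.T + np.eye(3)
        gm_ab = spd_geometric_mean(a, b)
        gm_ba = spd_geometric_mean(b, a)
        assert np.allclose(gm_ab, gm_ba, atol=1e-9)
        assert np.allclose(spd_geometric_mean(a, a), a, atol=1e-9)

    def test_non_pd_field_reported_with_location(self):
        bad = ConstantTensorField(np.diag([1.0, 1.0, -1.0]))
        with pytest.raises(ValueError, match="not positive definite"):
            cm.global_distortion(cm.identity_field(), bad, n_samples=50, seed=0)


class TestEmbed1d:
    def test_identity_field_unit_segment_is_arc_length(self):
        seg = cm.PathSpec(np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]))
        res = cm.embed_1d(cm.identity_field(), seg, density=100)
        assert res["total"] == pytest.approx(1.0, rel=1e-9)
        assert np.allclose(res["arc_length"], res["points"][:, 0], atol=1e-9)

    def test_closed_path_circle_embedding(self):
        locus = cm.full_colour_locus()
        res = cm.embed_1d(cm.identity_field(), locus, density=50)
        assert res["total"] == pytest.approx(6.0, rel=1e-9)
        assert res["radius"] == pytest.approx(6.0 / (2 * math.pi), rel=1e-9)
        circle = res["circle"]
        norms = np.linalg.norm(circle, axis=1)
        assert np.allclose(norms, res["radius"], atol=1e-9)
        gaps = np.linalg.norm(np.diff(circle, axis=0), axis=1)
        assert gaps.max() <= 2 * gaps.min() + 1e-9  # even spacing on circle

    def test_constant_regions_collapse_to_points(self):
        def fn(pts):
            out = np.zeros((len(pts), 3, 3))
            moving = pts[:, 0] >= 0.3
            out[moving] = np.eye(3)
            return out

        seg = cm.PathSpec(np.array([[0.0, 0.5, 0.5], [1.0, 0.5, 0.5]]))
        res = cm.embed_1d(cm.CallableTensorField(fn), seg, density=100)
        flat = res["arc_length"][res["points"][:, 0] <= 0.29]
        assert np.allclose(flat, 0.0, atol=1e-9)
        assert res["total"] == pytest.approx(0.7, rel=0.02)


class TestLaplaceSurface:
    def test_planar_boundary_gives_planar_surface(self):
        square = cm.PathSpec(np.array([[0.1, 0.1, 0.3], [0.9, 0.1, 0.3],
                                       [0.9, 0.9, 0.3], [0.1, 0.9, 0.3]]),
                             closed=True)
        mesh = cm.laplace_surface(square, rings=5)
        assert np.allclose(mesh.vertices[:, 2], 0.3, atol=1e-10)

    def test_full_colour_surface_is_saddle_through_cube_centre(self):
        mesh = cm.laplace_surface(cm.full_colour_locus(), rings=6)
        assert np.allclose(mesh.vertices[0], [0.5, 0.5, 0.5], atol=1e-8)

    def test_interior_vertices_harmonic(self):
        mesh = cm.laplace_surface(cm.full_colour_locus(), rings=5)
        nb = [[] for _ in range(len(mesh.vertices))]
        for u, v in mesh.edges:
            nb[u].append(v)
            nb[v].append(u)
        interior = mesh.interior_mask()
        res = max(np.linalg.norm(mesh.vertices[u]
                                 - mesh.vertices[nb[u]].mean(axis=0))
                  for u in range(len(mesh.vertices)) if interior[u])
        assert res < 1e-8

    def test_resolution_convergence(self):
        from scipy.spatial.distance import cdist

        coarse = cm.laplace_surface(cm.full_colour_locus(), rings=4,
                                    segments=24)
        fine = cm.laplace_surface(cm.full_colour_locus(), rings=8,
                                  segments=48)
        # every fine-mesh vertex lies within mesh-size order of the
        # coarse surface (nearest coarse vertex as a proxy)
        gap = cdist(fine.vertices, coarse.vertices).min(axis=1).max()
        assert gap < 0.15

    def test_open_boundary_rejected(self):
        with pytest.raises(ValueError):
            cm.laplace_surface(cm.achromatic_axis(), rings=4)


def _grid_mesh(nx=10, z=0.5):
    xs, ys = np.meshgrid(np.linspace(0.0, 1.0, nx),
                         np.linspace(0.0, 1.0, nx), indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.full(nx * nx, z)])
    tris = []
    for i in range(nx - 1):
        for j in range(nx - 1):
            a = i * nx + j
            tris.append([a, a + 1, a + nx + 1])
            tris.append([a, a + nx + 1, a + nx])
    loop = ([i for i in range(nx)]
            + [i * nx + nx - 1 for i in range(1, nx)]
            + [(nx - 1) * nx + j for j in range(nx - 2, -1, -1)]
            + [i * nx for i in range(nx - 2, 0, -1)])
    return cm.MeshSpec(verts, np.array(tris), np.array(loop))


class TestEmbedSphere:
    def _cap_field(self, radius):
        a_s, b_s = 1.2, 1.5

        def pullback(pts):
            theta = 0.15 + a_s * pts[:, 0]
            out = np.zeros((len(pts), 3, 3))
            out[:, 0, 0] = (radius * a_s) ** 2
            out[:, 1, 1] = (radius * np.sin(theta) * b_s) ** 2
            out[:, 2, 2] = 1.0
            return out

        return cm.CallableTensorField(pullback)

    def test_recovers_known_spherical_metric(self):
        field = self._cap_field(1.5)
        mesh = _grid_mesh(10)
        res = cm.embed_sphere(field, mesh, seed=0, restarts=2)
        assert res["radius"] == pytest.approx(1.5, rel=0.02)
        lo, hi = res["range95"]
        assert lo > 0.98 and hi < 1.02

    def test_flat_field_tends_to_large_radius(self):
        mesh = _grid_mesh(8)
        res = cm.embed_sphere(cm.identity_field(), mesh, seed=0, restarts=2)
        assert res["radius"] > 3.0  # mesh diameter ~1.4: nearly flat
        lo, hi = res["range95"]
        assert lo > 0.99 and hi < 1.01

    def test_rigid_rotation_leaves_edge_ratios_unchanged(self):
        field = self._cap_field(1.5)
        mesh = _grid_mesh(8)
        res = cm.embed_sphere(field, mesh, seed=0, restarts=1)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [0.3, -0.8, 1.1]).as_matrix()
        pos = res["positions"] @ rot.T
        edges = mesh.edges
        ang = np.arccos(np.clip(np.einsum(
            "ei,ei->e",
            pos[edges[:, 0]] / np.linalg.norm(pos[edges[:, 0]], axis=1, keepdims=True),
            pos[edges[:, 1]] / np.linalg.norm(pos[edges[:, 1]], axis=1, keepdims=True)),
            -1, 1))
        ref = np.arccos(np.clip(np.einsum(
            "ei,ei->e",
            res["positions"][edges[:, 0]] / res["radius"],
            res["positions"][edges[:, 1]] / res["radius"]), -1, 1))
        assert np.allclose(ang, ref, atol=1e-9)

    def test_mesh_without_interior_rejected(self):
        verts = np.array([[0.1, 0.1, 0.5], [0.9, 0.1, 0.5], [0.5, 0.9, 0.5]])
        mesh = cm.MeshSpec(verts, np.array([[0, 1, 2]]), np.array([0, 1, 2]))
        with pytest.raises(ValueError):
            cm.embed_sphere(cm.identity_field(), mesh, seed=0)
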