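"""Principal curvatures, curvedness and shape index."""

import numpy as np
import pytest
import trimesh

from fetalmorpho import curvature as cv
from fetalmorpho import surface_io as sio
from fetalmorpho import synthetic as syn

from conftest import make_icosphere


def sphere_errors(subdivisions: int) -> float:
    mesh = make_icosphere(radius=2.0, subdivisions=subdivisions)
    k1, k2 = cv.principal_curvatures(mesh)
    return float(max(np.abs(k1 - 0.5).max(), np.abs(k2 - 0.5).max()) / 0.5)


class TestPrincipalCurvatures:
    def test_icosphere_within_2pct(self):
        mesh = make_icosphere(radius=2.0, subdivisions=4)
        k1, k2 = cv.principal_curvatures(mesh)
        assert np.abs(k1 - 0.5).max() / 0.5 < 0.02
        assert np.abs(k2 - 0.5).max() / 0.5 < 0.02

    def test_cylinder_interior(self):
        tm = trimesh.creation.cylinder(radius=4.0, height=24.0, sections=64)
        mesh = sio.SurfaceMesh.from_trimesh(tm)
        k1, k2 = cv.principal_curvatures(mesh)
        interior = np.abs(mesh.vertices[:, 2]) < 8.0  # away from the cap rims
        assert np.allclose(k1[interior], 0.25, atol=0.01)
        assert np.allclose(k2[interior], 0.0, atol=0.01)

    def test_torus_matches_analytic(self):
        tm = trimesh.creation.torus(
            major_radius=10.0, minor_radius=3.0,
            major_sections=128, minor_sections=64,
        )
        mesh = sio.SurfaceMesh.from_trimesh(tm)
        k1, k2 = cv.principal_curvatures(mesh)
        v = mesh.vertices
        cosv = (np.sqrt(v[:, 0] ** 2 + v[:, 1] ** 2) - 10.0) / 3.0
        k_tube = np.full(len(v), 1 / 3)
        k_ring = cosv / (10.0 + 3.0 * cosv)
        ka1 = np.maximum(k_tube, k_ring)
        ka2 = np.minimum(k_tube, k_ring)
        # relative error floored at the torus's smallest curvature scale 1/R
        d1 = np.maximum(np.abs(ka1), 0.1)
        d2 = np.maximum(np.abs(ka2), 0.1)
        ok = (np.abs(k1 - ka1) / d1 < 0.03) & (np.abs(k2 - ka2) / d2 < 0.03)
        assert ok.mean() >= 0.95

    def test_convergence_with_subdivision(self):
        errs = [sphere_errors(s) for s in (2, 3, 4)]
        assert errs[0] > errs[1] > errs[2]

    def test_rigid_invariance(self):
        mesh = make_icosphere(radius=2.0, subdivisions=3)
        k1, k2 = cv.principal_curvatures(mesh)
        R = trimesh.transformations.rotation_matrix(0.7, [1, 2, 3])[:3, :3]
        moved = sio.SurfaceMesh(
            vertices=mesh.vertices @ R.T + np.array([5.0, -3.0, 2.0]),
            faces=mesh.faces,
        )
        k1r, k2r = cv.principal_curvatures(moved)
        assert np.abs(k1r - k1).max() / 0.5 < 1e-6
        assert np.abs(k2r - k2).max() / 0.5 < 1e-6

    def test_scaling_covariance(self):
        rng = np.random.default_rng(1)
        phases = syn.sample_fold_phases(rng)
        surf = syn.generate_surface(26.0, 25.0, 0.15, phases)
        for mesh in (make_icosphere(2.0, 3), surf):
            k1, k2 = cv.principal_curvatures(mesh)
            scaled = sio.SurfaceMesh(vertices=mesh.vertices * 2.5, faces=mesh.faces)
            k1s, k2s = cv.principal_curvatures(scaled)
            scale = np.abs(k1).max()
            assert np.allclose(2.5 * k1s, k1, atol=1e-6 * scale + 1e-9)
            assert np.allclose(2.5 * k2s, k2, atol=1e-6 * scale + 1e-9)
            si = cv.shape_index(k1, k2)
            sis = cv.shape_index(k1s, k2s)
            assert np.abs(si - sis).max() < 1e-6

    def test_mean_curvature_positive_on_convex(self):
        mesh = make_icosphere(radius=5.0, subdivisions=3)
        k1, k2 = cv.principal_curvatures(mesh)
        assert ((k1 + k2) / 2).sum() > 0

    def test_tiny_mesh_rejected(self):
        tetra = sio.SurfaceMesh(
            vertices=np.array(
                [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
            ),
            faces=np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]]),
        )
        with pytest.raises(ValueError, match="neighbours"):
            cv.principal_curvatures(tetra, neighborhood_rings=1)

    def test_angle_deficit_cross_check(self):
        # independent discrete estimator: Gaussian curvature ~ k1*k2
        mesh = make_icosphere(radius=2.0, subdivisions=4)
        k1, k2 = cv.principal_curvatures(mesh)
        K_ad = cv.angle_deficit_gaussian_curvature(mesh)
        assert np.median(K_ad) == pytest.approx(np.median(k1 * k2), rel=0.05)


class TestMarkers:
    @pytest.mark.parametrize(
        "k1,k2,expected",
        [(0.25, 0.25, 0.25), (0.0, 0.0, 0.0), (4.0, 3.0, np.sqrt(12.5))],
    )
    def test_curvedness_values(self, k1, k2, expected):
        assert cv.curvedness(k1, k2) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "k1,k2,expected",
        [
            (0.5, 0.5, 1.0),    # convex umbilic (gyral dome)
            (-0.5, -0.5, -1.0), # concave umbilic (sulcal pit)
            (0.3, -0.3, 0.0),   # perfect saddle
            (0.4, 0.0, 0.5),    # convex cylindrical ridge
            (0.0, -0.4, -0.5),  # concave trough
            (0.0, 0.0, 0.0),    # plane
        ],
    )
    def test_shape_index_special_points(self, k1, k2, expected):
        assert cv.shape_index(k1, k2) == pytest.approx(expected, abs=1e-9)

    def test_shape_index_requires_ordering(self):
        with pytest.raises(ValueError):
            cv.shape_index(0.1, 0.5)

    def test_shape_index_range_random(self, rng):
        k2 = rng.normal(size=1000)
        k1 = k2 + np.abs(rng.normal(size=1000))
        si = cv.shape_index(k1, k2)
        assert np.all(si >= -1.0) and np.all(si <= 1.0)


class TestCurvatureField:
    def test_icosphere_field(self):
        field = cv.curvature_field(make_icosphere(radius=2.0, subdivisions=4))
        assert np.median(field.curvedness) == pytest.approx(0.5, rel=0.02)
        assert np.all(np.abs(field.shape_index - 1.0) < 0.05)
        assert np.all(field.kappa1 >= field.kappa2)
        assert np.all(field.curvedness >= 0)

    def test_folding_creates_sulcal_mode(self):
        rng = np.random.default_rng(3)
        phases = syn.sample_fold_phases(rng)
        smooth = syn.generate_surface(24.0, 25.0, 0.0, phases)
        folded = syn.generate_surface(24.0, 25.0, 0.3, phases)
        f_smooth = cv.curvature_field(smooth)
        f_folded = cv.curvature_field(folded)
        frac_smooth = (f_smooth.shape_index < 0).mean()
        frac_folded = (f_folded.shape_index < 0).mean()
        assert np.median(f_smooth.shape_index) > 0.9  # ellipsoid: all gyral
        assert frac_folded > frac_smooth + 0.05       # sulci appear

    def test_ply_export_round_trips_scalars(self, tmp_path):
        mesh = make_icosphere(radius=2.0, subdivisions=2)
        field = cv.curvature_field(mesh)
        p = tmp_path / "curv.ply"
        cv.write_curvature_ply(mesh, field, p)
        text = p.read_text()
        assert "property float shape_index" in text
        assert text.count("\n") > mesh.n_vertices
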