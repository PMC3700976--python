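import numpy as np
import pytest

from surfmorph.conformal import (conformal_factor, conjugate_oneform,
                                 dilatation, harmonic_function,
                                 harmonic_oneform, integrate_to_rectangle,
                                 oneform_face_residuals, oneform_inner,
                                 oneform_period, parameterize,
                                 sample_feature_grid, sample_vertex_fields)
from surfmorph.mesh import VertexScalarField, cut_extremities
from surfmorph.synthetic import (CohortSpec, base_shape, generate_cohort,
                                 tube_mesh)


class TestHarmonicFunction:
    def test_tube_solution_linear_in_axial_coordinate(self, tube):
        f = harmonic_function(tube).values
        assert np.abs(f - tube.vertices[:, 2] / 10.0).max() < 1e-6

    def test_constant_boundary_data(self, tube):
        f = harmonic_function(tube, 0.0, 0.0).values
        assert np.abs(f).max() < 1e-12

    def test_interior_laplacian_residual(self, tube):
        from surfmorph.mesh import cotangent_laplacian
        f = harmonic_function(tube).values
        res = cotangent_laplacian(tube) @ f
        fixed = set(tube.loop_a) | set(tube.loop_b)
        interior = [i for i in range(tube.n_vertices) if i not in fixed]
        assert np.abs(res[interior]).max() < 1e-8

    def test_maximum_principle(self, tube):
        f = harmonic_function(tube).values
        assert f.min() >= -1e-9 and f.max() <= 1 + 1e-9


class TestOneForms:
    def test_df_closed_exactly(self, tube):
        f = harmonic_function(tube)
        om = harmonic_oneform(tube, f)
        assert np.abs(oneform_face_residuals(tube, om)).max() < 1e-12

    def test_constant_function_gives_zero_form(self, tube):
        om = harmonic_oneform(tube, VertexScalarField(np.zeros(tube.n_vertices)))
        assert np.abs(om.values).max() == 0.0

    def test_tube_axial_edge_values(self, tube):
        # on the flat cylinder df equals (edge axial extent) / length
        f = harmonic_function(tube)
        om = harmonic_oneform(tube, f)
        dz = (tube.vertices[om.edges[:, 1], 2]
              - tube.vertices[om.edges[:, 0], 2]) / 10.0
        assert np.abs(om.values - dz).max() < 1e-6

    def test_conjugate_closed_within_tolerance(self, tube):
        f = harmonic_function(tube)
        om = harmonic_oneform(tube, f)
        st = conjugate_oneform(tube, om)
        scale = np.abs(st.values).max()
        assert np.abs(oneform_face_residuals(tube, st)).max() < 1e-8 * max(1, scale)

    def test_tube_conformal_modulus(self, tube):
        f = harmonic_function(tube)
        om = harmonic_oneform(tube, f)
        st = conjugate_oneform(tube, om)
        h = abs(oneform_period(tube, st, tube.loop_a))
        expected = 2 * np.pi * 2.0 / 10.0
        assert abs(h - expected) / expected < 0.02

    def test_conjugate_orthogonal_to_original(self, tube):
        f = harmonic_function(tube)
        om = harmonic_oneform(tube, f)
        st = conjugate_oneform(tube, om)
        norm = np.sqrt(oneform_inner(tube, om, om) * oneform_inner(tube, st, st))
        assert abs(oneform_inner(tube, om, st)) < 1e-8 * norm


class TestIntegration:
    def test_tube_rectangle_coordinates(self, tube, tube_param):
        p = tube_param
        # u equals the axial fraction
        assert np.sqrt(np.mean((p.u - tube.vertices[:, 2] / 10.0) ** 2)) < 1e-2
        # v equals the (signed) arc-length angle up to a global rotation
        theta = np.arctan2(tube.vertices[:, 1], tube.vertices[:, 0])
        best = np.inf
        for sign in (1.0, -1.0):
            v_true = np.mod(sign * theta / (2 * np.pi) * p.h, p.h)
            d = np.mod(p.v - v_true, p.h)
            off = np.angle(np.exp(1j * d / p.h * 2 * np.pi)) / (2 * np.pi) * p.h
            dv = np.mod(d - off + p.h / 2, p.h) - p.h / 2
            best = min(best, np.sqrt(np.mean(dv ** 2)))
        assert best < 1e-2

    def test_boundary_loops_map_to_rectangle_edges(self, tube_param):
        p = tube_param
        assert np.abs(p.u[p.mesh.loop_a]).max() == 0.0
        assert np.abs(p.u[p.mesh.loop_b] - 1.0).max() == 0.0

    def test_no_flipped_parameter_triangles_on_cohort(self):
        from surfmorph.conformal import _param_signed_areas
        cohort = generate_cohort(CohortSpec(subdivisions=3, seed=3,
                                            n_group0=3, n_group1=3))
        for s in cohort:
            p = parameterize(cut_extremities(s.mesh))
            assert (_param_signed_areas(p.corner_uv) > 0).all()

    def test_deterministic(self, tube):
        a = parameterize(tube)
        b = parameterize(tube)
        assert np.array_equal(a.u, b.u) and np.array_equal(a.v, b.v)
        assert a.h == b.h


class TestConformalFactor:
    def test_tube_factor_constant(self, tube_param):
        lam = conformal_factor(tube_param).values
        assert lam.std() / lam.mean() < 0.05

    def test_scaling_by_s_scales_lambda_by_s_squared(self, tube, tube_param):
        from surfmorph.mesh import CylinderMesh
        from surfmorph.conformal import ParamMesh
        s = 2.5
        scaled = CylinderMesh(tube.vertices * s, tube.faces,
                              loop_a=tube.loop_a, loop_b=tube.loop_b)
        p2 = ParamMesh(mesh=scaled, u=tube_param.u, v=tube_param.v,
                       h=tube_param.h, corner_uv=tube_param.corner_uv)
        lam1 = conformal_factor(tube_param).values
        lam2 = conformal_factor(p2).values
        assert np.allclose(lam2, s ** 2 * lam1, rtol=1e-10)

    def test_dilatation_near_one_and_improves_with_refinement(self):
        # the tube is conformally flat: dilatation 1 at machine precision
        t = tube_mesh(2.0, 10.0, 24, 24)
        assert abs(np.median(dilatation(parameterize(t))) - 1.0) < 1e-8
        # on a curved analytic shape the median approaches 1 with refinement
        meds = []
        for level in (3, 4):
            shape = base_shape(level)
            p = parameterize(cut_extremities(shape))
            meds.append(np.median(dilatation(p)))
        assert abs(meds[1] - 1.0) < abs(meds[0] - 1.0) + 1e-12
        assert abs(meds[1] - 1.0) < 0.05


class TestFeatureGrid:
    def test_constant_field_z_normalizes_to_zero(self, tube_param):
        g = sample_vertex_fields(tube_param, np.full(tube_param.n_vertices, 7.0),
                                 (16, 16))
        assert np.allclose(g, 7.0, atol=1e-8)

    def test_vertex_values_reproduced(self, tube_param):
        vals = np.sin(tube_param.u * 3) + np.cos(tube_param.v / tube_param.h * 2 * np.pi)
        grid = sample_vertex_fields(tube_param, vals, (64, 64))
        # sample the grid back at a few vertex positions via nearest grid node
        n_u, n_v = 64, 64
        idx = np.arange(0, tube_param.n_vertices, 37)
        iu = np.clip(np.round(tube_param.u[idx] * (n_u - 1)).astype(int), 0, n_u - 1)
        iv = np.round(tube_param.v[idx] / tube_param.h * n_v).astype(int) % n_v
        assert np.abs(grid[iu, iv, 0] - vals[idx]).max() < 0.05

    def test_refinement_stability(self, tube_param):
        # (33, 32) and (65, 64) grids share every second node exactly
        p = parameterize(tube_param.mesh)
        g1 = sample_feature_grid(p, (33, 32), normalize=False)
        g2 = sample_feature_grid(p, (65, 64), normalize=False)
        sub = g2.data[::2, ::2]
        rms = np.sqrt(np.mean((g1.data - sub) ** 2))
        assert rms < 1e-2 * max(1.0, np.abs(g2.data).max())

    def test_tube_features_constant_normalize_to_zero(self, tube_param):
        # lambda and H are constant on a right tube; after z-scoring the
        # feature image must be (numerically) zero, not amplified noise
        p = parameterize(tube_param.mesh)
        g = sample_feature_grid(p, (48, 48))
        assert np.isfinite(g.data).all()
        assert np.abs(g.data).max() < 1e-6

    def test_curved_shape_features_z_normalized(self):
        p = parameterize(cut_extremities(base_shape(3)))
        g = sample_feature_grid(p, (48, 48))
        flat = g.data.reshape(-1, 2)
        assert np.abs(flat.mean(axis=0)).max() < 1e-8
        assert np.abs(flat.std(axis=0) - 1).max() < 1e-8
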