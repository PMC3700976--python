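import numpy as np
import pytest

from surfmorph.conformal import parameterize
from surfmorph.morphometry import (MorphometryError, compute_morphometry,
                                   deformation_features, face_jacobian,
                                   medial_axis, radial_distance)
from surfmorph.synthetic import tube_mesh


def rotation(theta, axis="z"):
    c, s = np.cos(theta), np.sin(theta)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


class TestJacobian:
    def test_identity_correspondence(self, tube_param):
        J = face_jacobian(tube_param, tube_param.mesh.vertices.copy())
        assert np.abs(J - np.eye(2)).max() < 1e-12

    def test_uniform_scaling(self, tube_param):
        J = face_jacobian(tube_param, 2.0 * tube_param.mesh.vertices)
        detJ, logS = deformation_features(J)
        assert np.abs(J - 2 * np.eye(2)).max() < 1e-12
        assert np.abs(detJ - 4.0).max() < 1e-12

    def test_exact_affine_recovery_on_flat_patch(self):
        # an in-plane affine map of a flat patch must be recovered exactly
        from surfmorph.mesh import CylinderMesh
        from surfmorph.conformal import ParamMesh
        n = 8
        xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float),
                             indexing="ij")
        verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + n, a + 1])
                faces.append([a + 1, a + n, a + n + 1])
        faces = np.array(faces)
        mesh = CylinderMesh(verts, faces)
        corner_uv = verts[faces][:, :, :2]
        param = ParamMesh(mesh=mesh, u=verts[:, 0], v=verts[:, 1], h=np.inf,
                          corner_uv=corner_uv)
        A = np.array([[1.4, 0.3], [0.1, 0.8]])
        corresponded = verts.copy()
        corresponded[:, :2] = verts[:, :2] @ A.T
        J = face_jacobian(param, corresponded)
        # the per-vertex J equals A up to the tangent-frame gauge: compare
        # the rotation-invariant deformation features instead
        detJ, logS = deformation_features(J)
        detA, logA = deformation_features(A[None])
        assert np.abs(detJ - detA).max() < 1e-9
        assert np.abs(logS - logA).max() < 1e-9

    def test_degenerate_corresponded_face_raises(self, tube_param):
        collapsed = np.zeros_like(tube_param.mesh.vertices)
        with pytest.raises(MorphometryError):
            face_jacobian(tube_param, collapsed)


class TestDeformationFeatures:
    def test_identity(self):
        detJ, logS = deformation_features(np.eye(2)[None])
        assert detJ[0] == pytest.approx(1.0)
        assert np.abs(logS).max() < 1e-15

    def test_diagonal_stretch(self):
        detJ, logS = deformation_features(np.diag([4.0, 1.0])[None])
        assert detJ[0] == pytest.approx(4.0)
        assert logS[0] == pytest.approx([np.log(4), 0.0, 0.0])

    @pytest.mark.parametrize("theta", [0.3, 1.1, 2.5])
    def test_pure_rotation_gives_zero_log_tensor(self, theta):
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        detJ, logS = deformation_features(R[None])
        assert detJ[0] == pytest.approx(1.0)
        assert np.abs(logS).max() < 1e-12

    def test_det_equals_product_of_singular_values(self):
        rng = np.random.default_rng(0)
        J = rng.normal(0, 1, (50, 2, 2)) + 2 * np.eye(2)
        detJ, _ = deformation_features(J)
        sv = np.linalg.svd(J, compute_uv=False)
        keep = detJ > 0
        assert np.abs(detJ[keep] - sv.prod(axis=1)[keep]).max() < 1e-10

    def test_log_tensor_norm_rigid_invariance(self, tube_param):
        corresponded = 1.7 * tube_param.mesh.vertices
        J1 = face_jacobian(tube_param, corresponded)
        R = rotation(0.8, "x")
        J2 = face_jacobian(tube_param, corresponded @ R.T + np.array([3, -1, 2.0]))
        _, l1 = deformation_features(J1)
        _, l2 = deformation_features(J2)
        assert np.abs(np.linalg.norm(l1, axis=1)
                      - np.linalg.norm(l2, axis=1)).max() < 1e-9

    def test_area_conservation(self, tube_param):
        # sum over faces of detJ-weighted template areas ~ subject total area
        rng = np.random.default_rng(2)
        corresponded = tube_param.mesh.vertices * 1.3
        J = face_jacobian(tube_param, corresponded)
        detJ, _ = deformation_features(J)
        areas = tube_param.mesh.face_areas()
        vert_area = np.zeros(tube_param.n_vertices)
        for k in range(3):
            np.add.at(vert_area, tube_param.mesh.faces[:, k], areas / 3)
        from surfmorph.mesh import TriangleMesh
        subj_area = TriangleMesh(corresponded, tube_param.mesh.faces).face_areas().sum()
        assert abs((detJ * vert_area).sum() - subj_area) / subj_area < 0.01


class TestMedialAxis:
    def test_straight_tube_centerline(self, tube_param):
        axis = medial_axis(tube_param, resolution=(24, 32))
        assert len(axis.points) == 24
        # centerline of the tube is the z axis
        assert np.abs(axis.points[:, :2]).max() < 0.04  # < 2% of radius 2

    def test_point_count_matches_requested_levels(self, tube_param):
        for n_u in (8, 16, 33):
            axis = medial_axis(tube_param, resolution=(n_u, 24))
            assert len(axis.points) == n_u

    def test_bent_tube_axis_follows_bend(self):
        # bend the tube: x += 0.1 * z^2; the axis must follow monotonically
        tube = tube_mesh(1.0, 10.0, 40, 24)
        bent = tube.vertices.copy()
        bent[:, 0] += 0.05 * bent[:, 2] ** 2
        from surfmorph.mesh import CylinderMesh
        bt = CylinderMesh(bent, tube.faces, loop_a=tube.loop_a, loop_b=tube.loop_b)
        p = parameterize(bt)
        axis = medial_axis(p, resolution=(24, 32))
        # interior levels follow the analytic centerline x = 0.05 z^2;
        # the extreme slices are tilted by the bend and are excluded
        inner = slice(2, -2)
        expected_x = 0.05 * axis.points[inner, 2] ** 2
        assert np.abs(axis.points[inner, 0] - expected_x).max() < 0.2
        assert (np.diff(axis.points[:, 2]) > 0).all()


class TestRadialDistance:
    def test_tube_radius(self, tube_param):
        vm = compute_morphometry(tube_param, tube_param.mesh.vertices.copy())
        assert np.abs(vm.R - 2.0).max() / 2.0 < 0.02

    def test_uniform_scaling_scales_R(self, tube_param):
        s = 3.0
        vm = compute_morphometry(tube_param, s * tube_param.mesh.vertices)
        assert np.abs(vm.R - s * 2.0).max() / (s * 2.0) < 0.02

    def test_elliptic_cross_section(self, tube_param):
        # squash the tube into an ellipse (a, b) = (2, 1); R must vary
        # between the semi-axes and match the analytic distances
        pts = tube_param.mesh.vertices.copy()
        pts[:, 1] *= 0.5
        axis = medial_axis(tube_param, points=pts, resolution=(32, 32))
        R = radial_distance(tube_param, pts, axis)
        analytic = np.hypot(pts[:, 0], pts[:, 1])   # center axis is the z axis
        inner = np.abs(tube_param.u - 0.5) < 0.3
        assert np.abs(R[inner] - analytic[inner]).max() / 2.0 < 0.03
        # R spans the two semi-axes
        assert abs(R[inner].max() - 2.0) < 0.1 and abs(R[inner].min() - 1.0) < 0.1

    def test_combined_vector_layout(self, tube_param):
        vm = compute_morphometry(tube_param, 1.1 * tube_param.mesh.vertices)
        assert vm.combined.shape == (tube_param.n_vertices, 4)
        assert np.array_equal(vm.combined[:, :3], vm.logS)
        assert np.array_equal(vm.combined[:, 3], vm.R)
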