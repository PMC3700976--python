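"""Per-vertex morphometric statistics from a surface correspondence.

Given the template surface and, for each subject, the corresponded 3-D point
of every template vertex, this module computes the four measures used for
group comparison:

* ``detJ`` — determinant of the 2x2 surface Jacobian, the local areal ratio
  (univariate tensor-based morphometry);
* ``logS`` — the log deformation tensor log((J^T J)^(1/2)) vectorized as
  (l11, sqrt(2) l12, l22) so its Euclidean norm equals the tensor Frobenius
  norm (multivariate TBM);
* ``R``   — radial distance (mm) from the medial axis, the curve of
  iso-parametric slice centroids on the conformal grid;
* ``combined`` — the 4-vector (logS, R).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conformal import ParamMesh, sample_vertex_fields


class MorphometryError(RuntimeError):
    pass


@dataclass
class MedialAxis:
    """Centroid of each iso-u parameter curve: one 3-D point per u level."""

    u_levels: np.ndarray     # (n_u,)
    points: np.ndarray       # (n_u, 3)


@dataclass
class VertexMorphometry:
    """Per-template-vertex morphometry for one subject."""

    J: np.ndarray            # (n, 2, 2)
    detJ: np.ndarray         # (n,)
    logS: np.ndarray         # (n, 3)
    R: np.ndarray            # (n,) mm
    excluded: np.ndarray     # bool mask of vertices with det J <= 0

    @property
    def combined(self) -> np.ndarray:
        return np.column_stack([self.logS, self.R])


def _face_frames(vertices: np.ndarray, faces: np.ndarray,
                 align: np.ndarray | None = None):
    """Orthonormal tangent frame per face, (m, 2, 3) rows (t1, t2).

    ``align`` (m, 3) picks t1 as the in-plane direction of that vector
    (e.g. the conformal u-direction), so the frame field varies smoothly
    over the surface and per-face Jacobians share a gauge when averaged to
    vertices; it defaults to the first edge.  Returns (frames, degenerate).
    """
    e1 = vertices[faces[:, 1]] - vertices[faces[:, 0]]
    e2 = vertices[faces[:, 2]] - vertices[faces[:, 0]]
    n = np.cross(e1, e2)
    nn = np.linalg.norm(n, axis=1, keepdims=True)
    bad = nn[:, 0] <= 0
    nn[bad] = 1.0
    n = n / nn
    t1 = e1 if align is None else align
    t1 = t1 - (t1 * n).sum(1, keepdims=True) * n
    t1 = t1 / np.maximum(np.linalg.norm(t1, axis=1, keepdims=True), 1e-300)
    t2 = np.cross(n, t1)
    return np.stack([t1, t2], axis=1), bad


def face_jacobian(template: ParamMesh, corresponded: np.ndarray) -> np.ndarray:
    """2x2 surface Jacobians of the map template -> corresponded points,
    averaged from faces to vertices with template-area weights.

    Each face contributes J solving J (T X) = (S Y) where X / Y are the
    template / corresponded edge vectors and T / S the orthonormal tangent
    frames.  T is aligned with the conformal u-direction and S with its
    pushforward under the correspondence, so neighbouring faces share a
    rotational gauge and the vertex average is meaningful; the identity
    correspondence gives J = I exactly.
    """
    faces = template.mesh.faces
    if corresponded.shape != template.mesh.vertices.shape:
        raise ValueError("corresponded points must cover all template vertices")
    X1 = template.mesh.vertices[faces[:, 1]] - template.mesh.vertices[faces[:, 0]]
    X2 = template.mesh.vertices[faces[:, 2]] - template.mesh.vertices[faces[:, 0]]
    Y1 = corresponded[faces[:, 1]] - corresponded[faces[:, 0]]
    Y2 = corresponded[faces[:, 2]] - corresponded[faces[:, 0]]
    # parameter-domain edge matrix and the (u, v) -> barycentric pullback
    P = np.empty((len(faces), 2, 2))
    P[:, :, 0] = template.corner_uv[:, 1] - template.corner_uv[:, 0]
    P[:, :, 1] = template.corner_uv[:, 2] - template.corner_uv[:, 0]
    detP = P[:, 0, 0] * P[:, 1, 1] - P[:, 0, 1] * P[:, 1, 0]
    detP = np.where(np.abs(detP) < 1e-300, 1e-300, detP)
    # coefficients expressing the u-direction in the edge basis
    cu1 = P[:, 1, 1] / detP
    cu2 = -P[:, 1, 0] / detP
    u_dir_t = cu1[:, None] * X1 + cu2[:, None] * X2     # d(template)/du
    u_dir_s = cu1[:, None] * Y1 + cu2[:, None] * Y2     # pushforward of u
    T, bad_t = _face_frames(template.mesh.vertices, faces, align=u_dir_t)
    S, bad_c = _face_frames(corresponded, faces, align=u_dir_s)
    if bad_c.any():
        raise MorphometryError(
            f"degenerate corresponded faces: {np.flatnonzero(bad_c)[:10]}")
    TX = np.stack([np.einsum("mij,mj->mi", T, X1),
                   np.einsum("mij,mj->mi", T, X2)], axis=-1)   # (m, 2, 2)
    SY = np.stack([np.einsum("mij,mj->mi", S, Y1),
                   np.einsum("mij,mj->mi", S, Y2)], axis=-1)
    J_face = SY @ np.linalg.inv(TX)
    areas = template.mesh.face_areas()
    n = template.mesh.n_vertices
    J_acc = np.zeros((n, 2, 2))
    w_acc = np.zeros(n)
    for k in range(3):
        np.add.at(J_acc, faces[:, k], J_face * areas[:, None, None])
        np.add.at(w_acc, faces[:, k], areas)
    return J_acc / w_acc[:, None, None]


def deformation_features(J: np.ndarray) -> tuple:
    """(detJ, logS) from per-vertex Jacobians.

    S = (J^T J)^(1/2) by eigendecomposition; logS vectorized as
    (l11, sqrt(2) l12, l22).  Vertices with det J <= 0 are flagged (third
    return value) and carry NaN features.
    """
    J = np.asarray(J, dtype=float)
    detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
    C = np.swapaxes(J, -1, -2) @ J
    w, V = np.linalg.eigh(C)
    bad = detJ <= 0
    w_safe = np.clip(w, 1e-300, None)
    logw = 0.5 * np.log(w_safe)          # eigenvalues of log S
    logS_mat = (V * logw[..., None, :]) @ np.swapaxes(V, -1, -2)
    logS = np.stack([logS_mat[..., 0, 0],
                     np.sqrt(2.0) * logS_mat[..., 0, 1],
                     logS_mat[..., 1, 1]], axis=-1)
    if bad.any():
        logS[bad] = np.nan
    return detJ, logS


def medial_axis(param: ParamMesh, points: np.ndarray | None = None,
                resolution=(32, 32)) -> MedialAxis:
    """Centroids of the iso-parametric (constant-u) curves.

    ``points`` defaults to the parameterized surface's own vertices; passing a
    subject's corresponded points yields that subject's medial axis on the
    shared grid.
    """
    if points is None:
        points = param.mesh.vertices
    grid = sample_vertex_fields(param, np.asarray(points, dtype=float),
                                resolution)
    centers = grid.mean(axis=1)          # average over the circular direction
    if not np.isfinite(centers).all():
        raise MorphometryError("empty iso-parametric level in medial axis")
    u_levels = np.linspace(0.0, 1.0, resolution[0])
    return MedialAxis(u_levels=u_levels, points=centers)


def radial_distance(template: ParamMesh, corresponded: np.ndarray,
                    axis: MedialAxis) -> np.ndarray:
    """Euclidean distance (mm) from each corresponded point to the medial-axis
    point at the same u level (axis linearly interpolated in u)."""
    ax = np.column_stack([np.interp(template.u, axis.u_levels, axis.points[:, k])
                          for k in range(3)])
    return np.linalg.norm(corresponded - ax, axis=1)


def compute_morphometry(template: ParamMesh, corresponded: np.ndarray,
                        axis_source: str = "subject",
                        axis_resolution=(32, 32)) -> VertexMorphometry:
    """All four measures for one subject's correspondence.

    ``axis_source='subject'`` (default) recomputes the medial axis from the
    corresponded points so R measures the subject's own local thickness;
    ``'template'`` measures distances to the template's axis instead.
    """
    J = face_jacobian(template, corresponded)
    detJ, logS = deformation_features(J)
    pts = corresponded if axis_source == "subject" else None
    axis = medial_axis(template, points=pts, resolution=axis_resolution)
    R = radial_distance(template, corresponded, axis)
    excluded = ~(detJ > 0)
    return VertexMorphometry(J=J, detJ=detJ, logS=logS, R=R, excluded=excluded)
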