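"""Inverse-consistent fluid registration on the conformal parameter rectangle,
the constrained harmonic map baseline, and the induced 3-D correspondence.

The registration aligns two feature images (conformal factor + mean curvature)
defined on the parameter rectangle.  The deforming image is modeled as a
viscous fluid: at each iteration the multi-channel SSD body force drives a
velocity field obtained by solving the linear viscous PDE

    mu * lap(v) + (mu + lambda_visc) * grad(div(v)) = -force

on the rectangle (periodic in the circular direction v, zero-displacement
Dirichlet conditions on the two boundary-loop edges u = 0, 1).  Forward
(moving -> fixed) and backward (fixed -> moving) maps are estimated
simultaneously and blended toward each other's numerical inverse, which keeps
the composition g o h near the identity (inverse consistency).

All displacements are expressed in grid-node units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .conformal import FeatureGrid, ParamMesh


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationParams:
    """Viscous-fluid solver settings.

    viscosity ``mu`` and ``lambda_visc`` weight the Laplacian and grad-div
    terms; ``max_step`` caps the per-iteration displacement (node units),
    playing the role of a CFL bound; ``regrid_threshold`` is the minimum
    allowed Jacobian of a single incremental warp; ``ic_weight`` blends each
    map toward the inverse of its partner.
    """

    mu: float = 1.0
    lambda_visc: float = 0.0
    max_step: float = 0.4
    max_iterations: int = 200
    tolerance: float = 1e-5
    patience: int = 10
    regrid_threshold: float = 0.5
    ic_weight: float = 0.1
    ic_interval: int = 2
    #: search all integer circular shifts of the moving grid first, so the
    #: result does not depend on where each subject's seam anchor landed
    pre_align_rotation: bool = True

    def __post_init__(self):
        if min(self.mu, self.max_step, self.tolerance) <= 0:
            raise ValueError("mu, max_step and tolerance must be positive")
        if not 0 < self.regrid_threshold < 1:
            raise ValueError("regrid_threshold must be in (0, 1)")


@dataclass
class DisplacementField2D:
    """Forward map g (on the fixed grid, into moving coordinates) and backward
    map h (on the moving grid), both stored as displacements in node units."""

    forward: np.ndarray   # (n_u, n_v, 2)
    backward: np.ndarray
    ssd_log: list = field(default_factory=list)
    converged: bool = False
    ic_residual: float = np.nan

    @property
    def shape(self):
        return self.forward.shape[:2]


# ---------------------------------------------------------------------------
# grid helpers (axis 0 = u, clamped; axis 1 = v, periodic)
# ---------------------------------------------------------------------------

def bilinear_sample(img: np.ndarray, x0: np.ndarray, x1: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of ``img`` (n_u, n_v[, C]) at continuous node
    coordinates; clamped along u, wrapped along v."""
    n0, n1 = img.shape[:2]
    x0 = np.clip(x0, 0.0, n0 - 1.0)
    i0 = np.clip(np.floor(x0).astype(int), 0, n0 - 2)
    f0 = x0 - i0
    x1m = np.mod(x1, n1)
    i1 = np.floor(x1m).astype(int) % n1
    f1 = x1m - np.floor(x1m)
    j1 = (i1 + 1) % n1
    if img.ndim == 2:
        img = img[..., None]
        squeeze = True
    else:
        squeeze = False
    f0e = f0[..., None]
    f1e = f1[..., None]
    out = (img[i0, i1] * (1 - f0e) * (1 - f1e)
           + img[i0 + 1, i1] * f0e * (1 - f1e)
           + img[i0, j1] * (1 - f0e) * f1e
           + img[i0 + 1, j1] * f0e * f1e)
    return out[..., 0] if squeeze else out


def warp_image(img: np.ndarray, disp: np.ndarray) -> np.ndarray:
    n0, n1 = img.shape[:2]
    I, J = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    return bilinear_sample(img, I + disp[..., 0], J + disp[..., 1])


def image_gradient(img: np.ndarray) -> np.ndarray:
    """Central-difference gradient, one-sided at u edges, periodic in v.
    Returns (n_u, n_v, C, 2)."""
    if img.ndim == 2:
        img = img[..., None]
    gu = np.empty_like(img)
    gu[1:-1] = (img[2:] - img[:-2]) / 2.0
    gu[0] = img[1] - img[0]
    gu[-1] = img[-1] - img[-2]
    gv = (np.roll(img, -1, axis=1) - np.roll(img, 1, axis=1)) / 2.0
    return np.stack([gu, gv], axis=-1)


def jacobian_determinant(disp: np.ndarray) -> np.ndarray:
    """det of the Jacobian of the map x + disp(x)."""
    g0 = image_gradient(disp[..., 0])[:, :, 0, :]
    g1 = image_gradient(disp[..., 1])[:, :, 0, :]
    return (1 + g0[..., 0]) * (1 + g1[..., 1]) - g0[..., 1] * g1[..., 0]


def compose_displacements(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """Displacement of (id + outer) o (id + inner)."""
    n0, n1 = inner.shape[:2]
    I, J = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    sampled = bilinear_sample(outer, I + inner[..., 0], J + inner[..., 1])
    return inner + sampled


def invert_displacement(disp: np.ndarray, n_iter: int = 15) -> np.ndarray:
    """Fixed-point inversion: inv(x) = -disp(x + inv(x))."""
    n0, n1 = disp.shape[:2]
    I, J = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    inv = -disp.copy()
    for _ in range(n_iter):
        inv = -bilinear_sample(disp, I + inv[..., 0], J + inv[..., 1])
    return inv


# ---------------------------------------------------------------------------
# viscous PDE solver
# ---------------------------------------------------------------------------

def _viscous_operator(n0: int, n1: int, mu: float, lam: float) -> spla.SuperLU:
    """Factorized discrete operator -mu*lap - (mu+lam)*grad div on the
    rectangle grid, Dirichlet at u = 0, n0-1, periodic in v, acting on
    interleaved (comp0, comp1) node vectors."""
    I0 = sp.eye(n0, format="csr")
    I1 = sp.eye(n1, format="csr")
    d2 = sp.diags([1.0, -2.0, 1.0], [-1, 0, 1], shape=(n0, n0), format="lil")
    d2[0, :] = 0
    d2[-1, :] = 0
    d2 = d2.tocsr()
    ones = np.ones(n1)
    d2p = sp.diags([ones[:-1], -2.0 * ones, ones[:-1]], [-1, 0, 1], format="lil")
    d2p[0, -1] = 1.0
    d2p[-1, 0] = 1.0
    d2p = d2p.tocsr()
    lap = sp.kron(d2, I1) + sp.kron(I0, d2p)
    d1 = sp.diags([-0.5, 0.5], [-1, 1], shape=(n0, n0), format="lil")
    d1[0, :] = 0
    d1[-1, :] = 0
    d1 = d1.tocsr()
    d1p = sp.diags([-0.5 * ones[:-1], 0.5 * ones[:-1]], [-1, 1], format="lil")
    d1p[0, -1] = -0.5
    d1p[-1, 0] = 0.5
    d1p = d1p.tocsr()
    duu = sp.kron(d2, I1)
    dvv = sp.kron(I0, d2p)
    duv = sp.kron(d1, d1p)
    A00 = mu * lap + (mu + lam) * duu
    A11 = mu * lap + (mu + lam) * dvv
    A01 = (mu + lam) * duv
    A = sp.bmat([[A00, A01], [A01, A11]]).tolil()
    # Dirichlet rows: velocity pinned to zero on the two boundary-loop edges
    N = n0 * n1
    fixed = np.concatenate([np.arange(n1), np.arange((n0 - 1) * n1, n0 * n1)])
    for comp in (0, 1):
        for idx in fixed + comp * N:
            A.rows[idx] = [idx]
            A.data[idx] = [-1.0]
    return spla.splu((-A).tocsc())


def _solve_velocity(lu, force: np.ndarray) -> np.ndarray:
    n0, n1 = force.shape[:2]
    b = np.concatenate([force[..., 0].ravel(), force[..., 1].ravel()])
    # zero force on Dirichlet rows
    N = n0 * n1
    fixed = np.concatenate([np.arange(n1), np.arange((n0 - 1) * n1, N)])
    b[fixed] = 0.0
    b[fixed + N] = 0.0
    x = lu.solve(b)
    return np.stack([x[:N].reshape(n0, n1), x[N:].reshape(n0, n1)], axis=-1)


def _ssd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sum((a - b) ** 2))


def _body_force(moving: np.ndarray, fixed: np.ndarray, disp: np.ndarray) -> tuple:
    """Gauss-Newton SSD force for the map id + disp on the fixed grid; also
    returns the current SSD."""
    warped = warp_image(moving, disp)
    resid = warped - fixed
    grad = image_gradient(warped)          # (n0, n1, C, 2)
    force = -(resid[..., None] * grad).sum(axis=2)
    return force, _ssd(warped, fixed)


def fluid_register(moving: FeatureGrid, fixed: FeatureGrid,
                   params: RegistrationParams | None = None) -> DisplacementField2D:
    """Symmetric inverse-consistent fluid registration of two feature grids.

    Returns displacement fields in node units: ``forward`` maps fixed-grid
    nodes into the moving image, ``backward`` the reverse.
    """
    if params is None:
        params = RegistrationParams()
    if moving.shape != fixed.shape:
        raise RegistrationError("grids must share resolution")
    M, F = moving.data, fixed.data
    n0, n1 = M.shape[:2]
    shift = 0
    if params.pre_align_rotation:
        ssd_by_shift = [_ssd(np.roll(M, -s, axis=1), F) for s in range(n1)]
        shift = int(np.argmin(ssd_by_shift))
        M = np.roll(M, -shift, axis=1)
    lu = _viscous_operator(n0, n1, params.mu, params.lambda_visc)
    g = np.zeros((n0, n1, 2))
    h = np.zeros((n0, n1, 2))
    ssd_log = []
    scale = 1.0
    stall = 0
    prev = None
    converged = False
    for it in range(params.max_iterations):
        force_g, ssd_g = _body_force(M, F, g)
        force_h, ssd_h = _body_force(F, M, h)
        if not (np.isfinite(force_g).all() and np.isfinite(force_h).all()):
            raise RegistrationError("non-finite force encountered")
        ssd = ssd_g + ssd_h
        ssd_log.append(ssd)
        if prev is not None:
            rel = (prev - ssd) / max(prev, 1e-30)
            if rel < params.tolerance:
                stall += 1
                if stall >= params.patience:
                    converged = True
                    break
            else:
                stall = 0
        jac_floor = 0.5 * params.regrid_threshold
        accepted = False
        for _ in range(8):
            g_new = _fluid_step(g, force_g, lu, params, scale)
            h_new = _fluid_step(h, force_h, lu, params, scale)
            ssd_new = (_body_force(M, F, g_new)[1] + _body_force(F, M, h_new)[1])
            ok_jac = (jacobian_determinant(g_new).min() > jac_floor
                      and jacobian_determinant(h_new).min() > jac_floor)
            if ssd_new <= ssd + 1e-12 and ok_jac:
                accepted = True
                break
            scale *= 0.5
            if scale < 1e-4:
                break
        if not accepted:
            converged = True
            break
        g, h = g_new, h_new
        scale = min(scale * 1.2, 1.0)
        if params.ic_weight > 0 and (it + 1) % params.ic_interval == 0:
            g_inv = invert_displacement(g)
            h_inv = invert_displacement(h)
            ssd_ref = ssd_new
            w = params.ic_weight
            for _ in range(4):
                g_bl = (1 - w) * g + w * h_inv
                h_bl = (1 - w) * h + w * g_inv
                # the blend must keep the fields diffeomorphic and must not
                # undo the image match it is regularizing
                ssd_bl = (_body_force(M, F, g_bl)[1]
                          + _body_force(F, M, h_bl)[1])
                if (ssd_bl <= ssd_ref * (1 + params.tolerance)
                        and jacobian_determinant(g_bl).min() > jac_floor
                        and jacobian_determinant(h_bl).min() > jac_floor):
                    g, h = g_bl, h_bl
                    break
                w *= 0.5
        prev = ssd
    if min(jacobian_determinant(g).min(), jacobian_determinant(h).min()) <= 0:
        raise RegistrationError("registration left the diffeomorphic regime")
    comp = compose_displacements(g, h)
    ic = float(np.sqrt(np.mean(np.sum(comp ** 2, axis=-1))))
    if shift:
        # fold the integer pre-rotation back into the returned fields:
        # W_g_total = T_shift o W_g  and  W_h_total = W_h o T_{-shift}
        g = g + np.array([0.0, shift])
        h = np.roll(h, shift, axis=1) - np.array([0.0, shift])
    return DisplacementField2D(forward=g, backward=h, ssd_log=ssd_log,
                               converged=converged, ic_residual=ic)


def _fluid_step(disp, force, lu, params, scale):
    vel = _solve_velocity(lu, force)
    vmax = float(np.abs(vel).max())
    if vmax < 1e-30:
        return disp
    dt = scale * params.max_step / vmax
    step = dt * vel
    # the incremental warp must stay well inside the diffeomorphic regime
    if jacobian_determinant(step).min() < params.regrid_threshold:
        step *= 0.5
    return compose_displacements(disp, step)


# ---------------------------------------------------------------------------
# constrained harmonic map baseline
# ---------------------------------------------------------------------------

def harmonic_register(moving: ParamMesh | FeatureGrid, fixed: ParamMesh | FeatureGrid,
                      resolution=(64, 64)) -> DisplacementField2D:
    """Constrained harmonic map between the two parameter rectangles.

    Both map components solve the Laplace equation on the grid with the
    boundary correspondence fixed (loop A edge to loop A edge, loop B to
    loop B, seam anchor aligned) and v periodic.  With both domains expressed
    in grid-node units the boundary data is the identity, so the harmonic
    correspondence carries all inter-subject matching through the shared
    conformal coordinates rather than through image features.
    """
    if isinstance(moving, FeatureGrid):
        n0, n1 = moving.shape
    else:
        n0, n1 = resolution
    I0 = sp.eye(n1, format="csr")
    d2 = sp.diags([1.0, -2.0, 1.0], [-1, 0, 1], shape=(n0, n0), format="lil")
    d2[0, :] = 0
    d2[-1, :] = 0
    ones = np.ones(n1)
    d2p = sp.diags([ones[:-1], -2.0 * ones, ones[:-1]], [-1, 0, 1], format="lil")
    d2p[0, -1] = 1.0
    d2p[-1, 0] = 1.0
    lap = sp.kron(d2.tocsr(), I0) + sp.kron(sp.eye(n0, format="csr"), d2p.tocsr())
    lap = lap.tolil()
    # solve for the (v-periodic) displacement components; the identity
    # boundary correspondence pins the displacement to zero on both loop edges
    rhs0 = np.zeros(n0 * n1)
    rhs1 = np.zeros(n0 * n1)
    fixed_rows = np.concatenate([np.arange(n1), np.arange((n0 - 1) * n1, n0 * n1)])
    for idx in fixed_rows:
        lap.rows[idx] = [idx]
        lap.data[idx] = [1.0]
    lap = lap.tocsr()
    sol0 = spla.spsolve(lap, rhs0)
    sol1 = spla.spsolve(lap, rhs1)
    fwd = np.stack([sol0.reshape(n0, n1), sol1.reshape(n0, n1)], axis=-1)
    bwd = invert_displacement(fwd)
    comp = compose_displacements(fwd, bwd)
    ic = float(np.sqrt(np.mean(np.sum(comp ** 2, axis=-1))))
    return DisplacementField2D(forward=fwd, backward=bwd, converged=True,
                               ic_residual=ic)


# ---------------------------------------------------------------------------
# induced 3-D correspondence
# ---------------------------------------------------------------------------

class ParamLocator:
    """Point location in a parameterized surface's rectangle domain: maps a
    query (u, v) to the 3-D surface point with those conformal coordinates via
    barycentric interpolation (faces replicated at v +/- h for periodicity)."""

    def __init__(self, param: ParamMesh, n_candidates: int = 24):
        self.param = param
        corners = param.corner_uv
        reps = []
        for k in (-1.0, 0.0, 1.0):
            c = corners.copy()
            c[:, :, 1] += k * param.h
            reps.append(c)
        self.corners = np.concatenate(reps, axis=0)         # (3m, 3, 2)
        self.face_of = np.tile(np.arange(len(param.mesh.faces)), 3)
        scale = np.array([1.0, 1.0])
        cent = self.corners.mean(axis=1) * scale
        self.tree = cKDTree(cent)
        self.k = min(n_candidates, len(cent))

    def locate(self, uv: np.ndarray) -> np.ndarray:
        """Return (n, 3) surface points for (n, 2) parameter queries."""
        uv = np.atleast_2d(uv).astype(float)
        uv = uv.copy()
        uv[:, 1] = np.mod(uv[:, 1], self.param.h)
        _, idx = self.tree.query(uv, k=self.k)
        idx = np.atleast_2d(idx)
        P = self.corners[idx]                  # (n, k, 3, 2)
        a, b, c = P[:, :, 0], P[:, :, 1], P[:, :, 2]
        v0 = b - a
        v1 = c - a
        q = uv[:, None, :] - a
        den = v0[..., 0] * v1[..., 1] - v0[..., 1] * v1[..., 0]
        den = np.where(np.abs(den) < 1e-300, 1e-300, den)
        l1 = (q[..., 0] * v1[..., 1] - q[..., 1] * v1[..., 0]) / den
        l2 = (v0[..., 0] * q[..., 1] - v0[..., 1] * q[..., 0]) / den
        l0 = 1.0 - l1 - l2
        lam = np.stack([l0, l1, l2], axis=-1)   # (n, k, 3)
        worst = lam.min(axis=-1)                # most-negative barycentric
        best = np.argmax(worst, axis=1)
        rows = np.arange(len(uv))
        lam_best = lam[rows, best]              # (n, 3)
        face_best = self.face_of[idx[rows, best]]
        # queries whose candidate set missed the containing face: scan all
        unresolved = np.flatnonzero(worst[rows, best] < -1e-9)
        for qi in unresolved:
            lam_q, face_q = self._locate_exhaustive(uv[qi])
            if lam_q.min() > lam_best[qi].min():
                lam_best[qi] = lam_q
                face_best[qi] = face_q
        # clamp tiny negatives from floating point, renormalize
        lam_best = np.clip(lam_best, 0.0, None)
        lam_best /= lam_best.sum(axis=1, keepdims=True)
        faces = self.param.mesh.faces[face_best]
        X = self.param.mesh.vertices[faces]     # (n, 3, 3)
        return (lam_best[..., None] * X).sum(axis=1)

    def _locate_exhaustive(self, q: np.ndarray):
        P = self.corners                        # (3m, 3, 2)
        a, b, c = P[:, 0], P[:, 1], P[:, 2]
        v0 = b - a
        v1 = c - a
        d = q[None, :] - a
        den = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
        den = np.where(np.abs(den) < 1e-300, 1e-300, den)
        l1 = (d[:, 0] * v1[:, 1] - d[:, 1] * v1[:, 0]) / den
        l2 = (v0[:, 0] * d[:, 1] - v0[:, 1] * d[:, 0]) / den
        lam = np.column_stack([1.0 - l1 - l2, l1, l2])
        k = int(np.argmax(lam.min(axis=1)))
        return lam[k], self.face_of[k]


def induce_correspondence(subject: ParamMesh, template: ParamMesh,
                          disp_field: DisplacementField2D,
                          direction: str = "forward") -> np.ndarray:
    """Push each template vertex through the parameter-domain map and locate
    it on the subject surface.

    ``direction='forward'`` uses the forward field (defined on the template
    grid when the subject was registered as the moving image).
    Returns (n_template_vertices, 3) points lying on the subject surface.
    """
    disp = getattr(disp_field, direction)
    n0, n1 = disp.shape[:2]
    x0 = template.u * (n0 - 1)
    x1 = template.v / template.h * n1
    d = bilinear_sample(disp, x0, x1)
    y0 = np.clip(x0 + d[:, 0], 0.0, n0 - 1.0)
    y1 = x1 + d[:, 1]
    u_s = y0 / (n0 - 1)
    v_s = np.mod(y1 / n1 * subject.h, subject.h)
    locator = ParamLocator(subject)
    return locator.locate(np.column_stack([u_s, v_s]))
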