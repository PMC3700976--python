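"""Synthetic two-group cohorts of putamen-like surfaces with known ground
truth.

The study design this emulates compares 17 preterm against 19 term-born
neonates (ages at scan 41.1 +/- 5.0 and 45.1 +/- 5.1 weeks respectively).
Each subject is a deformed copy of a common base shape — a bent superellipsoid
with roughly 3 : 1.5 : 1 axis ratios, mimicking an elongated subcortical
structure — plus smooth band-limited per-subject shape noise.  Group 1
("preterm") additionally receives a localized inward deformation (focal
atrophy) on the anterior/inferior aspect, with a per-vertex ground-truth
indicator so detection maps can be scored against the implanted region.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy.special import sph_harm_y

from .mesh import CylinderMesh, TriangleMesh, graph_geodesic, validate_topology


@dataclass
class CohortSpec:
    """Conditions of a synthetic cohort.

    Group 0 plays the term-born controls, group 1 the preterm group carrying
    the implanted effect.  ``effect_delta`` is the fractional inward
    displacement at the patch center (0 = null cohort); ``noise_amplitude`` is
    the per-subject smooth shape-noise amplitude, both relative to the local
    radius.  ``age_slope`` optionally scales each mesh by
    (1 + age_slope * (age - 43 weeks)) per week.
    """

    n_group0: int = 19
    n_group1: int = 17
    age_mean0: float = 45.1
    age_sd0: float = 5.1
    age_mean1: float = 41.1
    age_sd1: float = 5.0
    effect_direction: np.ndarray = dc_field(
        default_factory=lambda: np.array([1.0, 0.0, -1.0]))
    effect_radius: float = 6.0           # geodesic radius, mm
    effect_delta: float = 0.1
    noise_amplitude: float = 0.02
    age_slope: float = 0.0               # fractional size change per week
    subdivisions: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_group0 < 2 or self.n_group1 < 2:
            raise ValueError("need at least two subjects per group")
        if self.effect_delta < 0 or self.noise_amplitude < 0:
            raise ValueError("effect_delta and noise_amplitude must be >= 0")


@dataclass
class SyntheticSubject:
    subject_id: str
    group: int
    age: float
    mesh: TriangleMesh
    indicator: np.ndarray    # 1 inside the implanted patch


# ---------------------------------------------------------------------------
# base shape
# ---------------------------------------------------------------------------

#: semi-axes of the base superellipsoid, mm (elongation ratio 3 : 1.5 : 1)
BASE_SEMI_AXES = (12.0, 6.0, 4.0)
#: superellipsoid shape exponent (< 1 flattens the profile slightly)
BASE_EXPONENT = 0.85
#: banana-bend sagitta as a fraction of the short semi-axis
BASE_BEND = 0.6


def _unit_sphere(subdivisions: int):
    import trimesh
    ico = trimesh.creation.icosphere(subdivisions=subdivisions)
    return np.asarray(ico.vertices, dtype=float), np.asarray(ico.faces, dtype=np.int64)


def _superellipsoid(sphere_pts: np.ndarray) -> np.ndarray:
    a, b, c = BASE_SEMI_AXES
    e = BASE_EXPONENT
    q = np.sign(sphere_pts) * np.abs(sphere_pts) ** e
    out = q * np.array([a, b, c])
    # gentle banana bend about the long axis
    out[:, 2] += BASE_BEND * c * (out[:, 0] / a) ** 2
    return out


def base_shape(subdivisions: int = 3, seed: int = 0) -> TriangleMesh:
    """The common closed genus-zero base surface (deterministic; ``seed`` is
    accepted for interface symmetry but the base shape itself is fixed)."""
    if subdivisions < 3:
        raise ValueError("need at least 3 subdivision levels")
    pts, faces = _unit_sphere(subdivisions)
    return TriangleMesh(_superellipsoid(pts), faces)


def tube_mesh(radius: float = 2.0, length: float = 10.0,
              n_axial: int = 30, n_circ: int = 24) -> CylinderMesh:
    """A right circular tube, open at both ends — the standard analytic
    fixture (conformal modulus 2*pi*radius/length, H = 1/(2*radius))."""
    zs = np.linspace(0.0, length, n_axial)
    th = np.arange(n_circ) / n_circ * 2 * np.pi
    verts = np.array([[radius * np.cos(t), radius * np.sin(t), z]
                      for z in zs for t in th])
    faces = []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = (i + 1) * n_circ + j
            d = (i + 1) * n_circ + (j + 1) % n_circ
            faces.append([a, b, d])
            faces.append([a, d, c])
    faces = np.array(faces, dtype=np.int64)
    rep = validate_topology(TriangleMesh(verts, faces))
    loops = rep.boundary_loops
    z_mean = [verts[lp][:, 2].mean() for lp in loops]
    ia = int(np.argmin(z_mean))
    return CylinderMesh(verts, faces, loop_a=loops[ia], loop_b=loops[1 - ia])


# ---------------------------------------------------------------------------
# effect and noise
# ---------------------------------------------------------------------------

def enclosed_volume(mesh: TriangleMesh) -> float:
    """Signed volume by the divergence theorem."""
    v = mesh.vertices
    f = mesh.faces
    return float(np.einsum("ij,ij->i", v[f[:, 0]],
                           np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0)


def implant_effect(mesh: TriangleMesh, center_direction: np.ndarray,
                   radius: float, delta: float):
    """Displace vertices within a geodesic ``radius`` of the surface point
    nearest ``center_direction`` inward along the normal by
    ``delta * local_radius`` with a cosine taper.

    Returns (deformed mesh, indicator array).  ``delta = 0`` returns the input
    mesh unchanged.
    """
    centroid = mesh.vertices.mean(axis=0)
    rel = mesh.vertices - centroid
    d = np.asarray(center_direction, dtype=float)
    d = d / np.linalg.norm(d)
    center = int(np.argmax(rel @ d / np.linalg.norm(rel, axis=1)))
    geo = graph_geodesic(mesh, np.array([center]))
    indicator = (geo < radius).astype(np.int8)
    if indicator.sum() == 0:
        raise ValueError("effect patch is empty; increase radius")
    if int(indicator.sum()) >= mesh.n_vertices:
        raise ValueError("effect patch covers the whole mesh; reduce radius")
    if delta == 0:
        return TriangleMesh(mesh.vertices.copy(), mesh.faces.copy()), indicator
    taper = np.where(geo < radius, 0.5 * (1 + np.cos(np.pi * geo / radius)), 0.0)
    normals = mesh.vertex_normals()
    local_scale = np.linalg.norm(rel, axis=1)
    verts = mesh.vertices - (delta * taper * local_scale)[:, None] * normals
    return TriangleMesh(verts, mesh.faces.copy()), indicator


def _sph_harm_basis(sphere_pts: np.ndarray, lmax: int = 4) -> np.ndarray:
    """Real spherical-harmonic design matrix on unit-sphere points."""
    x, y, z = sphere_pts.T
    theta = np.arccos(np.clip(z, -1, 1))
    phi = np.mod(np.arctan2(y, x), 2 * np.pi)
    cols = []
    for ell in range(1, lmax + 1):
        for m in range(-ell, ell + 1):
            Y = sph_harm_y(ell, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2) * Y.imag)
            elif m == 0:
                cols.append(Y.real)
            else:
                cols.append(np.sqrt(2) * Y.real)
    return np.column_stack(cols)


def _smooth_noise(basis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    coef = rng.standard_normal(basis.shape[1])
    f = basis @ coef
    sd = f.std()
    return f / sd if sd > 0 else f


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec, out_dir=None) -> list:
    """Generate the two-group cohort; fully reproducible per ``spec.seed``.

    When ``out_dir`` is given, writes per-subject PLY meshes, a manifest CSV
    (subject_id, group, age) and the ground-truth indicator CSV.
    """
    sphere_pts, faces = _unit_sphere(spec.subdivisions)
    base_verts = _superellipsoid(sphere_pts)
    base = TriangleMesh(base_verts, faces)
    deformed, indicator = implant_effect(base, spec.effect_direction,
                                         spec.effect_radius, spec.effect_delta)
    basis = _sph_harm_basis(sphere_pts)
    centroid = base_verts.mean(axis=0)
    normals = base.vertex_normals()
    local_scale = np.linalg.norm(base_verts - centroid, axis=1)

    subjects = []
    counter = 0
    for group, n, mu, sd in ((0, spec.n_group0, spec.age_mean0, spec.age_sd0),
                             (1, spec.n_group1, spec.age_mean1, spec.age_sd1)):
        for i in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, group, i]))
            age = float(rng.normal(mu, sd))
            verts = (deformed.vertices if group == 1 else base_verts).copy()
            noise = _smooth_noise(basis, rng)
            verts = verts + (spec.noise_amplitude * noise * local_scale)[:, None] * normals
            if spec.age_slope != 0.0:
                verts = centroid + (verts - centroid) * (1 + spec.age_slope * (age - 43.0))
            sid = f"s{counter:03d}"
            counter += 1
            subjects.append(SyntheticSubject(
                subject_id=sid, group=group, age=age,
                mesh=TriangleMesh(verts, faces.copy()),
                indicator=(indicator if group == 1
                           else np.zeros(len(verts), dtype=np.int8))))
    if out_dir is not None:
        _write_cohort(subjects, indicator, Path(out_dir))
    return subjects


def _write_cohort(subjects, indicator, out_dir: Path) -> None:
    from .mesh import write_mesh
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "group", "age_weeks", "mesh_file", "units"])
        for s in subjects:
            fname = f"{s.subject_id}.ply"
            write_mesh(out_dir / fname, s.mesh)
            w.writerow([s.subject_id, s.group, f"{s.age:.4f}", fname, "mm"])
    with open(out_dir / "ground_truth_indicator.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertex", "indicator"])
        for i, val in enumerate(indicator):
            w.writerow([i, int(val)])


def load_cohort(manifest_path) -> list:
    """Load a cohort written by :func:`generate_cohort` (or hand-assembled in
    the same layout) back into SyntheticSubject records; the indicator is
    loaded when the ground-truth CSV sits next to the manifest."""
    from .mesh import read_mesh
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    gt = root / "ground_truth_indicator.csv"
    indicator = None
    if gt.exists():
        rows = list(csv.reader(open(gt)))[1:]
        indicator = np.array([int(r[1]) for r in rows], dtype=np.int8)
    subjects = []
    with open(manifest_path) as fh:
        for row in csv.DictReader(fh):
            mesh = read_mesh(root / row["mesh_file"])
            grp = int(row["group"])
            ind = (indicator if (indicator is not None and grp == 1)
                   else np.zeros(mesh.n_vertices, dtype=np.int8))
            subjects.append(SyntheticSubject(
                subject_id=row["subject_id"], group=grp,
                age=float(row["age_weeks"]), mesh=mesh, indicator=ind))
    return subjects
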