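"""End-to-end orchestration: meshes -> parameterization -> registration ->
morphometry -> statistics -> report.

Every stage writes its artifacts under the run directory and is skipped on
re-run when its outputs already exist, so a pipeline can be resumed (or a
single stage re-executed from the command line) without recomputing earlier
stages.  A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import zlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conformal import FeatureGrid, ParamMesh, parameterize, sample_feature_grid
from .mesh import CylinderMesh, cut_extremities, write_mesh
from .morphometry import compute_morphometry
from .registration import (DisplacementField2D, RegistrationParams,
                           fluid_register, harmonic_register,
                           induce_correspondence, jacobian_determinant)
from .stats import CohortTable, group_analysis
from .synthetic import CohortSpec, SyntheticSubject, generate_cohort, load_cohort

ALL_STATISTICS = ("detJ", "logS", "R", "combined")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    manifest: str | None = None          # cohort manifest CSV; None -> synthetic
    cohort_spec: CohortSpec | None = None
    template_id: str | None = None       # subject id; None -> seeded random control
    registration: str = "fluid"          # fluid | harmonic
    grid_resolution: tuple = (64, 64)
    reg_params: RegistrationParams = field(default_factory=RegistrationParams)
    statistics: tuple = ALL_STATISTICS
    n_perm: int = 10000
    alpha: float = 0.05
    q: float = 0.05
    cut_k: int = 2
    axis_source: str = "subject"
    out_dir: str = "surfmorph_run"
    seed: int = 0

    def __post_init__(self):
        if not self.statistics:
            raise ValueError("statistics list must be non-empty")
        if self.registration not in ("fluid", "harmonic"):
            raise ValueError("registration must be 'fluid' or 'harmonic'")

    def config_hash(self) -> str:
        blob = json.dumps(_to_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class StatResult:
    statistic: str
    corrected_p: float
    fdr_critical: float | None
    n_suprathreshold: int
    dice: float | None = None


@dataclass
class RunReport:
    results: dict                        # statistic -> StatResult
    template_id: str = ""
    registration: str = ""
    n_subjects: int = 0
    n_vertices: int = 0
    n_excluded_vertices: int = 0
    convergence: dict = field(default_factory=dict)
    version: str = __version__
    config_hash: str = ""

    def to_json(self) -> str:
        return json.dumps(_to_jsonable(dataclasses.asdict(self)), indent=2,
                          sort_keys=True)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(x) for x in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    return obj


def _stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    ss = np.random.SeedSequence([global_seed, zlib.crc32(stage.encode()), index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# artifact (de)serialization
# ---------------------------------------------------------------------------

def save_param(path, param: ParamMesh) -> None:
    np.savez(path,
             vertices=param.mesh.vertices, faces=param.mesh.faces,
             loop_a=param.mesh.loop_a, loop_b=param.mesh.loop_b,
             orig_indices=(param.mesh.orig_indices
                           if param.mesh.orig_indices is not None
                           else np.arange(param.mesh.n_vertices)),
             u=param.u, v=param.v, h=param.h, corner_uv=param.corner_uv,
             conformal_factor=param.conformal_factor,
             mean_curvature=param.mean_curvature)


def load_param(path) -> ParamMesh:
    z = np.load(path)
    cyl = CylinderMesh(z["vertices"], z["faces"], loop_a=z["loop_a"],
                       loop_b=z["loop_b"], orig_indices=z["orig_indices"])
    return ParamMesh(mesh=cyl, u=z["u"], v=z["v"], h=float(z["h"]),
                     corner_uv=z["corner_uv"],
                     conformal_factor=z["conformal_factor"],
                     mean_curvature=z["mean_curvature"])


def export_param_vtk(path, param: ParamMesh) -> None:
    write_mesh(path, param.mesh, fmt="vtk", point_data={
        "u": param.u, "v": param.v,
        "lambda": param.conformal_factor, "H": param.mean_curvature})


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _cohort_from_config(config: RunConfig) -> list:
    if config.manifest is not None:
        return load_cohort(config.manifest)
    spec = config.cohort_spec or CohortSpec(seed=_stage_seed(config.seed, "cohort"))
    return generate_cohort(spec)


def stage_parameterize(cohort: list, config: RunConfig, out: Path) -> dict:
    """Cut and conformally parameterize every subject; cached as .npz."""
    pdir = out / "param"
    pdir.mkdir(parents=True, exist_ok=True)
    params = {}
    for s in cohort:
        f = pdir / f"{s.subject_id}.npz"
        if f.exists():
            params[s.subject_id] = load_param(f)
            continue
        cyl = cut_extremities(s.mesh, k=config.cut_k)
        param = parameterize(cyl)
        save_param(f, param)
        params[s.subject_id] = param
    return params


def select_template(cohort: list, config: RunConfig) -> str:
    """The template is one of the controls: either the configured subject id
    or a seeded random choice."""
    if config.template_id is not None:
        if not any(s.subject_id == config.template_id for s in cohort):
            raise ValueError(f"template {config.template_id!r} not in cohort")
        return config.template_id
    controls = [s.subject_id for s in cohort if s.group == 0]
    if not controls:
        raise ValueError("no control subjects to choose a template from")
    rng = np.random.default_rng(_stage_seed(config.seed, "template"))
    return controls[int(rng.integers(len(controls)))]


def stage_register(params: dict, template_id: str, config: RunConfig,
                   out: Path) -> tuple:
    """Register every subject's feature grid to the template's; cached."""
    rdir = out / f"register_{config.registration}"
    rdir.mkdir(parents=True, exist_ok=True)
    template = params[template_id]
    fixed = sample_feature_grid(template, config.grid_resolution)
    fields = {}
    logs = {}
    for sid, param in params.items():
        f = rdir / f"{sid}.npz"
        if f.exists():
            z = np.load(f)
            fields[sid] = DisplacementField2D(
                forward=z["forward"], backward=z["backward"],
                ssd_log=list(z["ssd_log"]), converged=bool(z["converged"]),
                ic_residual=float(z["ic_residual"]))
            logs[sid] = {"iterations": len(fields[sid].ssd_log),
                         "converged": fields[sid].converged,
                         "ic_residual": fields[sid].ic_residual}
            continue
        if sid == template_id:
            zero = np.zeros(config.grid_resolution + (2,))
            field_ = DisplacementField2D(forward=zero, backward=zero.copy(),
                                         converged=True, ic_residual=0.0)
        elif config.registration == "fluid":
            moving = sample_feature_grid(param, config.grid_resolution)
            field_ = fluid_register(moving, fixed, config.reg_params)
        else:
            field_ = harmonic_register(param, template, config.grid_resolution)
        np.savez(f, forward=field_.forward, backward=field_.backward,
                 ssd_log=np.asarray(field_.ssd_log), converged=field_.converged,
                 ic_residual=field_.ic_residual)
        fields[sid] = field_
        logs[sid] = {"iterations": len(field_.ssd_log),
                     "converged": field_.converged,
                     "ic_residual": field_.ic_residual}
        min_jac = min(jacobian_determinant(field_.forward).min(),
                      jacobian_determinant(field_.backward).min())
        if min_jac <= 0:
            raise RuntimeError(f"non-diffeomorphic field for subject {sid}")
    return fields, logs


def stage_morphometry(params: dict, fields: dict, template_id: str,
                      config: RunConfig, out: Path) -> dict:
    """Correspondence + the four measures for every subject; cached as CSV."""
    mdir = out / f"morpho_{config.registration}"
    mdir.mkdir(parents=True, exist_ok=True)
    template = params[template_id]
    tables = {}
    for sid, param in params.items():
        f = mdir / f"{sid}.csv"
        if f.exists():
            tables[sid] = pd.read_csv(f)
            continue
        corresponded = induce_correspondence(param, template, fields[sid])
        vm = compute_morphometry(template, corresponded,
                                 axis_source=config.axis_source)
        df = pd.DataFrame({
            "vertex": np.arange(template.n_vertices),
            "detJ": vm.detJ,
            "logS1": vm.logS[:, 0], "logS2": vm.logS[:, 1],
            "logS3": vm.logS[:, 2], "R": vm.R,
            "excluded": vm.excluded.astype(int)})
        df.to_csv(f, index=False)
        tables[sid] = df
    return tables


def stage_statistics(tables: dict, cohort: list, template: ParamMesh,
                     config: RunConfig, out: Path) -> tuple:
    """Group inference over the four measures; writes maps and summary."""
    sdir = out / f"stats_{config.registration}"
    sdir.mkdir(parents=True, exist_ok=True)
    order = [s.subject_id for s in cohort]
    detJ = np.stack([tables[sid]["detJ"].to_numpy() for sid in order])
    logS = np.stack([tables[sid][["logS1", "logS2", "logS3"]].to_numpy()
                     for sid in order])
    R = np.stack([tables[sid]["R"].to_numpy() for sid in order])
    excluded = np.stack([tables[sid]["excluded"].to_numpy() for sid in order])
    keep = ~excluded.any(axis=0)
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} vertices excluded (non-positive det J)")
    cohort_table = CohortTable(subject_ids=order,
                               groups=np.array([s.group for s in cohort]),
                               ages=np.array([s.age for s in cohort]))
    maps = group_analysis(detJ[:, keep], logS[:, keep], R[:, keep],
                          cohort_table, statistics=config.statistics,
                          n_perm=config.n_perm,
                          seed=_stage_seed(config.seed, "stats"),
                          threshold=config.alpha, q=config.q)
    # scatter p maps back over excluded vertices (p = 1 there)
    full_maps = {}
    for name, sm in maps.items():
        p_full = np.ones(template.n_vertices)
        stat_full = np.zeros(template.n_vertices)
        p_full[keep] = sm.p_values
        stat_full[keep] = sm.stat_values
        sm.p_values = p_full
        sm.stat_values = stat_full
        full_maps[name] = sm
        pd.DataFrame({"vertex": np.arange(template.n_vertices),
                      "stat": stat_full, "p": p_full}).to_csv(
            sdir / f"map_{name}.csv", index=False)
        np.savetxt(sdir / f"cdf_{name}.csv",
                   sm.cdf_curve, delimiter=",", header="p,cdf", comments="")
        write_mesh(sdir / f"map_{name}.vtk", template.mesh, fmt="vtk",
                   point_data={"stat": stat_full, "p": p_full})
    return full_maps, n_excluded


def detection_dice(p_values: np.ndarray, indicator: np.ndarray,
                   alpha: float = 0.05) -> float:
    """Dice overlap between the detected (p < alpha) vertex set and the
    ground-truth effect patch."""
    detected = p_values < alpha
    truth = indicator.astype(bool)
    denom = detected.sum() + truth.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.sum(detected & truth) / denom)


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, cohort: list | None = None) -> RunReport:
    """Execute all stages; identical config + seed reproduce the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = _cohort_from_config(config)
    params = stage_parameterize(cohort, config, out)
    template_id = select_template(cohort, config)
    fields, logs = stage_register(params, template_id, config, out)
    tables = stage_morphometry(params, fields, template_id, config, out)
    template = params[template_id]
    maps, n_excluded = stage_statistics(tables, cohort, template, config, out)

    # ground-truth indicator on the (cut) template vertices, when available
    indicator = None
    effect_subjects = [s for s in cohort if s.group == 1 and s.indicator.any()]
    if effect_subjects and template.mesh.orig_indices is not None:
        base_ind = effect_subjects[0].indicator
        if len(base_ind) > template.mesh.orig_indices.max():
            indicator = base_ind[template.mesh.orig_indices]

    results = {}
    for name, sm in maps.items():
        dice = (detection_dice(sm.p_values, indicator, config.alpha)
                if indicator is not None else None)
        results[name] = StatResult(statistic=name, corrected_p=sm.corrected_p,
                                   fdr_critical=sm.fdr_critical,
                                   n_suprathreshold=sm.n_suprathreshold,
                                   dice=dice)
    report = RunReport(results=results, template_id=template_id,
                       registration=config.registration,
                       n_subjects=len(cohort), n_vertices=template.n_vertices,
                       n_excluded_vertices=n_excluded, convergence=logs,
                       config_hash=config.config_hash())
    (out / f"report_{config.registration}.json").write_text(report.to_json())
    _write_summary_csv(out / f"summary_{config.registration}.csv", report)
    return report


def _write_summary_csv(path, report: RunReport) -> None:
    rows = []
    for name, r in report.results.items():
        rows.append({"statistic": name, "corrected_p": r.corrected_p,
                     "fdr_critical_p": r.fdr_critical,
                     "n_suprathreshold": r.n_suprathreshold, "dice": r.dice})
    pd.DataFrame(rows).to_csv(path, index=False)


def compare_registrations(config: RunConfig, cohort: list | None = None) -> dict:
    """Run fluid and harmonic registration on the same cohort and template and
    report the two sets of corrected p-values (and detection Dice when ground
    truth exists) side by side."""
    if cohort is None:
        cohort = _cohort_from_config(config)
    reports = {}
    for method in ("fluid", "harmonic"):
        cfg = dataclasses.replace(config, registration=method)
        reports[method] = run_pipeline(cfg, cohort=cohort)
    paired = {
        "template_id": reports["fluid"].template_id,
        "seed": config.seed,
        "statistics": {
            name: {m: {"corrected_p": reports[m].results[name].corrected_p,
                       "dice": reports[m].results[name].dice}
                   for m in ("fluid", "harmonic")}
            for name in config.statistics},
    }
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "compare_registrations.json").write_text(
        json.dumps(_to_jsonable(paired), indent=2, sort_keys=True))
    return paired
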