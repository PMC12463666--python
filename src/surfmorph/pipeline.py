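"""End-to-end study orchestration with manifests and determinism.

Stages mirror the analysis order: ``simulate`` (synthetic masks +
covariates), ``mesh`` (marching cubes + smoothing), ``register``
(template construction, remeshing to a fixed vertex budget, propagation),
``thickness`` (per-vertex fields, QC, cohort matrix), then the
statistical stages ``spm``, ``longitudinal``, ``ssa`` and ``survival``.

The geometric chain runs on a small set of voxelised subjects; the
statistical chain runs on a matrix-level cohort generated at the template
vertex directions (same planted-effect model, iid vertex noise), which is
what makes population-scale permutation studies tractable on a desk.

Every stage writes a JSON manifest (config hash, seed, input/output file
hashes); deterministic stages are byte-identical across reruns with the
same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as smio
from .correspondence import affine_align, build_template, propagate_template, rigid_align
from .geometry import SurfaceMesh, extract_surface, laplacian_smooth, vertex_adjacency
from .longitudinal import LongitudinalTable, run_longitudinal_map
from .spm import DesignMatrix, SPMConfig, run_spm
from .ssa import fit_spca, transform
from .survival import SurvivalTable, run_survival_study
from .synthetic import (
    CohortSpec,
    EffectRegion,
    SurvivalSpec,
    Visit2Spec,
    ellipsoid_directions,
    generate_cohort_thickness,
    generate_longitudinal_cohort,
    generate_subject_masks,
    generate_survival,
)
from .thickness import CohortMatrix, ThicknessField, compute_thickness, qc_filter, stack_cohort

__all__ = ["StudyConfig", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "mesh", "register", "thickness", "spm", "longitudinal", "ssa", "survival")

_STAGE_DEPENDENCIES = {
    "simulate": [],
    "mesh": ["covariates.csv"],
    "register": ["meshes/subject000_outer.ply"],
    "thickness": ["template.ply"],
    "spm": ["cohort_analysis.npy"],
    "longitudinal": ["template.ply"],
    "ssa": ["cohort_analysis.npy"],
    "survival": ["ssa_scores.csv"],
}


@dataclass
class StudyConfig:
    """Everything a full desk-scale study needs, JSON-serialisable."""

    seed: int = 0
    # synthetic cohort
    n_subjects: int = 200
    grid_shape: tuple = (64, 64, 64)
    voxel_spacing_mm: tuple = (3.0, 3.0, 3.0)
    inner_radii_mm: tuple = (55.0, 45.0, 40.0)
    base_thickness_mm: float = 20.0
    noise_sd_mm: float = 2.0
    effect_regions: list = field(default_factory=list)  # dicts, see _to_regions
    visit2_offset_regions: list = field(default_factory=list)
    visit2_measurement_sd_mm: float = 1.0
    survival_baseline_hazard: float = 0.05
    survival_log_hr: dict = field(default_factory=dict)
    survival_censor_time: float = 8.0
    # geometry / registration
    n_geometry_subjects: int = 6
    n_template_subjects: int = 4
    template_subdivisions: int = 3  # icosphere remesh budget: 3 -> 642, 4 -> 2562 vertices
    smooth_iterations: int = 10
    smooth_lambda: float = 0.5
    # QC
    qc_max_thickness_mm: float = 154.0
    # SPM
    spm_variables: list = field(default_factory=list)  # default: effect covariates
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_n_steps: int = 100
    n_permutations: int = 500
    fdr_q: float = 0.05
    # longitudinal
    longitudinal_fixed_effects: list = field(default_factory=lambda: ["visit"])
    # ssa / survival
    ssa_k: int = 4
    ssa_sparsity: float = 0.3
    survival_adjustment: list = field(default_factory=list)
    survival_volume_col: str = "asat_volume_l"
    survival_n_pcs: int = 4

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.grid_shape = tuple(cfg.grid_shape)
        cfg.voxel_spacing_mm = tuple(cfg.voxel_spacing_mm)
        cfg.inner_radii_mm = tuple(cfg.inner_radii_mm)
        return cfg

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]

    def _to_regions(self, raw: list) -> list[EffectRegion]:
        return [
            EffectRegion(
                center_direction=np.asarray(r["center_direction"], float),
                angular_radius_rad=float(r["angular_radius_rad"]),
                covariate=r["covariate"],
                beta_mm_per_sd=float(r["beta_mm_per_sd"]),
                profile=r.get("profile", "cosine"),
            )
            for r in raw
        ]

    def cohort_spec(self) -> CohortSpec:
        visit2 = None
        if self.visit2_offset_regions:
            visit2 = Visit2Spec(
                offset_regions=self._to_regions(self.visit2_offset_regions),
                measurement_sd_mm=self.visit2_measurement_sd_mm,
            )
        survival = SurvivalSpec(
            baseline_hazard=self.survival_baseline_hazard,
            log_hr=dict(self.survival_log_hr),
            censor_time=self.survival_censor_time,
        )
        return CohortSpec(
            n_subjects=self.n_subjects,
            grid_shape=self.grid_shape,
            voxel_spacing_mm=self.voxel_spacing_mm,
            inner_radii_mm=self.inner_radii_mm,
            base_thickness_mm=self.base_thickness_mm,
            effect_regions=self._to_regions(self.effect_regions),
            noise_sd_mm=self.noise_sd_mm,
            visit2=visit2,
            survival=survival,
            seed=self.seed,
        )

    def spm_config(self) -> SPMConfig:
        return SPMConfig(
            tfce_E=self.tfce_E,
            tfce_H=self.tfce_H,
            n_steps=self.tfce_n_steps,
            n_permutations=self.n_permutations,
            fdr_q=self.fdr_q,
            seed=self.seed,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(out: Path, stage: str, config: StudyConfig, inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "inputs": {str(p.relative_to(out)): _sha256(p) for p in inputs},
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(out: Path, stage: str) -> None:
    for rel in _STAGE_DEPENDENCIES[stage]:
        if not (out / rel).exists():
            raise FileNotFoundError(
                f"stage {stage!r} requires artifact {rel!r}; run its producing stage first"
            )


def _save_npy(path: Path, arr: np.ndarray) -> Path:
    np.save(path, arr)
    return path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(config: StudyConfig, out: Path) -> list[Path]:
    spec = config.cohort_spec()
    from .synthetic import generate_covariates

    table = generate_covariates(spec)
    outputs = [smio.write_table(table, out / "covariates.csv")]
    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    for i in range(min(config.n_geometry_subjects, spec.n_subjects)):
        outer, inner = generate_subject_masks(spec, i, table)
        outputs.append(smio.write_mask(outer, mask_dir / f"subject{i:03d}_outer.nii.gz"))
        outputs.append(smio.write_mask(inner, mask_dir / f"subject{i:03d}_inner.nii.gz"))
    return outputs


def _stage_mesh(config: StudyConfig, out: Path) -> list[Path]:
    mesh_dir = out / "meshes"
    mesh_dir.mkdir(exist_ok=True)
    outputs = []
    for i in range(config.n_geometry_subjects):
        for layer in ("outer", "inner"):
            mask = smio.read_mask(out / "masks" / f"subject{i:03d}_{layer}.nii.gz")
            mesh = laplacian_smooth(
                extract_surface(mask), config.smooth_iterations, config.smooth_lambda
            )
            outputs.append(smio.write_mesh(mesh, mesh_dir / f"subject{i:03d}_{layer}.ply"))
    return outputs


def _remesh_to_budget(template_mesh: SurfaceMesh, subdivisions: int) -> SurfaceMesh:
    """Resample a template onto icosphere topology for a fixed vertex budget."""
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions)
    center = template_mesh.vertices.mean(axis=0)
    radius = np.linalg.norm(template_mesh.vertices - center, axis=1).max() * 1.05
    probe = SurfaceMesh(np.asarray(ico.vertices) * radius + center, np.asarray(ico.faces))
    _, resampled = propagate_template(probe, template_mesh)
    return resampled


def _stage_register(config: StudyConfig, out: Path) -> list[Path]:
    meshes = [
        smio.read_mesh(out / "meshes" / f"subject{i:03d}_outer.ply")
        for i in range(config.n_geometry_subjects)
    ]
    n_tmpl = min(config.n_template_subjects, len(meshes))
    template_model = build_template(meshes[:n_tmpl], reference_index=0)
    template = _remesh_to_budget(template_model.mesh, config.template_subdivisions)
    outputs = [smio.write_mesh(template, out / "template.ply")]
    reg_dir = out / "registered"
    reg_dir.mkdir(exist_ok=True)
    transforms = {}
    for i, mesh in enumerate(meshes):
        rigid, aligned = rigid_align(mesh, template)
        aff, aligned = affine_align(mesh, template, rigid)
        _, resampled = propagate_template(template, aligned)
        transforms[f"subject{i:03d}"] = aff.matrix.tolist()
        outputs.append(smio.write_mesh(resampled, reg_dir / f"subject{i:03d}_outer_resampled.ply"))
    tr_path = out / "transforms.json"
    tr_path.write_text(json.dumps(transforms, indent=2, sort_keys=True))
    outputs.append(tr_path)
    return outputs


def _stage_thickness(config: StudyConfig, out: Path) -> list[Path]:
    transforms = json.loads((out / "transforms.json").read_text())
    fields = []
    for i in range(config.n_geometry_subjects):
        resampled = smio.read_mesh(out / "registered" / f"subject{i:03d}_outer_resampled.ply")
        inner = smio.read_mesh(out / "meshes" / f"subject{i:03d}_inner.ply")
        # thickness is measured in the subject's native frame (affine
        # alignment does not preserve distances): map template-space
        # resampled vertices back through the inverse transform
        M = np.asarray(transforms[f"subject{i:03d}"])
        Minv = np.linalg.inv(M)
        native = resampled.vertices @ Minv[:3, :3].T + Minv[:3, 3]
        field = compute_thickness(SurfaceMesh(native, resampled.faces), inner, subject_id=i)
        fields.append(field)
    kept, excluded, report = qc_filter(fields, max_thickness_mm=config.qc_max_thickness_mm)
    kept_fields = [f for f in fields if f.subject_id in kept]
    cohort = stack_cohort(kept_fields)
    outputs = []
    outputs.append(_save_npy(out / "cohort_geometry.npy", cohort.values))
    outputs.append(
        smio.write_table(pd.DataFrame({"subject_id": cohort.subject_ids}), out / "cohort_geometry_ids.csv")
    )
    (out / "qc_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    outputs.append(out / "qc_report.json")

    # analysis cohort at full n, generated at the template vertex directions
    template = smio.read_mesh(out / "template.ply")
    directions = ellipsoid_directions(template.vertices)
    spec = config.cohort_spec()
    M, table, gt = generate_cohort_thickness(spec, directions)
    outputs.append(_save_npy(out / "cohort_analysis.npy", M))
    gt.save(out / "ground_truth")
    outputs.extend(sorted((out / "ground_truth").glob("*")))
    return outputs


def _stage_spm(config: StudyConfig, out: Path) -> list[Path]:
    template = smio.read_mesh(out / "template.ply")
    adjacency = vertex_adjacency(template)
    M = np.load(out / "cohort_analysis.npy")
    table = smio.read_table(out / "covariates.csv", allow_missing=False)
    spec = config.cohort_spec()
    variables = list(config.spm_variables) or sorted({r.covariate for r in spec.effect_regions})
    if not variables:
        variables = ["age"]
    continuous = [
        v for v in variables if spec.covariates.get(v, ("binary",))[0] != "binary"
    ]
    design = DesignMatrix(table[variables].astype(float), continuous=continuous)
    result = run_spm(design, CohortMatrix(M), adjacency, config.spm_config(), variables=variables)
    outputs = [smio.write_table(result.summary, out / "spm_summary.csv")]
    for var in variables:
        arrays = {
            "beta_mm": result.beta_mm[var],
            "t": result.tstat[var],
            "tfce_pos": result.tfce_pos[var],
            "tfce_neg": result.tfce_neg[var],
            "p_pos": result.p_pos[var],
            "p_neg": result.p_neg[var],
            "sig": result.sig_pos[var].astype(float) - result.sig_neg[var].astype(float),
        }
        outputs.append(
            smio.write_vtk_polydata(template, out / f"spm_{var}.vtk", point_data=arrays)
        )
    return outputs


def _stage_longitudinal(config: StudyConfig, out: Path) -> list[Path]:
    template = smio.read_mesh(out / "template.ply")
    directions = ellipsoid_directions(template.vertices)
    spec = config.cohort_spec()
    if spec.visit2 is None:
        spec.visit2 = Visit2Spec(offset_regions=[], measurement_sd_mm=config.visit2_measurement_sd_mm)
    v1, v2, table, gt = generate_longitudinal_cohort(spec, directions)
    n = spec.n_subjects
    long_df = pd.DataFrame(
        {
            "subject": np.concatenate([np.arange(n), np.arange(n)]),
            "visit": np.concatenate([np.zeros(n, int), np.ones(n, int)]),
        }
    )
    for eff in config.longitudinal_fixed_effects:
        if eff == "visit":
            continue
        long_df[eff] = np.concatenate([table[eff].to_numpy(float)] * 2)
    ltab = LongitudinalTable(long_df)
    result = run_longitudinal_map(
        ltab, CohortMatrix(v1), CohortMatrix(v2), config.longitudinal_fixed_effects,
        fdr_q=config.fdr_q,
    )
    outputs = []
    arrays = {f"beta_{e}": result.beta[e] for e in result.effects}
    arrays.update({f"sig_{e}": result.sig[e].astype(float) for e in result.effects})
    outputs.append(smio.write_vtk_polydata(template, out / "longitudinal_maps.vtk", point_data=arrays))
    summary = {"visit_summary": result.visit_summary}
    (out / "longitudinal_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs.append(out / "longitudinal_summary.json")
    if gt.visit_offset_map is not None:
        outputs.append(_save_npy(out / "true_visit_offsets.npy", gt.visit_offset_map))
    return outputs


def _stage_ssa(config: StudyConfig, out: Path) -> list[Path]:
    M = np.load(out / "cohort_analysis.npy")
    model = fit_spca(M, k=config.ssa_k, sparsity=config.ssa_sparsity, seed=config.seed)
    scores = pd.DataFrame(
        model.scores, columns=[f"PC{j + 1}" for j in range(model.k)]
    )
    outputs = [smio.write_table(scores, out / "ssa_scores.csv")]
    outputs.append(_save_npy(out / "ssa_loadings.npy", model.loadings))
    meta = {
        "k": model.k,
        "sparsity": model.sparsity,
        "explained_variance_ratio": model.explained_variance_ratio.tolist(),
        "cumulative_explained": model.cumulative_explained.tolist(),
    }
    (out / "ssa_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    outputs.append(out / "ssa_meta.json")
    return outputs


def _stage_survival(config: StudyConfig, out: Path) -> list[Path]:
    spec = config.cohort_spec()
    table = smio.read_table(out / "covariates.csv")
    scores = smio.read_table(out / "ssa_scores.csv")
    # standardize scores before survival use
    z = (scores - scores.mean()) / scores.std(ddof=1)
    surv_df = generate_survival(spec, z)
    # guard against zero-duration rows from degenerate censoring settings
    surv_df["time"] = np.maximum(surv_df["time"], 1e-6)
    stable = SurvivalTable(pd.concat([surv_df], axis=1))
    adjustment = list(config.survival_adjustment) or ["age", "vat_l"]
    study = run_survival_study(
        table[adjustment + [config.survival_volume_col]],
        stable,
        z,
        adjustment,
        volume_col=config.survival_volume_col,
        n_pcs=config.survival_n_pcs,
        fdr_q=config.fdr_q,
    )
    outputs = []
    for name in ("volume", "thickness"):
        outputs.append(
            smio.write_table(study[name].summary_frame(), out / f"cox_{name}.csv", index=True)
        )
    (out / "cox_comparison.json").write_text(json.dumps(study["comparison"], indent=2, sort_keys=True))
    outputs.append(out / "cox_comparison.json")
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "mesh": _stage_mesh,
    "register": _stage_register,
    "thickness": _stage_thickness,
    "spm": _stage_spm,
    "longitudinal": _stage_longitudinal,
    "ssa": _stage_ssa,
    "survival": _stage_survival,
}


def run_pipeline(
    config: StudyConfig, out_dir: str | Path, stages: list[str] | None = None
) -> dict:
    """Run the requested stages in canonical order; returns a status dict.

    Each stage validates its input artifacts (error names the absent
    file), writes versioned outputs and a manifest carrying the config
    hash and seed. Reruns with an identical config are byte-identical for
    the deterministic stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    (out / "config.json").write_text(config.to_json())
    status = {}
    for stage in ordered:
        _require(out, stage)
        t0 = time.perf_counter()
        outputs = _STAGE_FUNCS[stage](config, out)
        inputs = [out / rel for rel in _STAGE_DEPENDENCIES[stage] if (out / rel).exists()]
        _write_manifest(out, stage, config, inputs, outputs)
        dt = time.perf_counter() - t0
        log.info("stage %-12s: %d outputs in %.1f s", stage, len(outputs), dt)
        status[stage] = {"outputs": len(outputs), "seconds": dt}
    return status
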