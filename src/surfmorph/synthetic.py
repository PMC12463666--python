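"""Synthetic cohorts with known ground truth.

The generator emulates the data a population-imaging thickness study
consumes, at desk scale and with every planted quantity recoverable:

* paired nested closed surfaces — an "inner" body-cavity ellipsoid and an
  "outer" tissue envelope whose radial separation carries the base
  thickness, spatially localised covariate effects and noise;
* a covariate table (age, height, grip strength, deprivation, lifestyle,
  muscle and visceral-fat volumes, sex-specific fat-to-muscle ratio and
  disease indicators) with declared means/SDs and prevalences;
* a second-visit copy with regional thickness offsets;
* survival times from a proportional-hazards model on shape scores.

Shapes are ellipsoids with angular raised-cosine (or top-hat) "bump"
effect regions, so the radial thickness function is analytic and serves
as the oracle for the whole geometric chain. Two noise models are used
deliberately: voxel-level masks perturb thickness with a *smooth* random
angular field (surfaces must stay meshable), while the matrix-level
generator adds iid per-vertex noise (emulating post-registration residual
noise); both have the declared marginal SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import VoxelMask
from .thickness import derive_lipodystrophy

__all__ = [
    "EffectRegion",
    "Visit2Spec",
    "SurvivalSpec",
    "CohortSpec",
    "GroundTruth",
    "generate_covariates",
    "generate_subject_masks",
    "generate_cohort_thickness",
    "generate_longitudinal_cohort",
    "generate_survival",
    "ellipsoid_directions",
]

#: Declared covariate distributions: name -> (kind, *params).
#: Continuous kinds record (mean, sd) or lognormal (mu, sigma);
#: binary kinds record the prevalence. Values are desk-scale stand-ins
#: for a late-middle-aged imaging cohort.
DEFAULT_COVARIATES: dict[str, tuple] = {
    "age": ("normal", 64.0, 7.5),
    "height_cm": ("normal", 168.5, 9.2),
    "hgs_kg": ("normal", 32.0, 11.0),
    "townsend": ("normal", -1.3, 3.0),
    "alcohol_freq": ("normal", 3.0, 1.4),
    "met_hours": ("normal", 6.0, 5.0),
    "total_muscle_l": ("normal", 23.0, 5.0),
    "vat_l": ("lognormal", 1.2, 0.5),
    "asat_volume_l": ("lognormal", 2.0, 0.35),
    "smoking": ("binary", 0.45),
    "t2d": ("binary", 0.055),
    "hypertension": ("binary", 0.37),
}

#: Sex-specific fat-to-muscle-ratio distributions (normal mean, sd),
#: tuned so the sex-specific lipodystrophy rule flags roughly 11%.
FMR_DISTRIBUTION = {"F": (0.9, 0.25), "M": (1.35, 0.28)}


@dataclass
class EffectRegion:
    """Angular bump carrying a covariate effect on thickness.

    ``beta_mm_per_sd`` is the peak thickness change (mm) per SD of the
    covariate (per category for binary covariates). ``profile`` is
    'cosine' (raised-cosine falloff to the region edge) or 'flat'
    (constant inside the region).
    """

    center_direction: np.ndarray
    angular_radius_rad: float
    covariate: str
    beta_mm_per_sd: float
    profile: str = "cosine"

    def __post_init__(self) -> None:
        d = np.asarray(self.center_direction, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError("center_direction must be a nonzero vector")
        self.center_direction = d / nrm
        if not (0 < self.angular_radius_rad < np.pi):
            raise ValueError("angular_radius_rad must lie in (0, pi)")
        if self.profile not in ("cosine", "flat"):
            raise ValueError("profile must be 'cosine' or 'flat'")

    def bump(self, directions: np.ndarray) -> np.ndarray:
        """Evaluate the bump (0..1) at unit directions (V, 3)."""
        cosang = np.clip(directions @ self.center_direction, -1.0, 1.0)
        theta = np.arccos(cosang)
        inside = theta < self.angular_radius_rad
        if self.profile == "flat":
            return inside.astype(float)
        out = np.zeros(len(directions))
        out[inside] = 0.5 * (1 + np.cos(np.pi * theta[inside] / self.angular_radius_rad))
        return out


@dataclass
class Visit2Spec:
    """Follow-up visit: regional thickness offsets plus rescan noise."""

    offset_regions: list = field(default_factory=list)  # (EffectRegion-like with offset in beta slot)
    measurement_sd_mm: float = 1.0


@dataclass
class SurvivalSpec:
    """Proportional-hazards outcome generator settings."""

    baseline_hazard: float = 0.05  # events per year
    log_hr: dict = field(default_factory=dict)  # score column -> log hazard ratio per unit
    censor_time: float = 10.0  # years

    def __post_init__(self) -> None:
        if self.baseline_hazard < 0:
            raise ValueError("baseline hazard must be nonnegative")
        if self.censor_time < 0:
            raise ValueError("censor time must be nonnegative")


@dataclass
class CohortSpec:
    """Full description of one synthetic study."""

    n_subjects: int = 200
    grid_shape: tuple = (64, 64, 64)
    voxel_spacing_mm: tuple = (3.0, 3.0, 3.0)
    inner_radii_mm: tuple = (55.0, 45.0, 40.0)
    base_thickness_mm: float = 20.0
    effect_regions: list = field(default_factory=list)
    noise_sd_mm: float = 2.0  # between-subject anatomical variation
    visit2: Visit2Spec | None = None
    survival: SurvivalSpec | None = None
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be nonnegative")
        for region in self.effect_regions:
            if region.covariate not in self.covariates:
                raise KeyError(f"effect region references undeclared covariate {region.covariate!r}")
        extent = np.asarray(self.grid_shape) * np.asarray(self.voxel_spacing_mm)
        max_offset = sum(abs(r.beta_mm_per_sd) * 4 for r in self.effect_regions)
        max_radius = (
            max(self.inner_radii_mm) + self.base_thickness_mm + max_offset + 5 * self.noise_sd_mm
        )
        if max_radius >= extent.min() / 2:
            raise ValueError(
                f"outer surface (radius up to ~{max_radius:.0f} mm) does not fit strictly inside "
                f"the grid (half-extent {extent.min() / 2:.0f} mm)"
            )

    # -- seeded generators -------------------------------------------------
    def rng_covariates(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, 0]))

    def rng_subject(self, i: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, 1, i]))

    def rng_survival(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, 2]))

    def rng_matrix(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, 3]))


@dataclass
class GroundTruth:
    """Planted quantities, stored alongside the generated outputs."""

    beta_maps: dict  # covariate -> (V,) true peak-profile effect in mm per SD
    visit_offset_map: np.ndarray | None  # (V,) true visit-2 change in mm
    log_hr: dict  # score column -> true log hazard ratio
    covariate_table: pd.DataFrame

    def effect_support(self, covariate: str) -> np.ndarray:
        return self.beta_maps[covariate] != 0

    def save(self, directory) -> None:
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.beta_maps).to_csv(directory / "true_beta_maps.csv", index=False)
        if self.visit_offset_map is not None:
            pd.DataFrame({"visit_offset_mm": self.visit_offset_map}).to_csv(
                directory / "true_visit_offsets.csv", index=False
            )
        self.covariate_table.to_csv(directory / "covariates.csv", index=False)
        (directory / "true_log_hr.json").write_text(json.dumps(self.log_hr, indent=2))


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def generate_covariates(spec: CohortSpec, n: int | None = None) -> pd.DataFrame:
    """Draw the subject covariate table from the declared distributions.

    Adds ``sex`` ('F'/'M', balanced), ``fmr`` (sex-specific) and the
    derived ``lipodystrophy`` indicator. Declared means/SDs are recorded
    in ``DataFrame.attrs['declared']``.
    """
    n = spec.n_subjects if n is None else n
    rng = spec.rng_covariates()
    out = {}
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    out["sex"] = sex
    for name, decl in spec.covariates.items():
        kind = decl[0]
        if kind == "normal":
            out[name] = rng.normal(decl[1], decl[2], size=n)
        elif kind == "lognormal":
            out[name] = rng.lognormal(decl[1], decl[2], size=n)
        elif kind == "binary":
            out[name] = (rng.random(n) < decl[1]).astype(int)
        else:
            raise ValueError(f"unknown covariate kind {kind!r} for {name!r}")
    fmr = np.empty(n)
    for code, (mu, sd) in FMR_DISTRIBUTION.items():
        m = sex == code
        fmr[m] = np.maximum(rng.normal(mu, sd, size=int(m.sum())), 0.0)
    out["fmr"] = fmr
    out["lipodystrophy"] = [int(derive_lipodystrophy(f, s)) for f, s in zip(fmr, sex)]
    df = pd.DataFrame(out)
    df.attrs["declared"] = dict(spec.covariates)
    return df


def _covariate_z(spec: CohortSpec, table: pd.DataFrame, name: str) -> np.ndarray:
    """Covariate on its effect scale: z-score (declared moments) for
    continuous, raw category for binary/derived indicators."""
    if name not in table.columns:
        raise KeyError(f"undeclared covariate {name!r}")
    decl = spec.covariates.get(name)
    x = table[name].to_numpy(float)
    if decl is None or decl[0] == "binary":  # indicator (incl. derived lipodystrophy)
        return x
    if decl[0] == "normal":
        return (x - decl[1]) / decl[2]
    if decl[0] == "lognormal":
        mu, sig = decl[1], decl[2]
        mean = np.exp(mu + sig**2 / 2)
        sd = mean * np.sqrt(np.expm1(sig**2))
        return (x - mean) / sd
    raise ValueError(f"unknown covariate kind for {name!r}")


# ---------------------------------------------------------------------------
# Radial thickness field (the analytic oracle)
# ---------------------------------------------------------------------------

def ellipsoid_radius(directions: np.ndarray, radii) -> np.ndarray:
    """Radius of an origin-centred ellipsoid along unit directions."""
    radii = np.asarray(radii, dtype=float)
    return 1.0 / np.sqrt(((directions / radii) ** 2).sum(axis=1))


def radial_thickness(
    spec: CohortSpec,
    directions: np.ndarray,
    covariate_table: pd.DataFrame,
    subject_index: int,
) -> np.ndarray:
    """Noiseless planted thickness at unit directions for one subject."""
    t = np.full(len(directions), spec.base_thickness_mm)
    for region in spec.effect_regions:
        z = _covariate_z(spec, covariate_table, region.covariate)[subject_index]
        t = t + region.beta_mm_per_sd * z * region.bump(directions)
    return t


def _smooth_noise_field(spec: CohortSpec, rng: np.random.Generator, n_bumps: int = 48):
    """A smooth random angular field with marginal SD ~ noise_sd_mm.

    Sum of raised-cosine bumps at random directions with iid normal
    amplitudes, normalised by the analytic RMS of the basis.
    """
    dirs = rng.standard_normal((n_bumps, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    width = 0.6  # rad
    amps = rng.standard_normal(n_bumps)
    # E[bump^2] over the sphere for a raised-cosine cap of half-angle w:
    # computed once numerically at module scale would be overkill; the
    # closed form of the cap-area integral is used instead.
    w = width
    # integral of (0.5(1+cos(pi t/w)))^2 sin t dt over [0, w], normalised by 2
    tt = np.linspace(0, w, 2049)
    f = (0.5 * (1 + np.cos(np.pi * tt / w))) ** 2 * np.sin(tt)
    e_b2 = np.trapezoid(f, tt) / 2.0
    scale = spec.noise_sd_mm / np.sqrt(n_bumps * e_b2)

    def evaluate(directions: np.ndarray) -> np.ndarray:
        cosang = np.clip(directions @ dirs.T, -1, 1)
        theta = np.arccos(cosang)
        bumps = np.where(theta < w, 0.5 * (1 + np.cos(np.pi * theta / w)), 0.0)
        return scale * bumps @ amps

    return evaluate


def generate_subject_masks(
    spec: CohortSpec, subject_index: int, covariate_table: pd.DataFrame | None = None
) -> tuple[VoxelMask, VoxelMask]:
    """Voxelise one subject's outer and inner surfaces.

    The inner mask is the body-cavity ellipsoid; the outer mask extends it
    radially by the planted thickness field (base + effects + smooth
    noise, clipped at one voxel). The inner mask is strictly contained in
    the outer one. Identical spec + seed give bitwise-identical masks.
    """
    if subject_index >= spec.n_subjects:
        raise IndexError("subject_index out of range")
    if covariate_table is None:
        covariate_table = generate_covariates(spec)
    shape = np.asarray(spec.grid_shape)
    spacing = np.asarray(spec.voxel_spacing_mm, dtype=float)
    center = (shape - 1) / 2.0 * spacing
    idx = np.indices(shape).reshape(3, -1).T
    delta = idx * spacing - center
    r = np.linalg.norm(delta, axis=1)
    r_safe = np.where(r == 0, 1.0, r)
    u = delta / r_safe[:, None]

    r_in = ellipsoid_radius(u, spec.inner_radii_mm)
    t = radial_thickness(spec, u, covariate_table, subject_index)
    if spec.noise_sd_mm > 0:
        noise = _smooth_noise_field(spec, spec.rng_subject(subject_index))
        t = t + noise(u)
    t = np.maximum(t, spacing.min())  # keep the shell at least one voxel thick

    inner_occ = (r <= r_in).reshape(tuple(shape))
    outer_occ = (r <= r_in + t).reshape(tuple(shape))
    inner_occ[tuple((shape - 1) // 2)] = True  # centre voxel always inside
    outer_occ |= inner_occ
    origin = np.zeros(3)
    return (
        VoxelMask(outer_occ, spacing, origin),
        VoxelMask(inner_occ, spacing, origin),
    )


# ---------------------------------------------------------------------------
# Matrix-level cohorts (post-registration scale)
# ---------------------------------------------------------------------------

def generate_cohort_thickness(
    spec: CohortSpec, directions: np.ndarray
) -> tuple[np.ndarray, pd.DataFrame, GroundTruth]:
    """Planted thickness matrix directly at template vertex directions.

    Emulates the cohort matrix *after* registration and resampling:
    ``thickness[s, v] = base + sum_j beta_j z_js bump_j(u_v) + eps`` with
    iid N(0, noise_sd^2) vertex noise. Returns (subjects x vertices
    matrix, covariate table, ground truth with per-vertex true beta maps).
    """
    directions = np.asarray(directions, dtype=float)
    table = generate_covariates(spec)
    n, V = spec.n_subjects, len(directions)
    base = np.full(V, spec.base_thickness_mm)
    M = np.tile(base, (n, 1))
    beta_maps: dict[str, np.ndarray] = {}
    for region in spec.effect_regions:
        z = _covariate_z(spec, table, region.covariate)
        bump = region.bump(directions)
        M += np.outer(z, region.beta_mm_per_sd * bump)
        beta_maps[region.covariate] = beta_maps.get(region.covariate, np.zeros(V)) + (
            region.beta_mm_per_sd * bump
        )
    if spec.noise_sd_mm > 0:
        M += spec.rng_matrix().normal(0.0, spec.noise_sd_mm, size=(n, V))
    M = np.maximum(M, 0.0)
    gt = GroundTruth(
        beta_maps=beta_maps,
        visit_offset_map=None,
        log_hr=dict(spec.survival.log_hr) if spec.survival else {},
        covariate_table=table,
    )
    return M, table, gt


def generate_longitudinal_cohort(
    spec: CohortSpec, directions: np.ndarray
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, GroundTruth]:
    """Two-visit thickness matrices with planted regional change.

    Visit 1 is the anatomical field (base + effects + between-subject
    noise); visit 2 adds the spec's regional offsets. Both visits receive
    independent rescan noise (``visit2.measurement_sd_mm``), so the
    between-subject field acts as the random intercept and the rescan
    noise as the residual.
    """
    if spec.visit2 is None:
        raise ValueError("spec.visit2 is not set")
    directions = np.asarray(directions, dtype=float)
    M1, table, gt = generate_cohort_thickness(spec, directions)
    V = len(directions)
    offset = np.zeros(V)
    for region in spec.visit2.offset_regions:
        offset += region.beta_mm_per_sd * region.bump(directions)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 4]))
    sd = spec.visit2.measurement_sd_mm
    e1 = rng.normal(0.0, sd, size=M1.shape)
    e2 = rng.normal(0.0, sd, size=M1.shape)
    visit1 = np.maximum(M1 + e1, 0.0)
    visit2 = np.maximum(M1 + offset + e2, 0.0)
    gt.visit_offset_map = offset
    return visit1, visit2, table, gt


# ---------------------------------------------------------------------------
# Survival outcomes
# ---------------------------------------------------------------------------

def generate_survival(spec: CohortSpec, shape_scores: pd.DataFrame) -> pd.DataFrame:
    """Exponential event times under a proportional-hazards model.

    rate_i = baseline * exp(sum_j log_hr_j * score_ij), administratively
    censored at ``censor_time``. Returns columns (time, event).
    """
    if spec.survival is None:
        raise ValueError("spec.survival is not set")
    surv = spec.survival
    lp = np.zeros(len(shape_scores))
    for name, coef in surv.log_hr.items():
        if name not in shape_scores.columns:
            raise KeyError(f"log_hr references unknown score column {name!r}")
        lp += coef * shape_scores[name].to_numpy(float)
    rate = surv.baseline_hazard * np.exp(lp)
    rng = spec.rng_survival()
    with np.errstate(divide="ignore"):
        raw = np.where(rate > 0, rng.exponential(1.0, size=len(rate)) / np.maximum(rate, 1e-300), np.inf)
    event = (raw <= surv.censor_time).astype(int)
    time = np.minimum(raw, surv.censor_time)
    if surv.censor_time == 0:
        time = np.zeros_like(time)
        event[:] = 0
    return pd.DataFrame({"time": time, "event": event}, index=shape_scores.index)


def ellipsoid_directions(mesh_vertices: np.ndarray, center: np.ndarray | None = None) -> np.ndarray:
    """Unit directions of mesh vertices about their centroid (or ``center``)."""
    v = np.asarray(mesh_vertices, dtype=float)
    c = v.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    d = v - c
    return d / np.linalg.norm(d, axis=1, keepdims=True)
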