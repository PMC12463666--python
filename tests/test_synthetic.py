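"""The cohort generator: determinism, planted signals, analytic oracles."""

import numpy as np
import pandas as pd
import pytest

from surfmorph.geometry import extract_surface, laplacian_smooth
from surfmorph.synthetic import (
    CohortSpec,
    EffectRegion,
    SurvivalSpec,
    ellipsoid_radius,
    generate_cohort_thickness,
    generate_covariates,
    generate_longitudinal_cohort,
    generate_subject_masks,
    generate_survival,
    radial_thickness,
)
from surfmorph.thickness import compute_thickness

from conftest import icosphere_mesh


def small_spec(**kw) -> CohortSpec:
    defaults = dict(n_subjects=4, seed=42, noise_sd_mm=0.0)
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestSpecValidation:
    def test_containment_violation_rejected(self):
        with pytest.raises(ValueError, match="fit strictly inside"):
            CohortSpec(inner_radii_mm=(90.0, 90.0, 90.0), base_thickness_mm=20.0)

    def test_undeclared_effect_covariate_rejected(self):
        with pytest.raises(KeyError, match="undeclared"):
            small_spec(
                effect_regions=[EffectRegion([0, 0, 1], 0.5, "no_such_cov", 1.0)]
            )

    def test_negative_baseline_hazard_rejected(self):
        with pytest.raises(ValueError):
            SurvivalSpec(baseline_hazard=-0.1)


class TestMasks:
    def test_inner_strictly_contained_in_outer(self):
        outer, inner = generate_subject_masks(small_spec(noise_sd_mm=2.0), 0)
        assert (inner.occupancy & ~outer.occupancy).sum() == 0
        assert outer.n_occupied > inner.n_occupied

    def test_noiseless_uniform_shell_thickness(self):
        spec = small_spec(inner_radii_mm=(50.0, 50.0, 50.0))
        outer, inner = generate_subject_masks(spec, 0)
        om = laplacian_smooth(extract_surface(outer))
        im = laplacian_smooth(extract_surface(inner))
        field = compute_thickness(om, im)
        # uniform radial thickness up to voxel discretisation (3 mm voxels)
        assert abs(field.values.mean() - spec.base_thickness_mm) < 3.0
        assert field.values.std() < 1.5

    def test_planted_region_raises_mean_thickness(self):
        spec = small_spec(
            n_subjects=2,
            effect_regions=[EffectRegion([0, 0, 1], 1.0, "age", 3.0, profile="flat")],
        )
        table = generate_covariates(spec)
        # pin the subject at +2 SD of age
        table.loc[0, "age"] = spec.covariates["age"][1] + 2 * spec.covariates["age"][2]
        outer, inner = generate_subject_masks(spec, 0, table)
        om = laplacian_smooth(extract_surface(outer))
        im = laplacian_smooth(extract_surface(inner))
        field = compute_thickness(om, im)
        center = om.vertices.mean(axis=0)
        d = om.vertices - center
        u = d / np.linalg.norm(d, axis=1, keepdims=True)
        inside = u @ np.array([0, 0, 1.0]) > np.cos(0.8)  # comfortably inside
        outside = u @ np.array([0, 0, 1.0]) < np.cos(1.2)
        excess = field.values[inside].mean() - field.values[outside].mean()
        assert abs(excess - 2 * 3.0) < 1.5  # ~2 SD * beta, voxel tolerance

    def test_masks_bitwise_deterministic(self):
        spec = small_spec(noise_sd_mm=2.0)
        o1, i1 = generate_subject_masks(spec, 1)
        o2, i2 = generate_subject_masks(spec, 1)
        assert np.array_equal(o1.occupancy, o2.occupancy)
        assert np.array_equal(i1.occupancy, i2.occupancy)

    def test_noiseless_radial_oracle_at_outer_vertices(self):
        spec = small_spec(
            effect_regions=[EffectRegion([1, 0, 0], 0.9, "vat_l", 2.0)]
        )
        table = generate_covariates(spec)
        outer, inner = generate_subject_masks(spec, 0, table)
        om = laplacian_smooth(extract_surface(outer))
        im = laplacian_smooth(extract_surface(inner))
        measured = compute_thickness(om, im).values
        center = np.asarray(spec.grid_shape) / 2 * np.asarray(spec.voxel_spacing_mm)
        center = (np.asarray(spec.grid_shape) - 1) / 2 * np.asarray(spec.voxel_spacing_mm)
        d = om.vertices - center
        u = d / np.linalg.norm(d, axis=1, keepdims=True)
        predicted = radial_thickness(spec, u, table, 0)
        tol = 1.5 * np.linalg.norm(spec.voxel_spacing_mm)
        assert np.abs(measured - predicted).max() < tol


class TestCovariates:
    def test_zero_prevalence_all_zero(self):
        spec = small_spec(n_subjects=50)
        spec.covariates["t2d"] = ("binary", 0.0)
        table = generate_covariates(spec)
        assert (table["t2d"] == 0).all()

    def test_large_sample_sd_within_2pct(self):
        spec = small_spec(n_subjects=10_000)
        spec.covariates["znorm"] = ("normal", 0.0, 1.0)
        table = generate_covariates(spec)
        assert abs(table["znorm"].std(ddof=1) - 1.0) < 0.02

    def test_undeclared_covariate_key_error(self):
        from surfmorph.synthetic import _covariate_z

        spec = small_spec()
        table = generate_covariates(spec)
        with pytest.raises(KeyError):
            _covariate_z(spec, table, "not_a_covariate")

    def test_lipodystrophy_follows_fmr_rule(self):
        table = generate_covariates(small_spec(n_subjects=500))
        f = table["sex"] == "F"
        assert (table.loc[f, "lipodystrophy"] == (table.loc[f, "fmr"] > 1.2).astype(int)).all()
        m = ~f
        assert (table.loc[m, "lipodystrophy"] == (table.loc[m, "fmr"] > 1.7).astype(int)).all()

    def test_deterministic(self):
        t1 = generate_covariates(small_spec(n_subjects=100))
        t2 = generate_covariates(small_spec(n_subjects=100))
        pd.testing.assert_frame_equal(t1, t2)


class TestMatrixCohort:
    def test_null_cohort_correlations_centered_at_zero(self, template_mesh):
        from surfmorph.synthetic import ellipsoid_directions

        spec = CohortSpec(n_subjects=150, noise_sd_mm=1.0, seed=9)
        dirs = ellipsoid_directions(template_mesh.vertices)
        M, table, _ = generate_cohort_thickness(spec, dirs)
        x = table["age"].to_numpy(float)
        xc = (x - x.mean()) / x.std(ddof=1)
        Yc = (M - M.mean(0)) / M.std(0, ddof=1)
        r = xc @ Yc / (len(x) - 1)
        assert abs(r.mean()) < 3 / np.sqrt(spec.n_subjects)

    def test_ground_truth_zero_outside_regions(self, template_mesh):
        from surfmorph.synthetic import ellipsoid_directions

        region = EffectRegion([0, 1, 0], 0.7, "age", 1.0)
        spec = CohortSpec(n_subjects=10, seed=1, effect_regions=[region])
        dirs = ellipsoid_directions(template_mesh.vertices)
        _, _, gt = generate_cohort_thickness(spec, dirs)
        beta = gt.beta_maps["age"]
        inside = region.bump(dirs) > 0
        assert (beta[~inside] == 0).all()
        assert (beta[inside] != 0).any()


class TestSurvivalGenerator:
    def test_null_log_hr_exponential_median(self):
        spec = small_spec(n_subjects=20_000, survival=SurvivalSpec(baseline_hazard=0.2, censor_time=1e9))
        scores = pd.DataFrame({"PC1": np.zeros(spec.n_subjects)})
        out = generate_survival(spec, scores)
        assert out["event"].all()
        assert abs(np.median(out["time"]) - np.log(2) / 0.2) < 0.1

    def test_zero_censor_time_all_censored(self):
        spec = small_spec(survival=SurvivalSpec(baseline_hazard=0.2, censor_time=0.0))
        scores = pd.DataFrame({"PC1": np.zeros(spec.n_subjects)})
        out = generate_survival(spec, scores)
        assert (out["event"] == 0).all()

    def test_log2_hr_doubles_event_rate(self):
        spec = small_spec(
            n_subjects=40_000,
            survival=SurvivalSpec(baseline_hazard=0.1, log_hr={"g": np.log(2)}, censor_time=1e9),
        )
        g = np.repeat([0, 1], spec.n_subjects // 2)
        out = generate_survival(spec, pd.DataFrame({"g": g.astype(float)}))
        rate0 = 1 / out.loc[g == 0, "time"].mean()
        rate1 = 1 / out.loc[g == 1, "time"].mean()
        assert abs(rate1 / rate0 - 2.0) < 0.1


class TestLongitudinal:
    def test_visit2_offset_recoverable(self, template_mesh):
        from surfmorph.synthetic import Visit2Spec, ellipsoid_directions

        region = EffectRegion([0, 0, 1], 0.8, "age", 1.0, profile="flat")
        spec = CohortSpec(
            n_subjects=80,
            seed=2,
            noise_sd_mm=2.0,
            visit2=Visit2Spec(offset_regions=[region], measurement_sd_mm=0.5),
        )
        dirs = ellipsoid_directions(template_mesh.vertices)
        v1, v2, _, gt = generate_longitudinal_cohort(spec, dirs)
        diff = (v2 - v1).mean(axis=0)
        inside = gt.visit_offset_map > 0
        assert abs(diff[inside].mean() - 1.0) < 0.1
        assert abs(diff[~inside].mean()) < 0.1
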