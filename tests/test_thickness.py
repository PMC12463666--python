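"""Thickness fields, QC rules and phenotype derivation."""

import numpy as np
import pytest

from surfmorph.geometry import SurfaceMesh
from surfmorph.thickness import (
    ThicknessField,
    compute_thickness,
    derive_lipodystrophy,
    qc_filter,
    stack_cohort,
)

from conftest import icosphere_mesh


def capped_cylinder(radius: float, height: float, sections: int = 64, rings: int = 13) -> SurfaceMesh:
    """Closed cylinder with intermediate rings so the side band has vertices."""
    zs = np.linspace(-height / 2, height / 2, rings)
    ang = np.linspace(0, 2 * np.pi, sections, endpoint=False)
    ring = np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])
    verts = [np.column_stack([ring, np.full(sections, z)]) for z in zs]
    verts = np.vstack(verts + [[[0.0, 0.0, zs[0]]], [[0.0, 0.0, zs[-1]]]])
    faces = []
    for k in range(rings - 1):
        for j in range(sections):
            a = k * sections + j
            b = k * sections + (j + 1) % sections
            c = a + sections
            d = b + sections
            faces += [[a, b, d], [a, d, c]]
    bot, top = rings * sections, rings * sections + 1
    for j in range(sections):
        faces.append([bot, (j + 1) % sections, j])
        faces.append([top, (rings - 1) * sections + j, (rings - 1) * sections + (j + 1) % sections])
    return SurfaceMesh(verts, np.array(faces))


class TestComputeThickness:
    def test_concentric_spheres(self):
        outer = icosphere_mesh(4, radius=70.0)  # 5120 faces
        inner = icosphere_mesh(4, radius=50.0)
        field = compute_thickness(outer, inner)
        assert np.abs(field.values - 20.0).max() < 0.2  # 1%

    def test_identical_meshes_zero(self):
        mesh = icosphere_mesh(3, radius=30.0)
        field = compute_thickness(mesh, mesh)
        assert np.abs(field.values).max() < 1e-9

    def test_coaxial_cylinders_mid_band(self):
        outer = capped_cylinder(30.0, 120.0)
        inner = capped_cylinder(20.0, 120.0)
        field = compute_thickness(outer, inner)
        # mid-band vertices, away from cap influence
        z = outer.vertices[:, 2]
        r = np.linalg.norm(outer.vertices[:, :2], axis=1)
        band = (np.abs(z) < 30) & (r > 29.9)
        assert band.sum() > 10
        assert np.abs(field.values[band] - 10.0).max() < 0.1

    def test_rigid_invariance(self, rng):
        outer = icosphere_mesh(3, radius=40.0)
        inner = SurfaceMesh(
            icosphere_mesh(3).vertices * np.array([30.0, 25.0, 20.0]), icosphere_mesh(3).faces
        )
        base = compute_thickness(outer, inner).values
        th = 0.7
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        t = np.array([7.0, -3.0, 11.0])
        outer2 = SurfaceMesh(outer.vertices @ R.T + t, outer.faces)
        inner2 = SurfaceMesh(inner.vertices @ R.T + t, inner.faces)
        moved = compute_thickness(outer2, inner2).values
        assert np.abs(base - moved).max() < 1e-6

    def test_nested_convex_bounded_by_radial_gap(self, rng):
        # closest-point distance never exceeds the radial gap for nested
        # star-shaped surfaces; dense-sampling oracle on random ellipsoids
        from surfmorph.synthetic import ellipsoid_radius

        for trial in range(3):
            radii_in = rng.uniform(15, 25, 3)
            gap = rng.uniform(5, 15)
            ico = icosphere_mesh(3)
            u = ico.vertices
            outer = SurfaceMesh(u * (ellipsoid_radius(u, radii_in) + gap)[:, None], ico.faces)
            inner = SurfaceMesh(u * ellipsoid_radius(u, radii_in)[:, None], ico.faces)
            field = compute_thickness(outer, inner)
            r_out = np.linalg.norm(outer.vertices, axis=1)
            radial_gap = r_out - ellipsoid_radius(outer.vertices / r_out[:, None], radii_in)
            assert (field.values <= radial_gap + 1e-6).all()

    def test_empty_inner_raises(self):
        mesh = icosphere_mesh(2)
        empty = SurfaceMesh(np.empty((0, 3)), np.empty((0, 3), dtype=int))
        with pytest.raises(ValueError):
            compute_thickness(mesh, empty)

    def test_normal_ray_variant_on_spheres(self):
        outer = icosphere_mesh(3, radius=40.0)
        inner = icosphere_mesh(3, radius=25.0)
        field = compute_thickness(outer, inner, method="normal_ray")
        assert np.abs(field.values - 15.0).max() < 0.3


class TestQCFilter:
    @staticmethod
    def _fields(maxima):
        return [
            ThicknessField(np.array([10.0, m]), subject_id=i) for i, m in enumerate(maxima)
        ]

    def test_explicit_154mm_threshold(self):
        kept, excluded, report = qc_filter(self._fields([80.0, 120.0, 160.0]), max_thickness_mm=154.0)
        assert kept == [0, 1] and excluded == [2]
        assert report["threshold_mm"] == 154.0

    def test_threshold_above_all_maxima(self):
        kept, excluded, _ = qc_filter(self._fields([10.0, 20.0]), max_thickness_mm=100.0)
        assert excluded == []

    def test_percentile_rule_hand_computed(self):
        # 50th percentile (linear interpolation) of {10,20,30,40} is 25
        kept, excluded, report = qc_filter(self._fields([10.0, 20.0, 30.0, 40.0]), percentile=50.0)
        assert kept == [0, 1] and excluded == [2, 3]
        assert np.isclose(report["threshold_mm"], 25.0)

    def test_exactly_one_rule_required(self):
        with pytest.raises(ValueError):
            qc_filter(self._fields([1.0]), max_thickness_mm=100.0, percentile=50.0)
        with pytest.raises(ValueError):
            qc_filter(self._fields([1.0]))

    def test_percentile_bounds(self):
        with pytest.raises(ValueError):
            qc_filter(self._fields([1.0, 2.0]), percentile=101.0)


class TestLipodystrophyRule:
    @pytest.mark.parametrize(
        "fmr,sex,expected",
        [
            (1.3, "F", True),
            (1.3, "M", False),
            (1.2, "F", False),  # strict inequality at the cut-off
            (1.7, "M", False),
            (1.71, "M", True),
            (0.0, "F", False),
        ],
    )
    def test_sex_specific_cutoffs(self, fmr, sex, expected):
        assert derive_lipodystrophy(fmr, sex) is expected

    def test_unknown_sex_code_raises(self):
        with pytest.raises(ValueError, match="sex"):
            derive_lipodystrophy(1.0, "X")


class TestStackCohort:
    def test_shape_and_row_order(self):
        fields = [ThicknessField(np.full(2000, float(i)), subject_id=f"s{i}") for i in range(3)]
        cohort = stack_cohort(fields)
        assert cohort.values.shape == (3, 2000)
        assert cohort.subject_ids == ["s0", "s1", "s2"]
        assert (cohort.values[1] == 1.0).all()

    def test_single_subject(self):
        field = ThicknessField(np.arange(5, dtype=float))
        cohort = stack_cohort([field])
        assert cohort.values.shape == (1, 5)
        assert np.array_equal(cohort.values[0], field.values)

    def test_mixed_templates_raise(self):
        fields = [ThicknessField(np.zeros(10)), ThicknessField(np.zeros(12))]
        with pytest.raises(ValueError, match="different templates"):
            stack_cohort(fields)
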