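"""Vertex-wise OLS, TFCE, permutation inference and FDR against oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from surfmorph.spm import (
    DesignMatrix,
    SPMConfig,
    bh_fdr,
    permutation_inference,
    standardize,
    summarize,
    tfce_enhance,
    vertexwise_ols,
)
from surfmorph.thickness import CohortMatrix


def brute_force_tfce(stat, adjacency, E, H, n_steps):
    """Independent oracle: explicit loop over thresholds and components."""
    V = len(stat)
    out = np.zeros(V)
    h_max = stat.max()
    if h_max <= 0:
        return out
    dh = h_max / n_steps
    for k in range(1, n_steps + 1):
        h = h_max * k / n_steps
        mask = stat >= h
        if not mask.any():
            continue
        sub = adjacency[np.ix_(mask, mask)]
        _, labels = connected_components(sub, directed=False)
        sizes = np.bincount(labels)
        idx = np.flatnonzero(mask)
        out[idx] += sizes[labels] ** E * h**H * dh
    return out


def random_graph(rng, V, density=0.15):
    A = np.triu(rng.random((V, V)) < density, 1)
    A = A | A.T
    return sparse.csr_matrix(A)


class TestStandardize:
    @staticmethod
    def _design():
        return DesignMatrix(
            pd.DataFrame({"x": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 1.0]}), continuous=["x"]
        )

    def test_hand_zscore(self):
        d, _, _ = standardize(self._design(), CohortMatrix(np.zeros((3, 2)) + [[1.0, 5.0], [2.0, 6.0], [3.0, 7.0]][0]))
        # recompute cleanly: column (1,2,3) -> (-1,0,1) with n-1 denominator
        design_s, _, _ = standardize(self._design(), CohortMatrix(np.arange(6, dtype=float).reshape(3, 2)))
        assert np.allclose(design_s.data["x"], [-1.0, 0.0, 1.0])

    def test_binary_untouched(self):
        design_s, _, _ = standardize(self._design(), CohortMatrix(np.arange(6, dtype=float).reshape(3, 2)))
        assert np.array_equal(design_s.data["b"], [0.0, 1.0, 1.0])

    def test_response_roundtrip(self, rng):
        from surfmorph.spm import invert_standardization

        Y = rng.normal(3, 2, (20, 7))
        _, resp_s, params = standardize(self._design_n(20), CohortMatrix(Y))
        back = invert_standardization(resp_s.values, params)
        assert np.abs(back - Y).max() < 1e-12

    @staticmethod
    def _design_n(n):
        x = np.linspace(0, 1, n)
        return DesignMatrix(pd.DataFrame({"x": x}), continuous=["x"])

    def test_zero_variance_column_names_culprit(self):
        with pytest.raises(ValueError, match="'x'"):
            DesignMatrix(
                pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 4.0]}),
                continuous=["x", "y"],
            )


class TestVertexwiseOLS:
    def test_noiseless_planted_model_exact(self, rng):
        n, V = 50, 30
        x = rng.normal(0, 1, n)
        design = DesignMatrix(pd.DataFrame({"x": x}), continuous=[])
        Y = np.zeros((n, V))
        Y[:, :10] = 0.5 * x[:, None]
        B, T, _ = vertexwise_ols(CohortMatrix(Y), design)
        j = design.columns.index("x")
        assert np.abs(B[j, :10] - 0.5).max() < 1e-10
        assert (np.abs(T[j, :10]) >= 1e6).all()  # guarded large finite
        assert np.isfinite(T).all()

    def test_matches_per_vertex_textbook_ols(self, rng):
        n, V = 40, 5
        X = np.column_stack([np.ones(n), rng.normal(0, 1, (n, 2))])
        design = DesignMatrix(pd.DataFrame({"a": X[:, 1], "b": X[:, 2]}), continuous=[])
        Y = rng.normal(0, 1, (n, V))
        B, T, _ = vertexwise_ols(CohortMatrix(Y), design)
        for v in range(V):
            beta_naive, *_ = np.linalg.lstsq(X, Y[:, v], rcond=None)
            resid = Y[:, v] - X @ beta_naive
            s2 = resid @ resid / (n - 3)
            se = np.sqrt(s2 * np.diag(np.linalg.inv(X.T @ X)))
            assert np.abs(B[:, v] - beta_naive).max() < 1e-10
            assert np.abs(T[:, v] - beta_naive / se).max() < 1e-8

    def test_subject_permutation_invariance(self, rng):
        n, V = 30, 8
        x = rng.normal(0, 1, n)
        design = DesignMatrix(pd.DataFrame({"x": x}), continuous=[])
        Y = rng.normal(0, 1, (n, V))
        B1, _, _ = vertexwise_ols(CohortMatrix(Y), design)
        perm = rng.permutation(n)
        design2 = DesignMatrix(pd.DataFrame({"x": x[perm]}), continuous=[])
        B2, _, _ = vertexwise_ols(CohortMatrix(Y[perm]), design2)
        assert np.abs(B1 - B2).max() < 1e-10

    def test_rank_deficiency_raises(self, rng):
        x = rng.normal(0, 1, 20)
        with pytest.raises(ValueError, match="rank deficient"):
            DesignMatrix(pd.DataFrame({"x": x, "x2": 2 * x}), continuous=[])


class TestTFCE:
    def test_three_vertex_worked_example(self):
        adj = sparse.csr_matrix(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool))
        out = tfce_enhance(np.array([1.0, 2.0, 0.0]), adj, n_steps=2, E=0.5, H=2.0)
        expected = np.array([np.sqrt(2), np.sqrt(2) + 4.0, 0.0])
        assert np.abs(out - expected).max() < 1e-12

    def test_all_zero_stat_gives_zero(self, template_adjacency):
        out = tfce_enhance(np.zeros(template_adjacency.shape[0]), template_adjacency)
        assert (out == 0).all()

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(50):
            V = int(rng.integers(5, 31))
            adj = random_graph(rng, V)
            stat = rng.normal(0, 1, V)
            fast = tfce_enhance(stat, adj, n_steps=23, E=0.5, H=2.0)
            slow = brute_force_tfce(stat, adj, 0.5, 2.0, 23)
            assert np.abs(fast - slow).max() < 1e-9

    def test_riemann_sum_self_convergence(self, rng, template_adjacency):
        # smooth field: squared low-frequency signal
        V = template_adjacency.shape[0]
        x = rng.normal(0, 1, V)
        for _ in range(20):  # graph smoothing
            deg = np.asarray(template_adjacency.sum(axis=1)).ravel()
            x = (template_adjacency @ x) / deg
        stat = np.abs(x) / np.abs(x).std()
        coarse = tfce_enhance(stat, template_adjacency, n_steps=100)
        fine = tfce_enhance(stat, template_adjacency, n_steps=200)
        rel = np.abs(fine - coarse).max() / fine.max()
        assert rel < 0.02

    def test_monotone_in_stat_scaling(self, rng):
        adj = random_graph(rng, 25)
        stat = np.abs(rng.normal(0, 1, 25))
        base = tfce_enhance(stat, adj, n_steps=50)
        scaled = tfce_enhance(2.0 * stat, adj, n_steps=50)
        assert (scaled >= base - 1e-12).all()

    def test_area_weighted_extent(self):
        adj = sparse.csr_matrix(np.array([[0, 1], [1, 0]], dtype=bool))
        stat = np.array([1.0, 1.0])
        areas = np.array([2.0, 3.0])
        out = tfce_enhance(stat, adj, areas=areas, n_steps=10, E=1.0, H=1.0, extent_mode="area_weighted")
        # extent 5 at every threshold h = k/10: sum 5 * h * 0.1 = 5 * 0.55
        assert np.allclose(out, 5 * 0.55)

    def test_non_finite_raises(self, template_adjacency):
        bad = np.zeros(template_adjacency.shape[0])
        bad[0] = np.nan
        with pytest.raises(ValueError):
            tfce_enhance(bad, template_adjacency)


class TestPermutationInference:
    @staticmethod
    def _null_setup(rng, n=60, V=40):
        x = rng.normal(0, 1, n)
        z = rng.normal(0, 1, n)
        design = DesignMatrix(pd.DataFrame({"x": x, "z": z}), continuous=[])
        Y = rng.normal(0, 1, (n, V))
        adj = random_graph(rng, V, density=0.1)
        return design, CohortMatrix(Y), adj

    def test_p_values_within_bounds(self, rng):
        design, Y, adj = self._null_setup(rng)
        cfg = SPMConfig(n_permutations=100, seed=3)
        out = permutation_inference(Y, design, "x", adj, config=cfg)
        for key in ("p_pos", "p_neg"):
            assert out[key].min() >= 1 / 101 - 1e-12
            assert out[key].max() <= 1.0 + 1e-12

    def test_seeded_determinism(self, rng):
        design, Y, adj = self._null_setup(rng)
        cfg = SPMConfig(n_permutations=120, seed=7)
        a = permutation_inference(Y, design, "x", adj, config=cfg)
        b = permutation_inference(Y, design, "x", adj, config=cfg)
        assert np.array_equal(a["p_pos"], b["p_pos"])
        assert np.array_equal(a["p_neg"], b["p_neg"])

    def test_strong_effect_saturates_p(self, rng):
        n, V = 80, 30
        x = rng.normal(0, 1, n)
        design = DesignMatrix(pd.DataFrame({"x": x}), continuous=[])
        Y = rng.normal(0, 0.2, (n, V))
        Y[:, :10] += x[:, None]  # overwhelming effect
        adj = sparse.csr_matrix(sparse.diags([np.ones(V - 1)] * 2, [-1, 1]).astype(bool))
        cfg = SPMConfig(n_permutations=200, seed=1)
        out = permutation_inference(CohortMatrix(Y), design, "x", adj, config=cfg)
        assert np.isclose(out["p_pos"][:10].min(), 1 / 201)

    def test_unknown_variable_raises(self, rng):
        design, Y, adj = self._null_setup(rng)
        with pytest.raises(KeyError):
            permutation_inference(Y, design, "nope", adj, config=SPMConfig(n_permutations=100))


class TestBHFDR:
    def test_hand_computed_example(self):
        p = np.array([0.01, 0.02, 0.04, 0.50])
        mask = bh_fdr(p, q=0.05)
        assert mask.tolist() == [True, True, False, False]

    def test_all_ones_empty(self):
        assert not bh_fdr(np.ones(10), 0.05).any()

    def test_boundary_all_rejected(self):
        m = 8
        p = np.full(m, 0.05 / m)
        assert bh_fdr(p, 0.05).all()

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=50), st.floats(0.01, 0.2))
    def test_matches_step_up_definition(self, p_list, q):
        p = np.array(p_list)
        mask = bh_fdr(p, q)
        m = len(p)
        order = np.argsort(p)
        ranked = p[order]
        passing = np.flatnonzero(ranked <= (np.arange(1, m + 1) * q / m))
        expected = np.zeros(m, bool)
        if len(passing):
            expected[order[: passing[-1] + 1]] = True
        assert np.array_equal(mask, expected)


class TestSummarize:
    def test_full_mask_constant_beta(self):
        beta = {"x": np.full(10, 2.5)}
        sig_pos = {"x": np.ones(10, bool)}
        sig_neg = {"x": np.zeros(10, bool)}
        out = summarize(beta, sig_pos, sig_neg)
        row = out[(out.covariate == "x") & (out.sign == "pos")].iloc[0]
        assert row.median_beta == 2.5 and row.iqr_beta == 0.0 and row.significance_area_pct == 100.0

    def test_empty_mask_reports_absent(self):
        beta = {"x": np.arange(10, dtype=float)}
        masks0 = {"x": np.zeros(10, bool)}
        out = summarize(beta, masks0, masks0)
        assert out.median_beta.isna().all()
        assert (out.significance_area_pct == 0).all()
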