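"""Pseudotime pipeline: embedding, principal path, LOESS, staging, LMG."""

import numpy as np
import pytest
from scipy import stats

from proteotrans.trajectory import (TrajectoryError, classify_stage,
                                    compute_pseudotime, fit_trajectory,
                                    knn_graph, loess_fit,
                                    milestone_pseudotime,
                                    relative_importance, spectral_embedding,
                                    top_pcs)


class TestTopPcs:
    def test_rank2_data_reconstructed(self):
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((2, 8))
        coords = rng.standard_normal((30, 2))
        x = coords @ basis
        scores = top_pcs(x, 2)
        # scores retain all variance of the centered data
        xc = x - x.mean(0)
        assert np.allclose((scores ** 2).sum(), (xc ** 2).sum(), atol=1e-8)

    def test_duplicated_samples_duplicate_scores(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((10, 5))
        x[3] = x[7]
        scores = top_pcs(x, 3)
        np.testing.assert_allclose(scores[3], scores[7], atol=1e-10)

    def test_zero_components_rejected(self):
        with pytest.raises(TrajectoryError):
            top_pcs(np.ones((5, 5)), 0)


class TestKnnGraph:
    def test_three_collinear_points(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        adj = knn_graph(pts, k=1)
        expected = np.array([[False, True, False],
                             [True, False, True],
                             [False, True, False]])
        np.testing.assert_array_equal(adj, expected)

    def test_symmetry_property(self):
        rng = np.random.default_rng(2)
        adj = knn_graph(rng.standard_normal((40, 3)), k=5)
        np.testing.assert_array_equal(adj, adj.T)
        assert not adj.diagonal().any()

    def test_k_equals_n_minus_one_complete(self):
        rng = np.random.default_rng(3)
        adj = knn_graph(rng.standard_normal((8, 2)), k=7)
        assert adj.sum() == 8 * 7

    def test_k_too_large_rejected(self):
        with pytest.raises(TrajectoryError):
            knn_graph(np.ones((4, 2)), k=4)


class TestSpectralEmbedding:
    def test_path_graph_fiedler_ordering(self):
        n = 5
        adj = np.zeros((n, n))
        for i in range(n - 1):
            adj[i, i + 1] = adj[i + 1, i] = 1
        emb, mask = spectral_embedding(adj, dim=2)
        assert mask.all()
        fiedler = emb[:, 0]
        assert np.all(np.diff(fiedler) > 0) or np.all(np.diff(fiedler) < 0)

    def test_relabeling_permutes_rows(self):
        rng = np.random.default_rng(4)
        adj = knn_graph(rng.standard_normal((25, 3)), k=4).astype(float)
        emb, _ = spectral_embedding(adj)
        perm = rng.permutation(25)
        emb_p, _ = spectral_embedding(adj[np.ix_(perm, perm)])
        np.testing.assert_allclose(emb_p, emb[perm], atol=1e-8)

    def test_disconnected_graph_flags_minor_component(self):
        adj = np.zeros((7, 7))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 4)]:
            adj[i, j] = adj[j, i] = 1
        adj[5, 6] = adj[6, 5] = 1
        emb, mask = spectral_embedding(adj)
        assert mask.sum() == 5
        assert np.isnan(emb[5]).all() and np.isnan(emb[6]).all()


class TestFitTrajectory:
    def test_collinear_points_perfect_ordering(self):
        t = np.linspace(0, 1, 60)
        emb = np.column_stack([t, 0.5 * t])
        res = fit_trajectory(emb, seed=0)
        rho = stats.spearmanr(res.pseudotime, t).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_pseudotime_in_unit_interval(self):
        rng = np.random.default_rng(5)
        emb = rng.standard_normal((80, 2))
        res = fit_trajectory(emb, seed=0)
        assert res.pseudotime.min() == 0.0 and res.pseudotime.max() == 1.0

    def test_orientation_is_a_symmetry(self):
        # flipping the path yields 1 - pseudotime; comparisons use |rho|
        t = np.linspace(0, 1, 50)
        emb = np.column_stack([t, t ** 2])
        res = fit_trajectory(emb, seed=0)
        flipped = 1.0 - res.pseudotime
        rho = stats.spearmanr(res.pseudotime, flipped).statistic
        assert rho == pytest.approx(-1.0)

    def test_planted_noisy_arc_recovered(self):
        rng = np.random.default_rng(6)
        n = 500
        t = np.sort(rng.uniform(0, 1, n))
        arc = np.column_stack([np.cos(2.0 * t), np.sin(2.0 * t)])
        scale = np.linalg.norm(arc.max(0) - arc.min(0))
        emb = arc + rng.standard_normal((n, 2)) * 0.1 * scale / np.sqrt(2)
        res = fit_trajectory(emb, seed=0)
        rho = abs(stats.spearmanr(res.pseudotime, t).statistic)
        assert rho >= 0.9

    def test_degenerate_embedding_rejected(self):
        with pytest.raises(TrajectoryError):
            fit_trajectory(np.ones((20, 2)), seed=0)

    def test_pseudotime_invariant_under_rotation(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 1, 100)
        emb = np.column_stack([t, np.sin(t)]) + rng.standard_normal((100, 2)) * 0.01
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        r1 = fit_trajectory(emb, seed=0)
        r2 = fit_trajectory(emb @ rot.T, seed=0)
        rho = abs(stats.spearmanr(r1.pseudotime, r2.pseudotime).statistic)
        assert rho > 0.99


class TestLoess:
    def test_constant_curve(self):
        x = np.linspace(0, 1, 50)
        _, fitted = loess_fit(x, np.full(50, 3.3))
        np.testing.assert_allclose(fitted, 3.3, atol=1e-10)

    @pytest.mark.parametrize("coeffs", [(2.0, 0.0, 0.0), (1.0, -2.0, 0.0),
                                        (0.5, 1.5, -3.0)])
    def test_polynomial_exactness_up_to_degree_two(self, coeffs):
        rng = np.random.default_rng(8)
        x = np.sort(rng.uniform(0, 1, 80))
        a, b, c = coeffs
        y = a + b * x + c * x ** 2
        grid, fitted = loess_fit(x, y, degree=2, span=0.5)
        expected = a + b * grid + c * grid ** 2
        np.testing.assert_allclose(fitted, expected, atol=1e-6)

    def test_span_too_small_rejected(self):
        x = np.linspace(0, 1, 10)
        with pytest.raises(TrajectoryError):
            loess_fit(x, x, degree=2, span=0.05)


class TestMilestone:
    def test_linear_ramp_crosses_at_quarter(self):
        grid = np.linspace(0, 1, 100)
        crossing = milestone_pseudotime(grid, grid.copy())
        assert abs(crossing - 0.25) <= grid[1] - grid[0]

    def test_flat_curve_has_no_crossing(self):
        grid = np.linspace(0, 1, 100)
        assert milestone_pseudotime(grid, np.ones(100)) is None

    def test_logistic_crossing_matches_root_finding(self):
        from scipy.optimize import brentq
        grid = np.linspace(0, 1, 100)
        curve = 1 / (1 + np.exp(-10 * (grid - 0.5)))
        crossing = milestone_pseudotime(grid, curve)
        lo, hi = curve.min(), curve.max()
        target = lo + 0.25 * (hi - lo)
        exact = brentq(lambda t: 1 / (1 + np.exp(-10 * (t - 0.5)))
                       - target, 0, 1)
        assert abs(crossing - exact) <= grid[1] - grid[0]


class TestClassifyStage:
    MILESTONES = {"amyloid": 0.2, "tau": 0.5, "cognition": 0.8}

    def _sigmoid_curve(self, center, slope=20):
        grid = np.linspace(0, 1, 100)
        return grid, 1 / (1 + np.exp(-slope * (grid - center)))

    def test_sigmoid_before_amyloid_is_early(self):
        curves = {"m": self._sigmoid_curve(0.08)}
        out = classify_stage(curves, self.MILESTONES)
        assert out[0].stage == "early"

    def test_sine_module_unspecified(self):
        grid = np.linspace(0, 1, 100)
        curves = {"m": (grid, np.sin(2 * np.pi * grid))}
        out = classify_stage(curves, self.MILESTONES)
        assert out[0].stage == "unspecified" and not out[0].monotone

    def test_stage_windows(self):
        curves = {"early": self._sigmoid_curve(0.1),
                  "mid": self._sigmoid_curve(0.4),
                  "late": self._sigmoid_curve(0.7)}
        out = {s.module_id: s.stage for s in
               classify_stage(curves, self.MILESTONES)}
        assert out == {"early": "early", "mid": "mid", "late": "late"}

    def test_nonincreasing_milestones_rejected(self):
        with pytest.raises(TrajectoryError):
            classify_stage({}, {"amyloid": 0.5, "tau": 0.2, "cognition": 0.8})


class TestRelativeImportance:
    def test_single_predictor_share_is_r2(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(100)
        y = 2 * x + rng.standard_normal(100)
        share = relative_importance(y, x[:, None])
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert share.iloc[0] == pytest.approx(r2, abs=1e-10)

    def test_shares_sum_to_total_r2(self):
        rng = np.random.default_rng(10)
        for seed in range(20):
            r = np.random.default_rng(seed)
            n, p = 80, int(r.integers(2, 6))
            X = r.standard_normal((n, p))
            y = X @ r.standard_normal(p) + r.standard_normal(n)
            shares = relative_importance(y, X)
            ones = np.column_stack([np.ones(n), X])
            beta, *_ = np.linalg.lstsq(ones, y, rcond=None)
            resid = y - ones @ beta
            yc = y - y.mean()
            r2 = 1 - (resid @ resid) / (yc @ yc)
            assert float(shares.sum()) == pytest.approx(r2, abs=1e-10)

    def test_too_many_predictors_rejected(self):
        rng = np.random.default_rng(11)
        with pytest.raises(TrajectoryError):
            relative_importance(rng.standard_normal(30),
                                rng.standard_normal((30, 7)))


class TestPipeline:
    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        t = rng.uniform(0, 1, 150)
        vals = np.outer(t, rng.standard_normal(30)) \
            + rng.standard_normal((150, 30)) * 0.1
        res = compute_pseudotime(vals, n_pcs=5, k=10, seed=0)
        perm = rng.permutation(150)
        res_p = compute_pseudotime(vals[perm], n_pcs=5, k=10, seed=0)
        rho = abs(stats.spearmanr(res.pseudotime[perm],
                                  res_p.pseudotime).statistic)
        assert rho > 0.999

    def test_anchor_orients_pseudotime(self):
        rng = np.random.default_rng(13)
        t = rng.uniform(0, 1, 150)
        vals = np.outer(t, rng.standard_normal(30)) \
            + rng.standard_normal((150, 30)) * 0.1
        res = compute_pseudotime(vals, n_pcs=5, k=10, seed=0, anchor=t)
        rho = stats.spearmanr(res.pseudotime, t).statistic
        assert rho > 0.9  # positive, not just |rho|
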