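import numpy as np
import pytest

import roiselect as rs
from roiselect.selection import (
    ROIWindow,
    SelectionProblem,
    brute_force_select,
    select_entropy,
    select_l1,
)

from conftest import small_grid_spec


def random_problem(seed, n_clusters=5, n_candidates=10, exact_b=True):
    rng = np.random.default_rng(seed)
    A = rng.dirichlet(np.ones(n_clusters) * 0.8, size=n_candidates).T
    if exact_b:
        b = A @ rng.dirichlet(np.ones(n_candidates))
    else:
        b = rng.dirichlet(np.ones(n_clusters))
    return SelectionProblem(A, b)


class TestProblemAssembly:
    def test_candidate_count_at_stride_equal_side(self):
        grid = rs.generate_tile_grid(rs.SyntheticSpec(
            image_size_px=8 * 32, tile_size_px=32, smoothness_px=48.0, seed=0))
        prob = SelectionProblem.from_grid(grid, 4, 4)
        assert prob.n_candidates == 4
        assert len(prob.candidates) == 4

    def test_partition_identity(self):
        """Pooling all non-overlapping candidates reproduces b exactly."""
        grid = rs.generate_tile_grid(small_grid_spec(0))
        prob = SelectionProblem.from_grid(grid, 4, 4)
        assert np.allclose(prob.A.mean(axis=1), prob.b, atol=1e-12)

    def test_homogeneous_grid_zero_entropy(self):
        comps = np.tile([1.0, 0.0], (16, 1))
        grid = rs.TileGrid(4, 4, 32, comps)
        prob = SelectionProblem.from_grid(grid, 2, 2)
        assert np.allclose(prob.E, 0.0)
        assert np.allclose(prob.A, prob.b[:, None])

    def test_pixel_roi_sizes_map_to_tiles(self):
        grid = rs.generate_tile_grid(rs.SyntheticSpec(seed=0))
        for px, side in [(1000, 4), (1500, 6), (2000, 8), (2500, 10)]:
            prob = SelectionProblem.from_pixel_roi_size(grid, px)
            assert prob.candidates[0].height_tiles == side

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SelectionProblem(np.ones((3, 4)), np.full(3, 1 / 3))


class TestSelectL1:
    def test_exact_column_match_singleton(self):
        prob = random_problem(0)
        b = prob.A[:, 3]
        prob2 = SelectionProblem(prob.A, b)
        res = select_l1(prob2, epsilon=1e-9)
        assert res.support.tolist() == [3]
        assert res.objective == pytest.approx(1.0)

    def test_exact_two_column_combination_recovered(self):
        rng = np.random.default_rng(3)
        A = rng.dirichlet(np.ones(6), size=10).T
        b = 0.5 * A[:, 1] + 0.5 * A[:, 4]
        res = select_l1(SelectionProblem(A, b), epsilon=1e-6)
        assert res.support.tolist() == [1, 4]

    def test_lp_mode_reported_in_status(self):
        prob = random_problem(1)
        res = select_l1(prob, mode="lp")
        assert res.status.startswith("lp:")
        assert np.all((res.x >= -1e-9) & (res.x <= 1 + 1e-9))

    def test_epsilon_doubling_is_logged_in_status(self):
        # b sits ~0.08 outside the candidate hull: eps=1e-3 is infeasible
        # but the bounded doubling reaches a feasible slack
        A = np.array([[0.62, 0.58, 0.60], [0.38, 0.42, 0.40]])
        b = np.array([0.5, 0.5])
        res = select_l1(SelectionProblem(A, b), epsilon=1e-3)
        assert "epsilon doubled" in res.status
        assert res.params["epsilon"] >= 0.08

    def test_unreachable_b_raises_with_diagnostic(self):
        A = np.tile([[1.0], [0.0]], (1, 3))
        b = np.array([0.0, 1.0])
        with pytest.raises(RuntimeError, match="best achievable"):
            select_l1(SelectionProblem(A, b))


class TestSelectEntropy:
    def test_lambda_zero_exact_match_is_vertex(self):
        prob = random_problem(4)
        b = prob.A[:, 2]
        prob2 = SelectionProblem(prob.A, b)
        res = select_entropy(prob2, lam=0.0)
        assert res.support.tolist() == [2]
        assert res.objective == pytest.approx(0.0, abs=1e-9)

    def test_objective_matches_agreeing_nnls_reduction(self):
        # lam=0 reduces to least squares on the simplex
        prob = random_problem(5)
        res = select_entropy(prob, lam=0.0, refine=False)
        x = res.x
        assert res.objective == pytest.approx(
            float(np.sum((prob.A @ x - prob.b) ** 2)), abs=1e-9
        )

    def test_duplicate_columns_tie_symmetry(self):
        rng = np.random.default_rng(6)
        A = rng.dirichlet(np.ones(4), size=5).T
        A = np.hstack([A, A])  # duplicated candidates
        b = A @ np.full(10, 0.1)
        res = select_entropy(SelectionProblem(A, b), lam=0.0, refine=False)
        # solutions are equivalent under swapping a duplicate pair
        x = res.x
        swapped = np.concatenate([x[5:], x[:5]])
        f = lambda v: float(np.sum((A @ v - b) ** 2))
        assert f(swapped) == pytest.approx(f(x), abs=1e-9)

    def test_entropy_weight_never_reduces_mean_entropy(self):
        for seed in range(8):
            prob = SelectionProblem.from_grid(
                rs.generate_tile_grid(small_grid_spec(seed)), 4
            )
            h0 = prob.E[select_entropy(prob, lam=0.0).support].mean()
            h1 = prob.E[select_entropy(prob, lam=1.0).support].mean()
            assert h1 >= h0 - 1e-9

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            select_entropy(random_problem(7), lam=-0.5)

    def test_entropy_sign_flip_prefers_homogeneous(self):
        prob = SelectionProblem.from_grid(
            rs.generate_tile_grid(small_grid_spec(11)), 4
        )
        hetero = select_entropy(prob, lam=1.0, entropy_sign=+1.0)
        homo = select_entropy(prob, lam=1.0, entropy_sign=-1.0)
        assert prob.E[homo.support].mean() <= prob.E[hetero.support].mean() + 1e-9


class TestRandomSelection:
    def _grid_problem(self, seed=0):
        return SelectionProblem.from_grid(
            rs.generate_tile_grid(small_grid_spec(seed)), 4
        )

    def test_all_candidates_zero_variance(self):
        prob = self._grid_problem()
        res = prob.fit("random", k=prob.n_candidates, n_draws=20, seed=0)
        assert res.metrics.mse.std() == 0.0
        assert res.metrics.mse.iloc[0] == pytest.approx(0.0, abs=1e-18)

    def test_seeded_reproducibility(self):
        prob = self._grid_problem(1)
        r1 = prob.fit("random", k=2, n_draws=30, seed=5)
        r2 = prob.fit("random", k=2, n_draws=30, seed=5)
        assert r1.draws == r2.draws
        assert np.allclose(r1.metrics, r2.metrics)

    def test_windows_pairwise_non_overlapping(self):
        grid = rs.generate_tile_grid(small_grid_spec(2))
        prob = SelectionProblem.from_grid(grid, 4, stride_tiles=2)  # overlapping cands
        res = prob.fit("random", k=3, n_draws=10, seed=0)
        for draw in res.draws:
            ws = [prob.candidates[i] for i in draw]
            for i in range(3):
                for j in range(i + 1, 3):
                    assert not ws[i].overlaps(ws[j])

    def test_mean_mse_decreases_with_k(self):
        prob = self._grid_problem(3)
        means = [
            prob.fit("random", k=k, n_draws=150, seed=7).metrics.mse.mean()
            for k in (1, 4, 9)
        ]
        assert means[0] > means[1] > means[2]

    def test_infeasible_k_raises(self):
        prob = self._grid_problem(4)
        with pytest.raises((ValueError, RuntimeError)):
            prob.fit("random", k=prob.n_candidates + 1, n_draws=2, seed=0)


class TestBruteForce:
    def test_support_counting(self):
        prob = random_problem(8, n_candidates=4)
        # evaluating sizes 1..2 of 4 candidates touches 4 + 6 = 10 supports
        sup, f = brute_force_select(prob, max_k=2, objective="entropy", lam=0.0)
        assert 1 <= sup.size <= 2

    def test_budget_guard(self):
        prob = random_problem(9, n_candidates=50)
        with pytest.raises(ValueError, match="budget"):
            brute_force_select(prob, max_k=25, budget=1000)

    def test_agrees_with_l1_on_exact_combination(self):
        rng = np.random.default_rng(10)
        A = rng.dirichlet(np.ones(5), size=8).T
        b = 0.5 * A[:, 0] + 0.5 * A[:, 6]
        prob = SelectionProblem(A, b)
        res = select_l1(prob, epsilon=1e-6)
        sup, f = brute_force_select(prob, max_k=8, objective="l1", epsilon=1e-6)
        assert f == res.support_objective == 2.0


class TestResultObject:
    def test_summary_and_dict(self):
        prob = SelectionProblem.from_grid(
            rs.generate_tile_grid(small_grid_spec(5)), 4
        )
        res = prob.fit("entropy", lam=1.0)
        text = res.summary()
        assert "entropy" in text and "selected ROIs" in text
        d = res.to_dict()
        assert d["support"] == res.support.tolist()

    def test_windows_and_evaluate_roundtrip(self):
        grid = rs.generate_tile_grid(small_grid_spec(6))
        prob = SelectionProblem.from_grid(grid, 4)
        res = prob.fit("entropy", lam=1.0)
        rep = res.evaluate()
        direct = rs.evaluate_selection(grid, res.windows)
        assert rep.mse == pytest.approx(direct.mse)

    def test_window_geometry(self):
        w = ROIWindow(1, 2, 3, 4)
        assert w.pixel_bounds(10) == (10, 20, 40, 60)
        assert w.overlaps(ROIWindow(3, 5, 2, 2))
        assert not w.overlaps(ROIWindow(4, 2, 1, 1))
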