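"""Sparse-grid surrogate: exactness, refinement, focusing, serialization."""
import numpy as np
import pytest

from mbdoe.models import InputSchedule, simulate
from mbdoe.screening import build_trajectory_surrogate, latin_hypercube
from mbdoe.sparse_grid import (SparseGridInterpolant, build_focused_grids,
                               build_interpolant, interpolate,
                               lagrange_time_interp, node_count)


class TestNodeCounts:
    @pytest.mark.parametrize("depth,dim,expected", [
        (0, 1, 1), (1, 1, 3), (3, 1, 9), (5, 1, 33), (3, 3, 69),
    ])
    def test_known_counts(self, depth, dim, expected):
        assert node_count(depth, dim) == expected

    def test_monotone_in_depth_and_dim(self):
        for d in range(1, 5):
            assert node_count(d, 2) > node_count(d - 1, 2)
            assert node_count(d, 3) > node_count(d, 2)


class TestBuildInterpolant:
    def test_constant_function_terminates_at_depth_zero(self):
        interp = build_interpolant(lambda p: np.array([7.0]), [[0, 1], [0, 1]],
                                   max_depth=4)
        assert interp.depth == 0
        assert interp.est_rel_error == 0.0
        assert interp.est_abs_error == 0.0

    def test_multilinear_polynomial_is_reproduced_exactly(self, rng):
        f = lambda p: np.array([1.0 + 2 * p[0] - 0.5 * p[1] + 3 * p[0] * p[1]])
        interp = build_interpolant(f, [[0, 2], [1, 3]], max_depth=3,
                                   rel_tol=0.0, abs_tol=0.0)
        pts = rng.uniform([0, 1], [2, 3], size=(100, 2))
        truth = np.array([f(p)[0] for p in pts])
        assert np.max(np.abs(interp.evaluate(pts)[:, 0] - truth)) < 1e-8

    def test_node_exactness(self, rng):
        f = lambda p: np.array([np.sin(3 * p[0]) * np.exp(p[1]), p[0] ** 3])
        interp = build_interpolant(f, [[0, 1], [0, 1]], max_depth=4,
                                   rel_tol=0.0, abs_tol=0.0)
        nodes = interp.node_points()
        err = np.abs(interp.evaluate(nodes) - interp.values)
        assert err.max() <= 1e-10

    def test_refinement_error_monotone_on_smooth_function(self):
        f = lambda p: np.array([np.exp(-(p[0] - 0.3) ** 2 - (p[1] - 0.6) ** 2)])
        errs = [build_interpolant(f, [[0, 1], [0, 1]], max_depth=d,
                                  rel_tol=0.0, abs_tol=0.0).est_abs_error
                for d in range(1, 6)]
        assert all(a >= b for a, b in zip(errs, errs[1:]))

    def test_failed_node_is_flagged_and_skipped(self):
        def f(p):
            if p[0] < 1e-9:          # fails at the left endpoint node
                raise RuntimeError("boom")
            return np.array([p[0]])

        interp = build_interpolant(f, [[0, 1]], max_depth=2)
        assert not interp.valid.all()
        assert np.all(np.isfinite(interp.evaluate(np.array([[0.3]]))))

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            build_interpolant(lambda p: np.array([0.0]), [[1, 1]])

    def test_max_nodes_cap_respected(self):
        f = lambda p: np.array([np.sin(10 * p[0]) + p[1]])
        interp = build_interpolant(f, [[0, 1], [0, 1]], max_depth=6,
                                   rel_tol=0.0, abs_tol=0.0, max_nodes=40)
        assert interp.n_nodes <= 40


class TestInterpolate:
    def test_stored_node_identity_with_time_basis(self):
        tg = np.linspace(0, 10, 11)
        f = lambda p: (p[0] * tg).ravel()
        interp = build_interpolant(f, [[0, 2]], max_depth=3, rel_tol=0,
                                   abs_tol=0, time_grid=tg, n_series=1)
        node = interp.node_points()[3]
        out = interpolate(interp, node, tg)
        assert np.allclose(out[0], node[0] * tg, atol=1e-12)

    def test_three_node_linear_basis_hand_value(self):
        # 1-D depth-1 grid: nodes 0, 0.5, 1 with hierarchical hats; a linear
        # function is reproduced exactly, so the midpoint of [0, 0.5] is the
        # average of the endpoint values
        f = lambda p: np.array([2.0 * p[0] + 1.0])
        interp = build_interpolant(f, [[0, 1]], max_depth=1, rel_tol=0, abs_tol=0)
        assert interp.n_nodes == 3
        val = interp.evaluate(np.array([[0.25]]))[0, 0]
        assert val == pytest.approx(0.5 * (f([0.0])[0] + f([0.5])[0]))

    def test_empty_time_grid_errors(self):
        tg = np.linspace(0, 1, 5)
        interp = build_interpolant(lambda p: np.ones(5), [[0, 1]], max_depth=1,
                                   time_grid=tg, n_series=1)
        with pytest.raises(ValueError):
            interp.evaluate_series(np.array([[0.5]]), np.array([]))

    def test_lagrange_time_interpolation_exact_for_cubic(self):
        grid = np.linspace(0, 10, 21)
        series = (0.3 * grid ** 3 - grid ** 2 + 2)[None, :]
        q = np.array([0.7, 3.33, 9.81])
        out = lagrange_time_interp(series, grid, q, degree=3)
        assert np.allclose(out[0], 0.3 * q ** 3 - q ** 2 + 2, rtol=1e-10)


class TestChebInterpolant1D:
    def test_polynomial_reproduced_exactly(self, rng):
        from mbdoe.sparse_grid import build_cheb_interpolant_1d
        coef = rng.standard_normal(6)
        f = lambda x: np.array([np.polyval(coef, x)])
        interp = build_cheb_interpolant_1d(f, -1.0, 2.0, max_depth=3,
                                           rel_tol=0.0, abs_tol=0.0)
        q = rng.uniform(-1, 2, 40)
        assert np.allclose(interp.evaluate(q)[:, 0], np.polyval(coef, q),
                           atol=1e-9)

    def test_node_identity(self, rng):
        from mbdoe.sparse_grid import build_cheb_interpolant_1d
        f = lambda x: np.array([np.sin(5 * x), x ** 2])
        interp = build_cheb_interpolant_1d(f, 0.0, 1.0, max_depth=4,
                                           rel_tol=0.0, abs_tol=0.0)
        assert np.allclose(interp.evaluate(interp.nodes), interp.values,
                           atol=1e-12)

    def test_adaptive_termination_on_smooth_function(self):
        from mbdoe.sparse_grid import build_cheb_interpolant_1d
        f = lambda x: np.array([np.exp(x)])
        interp = build_cheb_interpolant_1d(f, 0.0, 1.0, max_depth=5,
                                           rel_tol=1e-6, abs_tol=0.0)
        # exp on [0,1] converges spectrally: well below the depth cap
        assert interp.n_nodes <= 17
        assert interp.est_rel_error <= 1e-6


class TestHes1Surrogate:
    def test_surrogate_tracks_direct_simulation(self, hes1, base_schedule, rng):
        sur = build_trajectory_surrogate(hes1, base_schedule, max_depth=3)
        pts = latin_hypercube(50, hes1.bounds, rng)
        times = np.linspace(0, 300, 151)
        approx = sur.outputs_at(pts)
        scale = approx.max() - approx.min()
        worst = 0.0
        for i, p in enumerate(pts):
            tr = simulate(hes1, p, base_schedule, times)
            worst = max(worst, np.max(np.abs(approx[i] - tr.outputs.T)) / scale)
        # interpolation error within the achieved (coarse-grid) estimate
        assert worst <= max(sur.interpolant.est_rel_error, 0.10) * 1.5

    def test_serialization_roundtrip(self, hes1, base_schedule, tmp_path):
        sur = build_trajectory_surrogate(hes1, base_schedule, max_depth=2)
        path = tmp_path / "interp.npz"
        sur.interpolant.save(path)
        back = SparseGridInterpolant.load(path)
        pts = np.array([[2.4, 2.0, 0.025], [1.0, 5.0, 0.1]])
        assert np.allclose(back.evaluate(pts), sur.interpolant.evaluate(pts))
        assert back.depth == sur.interpolant.depth


class TestFocusedGrids:
    def test_no_acceptable_points_is_an_error(self):
        with pytest.raises(ValueError, match="widen T_A"):
            build_focused_grids(np.empty((0, 2)), [[0, 1], [0, 1]])

    def test_single_cluster_yields_one_bounding_box(self, rng):
        pts = rng.uniform(0.4, 0.5, size=(30, 2))
        boxes = build_focused_grids(pts, [[0, 1], [0, 1]])
        assert len(boxes) == 1
        b = boxes[0].box
        assert np.all(b[:, 0] <= pts.min(axis=0))
        assert np.all(b[:, 1] >= pts.max(axis=0))

    def test_two_disjoint_islands_get_two_boxes(self, rng):
        a = rng.uniform(0.05, 0.15, size=(25, 2))
        b = rng.uniform(0.8, 0.9, size=(25, 2))
        boxes = build_focused_grids(np.vstack([a, b]), [[0, 1], [0, 1]])
        assert len(boxes) == 2
        covered = []
        for pts in (a, b):
            covered.append(any(
                np.all(pts >= fb.box[:, 0]) and np.all(pts <= fb.box[:, 1])
                for fb in boxes))
        assert all(covered)

    def test_refined_interpolants_built_on_request(self, rng):
        pts = rng.uniform(0.4, 0.6, size=(20, 2))
        f = lambda p: np.array([p[0] + p[1]])
        boxes = build_focused_grids(pts, [[0, 1], [0, 1]], evaluator=f,
                                    max_depth=2, rel_tol=0.0, abs_tol=0.0)
        interp = boxes[0].interpolant
        assert interp is not None
        probe = rng.uniform(interp.box[:, 0], interp.box[:, 1], size=(20, 2))
        truth = probe.sum(axis=1)
        assert np.max(np.abs(interp.evaluate(probe)[:, 0] - truth)) < 1e-8
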