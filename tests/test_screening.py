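"""Acceptable-parameter screening, clustering, representatives, moments."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbdoe.models import Dataset, InputSchedule, generate_plant_data
from mbdoe.screening import (ClusterModel, DirectSource, batch_fitness,
                             build_trajectory_surrogate, cluster_dynamics,
                             fitness, latin_hypercube, screen_acceptable,
                             select_representatives, weighted_expectation,
                             weighted_variance)


def _toy_dataset(means, sds):
    return Dataset(pd.DataFrame({
        "output_id": ["m"] * len(means),
        "time_min": np.arange(len(means), dtype=float),
        "mean": means, "sd": sds, "schedule_id": "x"}))


class TestFitness:
    def test_perfect_fit_is_zero(self):
        ds = _toy_dataset([1.0, 2.0], [0.1, 0.1])
        assert fitness([1.0, 2.0], ds) == 0.0

    def test_boundary_ssr_99_equals_threshold(self):
        ds = _toy_dataset([0.0], [1.0])
        assert fitness([np.sqrt(99.0)], ds) == pytest.approx(2.0)

    def test_three_record_hand_value(self):
        ds = _toy_dataset([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        # z-scores 1, 2, 3 -> log10(1 + 14)
        assert fitness([1.0, 2.0, 3.0], ds) == pytest.approx(np.log10(15.0))

    def test_missing_simulated_value_errors(self):
        ds = _toy_dataset([1.0, 2.0], [0.1, 0.1])
        with pytest.raises(ValueError):
            fitness([1.0, np.nan], ds)
        with pytest.raises(ValueError):
            fitness([1.0], ds)


class TestScreenAcceptable:
    def test_infinite_threshold_accepts_everything(self, hes1, base_schedule,
                                                   initial_dataset, rng):
        sur = build_trajectory_surrogate(hes1, base_schedule, max_depth=1)
        acc = screen_acceptable([(sur, initial_dataset)], hes1.bounds,
                                n_lhs=200, T_A=np.inf, N_A=10, rng=rng)
        assert len(acc) == 200

    def test_acceptance_concentrates_under_tiny_noise(self, base_schedule, rng):
        """Synthetic data with small noise: every accepted point sits near the
        generating parameters."""
        from mbdoe.models import hes1_model
        model = hes1_model(bounds_scale=(0.5, 2.0))
        theta_star = model.nominal_unknowns
        points = [("m", t) for t in (20.0, 60.0, 120.0, 200.0)] + \
                 [("P1+P2", t) for t in (20.0, 60.0, 120.0, 200.0)]
        ds = generate_plant_data(model, theta_star, base_schedule, points,
                                 0.02, 3, seed=5)
        src = DirectSource(model, base_schedule)
        acc = screen_acceptable([(src, ds)], model.bounds, n_lhs=600, T_A=2.0,
                                N_A=1, rng=rng, focused_rounds=2)
        rel = np.abs(acc.parameters - theta_star) / theta_star
        # nu is pinned hard by the data; P0/h trade off along the Hill curve
        assert np.all(rel[:, 2] < 0.25)

    def test_zero_acceptable_raises(self, hes1, base_schedule, rng):
        ds = _toy_dataset([1e6], [1e-6])
        src = DirectSource(hes1, base_schedule)
        with pytest.raises(RuntimeError, match="no acceptable"):
            screen_acceptable([(src, ds)], hes1.bounds, n_lhs=20, T_A=2.0,
                              N_A=5, rng=rng, focused_rounds=0)

    def test_focused_rounds_enlarge_the_set(self, hes1, base_schedule,
                                            initial_dataset, rng):
        sur = build_trajectory_surrogate(hes1, base_schedule, max_depth=3)
        acc0 = screen_acceptable([(sur, initial_dataset)], hes1.bounds,
                                 n_lhs=4000, T_A=2.0, N_A=1, rng=np.random.default_rng(3),
                                 focused_rounds=0)
        acc1 = screen_acceptable([(sur, initial_dataset)], hes1.bounds,
                                 n_lhs=4000, T_A=2.0, N_A=20 * max(len(acc0), 1),
                                 rng=np.random.default_rng(3), focused_rounds=3)
        assert len(acc1) > len(acc0)
        assert any(p.startswith("focused") for p in acc1.provenance)


class TestClusterDynamics:
    def test_two_separated_bundles_recovered(self, rng):
        t = np.linspace(0, 1, 20)
        flat = np.sin(2 * np.pi * t)
        bumpy = np.cos(6 * np.pi * t) + 3.0
        trajs = np.array([[flat + 0.01 * rng.standard_normal(20)] for _ in range(15)] +
                         [[bumpy + 0.01 * rng.standard_normal(20)] for _ in range(15)])
        cm = cluster_dynamics(trajs, seed=0)
        assert cm.k == 2
        labels = cm.labels
        assert len(set(labels[:15])) == 1 and len(set(labels[15:])) == 1
        assert labels[0] != labels[15]

    def test_identical_trajectories_form_one_cluster(self):
        trajs = np.ones((10, 2, 30))
        cm = cluster_dynamics(trajs)
        assert cm.k == 1
        assert np.all(cm.labels == 0)

    def test_single_trajectory_is_an_error(self):
        with pytest.raises(ValueError):
            cluster_dynamics(np.ones((1, 2, 5)))


class TestSelectRepresentatives:
    def test_three_noncollinear_points_returned_verbatim(self, rng):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        cm = ClusterModel(affinity=np.ones((3, 3)), eigenvalues=np.zeros(3),
                          k=1, labels=np.zeros(3, dtype=int))
        reps = select_representatives(cm, pts, C=3, rng=rng)
        assert sorted(map(tuple, reps.parameters)) == sorted(map(tuple, pts))

    def test_square_corners_beat_interior_point(self, rng):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]], dtype=float)
        cm = ClusterModel(affinity=np.ones((5, 5)), eigenvalues=np.zeros(5),
                          k=1, labels=np.zeros(5, dtype=int))
        reps = select_representatives(cm, pts, C=4, rng=rng)
        assert len(reps) == 4
        assert (0.5, 0.5) not in set(map(tuple, reps.parameters))

    def test_count_and_uniform_weights_across_clusters(self, rng):
        a = rng.uniform(0, 1, size=(40, 3))
        b = rng.uniform(5, 6, size=(40, 3))
        labels = np.array([0] * 40 + [1] * 40)
        cm = ClusterModel(affinity=np.eye(80), eigenvalues=np.zeros(80),
                          k=2, labels=labels)
        reps = select_representatives(cm, np.vstack([a, b]), C=4, rng=rng)
        assert len(reps) == 8  # C * number of clusters
        assert np.allclose(reps.weights, 1.0 / 8)
        assert abs(reps.weights.sum() - 1.0) < 1e-12

    def test_c_below_three_rejected(self, rng):
        cm = ClusterModel(affinity=np.eye(3), eigenvalues=np.zeros(3), k=1,
                          labels=np.zeros(3, dtype=int))
        with pytest.raises(ValueError):
            select_representatives(cm, np.eye(3), C=2, rng=rng)


class TestWeightedMoments:
    def test_uniform_weights_reduce_to_population_moments(self, rng):
        x = rng.standard_normal(50)
        w = np.full(50, 0.02)
        assert weighted_expectation(x, w) == pytest.approx(x.mean())
        assert weighted_variance(x, w) == pytest.approx(x.var())

    def test_indicator_weight_picks_one_member(self):
        w = np.array([0.0, 1.0, 0.0])
        v = np.array([3.0, 7.0, 9.0])
        assert weighted_expectation(v, w) == 7.0
        assert weighted_variance(v, w) == 0.0

    def test_hand_computed_case(self):
        w = np.array([0.2, 0.3, 0.5])
        v = np.array([1.0, 2.0, 4.0])
        assert weighted_expectation(v, w) == pytest.approx(2.8)
        assert weighted_variance(v, w) == pytest.approx(1.56)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            weighted_expectation([1.0, 2.0], [1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=12),
           st.lists(st.floats(0.01, 1.0), min_size=2, max_size=12))
    def test_matches_bruteforce_summation_oracle(self, values, raw_w):
        n = min(len(values), len(raw_w))
        v = np.asarray(values[:n])
        w = np.asarray(raw_w[:n])
        w = w / w.sum()
        e_brute = sum(wi * vi for wi, vi in zip(w, v))
        var_brute = sum(wi * (vi - e_brute) ** 2 for wi, vi in zip(w, v))
        assert weighted_expectation(v, w) == pytest.approx(e_brute, abs=1e-9)
        assert weighted_variance(v, w) == pytest.approx(var_brute, abs=1e-9)


def test_batch_fitness_matches_scalar_fitness(hes1, base_schedule,
                                              initial_dataset, rng):
    src = DirectSource(hes1, base_schedule)
    pts = latin_hypercube(5, hes1.bounds, rng)
    batched = batch_fitness([(src, initial_dataset)], pts)
    for i, p in enumerate(pts):
        preds = src.record_predictions(p[None, :], initial_dataset)[0]
        assert batched[i] == pytest.approx(fitness(preds, initial_dataset))
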