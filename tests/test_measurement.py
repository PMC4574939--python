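"""Hampel filter, distinguishability, Bayes updates, scenario tree."""
import numpy as np
import pytest

from mbdoe.measurement import (MeasurementPair, bayes_update,
                               build_scenario_tree, distinguishability,
                               gaussian_likelihood, hampel_smooth,
                               predicted_outcomes, select_measurement_pair)
from mbdoe.models import NoiseModel


class TestHampel:
    def test_constant_series_unchanged(self):
        x = np.full(9, 3.3)
        assert np.array_equal(hampel_smooth(x), x)

    def test_linear_ramp_unchanged(self):
        x = np.arange(10, dtype=float)
        assert np.array_equal(hampel_smooth(x, window=3), x)

    def test_spike_replaced_by_local_median(self):
        x = np.array([1.0, 1, 1, 100, 1, 1, 1])
        out = hampel_smooth(x, window=3, n_sigma=3)
        assert out[3] == 1.0
        assert np.array_equal(out[[0, 1, 2, 4, 5, 6]], np.ones(6))

    def test_short_series_returned_unchanged(self):
        x = np.array([5.0, -2.0])
        assert np.array_equal(hampel_smooth(x), x)

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            hampel_smooth(np.ones(5), window=0)


class TestDistinguishability:
    def test_identical_outputs_give_zero(self):
        outs = np.ones((4, 2, 10))
        xi = distinguishability(outs, np.full(4, 0.25), NoiseModel(0.1, 0, 0),
                                np.arange(10.0))
        assert np.allclose(xi, 0.0)

    def test_constant_offset_pair_hand_value(self):
        delta, sigma = 2.0, 0.5
        outs = np.stack([np.zeros((1, 8)), np.full((1, 8), delta)])
        xi = distinguishability(outs, np.array([0.5, 0.5]),
                                NoiseModel(sigma, 0, 0), np.arange(8.0))
        assert np.allclose(xi, (delta ** 2 / 4) / sigma ** 2)

    def test_zero_noise_denominator_errors(self):
        outs = np.zeros((2, 1, 5))
        with pytest.raises(ValueError):
            distinguishability(outs, np.array([0.5, 0.5]), NoiseModel(0, 0.1, 0),
                               np.arange(5.0))


class TestSelectPair:
    def test_single_peak_recovered(self):
        xi = np.zeros((1, 10))
        xi[0, 6] = 3.0
        p = select_measurement_pair(xi, np.arange(10.0) * 10, ["m"])
        assert (p.species_index, p.time) == (0, 60.0)

    def test_tie_breaks_to_earlier_time_then_lower_species(self):
        xi = np.zeros((2, 5))
        xi[1, 1] = 5.0
        xi[0, 3] = 5.0
        p = select_measurement_pair(xi, np.arange(5.0))
        assert (p.species_index, p.time_index) == (1, 1)
        xi2 = np.zeros((2, 5))
        xi2[0, 2] = 5.0
        xi2[1, 2] = 5.0
        p2 = select_measurement_pair(xi2, np.arange(5.0))
        assert p2.species_index == 0

    def test_planted_argmax_surface(self, rng):
        xi = rng.uniform(0, 1, size=(3, 31))
        xi[2, 17] = 9.0
        p = select_measurement_pair(xi, np.arange(31.0))
        assert (p.species_index, p.time_index) == (2, 17)

    def test_all_zero_metric_returns_first_pair(self):
        p = select_measurement_pair(np.zeros((2, 4)), np.arange(4.0))
        assert (p.species_index, p.time_index) == (0, 0)


class TestGaussianLikelihood:
    def test_mode_density(self):
        assert gaussian_likelihood(1.0, 1.0, 0.2) == pytest.approx(
            1.0 / np.sqrt(2 * np.pi * 0.04))

    def test_one_sigma_ratio(self):
        mode = gaussian_likelihood(0.0, 0.0, 0.3)
        assert gaussian_likelihood(0.3, 0.0, 0.3) == pytest.approx(
            mode * np.exp(-0.5))

    def test_hand_value(self):
        val = gaussian_likelihood(1.2, 1.0, 0.1)
        assert val == pytest.approx((1 / np.sqrt(2 * np.pi * 0.01)) * np.exp(-2),
                                    rel=1e-6)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            gaussian_likelihood(0.0, 0.0, 0.0)


class TestBayesUpdate:
    def test_flat_likelihood_keeps_prior(self):
        prior = np.array([0.3, 0.7])
        post = bayes_update(prior, 5.0, np.array([5.0, 5.0]), 1.0)
        assert np.allclose(post, prior)

    def test_zero_likelihood_member_excluded(self):
        post = bayes_update(np.array([0.5, 0.5]), 0.0, np.array([0.0, 1e6]), 0.1)
        assert post[0] == pytest.approx(1.0)
        assert post[1] == pytest.approx(0.0)

    def test_hand_computed_ratio(self):
        # likelihood ratio 4:1 from |datum - pred| of 0 vs sd*sqrt(2 ln 4)
        sd = 0.5
        gap = sd * np.sqrt(2 * np.log(4))
        post = bayes_update(np.array([0.5, 0.5]), 0.0, np.array([0.0, gap]), sd)
        assert post[0] == pytest.approx(0.8)
        assert post[1] == pytest.approx(0.2)

    def test_normalization_to_1e12(self, rng):
        prior = rng.dirichlet(np.ones(30))
        post = bayes_update(prior, 0.3, rng.standard_normal(30), 0.4)
        assert abs(post.sum() - 1.0) < 1e-12
        assert np.all(post >= 0)

    def test_log_domain_fallback_for_underflow(self):
        # every density underflows in linear space; the posterior must still
        # prefer the closer representative
        post = bayes_update(np.array([0.5, 0.5]), 0.0,
                            np.array([100.0, 120.0]), 1.0)
        assert post[0] == pytest.approx(1.0)
        assert abs(post.sum() - 1.0) < 1e-12

    def test_conditioning_concentrates_on_generating_member(self, rng):
        """Weight of the data-generating representative tends to 1 as noise
        shrinks."""
        preds = np.linspace(0.0, 9.0, 10)   # distinct predictions
        j = 4
        for sd, target in ((1.0, 0.3), (0.3, 0.9), (0.05, 0.999)):
            w = np.full(10, 0.1)
            for _ in range(3):  # three repeated measurements of the same pair
                datum = preds[j] + 0.01 * sd * rng.standard_normal()
                w = bayes_update(w, datum, preds, sd)
            assert w[j] > target


class TestPredictedOutcomes:
    def test_equal_predictions_collapse(self):
        g = predicted_outcomes(np.full(7, 2.5), np.full(7, 1 / 7))
        assert g == (2.5, 2.5, 2.5)

    def test_ten_point_hand_cdf(self):
        g1, g2, g3 = predicted_outcomes(np.arange(1.0, 11.0), np.full(10, 0.1))
        assert (g1, g2, g3) == (1.0, 5.0, 9.0)

    def test_degenerate_weight(self):
        w = np.zeros(5)
        w[3] = 1.0
        g = predicted_outcomes(np.array([1.0, 2, 3, 4, 5]), w)
        assert g == (4.0, 4.0, 4.0)

    def test_outcomes_are_sorted(self, rng):
        for _ in range(20):
            preds = rng.standard_normal(8)
            w = rng.dirichlet(np.ones(8))
            g1, g2, g3 = predicted_outcomes(preds, w)
            assert g1 <= g2 <= g3


class TestScenarioTree:
    def _toy(self, rng):
        # 6 representatives, 2 species, 8 times; spread grows with time
        t = np.arange(8.0)
        outs = np.empty((6, 2, 8))
        for r in range(6):
            outs[r, 0] = 1.0 + 0.5 * r * t / 7
            outs[r, 1] = 2.0 + 0.1 * np.sin(t + r)
        target = outs[:, :1, :].transpose(0, 2, 1)
        return outs, t, target

    def test_k1_returns_root_only(self, rng):
        outs, t, target = self._toy(rng)
        root, unique = build_scenario_tree(outs, t, np.full(6, 1 / 6), 1,
                                           NoiseModel(0.1, 0.05, 0), target)
        assert len(unique) == 1
        assert root.children == []
        assert root.level == 1

    def test_k4_grows_at_least_two_levels(self, rng):
        outs, t, target = self._toy(rng)
        root, unique = build_scenario_tree(outs, t, np.full(6, 1 / 6), 4,
                                           NoiseModel(0.1, 0.05, 0), target)
        assert len(unique) >= 4
        assert len(root.children) == 3
        levels = {n.level for n in root.children}
        assert levels == {2}

    def test_node_invariants(self, rng):
        outs, t, target = self._toy(rng)
        root, unique = build_scenario_tree(outs, t, np.full(6, 1 / 6), 4,
                                           NoiseModel(0.1, 0.05, 0), target)
        count = [0]

        def walk(n, depth):
            count[0] += 1
            g1, g2, g3 = n.outcomes
            assert g1 <= g2 <= g3
            for w in n.branch_weights:
                assert abs(w.sum() - 1.0) < 1e-9
            for c in n.children:
                walk(c, depth + 1)

        walk(root, 1)
        levels = max(n.level for n in _all_nodes(root))
        # full ternary tree bound: 3^0 + ... + 3^(levels-1)
        assert count[0] <= (3 ** levels - 1) // 2

    def test_unique_pairs_preserve_first_occurrence_order(self, rng):
        outs, t, target = self._toy(rng)
        root, unique = build_scenario_tree(outs, t, np.full(6, 1 / 6), 5,
                                           NoiseModel(0.1, 0.05, 0), target)
        seen = []
        for node in _breadth_first(root):
            if node.pair not in seen:
                seen.append(node.pair)
        assert unique == seen

    def test_invalid_k_rejected(self, rng):
        outs, t, target = self._toy(rng)
        with pytest.raises(ValueError):
            build_scenario_tree(outs, t, np.full(6, 1 / 6), 0,
                                NoiseModel(0.1, 0, 0), target)


def _all_nodes(root):
    out = [root]
    for c in root.children:
        out.extend(_all_nodes(c))
    return out


def _breadth_first(root):
    frontier = [root]
    while frontier:
        nxt = []
        for n in frontier:
            yield n
            nxt.extend(n.children)
        frontier = nxt
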