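"""Measurement selection: distinguishability, Bayes updates, scenario trees.

Informative measurement pairs (species, time) are where the ensemble of
data-consistent dynamics disagrees most relative to the expected
measurement noise.  The distinguishability metric is the Hampel-smoothed
ratio of the probability-weighted output variance to the expected squared
noise; the pair maximizing it is measured.  Because no data exist while
the experiment is still being designed, hypothetical outcomes (weighted
10th/50th/90th percentile predictions) branch a 3-way scenario tree whose
nodes each Bayes-update the representative-parameter weights and select
the next pair under the branch posterior, until K unique pairs are found.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import NoiseModel
from .screening import weighted_expectation, weighted_variance

logger = logging.getLogger(__name__)

__all__ = [
    "MeasurementPair",
    "ScenarioTreeNode",
    "hampel_smooth",
    "distinguishability",
    "select_measurement_pair",
    "gaussian_likelihood",
    "bayes_update",
    "predicted_outcomes",
    "build_scenario_tree",
]


@dataclass(frozen=True)
class MeasurementPair:
    species_index: int
    time: float
    time_index: int
    species: str = ""


# ---------------------------------------------------------------------------
# Hampel identifier
# ---------------------------------------------------------------------------

def hampel_smooth(series, window: int = 3, n_sigma: float = 3.0) -> np.ndarray:
    """Rolling median/MAD outlier filter.

    Points farther than ``n_sigma * 1.4826 * MAD`` from the median of their
    ``[i-window, i+window]`` neighbourhood are replaced by that median;
    everything else passes through.  Series shorter than 3 are returned
    unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        return x.copy()
    out = x.copy()
    for i in range(x.size):
        lo, hi = max(0, i - window), min(x.size, i + window + 1)
        win = x[lo:hi]
        med = np.median(win)
        mad = np.median(np.abs(win - med))
        if abs(x[i] - med) > n_sigma * 1.4826 * mad:
            out[i] = med
    return out


# ---------------------------------------------------------------------------
# Distinguishability
# ---------------------------------------------------------------------------

def _ensemble_moments(outputs: np.ndarray, weights: np.ndarray,
                      noise_model: NoiseModel, times: np.ndarray):
    """Weighted output variance and expected squared noise, both (n_m, T)."""
    var = weighted_variance(outputs, weights)
    rates = np.gradient(outputs, times, axis=2)
    sig2 = weighted_expectation(noise_model.sd(outputs, rates) ** 2, weights)
    return var, sig2


def distinguishability(outputs: np.ndarray, weights, noise_model: NoiseModel,
                       times, hampel_window: int = 3,
                       hampel_n_sigma: float = 3.0) -> np.ndarray:
    """Hampel-smoothed variance-to-noise ratio, per output over the time grid.

    ``outputs`` is ``(R, n_m, T)`` over the representative ensemble.
    """
    outputs = np.asarray(outputs, dtype=float)
    times = np.asarray(times, dtype=float)
    var, sig2 = _ensemble_moments(outputs, np.asarray(weights, float), noise_model, times)
    if np.any(sig2 <= 0):
        raise ValueError("expected squared noise vanishes somewhere; use a "
                         "noise model with zeta_b > 0")
    xi = var / sig2
    for i in range(xi.shape[0]):
        xi[i] = hampel_smooth(xi[i], window=hampel_window, n_sigma=hampel_n_sigma)
    return xi


def select_measurement_pair(xi: np.ndarray, times, species=None) -> MeasurementPair:
    """Global argmax of the metric; ties break to earlier time, lower species."""
    xi = np.asarray(xi, dtype=float)
    times = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(xi)):
        raise ValueError("distinguishability metric must be finite")
    if np.all(xi == 0):
        logger.warning("distinguishability is identically zero: dynamics are "
                       "already resolved; returning the first pair")
        best_i, best_t = 0, 0
    else:
        best = np.max(xi)
        cand = np.argwhere(xi == best)
        # earliest time wins, then lowest species index
        order = np.lexsort((cand[:, 0], cand[:, 1]))
        best_i, best_t = cand[order[0]]
    name = species[best_i] if species is not None else ""
    return MeasurementPair(species_index=int(best_i), time=float(times[best_t]),
                           time_index=int(best_t), species=name)


# ---------------------------------------------------------------------------
# Bayesian weight updates
# ---------------------------------------------------------------------------

def gaussian_likelihood(datum: float, prediction, sd: float):
    """Normal density of the datum at each representative's prediction."""
    if np.any(np.asarray(sd) <= 0):
        raise ValueError("sd must be positive")
    pred = np.asarray(prediction, dtype=float)
    return np.exp(-((datum - pred) ** 2) / (2.0 * sd ** 2)) / np.sqrt(2 * np.pi * sd ** 2)


def bayes_update(prior, datum: float, predictions, sd: float) -> np.ndarray:
    """Posterior over representatives: likelihood x prior, renormalized.

    Falls back to a log-domain computation when all densities underflow;
    if the posterior is still degenerate the prior is kept (with a warning).
    """
    prior = np.asarray(prior, dtype=float)
    pred = np.asarray(predictions, dtype=float)
    like = gaussian_likelihood(datum, pred, sd)
    post = like * prior
    total = post.sum()
    if total > 0 and np.isfinite(total):
        return post / total
    loglike = -((datum - pred) ** 2) / (2.0 * sd ** 2)
    with np.errstate(divide="ignore"):
        logpost = loglike + np.log(prior)
    if np.all(~np.isfinite(logpost)):
        logger.warning("degenerate Bayes update; keeping prior")
        return prior.copy()
    logpost -= np.max(logpost[np.isfinite(logpost)])
    post = np.where(np.isfinite(logpost), np.exp(logpost), 0.0)
    return post / post.sum()


def predicted_outcomes(predictions, weights) -> tuple[float, float, float]:
    """Weighted 10th/50th/90th percentile predictions (>=-threshold CDF)."""
    pred = np.asarray(predictions, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(pred, kind="stable")
    p_sorted, w_sorted = pred[order], w[order]
    cum = np.cumsum(w_sorted)
    out = []
    for q in (0.10, 0.50, 0.90):
        idx = int(np.searchsorted(cum, q - 1e-12, side="left"))
        out.append(float(p_sorted[min(idx, p_sorted.size - 1)]))
    return tuple(out)


# ---------------------------------------------------------------------------
# Scenario tree
# ---------------------------------------------------------------------------

@dataclass
class ScenarioTreeNode:
    pair: MeasurementPair
    xi: float
    gamma: float
    outcomes: tuple[float, float, float]   # G1 <= G2 <= G3
    prior_weights: np.ndarray
    level: int
    children: list = field(default_factory=list)
    branch_weights: list = field(default_factory=list)  # posterior per branch

    def to_dict(self) -> dict:
        return {
            "species": self.pair.species or str(self.pair.species_index),
            "time": self.pair.time,
            "xi": self.xi,
            "gamma": self.gamma,
            "G1": self.outcomes[0], "G2": self.outcomes[1], "G3": self.outcomes[2],
            "level": self.level,
            "branch_weights": [w.tolist() for w in self.branch_weights],
            "children": [c.to_dict() for c in self.children],
        }


def _node_pair(outputs, weights, noise_model, times, target_states, dense_times,
               species, top_m, hampel_window, hampel_n_sigma, exclude=()):
    """Pick the pair: among the top-ranked by distinguishability, the one whose
    predicted (median-outcome) Bayes update minimizes the target uncertainty.

    Pairs already measured on this branch's root path (``exclude``) are
    skipped so the tree keeps proposing new measurements; if every pair is
    excluded, repeats become admissible again.
    """
    from .input_design import tdu  # runtime import to avoid an import cycle

    xi = distinguishability(outputs, weights, noise_model, times,
                            hampel_window, hampel_n_sigma)
    var, sig2 = _ensemble_moments(outputs, np.asarray(weights, float),
                                  noise_model, np.asarray(times, float))
    flat = xi.ravel()
    order = np.argsort(-flat, kind="stable")
    if exclude:
        ex_flat = {si * xi.shape[1] + ti for si, ti in exclude}
        kept = [fl for fl in order if fl not in ex_flat]
        order = np.asarray(kept if kept else order)
    order = order[:top_m]
    best = None
    for rank, fl in enumerate(order):
        si, ti = np.unravel_index(fl, xi.shape)
        preds = outputs[:, si, ti]
        g1, g2, g3 = predicted_outcomes(preds, weights)
        sd = math.sqrt(sig2[si, ti])
        post = bayes_update(weights, g2, preds, sd)
        gamma = tdu(target_states, post)
        if best is None or gamma < best[0] - 1e-15:
            best = (gamma, si, ti, xi[si, ti])
    gamma, si, ti, xv = best
    name = species[si] if species is not None else ""
    pair = MeasurementPair(species_index=int(si), time=float(times[ti]),
                           time_index=int(ti), species=name)
    return pair, float(xv), float(gamma)


def build_scenario_tree(outputs: np.ndarray, times, weights, K: int,
                        noise_model: NoiseModel, target_states: np.ndarray,
                        species=None, top_m: int = 5, hampel_window: int = 3,
                        hampel_n_sigma: float = 3.0, max_levels: int = 12
                        ) -> tuple[ScenarioTreeNode, list[MeasurementPair]]:
    """Breadth-first 3-branch scenario tree until >= K unique pairs.

    ``outputs``: (R, n_m, T) representative predictions under the designed
    input on the sampling grid; ``target_states``: (R, T_dense, n_targets)
    under the target input, used for the per-node uncertainty value.
    Returns the root node and the unique measurement list in first-occurrence
    (breadth-first) order.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    outputs = np.asarray(outputs, dtype=float)
    times = np.asarray(times, dtype=float)
    w0 = np.asarray(weights, dtype=float)

    def make_node(w, level, exclude=()):
        pair, xv, gamma = _node_pair(outputs, w, noise_model, times,
                                     target_states, None, species, top_m,
                                     hampel_window, hampel_n_sigma, exclude)
        preds = outputs[:, pair.species_index, pair.time_index]
        outcomes = predicted_outcomes(preds, w)
        node = ScenarioTreeNode(pair=pair, xi=xv, gamma=gamma,
                                outcomes=outcomes, prior_weights=w, level=level)
        node._path = tuple(exclude) + ((pair.species_index, pair.time_index),)
        return node

    root = make_node(w0, 1)
    unique: list[MeasurementPair] = [root.pair]
    frontier = [root]
    level = 1
    stale_levels = 0
    while len(unique) < K:
        if level >= max_levels:
            logger.warning("scenario tree hit the level cap with %d unique "
                           "pairs (wanted %d)", len(unique), K)
            break
        new_frontier = []
        added = 0
        for node in frontier:
            preds = outputs[:, node.pair.species_index, node.pair.time_index]
            sd = math.sqrt(_ensemble_moments(
                outputs, node.prior_weights, noise_model, times
            )[1][node.pair.species_index, node.pair.time_index])
            for g in node.outcomes:
                post = bayes_update(node.prior_weights, g, preds, sd)
                child = make_node(post, level + 1, exclude=node._path)
                node.children.append(child)
                node.branch_weights.append(post)
                new_frontier.append(child)
                if child.pair not in unique:
                    unique.append(child.pair)
                    added += 1
        level += 1
        frontier = new_frontier
        if added == 0:
            stale_levels += 1
            if stale_levels >= 2:
                logger.warning("scenario tree exhausted distinct pairs with %d "
                               "unique (wanted %d)", len(unique), K)
                break
        else:
            stale_levels = 0
        if not frontier:
            break
    return root, unique


def tree_to_json(root: ScenarioTreeNode) -> str:
    return json.dumps(root.to_dict(), indent=2)


def measurements_to_frame(root: ScenarioTreeNode,
                          unique: list[MeasurementPair]) -> pd.DataFrame:
    """Measurement plan table: time, action, scenario-tree level."""
    level_of: dict[MeasurementPair, int] = {}

    def walk(node):
        level_of.setdefault(node.pair, node.level)
        for c in node.children:
            walk(c)

    walk(root)
    rows = [{"time_min": p.time,
             "action": f"Measure {p.species or p.species_index}",
             "tree_level": level_of.get(p, 0)} for p in unique]
    return pd.DataFrame(rows).sort_values("time_min").reset_index(drop=True)
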