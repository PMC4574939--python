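"""Greedy control-vector-parameterization input design.

The stimulus is piecewise constant over user-fixed admissible times; its
magnitudes are chosen to minimize the target-state dynamical uncertainty
(TDU): the sum over target states of the time-maximum probability-weighted
variance of their trajectories under the target input.  Each greedy
iteration scores, for every not-yet-optimized admissible time and every
discrete input level, the TDU that would remain after the single most
informative measurement under that candidate input is (hypothetically)
taken and used to Bayes-update the representative-parameter weights; the
best (time, level) is accepted, spliced into the schedule up to the next
previously optimized time, and the search repeats until no change improves
the TDU or every admissible time is optimized.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import DynamicalModel, InputSchedule, IntegrationFailure, NoiseModel, simulate
from .measurement import (_ensemble_moments, bayes_update, distinguishability,
                          predicted_outcomes, select_measurement_pair)
from .screening import weighted_variance
from .sparse_grid import build_cheb_interpolant_1d, node_count

logger = logging.getLogger(__name__)

__all__ = [
    "DesignState",
    "CandidateEvaluation",
    "num_input_levels",
    "input_levels",
    "tdu",
    "evaluate_input_candidate",
    "greedy_input_search",
    "simulation_budget_bound",
]


def num_input_levels(u_min: float, u_max: float, du: float) -> int:
    """N_u = floor((u_max - u_min)/du) + 1 discrete magnitudes per input."""
    if du <= 0:
        raise ValueError("du must be positive")
    if u_max <= u_min:
        raise ValueError("u_max must exceed u_min")
    if du > u_max - u_min:
        logger.warning("input resolution %g exceeds the input range; a single "
                       "level remains", du)
        return 1
    return int(math.floor((u_max - u_min) / du + 1e-9)) + 1


def input_levels(u_min: float, u_max: float, du: float) -> np.ndarray:
    n = num_input_levels(u_min, u_max, du)
    return u_min + np.arange(n) * du


def tdu(target_states: np.ndarray, weights) -> float:
    """Sum over target states of the time-max weighted trajectory variance.

    ``target_states`` is ``(R, T, n_targets)`` over the representative
    ensemble under the target input.
    """
    ts = np.asarray(target_states, dtype=float)
    if ts.ndim == 2:
        ts = ts[:, :, None]
    if ts.shape[2] == 0:
        raise ValueError("empty target-state set")
    var = weighted_variance(ts, weights)          # (T, n_targets)
    return float(var.max(axis=0).sum())


def simulation_budget_bound(SG_theta: int, N_A: int, N_u: int, SG_u: int,
                            N_RA: int, N: int) -> int:
    """Closed-form upper bound on the pipeline's total model simulations."""
    return int(SG_theta + N_A + min(N_u, SG_u) * N_RA * (N * (N + 1)) // 2 + N_RA)


# ---------------------------------------------------------------------------
# Candidate evaluation
# ---------------------------------------------------------------------------

@dataclass
class CandidateEvaluation:
    tau: float
    input_dim: int
    level_index: int           # p, 1-based as in u_j^p = u_min + (p-1) du
    level_value: float
    pair: object
    tdu_value: float
    posterior_weights: np.ndarray


@dataclass
class DesignState:
    schedule: InputSchedule
    optimized_times: list[float]
    remaining_times: list[float]
    weights: np.ndarray
    tdu_history: list[dict] = field(default_factory=list)
    current_tdu: float = np.inf

    def trace_frame(self) -> pd.DataFrame:
        rows = [{"iteration": h["iteration"], "min_TDU": h["tdu"],
                 "tau_star": h["tau"], "u_star": h["level"],
                 "levels": " ".join(f"{v:g}" for v in h["schedule_levels"])}
                for h in self.tdu_history]
        return pd.DataFrame(rows)


def evaluate_input_candidate(outputs: np.ndarray, sampling_times, weights,
                             noise_model: NoiseModel, target_states,
                             tau: float, input_dim: int, level_index: int,
                             level_value: float, hampel_window: int = 3,
                             hampel_n_sigma: float = 3.0,
                             species=None) -> CandidateEvaluation:
    """Score one (admissible time, input level) candidate.

    ``outputs``: (R, n_m, T) representative measurable outputs simulated (or
    interpolated) under the candidate schedule.  The single most
    distinguishing measurement pair is chosen, its datum predicted as the
    weighted median outcome, the weights Bayes-updated on a copy, and the
    TDU recomputed from the (fixed) target trajectories with those weights.
    """
    w = np.asarray(weights, dtype=float)
    xi = distinguishability(outputs, w, noise_model, sampling_times,
                            hampel_window, hampel_n_sigma)
    pair = select_measurement_pair(xi, sampling_times, species)
    preds = outputs[:, pair.species_index, pair.time_index]
    _, sig2 = _ensemble_moments(outputs, w, noise_model,
                                np.asarray(sampling_times, float))
    sd = math.sqrt(sig2[pair.species_index, pair.time_index])
    _, g2, _ = predicted_outcomes(preds, w)
    post = bayes_update(w, g2, preds, sd)
    val = tdu(target_states, post)
    return CandidateEvaluation(tau=tau, input_dim=input_dim,
                               level_index=level_index, level_value=level_value,
                               pair=pair, tdu_value=val, posterior_weights=post)


def _candidate_output_bank(model: DynamicalModel, rep_params: np.ndarray,
                           schedule: InputSchedule, tau: float, tau_prime: float,
                           dim: int, levels: np.ndarray, sampling_times: np.ndarray,
                           grid_max_depth: int, counter=None) -> np.ndarray:
    """(n_levels, R, n_m, T) outputs under the spliced candidate schedules.

    When the number of candidate levels exceeds the predicted 1-D grid node
    count, a per-representative adaptive Chebyshev-polynomial interpolant
    over the input magnitude is built and sampled at every level; otherwise
    levels are simulated directly.
    """
    R = rep_params.shape[0]
    n_m = model.n_m
    T = sampling_times.size
    n_lev = levels.size
    lo, hi = float(levels.min()), float(levels.max())
    sg_u_pred = node_count(grid_max_depth, 1)
    bank = np.empty((n_lev, R, n_m, T))
    use_grid = n_lev > sg_u_pred and hi > lo
    for r in range(R):
        theta_r = rep_params[r]

        def outputs_for(v: float) -> np.ndarray:
            sched = schedule.spliced(tau, tau_prime, v, input_dim=dim)
            tr = simulate(model, theta_r, sched, sampling_times)
            if counter is not None:
                counter.add(1)
            return tr.outputs.T  # (n_m, T)

        if use_grid:
            try:
                interp = build_cheb_interpolant_1d(
                    lambda v: outputs_for(float(np.ravel(v)[0])).ravel(),
                    lo, hi, max_depth=grid_max_depth)
                bank[:, r] = interp.evaluate(levels).reshape(n_lev, n_m, T)
            except IntegrationFailure as exc:
                logger.warning("input grid failed (tau=%g, rep %d): %s",
                               tau, r, exc)
                bank[:, r] = np.nan
        else:
            for li, v in enumerate(levels):
                try:
                    bank[li, r] = outputs_for(float(v))
                except IntegrationFailure as exc:
                    logger.warning("candidate simulation failed (tau=%g, u=%g, "
                                   "rep %d): %s", tau, v, r, exc)
                    bank[li, r] = np.nan
    return bank


def greedy_input_search(model: DynamicalModel, rep_params: np.ndarray,
                        weights, base_schedule: InputSchedule,
                        target_states: np.ndarray, sampling_times,
                        noise_model: NoiseModel, input_bounds,
                        input_resolution, grid_max_depth: int = 3,
                        hampel_window: int = 3, hampel_n_sigma: float = 3.0,
                        species=None, counter=None) -> DesignState:
    """Greedy minimization of TDU over (admissible time, input level) choices.

    Ties in the argmin break toward the smaller admissible time, then the
    smaller level index, for deterministic reproducibility.  Every candidate
    is scored as "prior weights + the single best hypothetical measurement
    under this input": the Bayes update happens on a fresh copy each time
    and never accumulates across iterations, so the TDU trace reflects how
    much one optimally placed measurement would resolve under each input.
    """
    rep_params = np.atleast_2d(np.asarray(rep_params, dtype=float))
    sampling_times = np.asarray(sampling_times, dtype=float)
    input_bounds = np.atleast_2d(np.asarray(input_bounds, dtype=float))  # (n_u, 2)
    input_resolution = np.atleast_1d(np.asarray(input_resolution, dtype=float))
    t_f = model.t_span[1]

    state = DesignState(
        schedule=base_schedule,
        optimized_times=[],
        remaining_times=[float(t) for t in base_schedule.times],
        weights=np.asarray(weights, dtype=float).copy(),
        current_tdu=tdu(target_states, weights),
    )
    state.tdu_history.append({"iteration": 0, "tau": None, "level": None,
                              "tdu": state.current_tdu,
                              "schedule_levels": base_schedule.levels[:, 0].tolist()})

    iteration = 0
    while state.remaining_times:
        iteration += 1
        best: CandidateEvaluation | None = None
        for tau in sorted(state.remaining_times):
            later = [t for t in state.optimized_times if t > tau]
            tau_prime = min(later) if later else t_f
            for dim in range(base_schedule.n_u):
                u_min, u_max = input_bounds[dim]
                levels = input_levels(u_min, u_max, input_resolution[dim])
                bank = _candidate_output_bank(
                    model, rep_params, state.schedule, tau, tau_prime, dim,
                    levels, sampling_times, grid_max_depth, counter)
                for p, v in enumerate(levels, start=1):
                    outs = bank[p - 1]
                    ok = np.all(np.isfinite(outs), axis=(1, 2))
                    if not ok.all():
                        if not ok.any():
                            logger.warning("all simulations failed for "
                                           "candidate tau=%g level=%g", tau, v)
                            continue
                        outs = outs[ok]
                        w_ok = state.weights[ok] / state.weights[ok].sum()
                    else:
                        w_ok = state.weights
                    cand = evaluate_input_candidate(
                        outs, sampling_times, w_ok, noise_model, target_states
                        if ok.all() else target_states[ok],
                        tau, dim, p, float(v), hampel_window, hampel_n_sigma,
                        species)
                    if best is None or cand.tdu_value < best.tdu_value:
                        best = cand
        if best is None or best.tdu_value >= state.current_tdu:
            logger.info("greedy search stops at iteration %d: no candidate "
                        "improves TDU", iteration)
            break
        # accept: splice the level in and persist the associated Bayes update
        later = [t for t in state.optimized_times if t > best.tau]
        tau_prime = min(later) if later else t_f
        state.schedule = state.schedule.spliced(best.tau, tau_prime,
                                                best.level_value,
                                                input_dim=best.input_dim)
        state.optimized_times.append(best.tau)
        state.remaining_times.remove(best.tau)
        state.current_tdu = best.tdu_value
        state.tdu_history.append({
            "iteration": iteration, "tau": best.tau, "level": best.level_value,
            "tdu": best.tdu_value,
            "schedule_levels": state.schedule.levels[:, 0].tolist()})
        logger.info("greedy iteration %d: tau*=%g u*=%g TDU=%g", iteration,
                    best.tau, best.level_value, best.tdu_value)
    return state
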