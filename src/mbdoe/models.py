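"""Uncertain ODE models, piecewise-constant inputs, and the in-silico plant.

The design problem is posed for a nonlinear ODE system

    dx/dt = f(x, u, theta, theta', t),    x(T_I) = x0
    y     = h(x, u, theta, theta', t)

where ``theta`` are known parameters, ``theta'`` are unknown parameters
confined to a box ``Omega``, ``u`` is an exogenous piecewise-constant input
(control vector parameterization), and ``y`` are the experimentally
measurable outputs.  This module holds the model container, the input
schedule representation, trajectory simulation, the measurement-noise
model, and a synthetic "plant" that generates noisy data from a fully
specified parameterization.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

logger = logging.getLogger(__name__)

__all__ = [
    "DynamicalModel",
    "InputSchedule",
    "TargetSystem",
    "Trajectory",
    "Dataset",
    "NoiseModel",
    "IntegrationFailure",
    "simulate",
    "hes1_rhs",
    "hes1_model",
    "expected_noise",
    "generate_plant_data",
    "get_model",
    "register_model",
    "MODEL_REGISTRY",
]


class IntegrationFailure(RuntimeError):
    """Raised when the stiff ODE solver fails to converge on a segment.

    Ensemble-level callers catch this, log a warning, and exclude the
    trajectory; it never silently propagates NaNs.
    """


# ---------------------------------------------------------------------------
# Input schedules (control vector parameterization)
# ---------------------------------------------------------------------------

@dataclass
class InputSchedule:
    """Piecewise-constant input over a set of admissible switch times.

    Parameters
    ----------
    times : array, shape (N,)
        Strictly increasing admissible times ``tau_1 .. tau_N`` (minutes).
    levels : array, shape (N, n_u)
        Input magnitude applied from ``tau_j`` (inclusive) to ``tau_{j+1}``
        (exclusive); the last segment extends to the end of the simulation.
        Segments are half-open so evaluation at a switch time is unambiguous.
    base : array, shape (n_u,)
        Level applied before ``tau_1`` (relevant only when ``tau_1 > T_I``).
    bounds : array, shape (2, n_u), optional
        Per-input ``[u_min, u_max]``; levels are validated against it.
    resolution : array, shape (n_u,), optional
        Input magnitude resolution ``delta_u`` per input dimension.
    """

    times: np.ndarray
    levels: np.ndarray
    base: np.ndarray
    bounds: np.ndarray | None = None
    resolution: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim == 1:
            self.levels = self.levels[:, None]
        self.base = np.atleast_1d(np.asarray(self.base, dtype=float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("admissible times must be strictly increasing")
        if self.levels.shape[0] != self.times.size:
            raise ValueError("need one level row per admissible time")
        if self.bounds is not None:
            self.bounds = np.asarray(self.bounds, dtype=float)
            lo, hi = self.bounds
            if np.any(self.levels < lo - 1e-12) or np.any(self.levels > hi + 1e-12):
                raise ValueError("schedule levels outside input bounds")

    @property
    def n_u(self) -> int:
        return self.levels.shape[1]

    def value(self, t) -> np.ndarray:
        """Right-continuous evaluation: level of the segment containing ``t``."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        scalar = t.ndim == 0
        idx = np.atleast_1d(idx)
        out = np.empty((idx.size, self.n_u))
        before = idx < 0
        out[before] = self.base
        out[~before] = self.levels[idx[~before]]
        return out[0] if scalar else out

    def segments(self, t_span: Sequence[float]) -> list[tuple[float, float, np.ndarray]]:
        """Constant-level segments ``(t0, t1, level)`` covering ``t_span``.

        Adjacent segments with identical levels are merged, so schedules that
        differ only by redundant switch points integrate identically.
        """
        t_i, t_f = float(t_span[0]), float(t_span[1])
        edges = [t_i] + [float(t) for t in self.times if t_i < t < t_f] + [t_f]
        segs: list[tuple[float, float, np.ndarray]] = []
        for a, b in zip(edges[:-1], edges[1:]):
            level = self.value(a)
            if segs and np.array_equal(segs[-1][2], level):
                segs[-1] = (segs[-1][0], b, segs[-1][2])
            else:
                segs.append((a, b, level))
        return segs

    def with_levels(self, new_levels: np.ndarray) -> "InputSchedule":
        return replace(self, levels=np.asarray(new_levels, dtype=float).reshape(self.levels.shape))

    def spliced(self, tau_j: float, tau_prime: float, level: np.ndarray,
                input_dim: int | None = None) -> "InputSchedule":
        """Overwrite levels for all admissible segments in ``[tau_j, tau_prime)``.

        When ``input_dim`` is given only that input component changes; the
        greedy search varies one input dimension at a time.
        """
        new = self.levels.copy()
        mask = (self.times >= tau_j - 1e-12) & (self.times < tau_prime - 1e-12)
        if input_dim is None:
            new[mask] = np.asarray(level, dtype=float)
        else:
            new[mask, input_dim] = float(np.asarray(level).ravel()[0])
        return replace(self, levels=new)

    def to_json(self) -> str:
        return json.dumps({
            "times": self.times.tolist(),
            "levels": self.levels.tolist(),
            "base": self.base.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "InputSchedule":
        d = json.loads(text)
        return cls(times=np.asarray(d["times"]), levels=np.asarray(d["levels"]),
                   base=np.asarray(d["base"]))

    @classmethod
    def constant(cls, times, level, n_u: int = 1, **kw) -> "InputSchedule":
        times = np.atleast_1d(np.asarray(times, dtype=float))
        lev = np.full((times.size, n_u), float(level))
        return cls(times=times, levels=lev, base=np.full(n_u, float(level)), **kw)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class DynamicalModel:
    """An uncertain ODE model with a known/unknown parameter split.

    ``rhs(x, u, theta, theta_p, t)`` returns the state derivative and
    ``output_map(states, u, theta, theta_p, times)`` maps a ``(T, n_x)``
    state matrix (with the input evaluated at each time) to the ``(T, n_m)``
    measurable outputs.  Both must be deterministic.
    """

    name: str
    state_names: list[str]
    output_names: list[str]
    rhs: Callable
    output_map: Callable
    x0: np.ndarray
    known_params: dict[str, float]
    unknown_names: list[str]
    bounds: np.ndarray            # (n_p', 2) box Omega
    t_span: tuple[float, float]
    nominal_unknowns: np.ndarray | None = None

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, dtype=float)
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.bounds.shape != (len(self.unknown_names), 2):
            raise ValueError("bounds must be (n_p', 2)")
        if not np.all(np.isfinite(self.bounds)):
            raise ValueError("parameter bounds must be finite")
        if np.any(self.bounds[:, 0] >= self.bounds[:, 1]):
            raise ValueError("each bound must satisfy low < high")

    @property
    def n_x(self) -> int:
        return len(self.state_names)

    @property
    def n_m(self) -> int:
        return len(self.output_names)

    @property
    def n_unknown(self) -> int:
        return len(self.unknown_names)

    def outputs_of(self, traj_states: np.ndarray, schedule: InputSchedule,
                   unknowns: np.ndarray, times: np.ndarray) -> np.ndarray:
        u = schedule.value(times)
        return np.asarray(self.output_map(traj_states, u, self.known_params,
                                          np.asarray(unknowns, dtype=float), times))


@dataclass
class TargetSystem:
    """Target states (by index) whose trajectory uncertainty the design shrinks,
    observed under a fixed target input schedule."""

    target_state_indices: list[int]
    target_schedule: InputSchedule

    def validate(self, model: DynamicalModel) -> None:
        for i in self.target_state_indices:
            if not 0 <= i < model.n_x:
                raise ValueError(f"target state index {i} out of range")


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray   # (T, n_x)
    outputs: np.ndarray  # (T, n_m)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_ODE_RTOL = 1e-6
_ODE_ATOL = 1e-8


def simulate(model: DynamicalModel, unknowns, schedule: InputSchedule,
             times) -> Trajectory:
    """Integrate the model under a piecewise-constant schedule.

    The stiff-capable LSODA integrator is restarted at every input switch
    time with the post-switch level, so input discontinuities are never
    stepped across.  Raises :class:`IntegrationFailure` on solver
    non-convergence or non-finite states.
    """
    unknowns = np.asarray(unknowns, dtype=float)
    times = np.asarray(times, dtype=float)
    lo, hi = model.bounds[:, 0], model.bounds[:, 1]
    if np.any(unknowns < lo) or np.any(unknowns > hi):
        logger.warning("parameters outside Omega for model %s; simulating anyway",
                       model.name)
    t_i, t_f = model.t_span
    if times.size and (times[0] < t_i - 1e-9 or times[-1] > t_f + 1e-9):
        raise ValueError("evaluation times outside the model t_span")

    theta = model.known_params
    states = np.empty((times.size, model.n_x))
    x = model.x0.copy()
    for t0, t1, level in schedule.segments(model.t_span):
        mask = (times >= t0) & (times < t1)
        if t1 >= t_f:  # last segment is closed at T_F
            mask = (times >= t0) & (times <= t1)
        seg_times = times[mask]
        grid = np.unique(np.concatenate(([t0], seg_times, [t1])))
        if grid.size < 2:
            grid = np.array([t0, t1])

        def f(xv, t, _lev=level):
            return model.rhs(xv, _lev, theta, unknowns, t)

        sol, info = odeint(f, x, grid, rtol=_ODE_RTOL, atol=_ODE_ATOL,
                           full_output=True, mxstep=5000)
        if info["message"] != "Integration successful." or not np.all(np.isfinite(sol)):
            raise IntegrationFailure(
                f"LSODA failed on [{t0}, {t1}] for model {model.name}: "
                f"{info['message']}")
        if seg_times.size:
            idx = np.searchsorted(grid, seg_times)
            states[mask] = sol[idx]
        x = sol[-1]
    outputs = model.outputs_of(states, schedule, unknowns, times)
    return Trajectory(times=times, states=states, outputs=outputs)


def simulate_ensemble(model: DynamicalModel, params: np.ndarray,
                      schedule: InputSchedule, times) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate every parameter row; failed rows are dropped with a warning.

    Returns ``(ok_mask, states, outputs)`` where the arrays stack only the
    successful rows, in order.
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    ok = np.ones(params.shape[0], dtype=bool)
    st, out = [], []
    for r, p in enumerate(params):
        try:
            tr = simulate(model, p, schedule, times)
        except IntegrationFailure as exc:
            logger.warning("dropping ensemble member %d: %s", r, exc)
            ok[r] = False
            continue
        st.append(tr.states)
        out.append(tr.outputs)
    return ok, np.asarray(st), np.asarray(out)


# ---------------------------------------------------------------------------
# Measurement noise model
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Expected-measurement-noise model: sd = zeta_b + zeta_s*|y| + zeta_t*|dy/dt|.

    ``zeta_b`` is a baseline floor in output units, ``zeta_s`` a fractional
    signal coefficient, and ``zeta_t`` (minutes) scales the output's time
    derivative — fast transients are assumed harder to measure precisely.
    """

    zeta_b: float = 0.05
    zeta_s: float = 0.1
    zeta_t: float = 0.01

    def __post_init__(self):
        if self.zeta_b < 0 or self.zeta_s < 0 or self.zeta_t < 0:
            raise ValueError("noise coefficients must be non-negative")

    def sd(self, y, y_rate):
        return self.zeta_b + self.zeta_s * np.abs(y) + self.zeta_t * np.abs(y_rate)


def expected_noise(y_value, y_rate, nm: NoiseModel):
    """Pointwise expected measurement sd; errors out if it is not positive."""
    sd = nm.sd(np.asarray(y_value, dtype=float), np.asarray(y_rate, dtype=float))
    if np.any(sd <= 0):
        raise ValueError("expected noise is zero (all coefficients and signals "
                         "vanish); a positive zeta_b avoids division by zero "
                         "in the distinguishability metric")
    return sd


# ---------------------------------------------------------------------------
# Datasets and the in-silico plant
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Experimental records: (output_id, time_min, mean, sd, schedule_id)."""

    frame: pd.DataFrame
    n_replicates: int = 3

    COLUMNS = ["output_id", "time_min", "mean", "sd", "schedule_id"]

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        if np.any(self.frame["sd"].to_numpy() <= 0):
            raise ValueError("every dataset record needs sd > 0")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def for_schedule(self, schedule_id: str) -> "Dataset":
        return Dataset(self.frame[self.frame["schedule_id"] == schedule_id],
                       self.n_replicates)

    @property
    def schedule_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["schedule_id"]))

    def output_indices(self, model: DynamicalModel) -> np.ndarray:
        name_to_idx = {n: i for i, n in enumerate(model.output_names)}
        return np.array([name_to_idx[o] for o in self.frame["output_id"]])

    def concat(self, other: "Dataset") -> "Dataset":
        return Dataset(pd.concat([self.frame, other.frame], ignore_index=True),
                       self.n_replicates)

    def to_csv(self, path) -> None:
        self.frame[self.COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_replicates: int = 3) -> "Dataset":
        return cls(pd.read_csv(path), n_replicates)


def generate_plant_data(model: DynamicalModel, nominal_unknowns, schedule: InputSchedule,
                        points: Sequence[tuple[str, float]], noise_frac: float,
                        n_replicates: int = 3, seed=None,
                        schedule_id: str = "plant") -> Dataset:
    """Noisy data from the in-silico plant at the requested (output, time) points.

    Replicates are drawn from ``Normal(y_true, noise_frac * |y_true|)``; the
    dataset stores their empirical mean and standard deviation.  A floor of
    ``1e-6 * max |output|`` keeps the sd positive for zero-noise or
    zero-signal points.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    rng = np.random.default_rng(seed)
    times = np.unique([t for _, t in points])
    traj = simulate(model, nominal_unknowns, schedule, times)
    name_to_idx = {n: i for i, n in enumerate(model.output_names)}
    floor = 1e-6 * max(np.max(np.abs(traj.outputs)), 1.0)
    rows = []
    for out_name, t in points:
        ti = int(np.searchsorted(times, t))
        y_true = traj.outputs[ti, name_to_idx[out_name]]
        reps = y_true + noise_frac * abs(y_true) * rng.standard_normal(n_replicates)
        sd = float(np.std(reps, ddof=1)) if n_replicates > 1 else 0.0
        rows.append({"output_id": out_name, "time_min": float(t),
                     "mean": float(np.mean(reps)), "sd": max(sd, floor),
                     "schedule_id": schedule_id})
    return Dataset(pd.DataFrame(rows), n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# Bundled Hes1 oscillator model
# ---------------------------------------------------------------------------

def hes1_rhs(state, alpha, params):
    """Hes1 negative-feedback oscillator right-hand side.

    States are Hes1 mRNA ``m``, cytosolic protein ``P1`` and nuclear protein
    ``P2``; ``params = (k, k1, P0, h, nu)``.  The stimulus ``alpha`` scales
    the protein transport rate ``k1``:

        dm/dt  = -k*m  + 1 / (1 + (P2/P0)**h)
        dP1/dt = -k*P1 + nu*m - alpha*k1*P1
        dP2/dt = -k*P2 + alpha*k1*P1
    """
    m, P1, P2 = state
    k, k1, P0, h, nu = params
    transcription = 1.0 / (1.0 + (P2 / P0) ** h)
    return (-k * m + transcription,
            -k * P1 + nu * m - alpha * k1 * P1,
            -k * P2 + alpha * k1 * P1)


_HES1_NOMINAL = {"k": 0.03, "k1": 0.16, "P0": 2.4, "h": 2.0, "nu": 0.025}


def hes1_model(x0=(2.0, 5.0, 3.0), t_span=(0.0, 300.0),
               bounds_scale=(0.1, 10.0)) -> DynamicalModel:
    """The bundled 3-state Hes1 model.

    ``P0`` (repression threshold), ``h`` (Hill coefficient) and ``nu``
    (translation rate) are unknown with box bounds ``bounds_scale`` times
    their nominal values; the degradation rate ``k`` and transport rate
    ``k1`` are known.  The initial condition defaults to
    ``(m, P1, P2) = (2, 5, 3)`` — uncertainty-reduction percentages are
    conditional on this choice, which is configurable.
    """
    nom = _HES1_NOMINAL

    def rhs(x, u, theta, theta_p, t):
        alpha = float(np.asarray(u).ravel()[0])
        P0, h, nu = theta_p
        return hes1_rhs(x, alpha, (theta["k"], theta["k1"], P0, h, nu))

    def output_map(states, u, theta, theta_p, times):
        states = np.atleast_2d(states)
        return np.column_stack([states[:, 0], states[:, 1] + states[:, 2]])

    unknown = ["P0", "h", "nu"]
    nominal = np.array([nom[p] for p in unknown])
    bounds = np.column_stack([nominal * bounds_scale[0], nominal * bounds_scale[1]])
    return DynamicalModel(
        name="hes1",
        state_names=["m", "P1", "P2"],
        output_names=["m", "P1+P2"],
        rhs=rhs,
        output_map=output_map,
        x0=np.asarray(x0, dtype=float),
        known_params={"k": nom["k"], "k1": nom["k1"]},
        unknown_names=unknown,
        bounds=bounds,
        t_span=(float(t_span[0]), float(t_span[1])),
        nominal_unknowns=nominal,
    )


MODEL_REGISTRY: dict[str, Callable[..., DynamicalModel]] = {"hes1": hes1_model}


def register_model(name: str, factory: Callable[..., DynamicalModel]) -> None:
    MODEL_REGISTRY[name] = factory


def get_model(name: str, **overrides) -> DynamicalModel:
    try:
        factory = MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model '{name}'; registered: "
                       f"{sorted(MODEL_REGISTRY)}") from None
    return factory(**overrides)
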