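"""Data-consistent parameter screening and representative selection.

A parameter vector is *acceptable* when the log-transformed weighted
least-squares misfit of its simulated outputs against the data stays below
the threshold ``T_A``:

    fitness(theta') = log10(1 + sum_records ((y_model - y_data)/sd)^2) <= T_A

Acceptable parameters are found by Latin-hypercube sampling of the box
Omega, with model outputs supplied by a sparse-grid trajectory surrogate
(or direct simulation).  Their trajectories are then grouped by spectral
clustering into experimentally distinguishable dynamics, and a small set
of *representative* parameters is drawn from the convex hull of each
cluster; uniform probability weights over the representatives seed the
Bayesian updates used downstream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import qmc
from sklearn.cluster import SpectralClustering

from .models import Dataset, DynamicalModel, InputSchedule, simulate
from .sparse_grid import SparseGridInterpolant, build_focused_grids, build_interpolant

logger = logging.getLogger(__name__)

__all__ = [
    "AcceptableSet",
    "RepresentativeSet",
    "ClusterModel",
    "TrajectorySurrogate",
    "DirectSource",
    "build_trajectory_surrogate",
    "fitness",
    "batch_fitness",
    "screen_acceptable",
    "cluster_dynamics",
    "select_representatives",
    "weighted_expectation",
    "weighted_variance",
    "latin_hypercube",
]


# ---------------------------------------------------------------------------
# Trajectory surrogates over the parameter box
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySurrogate:
    """Sparse-grid surrogate of full state+output trajectories under one schedule."""

    model: DynamicalModel
    schedule: InputSchedule
    interpolant: SparseGridInterpolant

    @property
    def time_grid(self) -> np.ndarray:
        return self.interpolant.time_grid

    def _series(self, points, times=None) -> np.ndarray:
        return self.interpolant.evaluate_series(points, times)

    def states_at(self, points, times=None) -> np.ndarray:
        """(n_points, n_x, n_times) interpolated state trajectories."""
        return self._series(points, times)[:, :self.model.n_x, :]

    def outputs_at(self, points, times=None) -> np.ndarray:
        """(n_points, n_m, n_times) interpolated measurable outputs."""
        return self._series(points, times)[:, self.model.n_x:, :]

    def record_predictions(self, points, dataset: Dataset) -> np.ndarray:
        """(n_points, n_records) model outputs at the dataset's (output, time) pairs."""
        rec_times = dataset.frame["time_min"].to_numpy(dtype=float)
        uniq = np.unique(rec_times)
        outs = self.outputs_at(points, uniq)
        oi = dataset.output_indices(self.model)
        ti = np.searchsorted(uniq, rec_times)
        return outs[:, oi, ti]


def build_trajectory_surrogate(model: DynamicalModel, schedule: InputSchedule,
                               box=None, dense_grid=None, max_depth: int = 3,
                               rel_tol: float = 0.10, abs_tol: float = 5.0,
                               max_nodes=None, counter=None) -> TrajectorySurrogate:
    """Build the parameter-box surrogate by direct ODE solves at grid nodes."""
    box = model.bounds if box is None else np.atleast_2d(box)
    if dense_grid is None:
        dense_grid = np.linspace(model.t_span[0], model.t_span[1], 151)
    dense_grid = np.asarray(dense_grid, dtype=float)
    n_series = model.n_x + model.n_m

    def evaluator(point):
        tr = simulate(model, point, schedule, dense_grid)
        return np.concatenate([tr.states.T.ravel(), tr.outputs.T.ravel()])

    interp = build_interpolant(evaluator, box, max_depth=max_depth,
                               rel_tol=rel_tol, abs_tol=abs_tol,
                               max_nodes=max_nodes, time_grid=dense_grid,
                               n_series=n_series, counter=counter)
    return TrajectorySurrogate(model=model, schedule=schedule, interpolant=interp)


@dataclass
class DirectSource:
    """Direct-simulation stand-in for a surrogate (oracle/verification path)."""

    model: DynamicalModel
    schedule: InputSchedule

    def record_predictions(self, points, dataset: Dataset) -> np.ndarray:
        rec_times = dataset.frame["time_min"].to_numpy(dtype=float)
        uniq = np.unique(rec_times)
        oi = dataset.output_indices(self.model)
        ti = np.searchsorted(uniq, rec_times)
        preds = np.empty((np.atleast_2d(points).shape[0], len(dataset)))
        for r, p in enumerate(np.atleast_2d(points)):
            tr = simulate(self.model, p, self.schedule, uniq)
            preds[r] = tr.outputs[ti, oi]
        return preds


# ---------------------------------------------------------------------------
# Fitness (acceptability criterion)
# ---------------------------------------------------------------------------

def fitness(simulated_outputs, dataset: Dataset) -> float:
    """log10(1 + sum of squared standardized residuals) for one parameter set."""
    y = np.asarray(simulated_outputs, dtype=float).ravel()
    if y.size != len(dataset):
        raise ValueError("need one simulated value per dataset record")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing simulated value at a dataset record")
    z = (y - dataset.frame["mean"].to_numpy()) / dataset.frame["sd"].to_numpy()
    return float(np.log10(1.0 + np.sum(z ** 2)))


def batch_fitness(sources, points) -> np.ndarray:
    """Pooled fitness over (surrogate, dataset) sources for many points."""
    points = np.atleast_2d(points)
    ssr = np.zeros(points.shape[0])
    for src, ds in sources:
        preds = src.record_predictions(points, ds)
        z = (preds - ds.frame["mean"].to_numpy()) / ds.frame["sd"].to_numpy()
        ssr += np.sum(z ** 2, axis=1)
    return np.log10(1.0 + ssr)


def latin_hypercube(n: int, box, rng) -> np.ndarray:
    box = np.atleast_2d(np.asarray(box, dtype=float))
    sampler = qmc.LatinHypercube(d=box.shape[0], seed=rng)
    return qmc.scale(sampler.random(n), box[:, 0], box[:, 1])


@dataclass
class AcceptableSet:
    parameters: np.ndarray     # (n, n_p')
    fitness_values: np.ndarray
    provenance: np.ndarray     # per-row: "screen" or "focused-<round>"

    def __len__(self) -> int:
        return self.parameters.shape[0]

    def to_csv(self, path, param_names=None) -> None:
        cols = param_names or [f"p{i}" for i in range(self.parameters.shape[1])]
        df = pd.DataFrame(self.parameters, columns=cols)
        df["fitness"] = self.fitness_values
        df["provenance"] = self.provenance
        df.to_csv(path, index=False)


def screen_acceptable(sources, box, n_lhs: int, T_A: float, N_A: int, rng,
                      focused_rounds: int = 5, focused_depth: int = 5,
                      counter=None, dense_grid=None) -> AcceptableSet:
    """LHS screen of Omega; focused-grid rounds refill when too few are found.

    ``sources`` is a list of ``(surrogate_or_direct, dataset)`` pairs whose
    squared standardized residuals pool into one acceptability criterion.
    Focused rounds build refined sparse grids on sub-boxes bounding the
    acceptable points found so far and re-sample there until the set
    reaches ``N_A`` or the round cap is hit.
    """
    box = np.atleast_2d(np.asarray(box, dtype=float))
    pts = latin_hypercube(n_lhs, box, rng)
    fit = batch_fitness(sources, pts)
    keep = fit <= T_A
    params = [pts[keep]]
    fits = [fit[keep]]
    prov = [np.full(int(keep.sum()), "screen", dtype=object)]
    count = int(keep.sum())

    for rnd in range(1, focused_rounds + 1):
        if count >= N_A:
            break
        current = np.vstack(params)
        if current.shape[0] == 0:
            raise RuntimeError(
                "no acceptable parameters found; widen T_A or deepen the "
                "screening grid")
        boxes = [fb.box for fb in build_focused_grids(current, box)]
        per_box_sources = []
        for b in boxes:
            srcs_b = []
            for src, ds in sources:
                if isinstance(src, TrajectorySurrogate):
                    refined = build_trajectory_surrogate(
                        src.model, src.schedule, box=b,
                        dense_grid=src.time_grid if dense_grid is None else dense_grid,
                        max_depth=focused_depth, counter=counter)
                    srcs_b.append((refined, ds))
                else:
                    srcs_b.append((src, ds))
            per_box_sources.append(srcs_b)
        n_per_box = max(n_lhs // (2 * len(boxes)), 50)
        for b, srcs_b in zip(boxes, per_box_sources):
            sub_pts = latin_hypercube(n_per_box, b, rng)
            sub_fit = batch_fitness(srcs_b, sub_pts)
            sub_keep = sub_fit <= T_A
            params.append(sub_pts[sub_keep])
            fits.append(sub_fit[sub_keep])
            prov.append(np.full(int(sub_keep.sum()), f"focused-{rnd}", dtype=object))
            count += int(sub_keep.sum())

    if count == 0:
        raise RuntimeError("no acceptable parameters after focused rounds; "
                           "widen T_A or deepen the screening grid")
    if count < N_A:
        logger.warning("only %d acceptable parameters found (target N_A=%d)",
                       count, N_A)
    return AcceptableSet(parameters=np.vstack(params),
                         fitness_values=np.concatenate(fits),
                         provenance=np.concatenate(prov))


# ---------------------------------------------------------------------------
# Clustering of trajectory ensembles
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    affinity: np.ndarray
    eigenvalues: np.ndarray    # normalized-Laplacian spectrum, ascending
    k: int
    labels: np.ndarray


def cluster_dynamics(trajectories: np.ndarray, k_max: int = 15,
                     seed: int = 0) -> ClusterModel:
    """Spectral clustering of output trajectories with eigengap model order.

    ``trajectories`` is ``(R, n_m, T)`` (or ``(R, F)`` already flattened);
    each output is normalized by its ensemble range, distances are L2 on
    the concatenated series, and the affinity is a locally scaled Gaussian
    kernel, ``exp(-d_ij^2 / (s_i s_j))`` with ``s_i`` the distance to the
    7th nearest neighbour — a per-point bandwidth separates well-spaced
    trajectory bundles that a single global bandwidth blurs together.  The
    cluster count is the largest gap in the normalized-Laplacian spectrum.
    """
    traj = np.asarray(trajectories, dtype=float)
    if traj.ndim == 3:
        rng_out = traj.max(axis=(0, 2)) - traj.min(axis=(0, 2))
        rng_out = np.where(rng_out > 0, rng_out, 1.0)
        flat = (traj / rng_out[None, :, None]).reshape(traj.shape[0], -1)
    else:
        flat = traj
    n = flat.shape[0]
    if n < 2:
        raise ValueError("need at least two trajectories to cluster")
    sq = np.sum(flat ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * flat @ flat.T, 0.0)
    d = np.sqrt(d2)
    if not np.any(d > 0):  # all trajectories identical
        return ClusterModel(affinity=np.ones((n, n)),
                            eigenvalues=np.concatenate([[0.0], np.ones(n - 1)]),
                            k=1, labels=np.zeros(n, dtype=int))
    nn = min(7, n - 1)
    local = np.sort(d, axis=1)[:, nn]           # distance to nn-th neighbour
    local = np.maximum(local, 1e-12 * d.max())
    A = np.exp(-d2 / np.outer(local, local))
    deg = A.sum(axis=1)
    Dm12 = 1.0 / np.sqrt(deg)
    L = np.eye(n) - Dm12[:, None] * A * Dm12[None, :]
    evals = np.sort(eigh(L, eigvals_only=True))
    kk = min(k_max, n - 1)
    gaps = evals[1:kk + 1] - evals[:kk]
    k = int(np.argmax(gaps)) + 1
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        sc = SpectralClustering(n_clusters=k, affinity="precomputed",
                                random_state=seed, assign_labels="kmeans")
        labels = sc.fit_predict(A)
    return ClusterModel(affinity=A, eigenvalues=evals, k=k, labels=labels)


# ---------------------------------------------------------------------------
# Representative parameters
# ---------------------------------------------------------------------------

@dataclass
class RepresentativeSet:
    parameters: np.ndarray     # (N_RA, n_p')
    cluster_labels: np.ndarray
    weights: np.ndarray

    def __len__(self) -> int:
        return self.parameters.shape[0]

    def to_csv(self, path, param_names=None) -> None:
        cols = param_names or [f"p{i}" for i in range(self.parameters.shape[1])]
        df = pd.DataFrame(self.parameters, columns=cols)
        df["cluster"] = self.cluster_labels
        df["weight"] = self.weights
        df.to_csv(path, index=False)


def select_representatives(cluster_model: ClusterModel, acceptable_params,
                           C: int, rng) -> RepresentativeSet:
    """Sample C convex-hull vertices per cluster to span the dynamics.

    Hull vertices are the dynamical extremes of each cluster; when a
    cluster has fewer vertices than ``C`` the vertices are topped up with
    the members closest to the hull, and degenerate clusters (too few
    affinely independent points) fall back to their distinct members.
    Weights start uniform over the pooled representatives.
    """
    if C < 3:
        raise ValueError("C must be >= 3 (hull triangulation minimum)")
    params = np.atleast_2d(np.asarray(acceptable_params, dtype=float))
    reps, labels = [], []
    for lab in sorted(set(cluster_model.labels.tolist())):
        members = np.unique(params[cluster_model.labels == lab], axis=0)
        dim = params.shape[1]
        chosen = None
        if members.shape[0] >= dim + 2:
            try:
                hull = ConvexHull(members)
                verts = members[hull.vertices]
                if verts.shape[0] >= C:
                    idx = rng.choice(verts.shape[0], size=C, replace=False)
                    chosen = verts[idx]
                else:
                    # top up with members nearest the hull vertices
                    rest_mask = np.ones(members.shape[0], dtype=bool)
                    rest_mask[hull.vertices] = False
                    rest = members[rest_mask]
                    need = min(C - verts.shape[0], rest.shape[0])
                    if need > 0:
                        dmin = np.min(np.linalg.norm(
                            rest[:, None, :] - verts[None, :, :], axis=2), axis=1)
                        fill = rest[np.argsort(dmin)[:need]]
                        chosen = np.vstack([verts, fill])
                    else:
                        chosen = verts
            except QhullError:
                chosen = None
        if chosen is None:
            logger.warning("cluster %s degenerate for hull construction; "
                           "taking its %d distinct members", lab, members.shape[0])
            chosen = members
        reps.append(chosen)
        labels.extend([lab] * chosen.shape[0])
    parameters = np.vstack(reps)
    n = parameters.shape[0]
    return RepresentativeSet(parameters=parameters,
                             cluster_labels=np.asarray(labels),
                             weights=np.full(n, 1.0 / n))


# ---------------------------------------------------------------------------
# Probability-weighted moments over the representative ensemble
# ---------------------------------------------------------------------------

def _check_weights(values, weights):
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape[0] != weights.shape[0]:
        raise ValueError("values and weights must have matching leading length")
    if np.any(weights < -1e-12) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    return values, weights


def weighted_expectation(values, weights):
    """E = sum_i p_i f_i along the leading (representative) axis."""
    values, weights = _check_weights(values, weights)
    return np.tensordot(weights, values, axes=(0, 0))


def weighted_variance(values, weights):
    """Var = sum_i p_i (f_i - E)^2 along the leading axis."""
    values, weights = _check_weights(values, weights)
    mu = np.tensordot(weights, values, axes=(0, 0))
    return np.tensordot(weights, (values - mu) ** 2, axes=(0, 0))
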