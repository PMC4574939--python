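"""Adaptive sparse-grid interpolation surrogates.

A sparse (Smolyak-type) grid approximates model outputs over the unknown
parameter box (or an input box) from far fewer ODE solves than a dense
tensor grid.  The basis is piecewise multilinear on nested equidistant
nodes: level 0 contributes the box midpoint, level 1 the two endpoints,
and level ``l >= 2`` the odd multiples of ``2**-l``; a hierarchical
surplus is stored at every node so evaluation at a stored node reproduces
the stored value exactly.  Refinement proceeds level by level and stops at
a maximum depth or when the estimated relative/absolute interpolation
error (the largest hierarchical surplus of the newest level, optionally
scaled by the output range) falls below the configured tolerance.

Trajectory outputs are stored on a fixed dense time grid; evaluation at
off-grid times composes the spatial interpolant with local barycentric
Lagrange interpolation in time.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np
from sklearn.cluster import DBSCAN

logger = logging.getLogger(__name__)

__all__ = [
    "SparseGridInterpolant",
    "FocusedBox",
    "build_interpolant",
    "interpolate",
    "node_count",
    "build_focused_grids",
    "lagrange_time_interp",
]


def _new_nodes_1d(level: int) -> np.ndarray:
    """Unit-interval nodes newly introduced at ``level`` (nested family)."""
    if level == 0:
        return np.array([0.5])
    if level == 1:
        return np.array([0.0, 1.0])
    step = 0.5 ** level
    return np.arange(1, 2 ** level, 2) * step


def _level_node_counts(depth: int) -> list[int]:
    return [len(_new_nodes_1d(l)) for l in range(depth + 1)]


def node_count(depth: int, dim: int) -> int:
    """Number of sparse-grid nodes at total level <= ``depth`` in ``dim`` dims."""
    counts = _level_node_counts(depth)
    # DP over dimensions: table[s] = #nodes with total level exactly s
    table = np.zeros(depth + 1, dtype=np.int64)
    table[0] = 1
    for _ in range(dim):
        new = np.zeros_like(table)
        for s in range(depth + 1):
            for l in range(0, s + 1):
                new[s] += table[s - l] * counts[l]
        table = new
    return int(table.sum())


def _basis_matrix(points_unit: np.ndarray, nodes_unit: np.ndarray,
                  levels: np.ndarray) -> np.ndarray:
    """(n_points, n_nodes) product of 1-D hierarchical hat functions."""
    n_pts, dim = points_unit.shape
    B = np.ones((n_pts, nodes_unit.shape[0]))
    for d in range(dim):
        x = points_unit[:, d:d + 1]
        c = nodes_unit[:, d][None, :]
        lv = levels[:, d][None, :]
        width = np.power(2.0, lv)
        hat = np.clip(1.0 - width * np.abs(x - c), 0.0, None)
        B *= np.where(lv == 0, 1.0, hat)
    return B


@dataclass
class SparseGridInterpolant:
    """Hierarchical-surplus sparse grid over a box, with optional time basis."""

    box: np.ndarray                    # (d, 2)
    depth: int
    nodes_unit: np.ndarray             # (n_nodes, d)
    levels: np.ndarray                 # (n_nodes, d) int
    values: np.ndarray                 # (n_nodes, n_out) raw evaluator output
    surpluses: np.ndarray              # (n_nodes, n_out)
    valid: np.ndarray                  # (n_nodes,) evaluator-success flags
    est_rel_error: float
    est_abs_error: float
    time_grid: np.ndarray | None = None   # per-output time basis T_s
    n_series: int | None = None           # outputs = n_series x len(time_grid)
    n_evaluations: int = 0

    @property
    def dim(self) -> int:
        return self.box.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.nodes_unit.shape[0]

    def _to_unit(self, points: np.ndarray) -> np.ndarray:
        lo, hi = self.box[:, 0], self.box[:, 1]
        unit = (np.atleast_2d(points) - lo) / (hi - lo)
        if np.any(unit < -1e-9) or np.any(unit > 1 + 1e-9):
            logger.warning("point outside interpolation box; clamping")
        return np.clip(unit, 0.0, 1.0)

    def evaluate(self, points) -> np.ndarray:
        """Spatial interpolation: (n_points, n_out) surplus-weighted sum."""
        unit = self._to_unit(np.asarray(points, dtype=float))
        B = _basis_matrix(unit, self.nodes_unit, self.levels)
        return B @ self.surpluses

    def evaluate_series(self, points, times=None) -> np.ndarray:
        """Interpolate trajectory-valued outputs: (n_points, n_series, n_times)."""
        if self.time_grid is None or self.n_series is None:
            raise ValueError("interpolant has no time basis")
        flat = self.evaluate(points)
        series = flat.reshape(flat.shape[0], self.n_series, self.time_grid.size)
        if times is None:
            return series
        times = np.asarray(times, dtype=float)
        if times.size == 0:
            raise ValueError("empty time grid")
        return lagrange_time_interp(series, self.time_grid, times)

    def node_points(self) -> np.ndarray:
        lo, hi = self.box[:, 0], self.box[:, 1]
        return lo + self.nodes_unit * (hi - lo)

    # -- serialization: JSON header + binary node table in one npz archive --
    def save(self, path) -> None:
        header = {
            "box": self.box.tolist(), "depth": self.depth,
            "est_rel_error": self.est_rel_error, "est_abs_error": self.est_abs_error,
            "time_grid": None if self.time_grid is None else self.time_grid.tolist(),
            "n_series": self.n_series, "n_evaluations": self.n_evaluations,
        }
        np.savez_compressed(path, header=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8),
            nodes_unit=self.nodes_unit, levels=self.levels,
            values=self.values, surpluses=self.surpluses, valid=self.valid)

    @classmethod
    def load(cls, path) -> "SparseGridInterpolant":
        with np.load(path) as z:
            header = json.loads(bytes(z["header"]).decode())
            tg = header["time_grid"]
            return cls(box=np.asarray(header["box"], dtype=float),
                       depth=header["depth"], nodes_unit=z["nodes_unit"],
                       levels=z["levels"], values=z["values"],
                       surpluses=z["surpluses"], valid=z["valid"],
                       est_rel_error=header["est_rel_error"],
                       est_abs_error=header["est_abs_error"],
                       time_grid=None if tg is None else np.asarray(tg),
                       n_series=header["n_series"],
                       n_evaluations=header["n_evaluations"])


def _subgrid_nodes(level_vec: tuple[int, ...]) -> np.ndarray:
    axes = [_new_nodes_1d(l) for l in level_vec]
    return np.array(list(product(*axes)))


def build_interpolant(evaluator: Callable[[np.ndarray], np.ndarray],
                      box, max_depth: int = 3, rel_tol: float = 0.10,
                      abs_tol: float = 5.0, max_nodes: int | None = None,
                      time_grid=None, n_series: int | None = None,
                      counter=None) -> SparseGridInterpolant:
    """Refine a sparse grid until depth/error termination.

    ``evaluator`` maps a parameter point (length-d array) to a flat output
    vector and must be deterministic; a failure at a node (exception or
    non-finite output) flags the node, which then contributes nothing to the
    interpolant or the error estimate.  Refinement stops when the achieved
    depth reaches ``max_depth``, or the newest level's estimated relative
    error falls to ``rel_tol``, or its absolute error falls to ``abs_tol``,
    or adding a level would exceed ``max_nodes``.
    """
    box = np.atleast_2d(np.asarray(box, dtype=float))
    if np.any(box[:, 1] - box[:, 0] <= 0):
        raise ValueError("degenerate box")
    dim = box.shape[0]
    lo, span = box[:, 0], box[:, 1] - box[:, 0]

    nodes_u = np.empty((0, dim))
    levels = np.empty((0, dim), dtype=int)
    values: np.ndarray | None = None
    surpluses: np.ndarray | None = None
    valid = np.empty(0, dtype=bool)
    n_eval = 0
    achieved_depth = 0
    est_rel, est_abs = np.inf, np.inf

    for L in range(max_depth + 1):
        level_vecs = [lv for lv in product(range(L + 1), repeat=dim) if sum(lv) == L]
        new_u = np.vstack([_subgrid_nodes(lv) for lv in level_vecs])
        new_lv = np.vstack([np.tile(lv, (len(_subgrid_nodes(lv)), 1))
                            for lv in level_vecs])
        if max_nodes is not None and nodes_u.shape[0] + new_u.shape[0] > max_nodes:
            logger.info("sparse grid: max_nodes cap reached before level %d", L)
            break

        new_vals, new_ok = [], []
        for pu in new_u:
            point = lo + pu * span
            try:
                v = np.asarray(evaluator(point), dtype=float).ravel()
                ok = bool(np.all(np.isfinite(v)))
            except Exception as exc:  # noqa: BLE001 - evaluator is user code
                logger.warning("evaluator failed at node %s: %s", point, exc)
                v, ok = None, False
            n_eval += 1
            if counter is not None:
                counter.add(1)
            new_vals.append(v)
            new_ok.append(ok)
        n_out = next((len(v) for v in new_vals if v is not None), None)
        if n_out is None and values is None:
            raise RuntimeError("evaluator failed at every node of the first level")
        if n_out is None:
            n_out = values.shape[1]
        new_vals = np.array([v if v is not None else np.zeros(n_out)
                             for v in new_vals])
        new_ok = np.asarray(new_ok)

        # surplus = value - current interpolant at the node
        if values is None:
            new_sur = new_vals.copy()
        else:
            B = _basis_matrix(new_u, nodes_u, levels)
            new_sur = new_vals - B @ surpluses
        new_sur[~new_ok] = 0.0

        nodes_u = np.vstack([nodes_u, new_u])
        levels = np.vstack([levels, new_lv])
        values = new_vals if values is None else np.vstack([values, new_vals])
        surpluses = new_sur if surpluses is None else np.vstack([surpluses, new_sur])
        valid = np.concatenate([valid, new_ok])

        if L == 0:
            continue  # no error estimate from a single node
        ok_vals = values[valid]
        ranges = np.maximum(ok_vals.max(axis=0) - ok_vals.min(axis=0), 1e-300)
        abs_sur = np.abs(new_sur[new_ok]) if new_ok.any() else np.zeros((1, n_out))
        est_abs = float(abs_sur.max()) if abs_sur.size else 0.0
        est_rel = float((abs_sur / ranges).max()) if abs_sur.size else 0.0
        if est_abs == 0.0:
            # nothing was gained: report the previously achieved depth
            achieved_depth = max(L - 1, 0)
            est_rel = 0.0
            break
        achieved_depth = L
        if est_rel <= rel_tol or est_abs <= abs_tol:
            break

    return SparseGridInterpolant(
        box=box, depth=achieved_depth, nodes_unit=nodes_u, levels=levels,
        values=values, surpluses=surpluses, valid=valid,
        est_rel_error=0.0 if not np.isfinite(est_rel) else est_rel,
        est_abs_error=0.0 if not np.isfinite(est_abs) else est_abs,
        time_grid=None if time_grid is None else np.asarray(time_grid, dtype=float),
        n_series=n_series, n_evaluations=n_eval)


class ChebInterpolant1D:
    """Polynomial interpolant on nested Chebyshev–Gauss–Lobatto nodes.

    Used for the one-dimensional input-magnitude grids, where the model
    response is smooth in the input level and a polynomial basis is far
    more accurate per node than the piecewise-linear hierarchy.  Node
    counts per depth (1, 3, 5, 9, 17, 33, ...) coincide with the sparse
    grid's 1-D counts, so the simulation-budget accounting is unchanged.
    """

    def __init__(self, lo: float, hi: float, nodes: np.ndarray,
                 values: np.ndarray, depth: int, est_abs_error: float,
                 est_rel_error: float):
        self.lo, self.hi = float(lo), float(hi)
        self.nodes = nodes
        self.values = values
        self.depth = depth
        self.est_abs_error = est_abs_error
        self.est_rel_error = est_rel_error
        n = nodes.size
        if n == 1:
            self._w = np.array([1.0])
        else:
            self._w = np.array([1.0 / np.prod(nodes[i] - np.delete(nodes, i))
                                for i in range(n)])

    @property
    def n_nodes(self) -> int:
        return self.nodes.size

    def evaluate(self, points) -> np.ndarray:
        """Barycentric evaluation: (n_points, n_out)."""
        pts = np.atleast_1d(np.asarray(points, dtype=float)).ravel()
        out = np.empty((pts.size, self.values.shape[1]))
        for j, q in enumerate(pts):
            d = q - self.nodes
            hit = np.argmin(np.abs(d))
            if abs(d[hit]) < 1e-13 * max(abs(self.hi - self.lo), 1.0):
                out[j] = self.values[hit]
            else:
                c = self._w / d
                out[j] = (c[:, None] * self.values).sum(axis=0) / c.sum()
        return out


def _cgl_nodes(lo: float, hi: float, depth: int) -> np.ndarray:
    if depth == 0:
        return np.array([0.5 * (lo + hi)])
    n = 2 ** depth + 1
    x = np.cos(np.pi * np.arange(n) / (n - 1))[::-1]
    return lo + (x + 1.0) / 2.0 * (hi - lo)


def build_cheb_interpolant_1d(evaluator, lo: float, hi: float,
                              max_depth: int = 5, rel_tol: float = 0.10,
                              abs_tol: float = 5.0,
                              counter=None) -> ChebInterpolant1D:
    """Refine nested Chebyshev levels until depth/error termination.

    The error estimate at each new level is the largest deviation between
    the newly evaluated nodes and the previous level's interpolant there,
    relative (for the rel form) to the output range seen so far.
    """
    nodes = _cgl_nodes(lo, hi, 0)
    values = np.atleast_2d(np.asarray(evaluator(nodes[0]), dtype=float).ravel())
    if counter is not None:
        counter.add(1)
    est_abs, est_rel = np.inf, np.inf
    depth = 0
    for d in range(1, max_depth + 1):
        full = _cgl_nodes(lo, hi, d)
        new = np.setdiff1d(full, nodes)
        prev = ChebInterpolant1D(lo, hi, nodes, values, depth, est_abs, est_rel)
        new_vals = np.array([np.asarray(evaluator(x), dtype=float).ravel()
                             for x in new])
        if counter is not None:
            counter.add(len(new))
        pred = prev.evaluate(new)
        order = np.argsort(np.concatenate([nodes, new]))
        nodes = np.concatenate([nodes, new])[order]
        values = np.vstack([values, new_vals])[order]
        rng_out = np.maximum(values.max(axis=0) - values.min(axis=0), 1e-300)
        est_abs = float(np.abs(new_vals - pred).max())
        est_rel = float((np.abs(new_vals - pred) / rng_out).max())
        depth = d
        if est_rel <= rel_tol or est_abs <= abs_tol:
            break
    return ChebInterpolant1D(lo, hi, nodes, values, depth, est_abs, est_rel)


def build_input_interpolant(evaluator, input_box, max_depth: int = 5,
                            rel_tol: float = 0.10, abs_tol: float = 5.0,
                            **kw) -> SparseGridInterpolant:
    """Sparse grid over the input-magnitude box (one per representative).

    Worth building only when the number of candidate input levels exceeds
    the predicted node count ``node_count(max_depth, dim)``; otherwise the
    levels should be simulated directly.
    """
    return build_interpolant(evaluator, input_box, max_depth=max_depth,
                             rel_tol=rel_tol, abs_tol=abs_tol, **kw)


def interpolate(interp: SparseGridInterpolant, point, times=None) -> np.ndarray:
    """Outputs at ``point``; trajectory-valued interpolants add time interpolation."""
    point = np.atleast_2d(np.asarray(point, dtype=float))
    if interp.time_grid is not None and interp.n_series is not None:
        out = interp.evaluate_series(point, times)
        return out[0]
    return interp.evaluate(point)[0]


def lagrange_time_interp(series: np.ndarray, grid: np.ndarray, times: np.ndarray,
                         degree: int = 3) -> np.ndarray:
    """Local barycentric Lagrange interpolation along the last axis.

    For each query time a stencil of ``degree + 1`` neighbouring grid points
    is used; exact grid hits return stored samples unchanged.
    """
    grid = np.asarray(grid, dtype=float)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    k = min(degree + 1, grid.size)
    out = np.empty(series.shape[:-1] + (times.size,))
    for j, t in enumerate(times):
        i = int(np.searchsorted(grid, t))
        if i < grid.size and abs(grid[i] - t) < 1e-9:
            out[..., j] = series[..., i]
            continue
        if i > 0 and abs(grid[i - 1] - t) < 1e-9:
            out[..., j] = series[..., i - 1]
            continue
        s = int(np.clip(i - k // 2, 0, grid.size - k))
        xs = grid[s:s + k]
        d = xs - t
        w = np.empty(k)
        for a in range(k):
            w[a] = 1.0 / np.prod(xs[a] - np.delete(xs, a))
        coef = (w / d)
        out[..., j] = (series[..., s:s + k] * coef).sum(axis=-1) / coef.sum()
    return out


# ---------------------------------------------------------------------------
# Focused grids
# ---------------------------------------------------------------------------

@dataclass
class FocusedBox:
    """A refined sub-box of Omega centred on a cluster of acceptable points."""

    box: np.ndarray
    interpolant: SparseGridInterpolant | None = None
    parent: SparseGridInterpolant | None = None


def _cluster_bounding_boxes(points: np.ndarray, box: np.ndarray,
                            pad: float = 0.10) -> list[np.ndarray]:
    box = np.atleast_2d(box)
    lo, span = box[:, 0], box[:, 1] - box[:, 0]
    unit = (np.atleast_2d(points) - lo) / span
    if unit.shape[0] >= 3:
        labels = DBSCAN(eps=0.15, min_samples=3).fit_predict(unit)
    else:
        labels = np.zeros(unit.shape[0], dtype=int)
    if np.all(labels == -1):
        labels = np.zeros(unit.shape[0], dtype=int)
    boxes = []
    for lab in sorted(set(labels) - {-1}):
        pts = unit[labels == lab]
        b_lo, b_hi = pts.min(axis=0), pts.max(axis=0)
        extent = np.maximum(b_hi - b_lo, 0.02)  # keep boxes non-degenerate
        b_lo = np.clip(b_lo - pad * extent, 0.0, 1.0)
        b_hi = np.clip(b_hi + pad * extent, 0.0, 1.0)
        boxes.append(np.column_stack([lo + b_lo * span, lo + b_hi * span]))
    if -1 in labels and boxes:
        # outliers: fold into one extra bounding box so no acceptable
        # region is dropped
        pts = unit[labels == -1]
        b_lo = np.clip(pts.min(axis=0) - 0.02, 0.0, 1.0)
        b_hi = np.clip(pts.max(axis=0) + 0.02, 0.0, 1.0)
        boxes.append(np.column_stack([lo + b_lo * span, lo + b_hi * span]))
    return boxes


def build_focused_grids(acceptable_points, box, evaluator=None,
                        max_depth: int = 5, rel_tol: float = 0.10,
                        abs_tol: float = 5.0, pad: float = 0.10,
                        time_grid=None, n_series=None,
                        counter=None, max_nodes=None) -> list[FocusedBox]:
    """Sub-boxes around clusters of acceptable points, each with a refined grid.

    Raises if no acceptable point exists (the screen should then be re-run
    with a wider acceptability threshold or a deeper screening grid).
    """
    acceptable_points = np.atleast_2d(np.asarray(acceptable_points, dtype=float))
    if acceptable_points.size == 0:
        raise ValueError("no acceptable points: widen T_A or deepen the "
                         "screening grid before building focused grids")
    boxes = _cluster_bounding_boxes(acceptable_points, box, pad=pad)
    out = []
    for b in boxes:
        interp = None
        if evaluator is not None:
            interp = build_interpolant(evaluator, b, max_depth=max_depth,
                                       rel_tol=rel_tol, abs_tol=abs_tol,
                                       time_grid=time_grid, n_series=n_series,
                                       counter=counter, max_nodes=max_nodes)
        out.append(FocusedBox(box=b, interpolant=interp))
    return out
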