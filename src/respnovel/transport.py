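"""Exact discrete optimal transport and free-support Wasserstein barycenters.

The daily respiratory profile is treated as an empirical distribution of
(breathing rate, inspiratory amplitude) pairs.  The reference model for a
baseline week is the 2-Wasserstein barycenter of its daily distributions — the
Fréchet mean under optimal-transport geometry — and novelty is the W2 distance
from a new day to that barycenter.

The transport problem between two weighted point clouds is solved exactly as a
transportation linear program (squared-Euclidean ground cost) with scipy's
HiGHS backend; the barycenter uses the standard free-support fixed-point
scheme, alternating exact transport solves with barycentric-projection updates
of the support locations.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

__all__ = ["transport_plan", "wasserstein_distance", "free_support_barycenter"]


def _check_cloud(x: np.ndarray, w: np.ndarray | None, name: str):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 0:
        raise ValueError(f"{name}: empty point set")
    if w is None:
        w = np.full(x.shape[0], 1.0 / x.shape[0])
    else:
        w = np.asarray(w, dtype=float)
        if w.shape != (x.shape[0],):
            raise ValueError(f"{name}: weights shape mismatch")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError(f"{name}: weights must be a probability vector")
        w = w / w.sum()
    return x, w


def transport_plan(
    x: np.ndarray,
    y: np.ndarray,
    wx: np.ndarray | None = None,
    wy: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Optimal coupling between two weighted point clouds.

    Returns ``(plan, cost)`` where ``plan`` is the (n, m) optimal transport
    matrix with marginals ``wx`` / ``wy`` (uniform by default) and ``cost`` the
    optimal total squared-Euclidean cost, i.e. W2 squared.
    """
    x, wx = _check_cloud(x, wx, "x")
    y, wy = _check_cloud(y, wy, "y")
    if x.shape[1] != y.shape[1]:
        raise ValueError("point clouds live in different dimensions")
    n, m = x.shape[0], y.shape[0]
    cost_matrix = cdist(x, y, metric="sqeuclidean")

    if n == 1 or m == 1:
        plan = np.outer(wx, wy)
        return plan, float((plan * cost_matrix).sum())

    # transportation LP: rows sum to wx, columns to wy (one redundant
    # constraint dropped for full row rank)
    row_idx = np.repeat(np.arange(n), m)
    col_idx = n + np.tile(np.arange(m), n)
    var_idx = np.arange(n * m)
    a_eq = sparse.csr_matrix(
        (
            np.ones(2 * n * m),
            (np.concatenate([row_idx, col_idx]), np.concatenate([var_idx, var_idx])),
        ),
        shape=(n + m, n * m),
    )[:-1]
    b_eq = np.concatenate([wx, wy])[:-1]
    res = linprog(
        cost_matrix.ravel(),
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=(0, None),
        method="highs",
    )
    if not res.success:  # pragma: no cover - HiGHS is exact on feasible LPs
        raise RuntimeError(f"transport LP failed: {res.message}")
    plan = res.x.reshape(n, m)
    return plan, float(res.fun)


def wasserstein_distance(
    x: np.ndarray,
    y: np.ndarray,
    wx: np.ndarray | None = None,
    wy: np.ndarray | None = None,
) -> float:
    """Exact 2-Wasserstein distance between two empirical distributions.

    Symmetric, non-negative, and zero iff the weighted multisets coincide.
    """
    _, cost = transport_plan(x, y, wx, wy)
    return float(np.sqrt(max(cost, 0.0)))


def free_support_barycenter(
    point_sets: list[np.ndarray],
    n_support: int,
    rng: np.random.Generator,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float]:
    """W2 barycenter with free support and uniform weights.

    Minimises ``sum_d W2^2(B, P_d)`` over distributions ``B`` supported on
    ``n_support`` points with uniform mass, by block-coordinate descent:
    given the support, solve the exact transport to every input distribution;
    given the couplings, move each support point to the barycentric projection
    (weighted mean) of the mass it sends.  The objective is non-increasing.

    Support is initialised from a seeded subsample of the pooled input points.
    Returns ``(support, weights, objective)``.
    """
    if not point_sets:
        raise ValueError("need at least one input distribution")
    sets = [np.atleast_2d(np.asarray(p, dtype=float)) for p in point_sets]
    pooled = np.vstack(sets)
    n_support = min(n_support, pooled.shape[0])
    if n_support < 1:
        raise ValueError("n_support must be >= 1")
    idx = rng.choice(pooled.shape[0], size=n_support, replace=False)
    support = pooled[idx].copy()
    # tiny jitter so coincident initial points can separate
    support = support + 1e-9 * rng.standard_normal(support.shape)
    weights = np.full(n_support, 1.0 / n_support)

    objective = np.inf
    for _ in range(max_iter):
        new_support = np.zeros_like(support)
        new_objective = 0.0
        for pts in sets:
            plan, cost = transport_plan(support, pts)
            new_objective += cost
            # row sums equal 1/n_support, so this is the barycentric projection
            new_support += (plan @ pts) * n_support
        new_support /= len(sets)
        if objective - new_objective < tol * max(abs(objective), 1.0):
            support = new_support if new_objective < objective else support
            objective = min(objective, new_objective)
            break
        support = new_support
        objective = new_objective
    return support, weights, float(objective)
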