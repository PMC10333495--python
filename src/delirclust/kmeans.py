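"""K-means engine with multi-restart initialization and AIC model-order selection.

The same engine drives both stages of the pipeline: clustering the item@day
column vectors into feature groups, and clustering participants on the
group-averaged composites.  The number of clusters K is chosen by running
Lloyd's algorithm many times per candidate K (random restarts) and keeping
the solution with the lowest information-criterion score over the whole
(K, restart) table.

Two criterion forms are available (see docs/methods.md for the choice):

``profile``
    Spherical-Gaussian profile-likelihood AIC,
    ``n*d*ln(max(wcss/(n*d), eps)) + 2*K*d``.
``distortion``
    Penalized-distortion AIC, ``wcss + 2*K*d`` (the default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "ClusteringSolution",
    "SelectionReport",
    "lloyd",
    "aic",
    "distortion_aic",
    "select_k",
    "CRITERIA",
]

#: floor on wcss/(n*d) inside the profile-likelihood log, guarding exact fits
EPS_WCSS = 1e-12

DEFAULT_K_RANGE = range(1, 11)
DEFAULT_RESTARTS = 1000
DEFAULT_MAX_ITER = 300
DEFAULT_TOL = 1e-6


@dataclass
class ClusteringSolution:
    """One converged K-means fit."""

    K: int
    assignments: np.ndarray  # (n,) int, values in 0..K-1, every value present
    centroids: np.ndarray    # (K, d)
    wcss: float              # within-cluster sum of squared distances
    aic: float = float("nan")
    n_iter: int = 0
    seed: tuple[int, ...] | int | None = None
    wcss_history: list[float] | None = None

    def relabeled(self, perm: Sequence[int]) -> "ClusteringSolution":
        """Apply permutation ``perm`` (new index of old cluster i)."""
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        return ClusteringSolution(
            K=self.K,
            assignments=perm[self.assignments],
            centroids=self.centroids[inv],
            wcss=self.wcss,
            aic=self.aic,
            n_iter=self.n_iter,
            seed=self.seed,
        )


@dataclass
class SelectionReport:
    """Outcome of a multi-restart, multi-K selection sweep."""

    selected_K: int
    selected_solution: ClusteringSolution
    aic_table: "np.ndarray"          # (len(k_range), restarts) criterion scores
    k_range: list[int]
    restarts: int
    criterion: str
    master_seed: int

    def best_aic_per_k(self) -> dict[int, float]:
        return {
            k: float(np.min(self.aic_table[i]))
            for i, k in enumerate(self.k_range)
        }

    def to_dict(self) -> dict:
        return {
            "selected_K": int(self.selected_K),
            "criterion": self.criterion,
            "k_range": [int(k) for k in self.k_range],
            "restarts": int(self.restarts),
            "master_seed": int(self.master_seed),
            "selected_seed": list(self.selected_solution.seed),
            "selected_aic": float(self.selected_solution.aic),
            "selected_wcss": float(self.selected_solution.wcss),
            "best_aic_per_k": {str(k): v for k, v in self.best_aic_per_k().items()},
        }


def _validate_points(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] < 1:
        raise ValueError("points must be an n x d matrix with d >= 1")
    if not np.isfinite(points).all():
        raise ValueError("points contain non-finite values")
    return points


def _assign(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # squared Euclidean; np.argmin breaks ties toward the lowest index
    d2 = (
        (points**2).sum(axis=1)[:, None]
        - 2.0 * points @ centroids.T
        + (centroids**2).sum(axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def _wcss(points: np.ndarray, centroids: np.ndarray, assign: np.ndarray) -> float:
    diff = points - centroids[assign]
    return float(np.einsum("ij,ij->", diff, diff))


def lloyd(
    points: np.ndarray,
    K: int,
    seed: int | Sequence[int] = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    collect_history: bool = False,
) -> ClusteringSolution:
    """Run Lloyd's algorithm once from a random initialization.

    Initial centroids are K data points sampled uniformly without
    replacement.  Iteration alternates nearest-centroid assignment (squared
    Euclidean, ties to the lowest cluster index) with mean updates, and stops
    when assignments stabilize, every centroid moves less than ``tol``, or
    ``max_iter`` is reached.  An empty cluster is repaired by reseeding it at
    the point currently farthest from its assigned centroid (that point is
    force-assigned to the empty cluster), preserving the invariant that every
    cluster index occurs.
    """
    points = _validate_points(points)
    n, d = points.shape
    if not 1 <= K <= n:
        raise ValueError(f"K={K} must satisfy 1 <= K <= n={n}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol < 0:
        raise ValueError("tol must be >= 0")

    rng = np.random.default_rng(seed)
    centroids = points[rng.choice(n, size=K, replace=False)].copy()
    assign = _repair_empty(points, centroids, _assign(points, centroids), K)
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new_centroids = centroids.copy()
        for k in range(K):
            new_centroids[k] = points[assign == k].mean(axis=0)
        shift = float(np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max())
        centroids = new_centroids
        new_assign = _repair_empty(points, centroids, _assign(points, centroids), K)
        if collect_history:
            history.append(_wcss(points, centroids, new_assign))
        if np.array_equal(new_assign, assign) or shift < tol:
            assign = new_assign
            break
        assign = new_assign

    # make the returned triple self-consistent: centroids are the means of
    # the returned assignment, wcss is the objective of that partition
    for k in range(K):
        centroids[k] = points[assign == k].mean(axis=0)
    wcss = _wcss(points, centroids, assign)
    return ClusteringSolution(
        K=K,
        assignments=assign,
        centroids=centroids,
        wcss=wcss,
        n_iter=n_iter,
        seed=tuple(np.atleast_1d(seed).tolist()) if not np.isscalar(seed) else int(seed),
        wcss_history=history if collect_history else None,
    )


def _repair_empty(points: np.ndarray, centroids: np.ndarray,
                  assign: np.ndarray, K: int) -> np.ndarray:
    """Reseed every empty cluster so all K indices occur.

    The empty cluster takes the point farthest from its currently assigned
    centroid, drawing only from clusters that would not become empty in
    turn (ties: first index).
    """
    counts = np.bincount(assign, minlength=K)
    if (counts > 0).all():
        return assign
    d2 = ((points - centroids[assign]) ** 2).sum(axis=1)
    for k in range(K):
        while counts[k] == 0:
            eligible = counts[assign] > 1
            if not eligible.any():  # n < K cannot happen (validated); all singletons
                raise RuntimeError("cannot repair empty cluster")
            cand = np.where(eligible)[0]
            far = int(cand[np.argmax(d2[cand])])
            counts[assign[far]] -= 1
            assign = assign.copy()
            assign[far] = k
            counts[k] += 1
            d2[far] = 0.0
    return assign


def aic(solution: ClusteringSolution, n: int, d: int) -> float:
    """Spherical-Gaussian profile-likelihood AIC of a K-means fit.

    ``n*d*ln(max(wcss/(n*d), eps)) + 2*K*d`` with ``eps`` = 1e-12 guarding
    perfect fits.  The value is stored on the solution and returned.
    """
    if n * d <= 0:
        raise ValueError("n*d must be positive")
    value = n * d * np.log(max(solution.wcss / (n * d), EPS_WCSS)) + 2.0 * solution.K * d
    solution.aic = float(value)
    return solution.aic


def distortion_aic(solution: ClusteringSolution, n: int, d: int) -> float:
    """Penalized-distortion AIC: ``wcss + 2*K*d``.

    Distortion plays the role of the deviance and each centroid contributes
    d parameters; this is the form that reproduces the reference selection
    behavior on ordinal score data (see docs/methods.md).
    """
    if n * d <= 0:
        raise ValueError("n*d must be positive")
    solution.aic = float(solution.wcss + 2.0 * solution.K * d)
    return solution.aic


CRITERIA: dict[str, Callable[[ClusteringSolution, int, int], float]] = {
    "profile": aic,
    "distortion": distortion_aic,
}

DEFAULT_CRITERION = "distortion"


def select_k(
    points: np.ndarray,
    k_range: Iterable[int] = DEFAULT_K_RANGE,
    restarts: int = DEFAULT_RESTARTS,
    master_seed: int = 0,
    criterion: str = DEFAULT_CRITERION,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> SelectionReport:
    """Choose K by exhaustive multi-restart search over ``k_range``.

    Every (K, restart) pair runs :func:`lloyd` with the per-run seed
    ``(master_seed, K, restart)`` (fed to ``numpy.random.default_rng`` as an
    entropy sequence), so any single run can be replayed in isolation.  The
    returned solution is the argmin of the full recorded criterion table;
    ties go to the smaller K, then the earlier restart.
    """
    points = _validate_points(points)
    n, d = points.shape
    k_range = [int(k) for k in k_range]
    if not k_range:
        raise ValueError("k_range must be non-empty")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {sorted(CRITERIA)}")
    score = CRITERIA[criterion]

    table = np.full((len(k_range), restarts), np.nan)
    best: ClusteringSolution | None = None
    n_failed = 0
    for i, K in enumerate(sorted(k_range)):
        if K > n:
            n_failed += restarts
            continue
        for r in range(restarts):
            sol = lloyd(points, K, seed=(master_seed, K, r), max_iter=max_iter, tol=tol)
            table[i, r] = score(sol, n, d)
            if best is None or sol.aic < best.aic:
                best = sol
    if best is None:
        raise RuntimeError("selection failed: no K in k_range is feasible for the data")
    return SelectionReport(
        selected_K=best.K,
        selected_solution=best,
        aic_table=table,
        k_range=sorted(k_range),
        restarts=restarts,
        criterion=criterion,
        master_seed=int(master_seed),
    )
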