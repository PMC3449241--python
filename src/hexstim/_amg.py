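"""Smoothed-aggregation multigrid preconditioner for the FE stiffness matrix.

The stiffness matrix of the quasistatic problem is symmetric positive
semidefinite with a one-dimensional null space (constants).  CG handles the
singular-but-consistent system as long as iterates stay orthogonal to the
null space; this V-cycle is used purely as a symmetric preconditioner.

Aggregation exploits the voxel origin of the meshes: nodes are grouped into
3x3x3 spatial blocks of the (possibly adapted) node lattice, giving a
tentative piecewise-constant prolongator that is then smoothed with one
damped-Jacobi step.  Coarse levels recurse on the aggregate centroids until
the coarsest operator is small enough for a dense pseudo-inverse.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import LinearOperator

__all__ = ["SmoothedAggregationPreconditioner"]


def _aggregate_by_position(points: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Group points into cubic blocks of edge ``h``; returns (agg_id, centroids)."""
    keys = np.floor(points / h).astype(np.int64)
    # lexicographic unique over the 3 key columns
    order = np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0]))
    sk = keys[order]
    new_block = np.ones(len(sk), dtype=bool)
    new_block[1:] = (np.diff(sk, axis=0) != 0).any(axis=1)
    block_id_sorted = np.cumsum(new_block) - 1
    agg = np.empty(len(points), dtype=np.int64)
    agg[order] = block_id_sorted
    n_agg = block_id_sorted[-1] + 1
    centroids = np.zeros((n_agg, 3))
    counts = np.bincount(agg, minlength=n_agg).astype(float)
    for d in range(3):
        centroids[:, d] = np.bincount(agg, weights=points[:, d], minlength=n_agg) / counts
    return agg, centroids


def _rho_dinv_a(a: csr_matrix, dinv: np.ndarray, n_iter: int = 12, seed: int = 0) -> float:
    """Power-iteration estimate of the spectral radius of D^-1 A."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(a.shape[0])
    x /= np.linalg.norm(x)
    rho = 1.0
    for _ in range(n_iter):
        y = dinv * (a @ x)
        ny = np.linalg.norm(y)
        if ny == 0:
            return 1.0
        rho = ny
        x = y / ny
    return float(rho)


class _Level:
    __slots__ = ("a", "dinv", "omega", "p", "r")

    def __init__(self, a, dinv, omega, p=None, r=None):
        self.a, self.dinv, self.omega, self.p, self.r = a, dinv, omega, p, r


class SmoothedAggregationPreconditioner:
    """V(1,1)-cycle smoothed-aggregation multigrid, usable as a LinearOperator.

    Symmetric by construction (damped-Jacobi pre/post smoothing, Galerkin
    coarse operators, P^T restriction), hence safe inside CG.
    """

    def __init__(
        self,
        a: csr_matrix,
        points: np.ndarray,
        h: float,
        coarsening: int = 3,
        max_coarse: int = 400,
        max_levels: int = 12,
    ):
        a = csr_matrix(a)
        self.levels: list[_Level] = []
        pts = np.asarray(points, dtype=float)
        level_h = h * coarsening
        for _ in range(max_levels):
            d = a.diagonal()
            dinv = np.where(d > 0, 1.0 / np.maximum(d, 1e-300), 0.0)
            rho = _rho_dinv_a(a, dinv)
            omega = 4.0 / (3.0 * rho)
            if a.shape[0] <= max_coarse:
                self.levels.append(_Level(a, dinv, omega))
                break
            agg, centroids = _aggregate_by_position(pts, level_h)
            n_agg = centroids.shape[0]
            if n_agg >= a.shape[0]:  # no coarsening progress; stop here
                self.levels.append(_Level(a, dinv, omega))
                break
            t = csr_matrix(
                (np.ones(a.shape[0]), (np.arange(a.shape[0]), agg)),
                shape=(a.shape[0], n_agg),
            )
            # one damped-Jacobi smoothing step on the tentative prolongator
            da = a.multiply(dinv[:, None]).tocsr()
            p = (t - omega * (da @ t)).tocsr()
            r = p.T.tocsr()
            self.levels.append(_Level(a, dinv, omega, p, r))
            a = (r @ a @ p).tocsr()
            pts = centroids
            level_h *= coarsening
        else:
            self.levels.append(_Level(a, a.diagonal() * 0, 1.0))

        coarse_a = self.levels[-1].a.toarray()
        self._coarse_pinv = np.linalg.pinv(coarse_a, rcond=1e-10)
        n = self.levels[0].a.shape[0]
        self.shape = (n, n)
        self.dtype = np.float64

    def _smooth(self, level: _Level, x: np.ndarray, b: np.ndarray) -> np.ndarray:
        return x + level.omega * level.dinv * (b - level.a @ x)

    def _cycle(self, k: int, b: np.ndarray) -> np.ndarray:
        level = self.levels[k]
        if k == len(self.levels) - 1:
            return self._coarse_pinv @ b
        x = level.omega * level.dinv * b  # pre-smooth from zero guess
        r = b - level.a @ x
        x = x + level.p @ self._cycle(k + 1, level.r @ r)
        return self._smooth(level, x, b)

    def matvec(self, b: np.ndarray) -> np.ndarray:
        return self._cycle(0, np.asarray(b, dtype=float))

    def as_linear_operator(self) -> LinearOperator:
        return LinearOperator(self.shape, matvec=self.matvec, dtype=self.dtype)
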