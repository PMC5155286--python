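"""Discrete regularization operators.

Spatial side: the surface Laplacian on a triangle mesh, built by linearly
interpolating each neighbor value to the node's mean edge length d_bar_i
and applying the mean-value identity Lap x ~ (4 / d_bar_i**2) (x_ring - x_i)
— the irregular-mesh generalization of the 5-point lattice stencil, to
which it reduces exactly on a square lattice.  Temporal side: a windowed
sum of squared differences Sum_t Sum_{k=1..w} ||x_t - x_{t+k}||^2, whose
per-time quadratic contribution for interior t is 2 w lambda_t I.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .mesh import TriangleMesh


@dataclass
class LaplacianMatrix:
    """Sparse N x N discrete Laplacian with per-node metadata.

    ``n_i`` is the neighbor count and ``d_bar_i`` the mean neighbor
    distance of each node.  Rows sum to zero (constant fields are
    annihilated) and row i touches only node i and its mesh neighbors.
    """

    matrix: sp.csr_matrix
    n_i: np.ndarray
    d_bar_i: np.ndarray

    def __matmul__(self, other):
        return self.matrix @ other

    @property
    def shape(self):
        return self.matrix.shape

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def lattice_laplacian(grid_shape: tuple, d: float) -> LaplacianMatrix:
    """Five-point Laplacian on an (nu x nv) square lattice, constant d.

    Interior row i encodes (x_1 + x_2 + x_3 + x_4 - 4 x_0) / d**2 in
    row-major node order; boundary rows use the same mean-value form over
    the available neighbors, (4 / d**2) * (mean(neighbors) - x_0), keeping
    every row sum zero.  Exact on quadratics at interior nodes.
    """
    nu, nv = grid_shape
    if nu < 2 or nv < 2 or d <= 0:
        raise ValueError("grid must be at least 2x2 with positive lattice constant")
    idx = np.arange(nu * nv).reshape(nu, nv)
    rows, cols, vals = [], [], []
    for u in range(nu):
        for v in range(nv):
            i = idx[u, v]
            nbrs = []
            if u > 0:
                nbrs.append(idx[u - 1, v])
            if u < nu - 1:
                nbrs.append(idx[u + 1, v])
            if v > 0:
                nbrs.append(idx[u, v - 1])
            if v < nv - 1:
                nbrs.append(idx[u, v + 1])
            coef = 4.0 / (d * d) / len(nbrs)
            for j in nbrs:
                rows.append(i)
                cols.append(j)
                vals.append(coef)
            rows.append(i)
            cols.append(i)
            vals.append(-4.0 / (d * d))
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(nu * nv, nu * nv))
    n_i = np.array([(2 if 0 < u < nu - 1 else 1) + (2 if 0 < v < nv - 1 else 1)
                    for u in range(nu) for v in range(nv)], dtype=np.int64)
    return LaplacianMatrix(mat, n_i, np.full(nu * nv, float(d)))


def mesh_laplacian(mesh: TriangleMesh) -> LaplacianMatrix:
    """Interpolation surface Laplacian of a triangle mesh.

    For node i with neighbors j at edge lengths d_ij and mean edge length
    d_bar_i, each neighbor value is linearly interpolated to the common
    distance d_bar_i along its edge,

        x_interp_j = x_i + (d_bar_i / d_ij) (x_j - x_i),

    their average approximates the ring average at radius d_bar_i, and the
    2-D mean-value property gives

        (Lap x)_i = (4 / d_bar_i**2) * (mean_j x_interp_j - x_i).

    The matrix is generally asymmetric on irregular meshes; the spatial
    penalty uses ||Lap x||^2, which is symmetric PSD regardless.
    """
    nbrs = mesh.neighbors()
    n = mesh.node_count
    rows, cols, vals = [], [], []
    n_i = np.zeros(n, dtype=np.int64)
    d_bar = np.zeros(n)
    for i in range(n):
        js = nbrs[i]
        if len(js) == 0:
            raise ValueError(f"isolated node {i}")
        d_ij = np.linalg.norm(mesh.vertices[js] - mesh.vertices[i], axis=1)
        di = d_ij.mean()
        n_i[i] = len(js)
        d_bar[i] = di
        scale = 4.0 / (di * di)
        w = (di / d_ij) / len(js)          # interpolation weight on x_j
        rows.extend([i] * len(js))
        cols.extend(js.tolist())
        vals.extend((scale * w).tolist())
        rows.append(i)
        cols.append(i)
        vals.append(scale * (np.sum((1.0 - di / d_ij)) / len(js) - 1.0))
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return LaplacianMatrix(mat, n_i, d_bar)


def bidiagonal_gradient(n: int, h: float = 1.0) -> np.ndarray:
    """First-difference (bidiagonal) matrix: row i encodes (x_{i+1} - x_i)/h.

    The one-dimensional gradient surrogate used by column-stacked
    first-order regularization; provided for benchmarking.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    d = np.zeros((n - 1, n))
    idx = np.arange(n - 1)
    d[idx, idx] = -1.0 / h
    d[idx, idx + 1] = 1.0 / h
    return d


@dataclass
class TemporalPenalty:
    """Windowed temporal-difference penalty Sum_t Sum_{k=1..w} ||x_t - x_{t+k}||^2.

    Each unordered pair (t, t+k), k <= w, is counted once, so the
    quadratic contribution of an interior time t is 2 w ||x_t||^2 (the
    "2 w lambda_t I" diagonal term of the per-time block once scaled by
    lambda_t); the window is truncated at the record boundaries.
    """

    horizon: int
    window: int
    _lap: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not 1 <= self.window < self.horizon:
            raise ValueError("require 1 <= window < horizon")

    def pair_count(self, t: int) -> int:
        """Number of penalty pairs involving time index t (0-based)."""
        return min(self.window, self.horizon - 1 - t) + min(self.window, t)

    def neighbor_indices(self, t: int) -> np.ndarray:
        """Time indices coupled to t (both directions, boundary-truncated)."""
        lo = max(0, t - self.window)
        hi = min(self.horizon - 1, t + self.window)
        return np.array([k for k in range(lo, hi + 1) if k != t], dtype=np.int64)

    def coupling_matrix(self) -> np.ndarray:
        """Dense T x T matrix L with penalty(X) = trace(X L X^T).

        L is the graph Laplacian of the path-with-window graph: L[t, t] =
        pair_count(t), L[t, t+k] = -1 for 0 < k <= w.
        """
        if self._lap is None:
            T, w = self.horizon, self.window
            L = np.zeros((T, T))
            for t in range(T):
                L[t, t] = self.pair_count(t)
                for k in range(1, w + 1):
                    if t + k < T:
                        L[t, t + k] = L[t + k, t] = -1.0
            self._lap = L
        return self._lap

    def value(self, x: np.ndarray) -> float:
        """Evaluate the penalty for a (nodes, T) field (or (T,) scalar series)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.horizon:
            raise ValueError("field horizon mismatch")
        total = 0.0
        for k in range(1, self.window + 1):
            diff = x[:, k:] - x[:, :-k]
            total += float(np.sum(diff * diff))
        return total


def temporal_coupling(T: int, w: int) -> TemporalPenalty:
    """Construct the windowed temporal penalty for horizon T and window w."""
    return TemporalPenalty(horizon=T, window=w)
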