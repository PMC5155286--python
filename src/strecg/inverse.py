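"""Regularized inversion of y = R x: baselines and the spatiotemporal model.

Baselines solve each time slice independently:

* zero/first-order Tikhonov  min ||R x - y||^2 + lam ||G x||^2  (closed form),
* first-order L1             min ||R x - y||^2 + lam ||G x||_1  (ADMM),

with G the identity, the heart-surface normal-derivative operator, or any
conforming constraint matrix.  The spatiotemporal objective couples the
slices:

    J(X) = sum_t ||y_t - R x_t||^2 + lam_s sum_t ||Lap x_t||^2
           + lam_t sum_t sum_{k=1..w} ||x_t - x_{t+k}||^2,

an unconstrained convex quadratic.  Two solvers are provided: an exact
direct solve through a double spectral decomposition, and the dipole
multiplicative update, which splits x_t = x+ - x- into nonnegative parts
(mirroring the positive/negative poles of the bioelectric field) and
applies Sha-Saul-Lee multiplicative nonnegative-QP updates blockwise over
t, guaranteeing a monotone non-increasing objective.

Solvers are exposed both as functions and as sklearn-style estimators with
``fit(R, Y)`` and a fitted ``X_`` attribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from sklearn.base import BaseEstimator

from .operators import LaplacianMatrix, TemporalPenalty, temporal_coupling

_EPS_FLOOR = 1e-12  # guards exact-zero denominators in multiplicative updates


@dataclass
class SolveResult:
    """Outcome of an iterative inverse solve."""

    x: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    grad_norm: float = np.nan

    def __post_init__(self):
        self.objective_trace = np.asarray(self.objective_trace, dtype=float)


def _as_matrix(y) -> tuple[np.ndarray, bool]:
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        return y[:, None], True
    return y, False


def _operator_array(gamma, n: int) -> np.ndarray:
    if gamma is None or (isinstance(gamma, str) and gamma == "identity"):
        return np.eye(n)
    if isinstance(gamma, LaplacianMatrix):
        return gamma.toarray()
    g = np.asarray(gamma, dtype=float) if not hasattr(gamma, "toarray") else gamma.toarray()
    if g.shape[1] != n:
        raise ValueError(f"constraint operator has {g.shape[1]} columns, expected {n}")
    return g


# ---------------------------------------------------------------------------
# Tikhonov (orders 0 and 1) — closed form
# ---------------------------------------------------------------------------

def solve_tikhonov(R, y, gamma=None, lam: float = 0.0, order: int = 0) -> np.ndarray:
    """Closed-form minimizer of ||R x - y||^2 + lam ||G x||^2 per time slice.

    ``order=0`` defaults G to the identity (ridge shrinkage); ``order=1``
    requires an explicit gradient-type operator (normal derivative,
    bidiagonal, Laplacian).  ``lam`` weights the quadratic penalty
    directly.  A singular system at lam = 0 falls back to the
    pseudo-inverse with a warning.

    Matches the SVD filter-factor solution s_i / (s_i^2 + lam) in the
    identity-constraint case.
    """
    R = np.asarray(R, dtype=float)
    Y, was_vec = _as_matrix(y)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if order == 0 and gamma is None:
        gamma = None
    elif order == 1 and gamma is None:
        raise ValueError("order-1 Tikhonov needs an explicit constraint operator")
    G = _operator_array(gamma, R.shape[1])
    lhs = R.T @ R + lam * (G.T @ G)
    rhs = R.T @ Y
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sla.LinAlgWarning)
            X = sla.solve(lhs, rhs, assume_a="pos")
    except (sla.LinAlgError, np.linalg.LinAlgError, sla.LinAlgWarning):
        warnings.warn("normal equations singular; using pseudo-inverse solution")
        X = np.linalg.pinv(lhs) @ rhs
    return X[:, 0] if was_vec else X


# ---------------------------------------------------------------------------
# L1 first-order — ADMM with cached factorization
# ---------------------------------------------------------------------------

def solve_l1_first_order(R, y, gamma, lam: float, rho: float | None = None,
                         max_iter: int = 2000, tol: float = 1e-8,
                         tol_window: int = 10) -> SolveResult:
    """ADMM minimizer of ||R x - y||_2^2 + lam ||G x||_1 (all slices jointly).

    Splitting z = G x with penalty parameter ``rho`` (default: lam, or 1
    if lam = 0), with standard residual-balancing adaptation of rho.
    Convergence is declared when the relative objective change stays
    below ``tol`` over ``tol_window`` consecutive iterations.
    """
    R = np.asarray(R, dtype=float)
    Y, was_vec = _as_matrix(y)
    G = _operator_array(gamma, R.shape[1])
    if rho is None:
        rho = lam if lam > 0 else 1.0
    base = 2.0 * R.T @ R
    GtG = G.T @ G
    eye = 1e-14 * np.eye(base.shape[0])
    cho = sla.cho_factor(base + rho * GtG + eye)
    RtY2 = 2.0 * R.T @ Y
    Z = np.zeros((G.shape[0], Y.shape[1]))
    U = np.zeros_like(Z)
    trace = []
    converged = False
    X = np.zeros((R.shape[1], Y.shape[1]))
    for it in range(max_iter):
        X = sla.cho_solve(cho, RtY2 + rho * G.T @ (Z - U))
        GX = G @ X
        Z_old = Z
        Z = np.sign(GX + U) * np.maximum(np.abs(GX + U) - lam / rho, 0.0)
        U += GX - Z
        obj = float(np.sum((R @ X - Y) ** 2) + lam * np.abs(GX).sum())
        trace.append(obj)
        if len(trace) > tol_window:
            prev = trace[-tol_window - 1]
            if abs(prev - obj) <= tol * max(abs(prev), 1e-30):
                converged = True
                break
        # residual balancing keeps the splitting well conditioned
        if (it + 1) % 10 == 0:
            r_p = np.linalg.norm(GX - Z)
            r_d = rho * np.linalg.norm(G.T @ (Z - Z_old))
            if r_p > 10.0 * r_d:
                rho *= 2.0
                U /= 2.0
                cho = sla.cho_factor(base + rho * GtG + eye)
            elif r_d > 10.0 * r_p:
                rho /= 2.0
                U *= 2.0
                cho = sla.cho_factor(base + rho * GtG + eye)
    res = SolveResult(x=X[:, 0] if was_vec else X, objective_trace=trace,
                      n_iter=len(trace), converged=converged)
    return res


# ---------------------------------------------------------------------------
# spatiotemporal objective and solvers
# ---------------------------------------------------------------------------

def _lap_array(laplacian, n: int) -> np.ndarray:
    return _operator_array(laplacian, n)


def stre_objective(R, Y, laplacian, lam_s: float, lam_t: float, w: int,
                   X) -> float:
    """Evaluate the spatiotemporal objective J(X) (see module docstring)."""
    R = np.asarray(R, dtype=float)
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    L = _lap_array(laplacian, R.shape[1])
    resid = float(np.sum((Y - R @ X) ** 2))
    spatial = float(np.sum((L @ X) ** 2))
    temporal = temporal_coupling(Y.shape[1], w).value(X) if lam_t != 0 else 0.0
    return resid + lam_s * spatial + lam_t * temporal


def solve_stre_direct(R, Y, laplacian, lam_s: float, lam_t: float, w: int
                      ) -> np.ndarray:
    """Exact minimizer of the spatiotemporal objective.

    The normal equations  (R^T R + lam_s Lap^T Lap) X + lam_t X L_T = R^T Y
    (L_T the temporal window-graph Laplacian) are a Sylvester system,
    diagonalized by the eigenbases of the two symmetric PSD coefficient
    matrices; the solve is exact up to the eigendecompositions.  A
    semidefinite mode (possible only at lam_t = 0 with rank-deficient
    R and Lap) yields the minimum-norm solution with a warning.
    """
    R = np.asarray(R, dtype=float)
    Y = np.asarray(Y, dtype=float)
    L = _lap_array(laplacian, R.shape[1])
    A_s = R.T @ R + lam_s * L.T @ L
    s_vals, V = np.linalg.eigh((A_s + A_s.T) / 2.0)
    if lam_t != 0:
        pen = temporal_coupling(Y.shape[1], w)
        m_vals, U = np.linalg.eigh(pen.coupling_matrix())
    else:
        m_vals, U = np.zeros(Y.shape[1]), np.eye(Y.shape[1])
    B = V.T @ (R.T @ Y) @ U
    denom = s_vals[:, None] + lam_t * m_vals[None, :]
    scale = max(s_vals.max(), lam_t * m_vals.max() if lam_t else 0.0, 1.0)
    bad = denom <= 1e-14 * scale
    if bad.any():
        warnings.warn("semidefinite spatiotemporal system; returning the "
                      "minimum-norm solution")
        denom = np.where(bad, np.inf, denom)
    return V @ (B / denom) @ U.T


def solve_stre_dipole_mu(R, Y, laplacian, lam_s: float, lam_t: float, w: int,
                         init_seed: int = 0, max_iter: int = 5000,
                         tol: float = 1e-8) -> SolveResult:
    """Dipole multiplicative-update solver for the spatiotemporal objective.

    Each x_t is split into nonnegative parts x_t = x+ - x-.  Sweeping
    forward over t = 1..T (Gauss-Seidel: temporal neighbors at their
    latest values), the per-time convex quadratic

        x_t^T A_t x_t - 2 b_t^T x_t,
        A_t = R^T R + lam_s Lap^T Lap + lam_t n_t I,
        b_t = R^T y_t + lam_t sum_{0<|k|<=w} x_{t+k},

    is decreased by the multiplicative nonnegative-QP update applied to
    the split pair (with A+/A- the elementwise positive/negative parts of
    A_t and a = A+ x+ + A- x-, c = A- x+ + A+ x-):

        x+ <- x+ (b + sqrt(b^2 + 4 a c)) / (2 a),
        x- <- x- (-b + sqrt(b^2 + 4 a c)) / (2 c).

    Nonnegativity is preserved exactly by the multiplicative form and the
    objective is non-increasing at every sweep.  Since the objective is
    convex, the converged solution is independent of the random positive
    initialization (``init_seed`` only affects the iteration count).

    Stops when the relative objective change per sweep drops below
    ``tol`` or after ``max_iter`` sweeps.
    """
    R = np.asarray(R, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be (body_nodes, T)")
    n, T = R.shape[1], Y.shape[1]
    if not (lam_s >= 0 and lam_t >= 0):
        raise ValueError("regularization weights must be nonnegative")
    pen = temporal_coupling(T, w)
    L = _lap_array(laplacian, n)
    A_s = R.T @ R + lam_s * L.T @ L
    A_s = (A_s + A_s.T) / 2.0
    Apos = np.maximum(A_s, 0.0)
    Aneg = np.maximum(-A_s, 0.0)
    RtY = R.T @ Y
    n_pairs = np.array([pen.pair_count(t) for t in range(T)], dtype=float)
    nbrs = [pen.neighbor_indices(t) for t in range(T)]

    rng = np.random.default_rng(init_seed)
    Xp = rng.uniform(0.0, 1.0, size=(n, T))
    Xn = rng.uniform(0.0, 1.0, size=(n, T))

    def objective() -> float:
        return stre_objective(R, Y, L, lam_s, lam_t, w, Xp - Xn)

    trace = [objective()]
    converged = False
    for sweep in range(max_iter):
        for t in range(T):
            xp, xn = Xp[:, t], Xn[:, t]
            s = lam_t * n_pairs[t]
            P = Apos @ np.column_stack([xp, xn])
            Nn = Aneg @ np.column_stack([xp, xn])
            a = P[:, 0] + Nn[:, 1] + s * xp
            c = Nn[:, 0] + P[:, 1] + s * xn
            b = RtY[:, t]
            if lam_t != 0 and len(nbrs[t]):
                b = b + lam_t * (Xp[:, nbrs[t]] - Xn[:, nbrs[t]]).sum(axis=1)
            root = np.sqrt(b * b + 4.0 * a * c)
            Xp[:, t] = xp * (b + root) / (2.0 * a + _EPS_FLOOR)
            Xn[:, t] = xn * (-b + root) / (2.0 * c + _EPS_FLOOR)
        obj = objective()
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"objective became non-finite at sweep {sweep + 1} "
                f"(previous value {trace[-1]:.6g})")
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(abs(trace[-2]), 1e-30):
            converged = True
            break
    X = Xp - Xn
    grad = 2.0 * (A_s @ X + lam_t * X @ pen.coupling_matrix() - RtY)
    res = SolveResult(x=X, objective_trace=trace, n_iter=len(trace) - 1,
                      converged=converged,
                      grad_norm=float(np.linalg.norm(grad) /
                                      max(np.linalg.norm(2 * RtY), 1e-30)))
    res.x_pos, res.x_neg = Xp, Xn
    return res


# ---------------------------------------------------------------------------
# estimator layer
# ---------------------------------------------------------------------------

class _InverseEstimator(BaseEstimator):
    """Shared plumbing: fit(R, Y) stores the reconstruction in ``X_``."""

    def fit(self, R, Y):
        R = np.asarray(R, dtype=float)
        Y2, _ = _as_matrix(Y)
        if Y2.shape[0] != R.shape[0]:
            raise ValueError(
                f"Y has {Y2.shape[0]} rows but R maps to {R.shape[0]} body nodes")
        self.R_ = R
        self._solve(R, Y2)
        return self

    def predict(self, R=None) -> np.ndarray:
        """Forward-project the fitted heart potentials to the body surface."""
        R = self.R_ if R is None else np.asarray(R, dtype=float)
        return R @ self.X_


class TikhonovInverse(_InverseEstimator):
    """Tikhonov-regularized inversion (order 0: ridge; order 1: gradient penalty).

    Parameters
    ----------
    lam : float
        Penalty weight on ||G x||^2.
    order : {0, 1}
        Order 0 uses the identity constraint; order 1 requires ``operator``.
    operator : array_like, optional
        Constraint operator G (normal-derivative, bidiagonal, Laplacian...).
    """

    def __init__(self, lam: float = 1e-3, order: int = 0, operator=None):
        self.lam = lam
        self.order = order
        self.operator = operator

    def _solve(self, R, Y):
        self.X_ = solve_tikhonov(R, Y, gamma=self.operator, lam=self.lam,
                                 order=self.order)


class L1Inverse(_InverseEstimator):
    """First-order L1-regularized inversion solved by ADMM."""

    def __init__(self, lam: float = 1e-3, operator=None, rho: float | None = None,
                 max_iter: int = 2000, tol: float = 1e-8):
        self.lam = lam
        self.operator = operator
        self.rho = rho
        self.max_iter = max_iter
        self.tol = tol

    def _solve(self, R, Y):
        res = solve_l1_first_order(R, Y, self.operator, self.lam, rho=self.rho,
                                   max_iter=self.max_iter, tol=self.tol)
        self.X_ = res.x
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.objective_trace_ = res.objective_trace


class STREInverse(_InverseEstimator):
    """Spatiotemporal (surface-Laplacian + windowed temporal) inversion.

    Parameters
    ----------
    lambda_s, lambda_t : float
        Spatial and temporal penalty weights.
    window : int
        Temporal coupling window w.
    laplacian : array_like or LaplacianMatrix
        Mesh surface-Laplacian of the heart surface.
    method : {"direct", "mu"}
        Exact spectral solve, or the dipole multiplicative update (the two
        agree to the update's convergence tolerance).
    """

    def __init__(self, lambda_s: float = 0.015, lambda_t: float = 0.5,
                 window: int = 2, laplacian=None, method: str = "direct",
                 seed: int = 0, max_iter: int = 5000, tol: float = 1e-8):
        self.lambda_s = lambda_s
        self.lambda_t = lambda_t
        self.window = window
        self.laplacian = laplacian
        self.method = method
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol

    def _solve(self, R, Y):
        if self.method == "direct":
            self.X_ = solve_stre_direct(R, Y, self.laplacian, self.lambda_s,
                                        self.lambda_t, self.window)
            self.converged_ = True
        elif self.method == "mu":
            res = solve_stre_dipole_mu(R, Y, self.laplacian, self.lambda_s,
                                       self.lambda_t, self.window,
                                       init_seed=self.seed,
                                       max_iter=self.max_iter, tol=self.tol)
            self.X_ = res.x
            self.converged_ = res.converged
            self.n_iter_ = res.n_iter
            self.objective_trace_ = res.objective_trace
        else:
            raise ValueError(f"unknown method {self.method!r}")

    def objective(self, Y) -> float:
        Y2, _ = _as_matrix(Y)
        return stre_objective(self.R_, Y2, self.laplacian, self.lambda_s,
                              self.lambda_t, self.window, self.X_)
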