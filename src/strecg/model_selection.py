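"""L-curve selection of regularization parameters.

For a sweep of penalty weights, plot log residual norm ||R x_hat - y||
against log penalty norm; the corner of maximum curvature balances data
fit against regularity.  For the spatiotemporal model the two weights are
selected by alternating one-dimensional sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass
class LCurvePoint:
    """One sweep point: weight, residual norm, penalty (constraint) norm."""

    lam: float
    residual_norm: float
    penalty_norm: float
    failed: bool = False


def l_curve_sweep(solver, lam_grid) -> list:
    """Evaluate a solver across a sorted positive weight grid.

    ``solver(lam)`` must return ``(residual_norm, penalty_norm)``.  A
    solver failure at one grid point flags the point and continues.
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    if np.any(lam_grid <= 0) or np.any(np.diff(lam_grid) <= 0):
        raise ValueError("lam_grid must be positive and strictly increasing")
    points = []
    for lam in lam_grid:
        try:
            resid, pen = solver(float(lam))
            points.append(LCurvePoint(float(lam), float(resid), float(pen)))
        except Exception as exc:  # noqa: BLE001 - sweep must survive one failure
            warnings.warn(f"solver failed at lam={lam:g}: {exc}")
            points.append(LCurvePoint(float(lam), np.nan, np.nan, failed=True))
    return points


def l_curve_corner(points) -> float:
    """Weight at the corner (maximum curvature) of the log-log L-curve.

    Cubic splines are fit through (log lam) -> (log residual, log penalty)
    and the signed curvature kappa = (x' y'' - y' x'') / (x'^2 + y'^2)^1.5
    is evaluated at the grid points; the returned weight is the grid point
    of maximum convex curvature.  Degenerate (collinear) curves fall back
    to the mid-grid weight with a warning.
    """
    pts = [p for p in points if not p.failed and p.residual_norm > 0
           and p.penalty_norm > 0]
    if len(pts) < 5:
        raise ValueError("corner detection needs at least 5 valid sweep points")
    lam = np.array([p.lam for p in pts])
    x = np.log10([p.residual_norm for p in pts])
    y = np.log10([p.penalty_norm for p in pts])
    t = np.log10(lam)
    sx, sy = CubicSpline(t, x), CubicSpline(t, y)
    x1, y1 = sx(t, 1), sy(t, 1)
    x2, y2 = sx(t, 2), sy(t, 2)
    kappa = (x1 * y2 - y1 * x2) / np.maximum((x1**2 + y1**2) ** 1.5, 1e-30)
    # the L-curve corner is convex toward the origin: curvature positive with
    # x increasing / y decreasing parametrization
    finite = kappa[np.isfinite(kappa)]
    if finite.size == 0 or finite.max() <= 1e-9:
        warnings.warn("no convex corner found on the L-curve; returning the "
                      "mid-grid weight")
        return float(lam[len(lam) // 2])
    return float(lam[int(np.nanargmax(kappa))])


def select_lambda(solver, lam_grid) -> float:
    """Convenience: sweep then pick the corner weight."""
    return l_curve_corner(l_curve_sweep(solver, lam_grid))


def select_lambda_pair(solver2d, ls_grid, lt_grid, ls0: float, lt0: float,
                       rounds: int = 3) -> tuple[float, float]:
    """Alternating 1-D L-curve selection of a (spatial, temporal) pair.

    ``solver2d(lam_s, lam_t)`` returns (residual_norm, penalty_norm) for
    the penalty being swept.  Sweeps lam_s at fixed lam_t, then lam_t at
    fixed lam_s, up to ``rounds`` times or until a fixed point.
    """
    ls, lt = ls0, lt0
    for _ in range(rounds):
        new_ls = select_lambda(lambda a: solver2d(a, lt), ls_grid)
        new_lt = select_lambda(lambda b: solver2d(new_ls, b), lt_grid)
        if new_ls == ls and new_lt == lt:
            break
        ls, lt = new_ls, new_lt
    return ls, lt
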