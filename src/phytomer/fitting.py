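"""Nonlinear least squares for the logistic coordination curves.

Two fits are used throughout: the two-parameter logistic
``y = 1 / (1 + exp((x0 - x) / b))`` for the time course of fraction of
final length, and the three-parameter version with a free amplitude for
the component-coordination curves.  Positivity of ``b`` (and ``a``) is
enforced by optimizing on the log scale; scipy's Levenberg-Marquardt /
trust-region machinery does the minimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .growth_model import LinearCurve, SigmoidCurve

__all__ = ["FitResult", "ConvergenceError", "fit_sigmoid2", "fit_sigmoid3", "fit_linear"]


class ConvergenceError(RuntimeError):
    """Raised when a curve cannot be fitted to the data."""


@dataclass(frozen=True)
class FitResult:
    curve: SigmoidCurve | LinearCurve
    r_squared: float
    residual_standard_error: float
    n_points: int
    converged: bool
    iterations: int

    def to_dict(self) -> dict:
        c = self.curve
        params = (
            {"a": c.amplitude, "x0": c.midpoint, "b": c.scale}
            if isinstance(c, SigmoidCurve)
            else {"slope": c.slope, "intercept": c.intercept}
        )
        return {
            **params,
            "r_squared": self.r_squared,
            "residual_standard_error": self.residual_standard_error,
            "n_points": self.n_points,
        }


def _as_xy(x, y=None):
    if y is None:
        pts = np.asarray(x, dtype=float)
        x, y = pts[:, 0], pts[:, 1]
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def _gof(y, residuals, n_params) -> tuple[float, float]:
    ssr = float(np.sum(residuals**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    dof = len(y) - n_params
    rse = float(np.sqrt(ssr / dof)) if dof > 0 else float("nan")
    return max(min(r2, 1.0), 0.0), rse


def _init_x0_b(x, y, amplitude) -> tuple[float, float]:
    """Data-driven start values: half-range crossing and central slope."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    half = 0.5 * amplitude
    above = ys >= half
    if above.any() and (~above).any():
        i = int(np.argmax(above))
        x0 = xs[i] if i == 0 else 0.5 * (xs[i - 1] + xs[i])
    else:
        x0 = float(np.median(xs))
    lo, hi = np.quantile(xs, [0.25, 0.75])
    mid = (xs >= lo) & (xs <= hi)
    if mid.sum() >= 2 and np.ptp(xs[mid]) > 0:
        slope = np.polyfit(xs[mid], ys[mid], 1)[0]
    else:
        slope = np.polyfit(xs, ys, 1)[0] if np.ptp(xs) > 0 else 0.0
    # logistic slope at midpoint is a / (4 b)
    b = amplitude / (4.0 * slope) if slope > 0 else max(np.ptp(xs) / 4.0, 1e-3)
    b = float(np.clip(b, 1e-3, max(np.ptp(xs), 1.0) * 10))
    return float(x0), b


def _sigmoid(a, x0, b, x):
    return a / (1.0 + np.exp((x0 - x) / b))


def fit_sigmoid2(x, y=None, tol: float = 1e-12, max_iter: int = 500) -> FitResult:
    """Fit ``y = 1 / (1 + exp((x0 - x) / b))`` by least squares.

    Requires at least 4 points with responses on both sides of 0.5.
    """
    x, y = _as_xy(x, y)
    if len(x) < 4:
        raise ConvergenceError("need at least 4 points")
    if not ((y < 0.5).any() and (y > 0.5).any()):
        raise ConvergenceError("responses do not straddle the half amplitude")

    x0_init, b_init = _init_x0_b(x, y, 1.0)

    def resid(theta):
        x0, logb = theta
        return _sigmoid(1.0, x0, np.exp(logb), x) - y

    sol = least_squares(
        resid,
        [x0_init, np.log(b_init)],
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter * 3,
    )
    if not sol.success:
        raise ConvergenceError(f"sigmoid fit did not converge: {sol.message}")
    curve = SigmoidCurve(1.0, float(sol.x[0]), float(np.exp(sol.x[1])))
    r2, rse = _gof(y, sol.fun, 2)
    return FitResult(curve, r2, rse, len(y), True, int(sol.nfev))


def fit_sigmoid3(x, y=None, tol: float = 1e-12, max_iter: int = 500) -> FitResult:
    """Fit the three-parameter logistic ``y = a / (1 + exp((x0 - x) / b))``."""
    x, y = _as_xy(x, y)
    if len(x) < 5:
        raise ConvergenceError("need at least 5 points")
    if np.ptp(y) == 0:
        raise ConvergenceError("constant responses cannot constrain a sigmoid")

    a_init = 1.05 * float(y.max())
    if a_init <= 0:
        raise ConvergenceError("non-positive responses")
    x0_init, b_init = _init_x0_b(x, y, a_init)

    def resid(theta):
        loga, x0, logb = theta
        return _sigmoid(np.exp(loga), x0, np.exp(logb), x) - y

    sol = least_squares(
        resid,
        [np.log(a_init), x0_init, np.log(b_init)],
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter * 4,
    )
    if not sol.success:
        raise ConvergenceError(f"sigmoid fit did not converge: {sol.message}")
    curve = SigmoidCurve(float(np.exp(sol.x[0])), float(sol.x[1]), float(np.exp(sol.x[2])))
    r2, rse = _gof(y, sol.fun, 3)
    return FitResult(curve, r2, rse, len(y), True, int(sol.nfev))


def fit_linear(x, y=None) -> FitResult:
    """Ordinary least-squares straight line."""
    x, y = _as_xy(x, y)
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("need at least 2 distinct x values")
    slope, intercept = np.polyfit(x, y, 1)
    curve = LinearCurve(float(slope), float(intercept))
    r2, rse = _gof(y, curve(x) - y, 2)
    return FitResult(curve, r2, rse, len(y), True, 1)
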