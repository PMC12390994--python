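"""Piecewise sigmoid-growth / quadratic-decline model of panicle coverage.

Panicle coverage of a rice canopy rises sigmoidally after heading, plateaus,
and then declines as grains fill and panicles droop out of nadir view. The
model is

    f(x) = K / (1 + exp(-g (x - d0)))            for x <= d1
    f(x) = K / (1 + exp(-g (d1 - d0))) - a (x - d1)^2   for x > d1

with five parameters: K, the maximum coverage fraction reached during
growth; g, the steepness of the sigmoid (per day); d0, the day of maximum
growth rate (the inflection point, where f = K/2); d1, the day the curve
switches from growth to decline; and a, the curvature of the quadratic
decline (per day^2). The two branches agree at x = d1 by construction.

Fitting is bounded trust-region nonlinear least squares with data-driven
initial guesses. The d1 > d0 ordering is guaranteed by fitting the offset
delta = d1 - d0 > 0 instead of d1 itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PiecewiseParams",
    "FitResult",
    "evaluate",
    "initial_guess",
    "fit",
    "fit_table",
]


@dataclass(frozen=True)
class PiecewiseParams:
    """The five dynamic parameters of one plot's coverage curve.

    K : maximum coverage fraction (0 < K)
    g : sigmoid growth rate, per day (g > 0)
    d0 : day of maximum growth rate (inflection point)
    a : quadratic decline curvature, per day^2 (a >= 0)
    d1 : growth-to-decline transition day (d1 > d0)
    """

    K: float
    g: float
    d0: float
    a: float
    d1: float

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if not self.g > 0:
            raise ValueError(f"g must be > 0, got {self.g}")
        if self.a < 0:
            raise ValueError(f"a must be >= 0, got {self.a}")
        if not self.d1 > self.d0:
            raise ValueError(f"require d1 > d0, got d0={self.d0}, d1={self.d1}")

    def as_array(self) -> np.ndarray:
        return np.array([self.K, self.g, self.d0, self.a, self.d1])

    def as_dict(self) -> dict[str, float]:
        return {"K": self.K, "g": self.g, "d0": self.d0, "a": self.a, "d1": self.d1}


@dataclass
class FitResult:
    params: PiecewiseParams
    r_squared: float
    residuals: np.ndarray
    converged: bool
    n_obs: int
    bounds_hit: list[str] = field(default_factory=list)


def evaluate(params: PiecewiseParams, x) -> np.ndarray | float:
    """Model coverage at day(s) ``x``; raw value, not clamped to [0, 1].

    Vectorizes over ``x``. Past the transition the quadratic branch may go
    negative; callers that need a physical coverage clamp it themselves.
    """
    x_arr = np.asarray(x, dtype=float)
    sig = params.K / (1.0 + np.exp(-params.g * (x_arr - params.d0)))
    peak = params.K / (1.0 + np.exp(-params.g * (params.d1 - params.d0)))
    decline = peak - params.a * (x_arr - params.d1) ** 2
    out = np.where(x_arr <= params.d1, sig, decline)
    if np.isscalar(x) or x_arr.ndim == 0:
        return float(out)
    return out


class FitError(ValueError):
    """Raised when a coverage series cannot support the five-parameter fit."""


def initial_guess(days: np.ndarray, coverage: np.ndarray) -> PiecewiseParams:
    """Data-driven starting values for the five parameters.

    K0 is the observed maximum; d1_0 the day it occurs; d0_0 the first
    day coverage crosses K0/2 (linear interpolation between bracketing
    observations); g0 uses the logistic maximum-slope identity
    slope_max = g K / 4; a0 is the least-squares coefficient of
    (peak - coverage) on (day - d1_0)^2 over post-peak points, floored at 0.

    Raises FitError for series with no rise (constant or decreasing).
    """
    days = np.asarray(days, dtype=float)
    cov = np.asarray(coverage, dtype=float)
    if days.size < 5:
        raise FitError(f"need >= 5 observations for a 5-parameter fit, got {days.size}")
    k0 = float(np.max(cov))
    i_max = int(np.argmax(cov))
    slopes = np.diff(cov) / np.diff(days)
    if k0 <= 0 or np.max(slopes) <= 0:
        raise FitError("series shows no rise; cannot seed a growth-curve fit")
    d1_0 = float(days[i_max])

    # first upward crossing of K0/2, interpolated
    half = k0 / 2.0
    above = np.nonzero(cov >= half)[0]
    j = int(above[0])
    if j == 0:
        d0_0 = float(days[0])
    else:
        x0, x1 = days[j - 1], days[j]
        y0, y1 = cov[j - 1], cov[j]
        d0_0 = float(x0 + (half - y0) / (y1 - y0) * (x1 - x0)) if y1 > y0 else float(x1)

    g0 = float(4.0 * np.max(slopes) / k0)

    post = days > d1_0
    if np.any(post):
        z = (days[post] - d1_0) ** 2
        drop = k0 - cov[post]
        denom = float(z @ z)
        a0 = max(0.0, float(z @ drop) / denom) if denom > 0 else 0.0
    else:
        a0 = 0.0

    # d1 must strictly exceed d0; nudge degenerate orderings
    if d1_0 <= d0_0:
        d1_0 = d0_0 + 1.0
    return PiecewiseParams(K=k0, g=g0, d0=d0_0, a=a0, d1=d1_0)


def _residuals(theta: np.ndarray, days: np.ndarray, cov: np.ndarray) -> np.ndarray:
    k, g, d0, a, delta = theta
    d1 = d0 + delta
    sig = k / (1.0 + np.exp(-g * (days - d0)))
    peak = k / (1.0 + np.exp(-g * delta))
    pred = np.where(days <= d1, sig, peak - a * (days - d1) ** 2)
    return pred - cov


def fit(
    days,
    coverage,
    guess: PiecewiseParams | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> FitResult:
    """Fit the piecewise model to one coverage series by bounded least squares.

    Default box bounds: K in (0, 1], g in (0, 5], d0 in [0, max day],
    delta = d1 - d0 in (0, max day + 10], a in [0, 0.05]. ``bounds`` may
    override any of K, g, d0, a, delta. Non-convergence is reported via
    ``converged=False`` with the best parameters found, never an exception.
    """
    days = np.asarray(days, dtype=float)
    cov = np.asarray(coverage, dtype=float)
    if days.shape != cov.shape or days.ndim != 1:
        raise ValueError("days and coverage must be 1-D arrays of equal length")
    if days.size < 5:
        raise FitError(f"need >= 5 observations, got {days.size}")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")

    if guess is None:
        guess = initial_guess(days, cov)
    dmax = float(days.max())
    eps = 1e-9
    default_bounds = {
        "K": (eps, 1.0),
        "g": (eps, 5.0),
        "d0": (0.0, dmax),
        "a": (0.0, 0.05),
        "delta": (eps, dmax + 10.0),
    }
    if bounds:
        default_bounds.update(bounds)
    names = ["K", "g", "d0", "a", "delta"]
    lo = np.array([default_bounds[n][0] for n in names])
    hi = np.array([default_bounds[n][1] for n in names])

    theta0 = np.array(
        [guess.K, guess.g, guess.d0, guess.a, guess.d1 - guess.d0]
    )
    theta0 = np.clip(theta0, lo, hi)
    # reorder to solver layout (K, g, d0, a, delta)
    x0 = np.array([theta0[0], theta0[1], theta0[2], theta0[3], theta0[4]])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sol = least_squares(
            _residuals,
            x0,
            bounds=(lo, hi),
            args=(days, cov),
            method="trf",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=20000,
        )

    k, g, d0, a, delta = sol.x
    params = PiecewiseParams(K=k, g=g, d0=d0, a=a, d1=d0 + delta)
    resid = _residuals(sol.x, days, cov)
    sstot = float(np.sum((cov - cov.mean()) ** 2))
    ssres = float(resid @ resid)
    r2 = 1.0 - ssres / sstot if sstot > 0 else float("nan")
    tol = 1e-8
    bounds_hit = [
        n
        for n, v, l, h in zip(names, sol.x, lo, hi)
        if (v - l) < tol * max(1.0, abs(h - l)) or (h - v) < tol * max(1.0, abs(h - l))
    ]
    return FitResult(
        params=params,
        r_squared=r2,
        residuals=resid,
        converged=bool(sol.success),
        n_obs=days.size,
        bounds_hit=bounds_hit,
    )


def fit_table(series_list, guesses=None):
    """Fit many coverage series and tabulate parameters plus R^2.

    ``series_list`` is an iterable of objects with ``plot_id``, ``days`` and
    ``coverage`` attributes (see coverage_extraction.CoverageSeries) or
    (plot_id, days, coverage) triples. Per-series failures are recorded as
    flagged rows and the run continues.

    Returns a pandas DataFrame with columns
    plot_id, K, g, d0, a, d1, r_squared, converged, error.
    """
    import pandas as pd

    series_list = list(series_list)
    if not series_list:
        raise ValueError("fit_table requires at least one series")
    rows = []
    for i, s in enumerate(series_list):
        if hasattr(s, "plot_id"):
            pid, days, cov = s.plot_id, s.days, s.coverage
        else:
            pid, days, cov = s
        guess = None if guesses is None else guesses[i]
        try:
            res = fit(days, cov, guess=guess)
            rows.append(
                {
                    "plot_id": pid,
                    **res.params.as_dict(),
                    "r_squared": res.r_squared,
                    "converged": res.converged,
                    "error": "",
                }
            )
        except (FitError, ValueError) as exc:
            rows.append(
                {
                    "plot_id": pid,
                    "K": np.nan,
                    "g": np.nan,
                    "d0": np.nan,
                    "a": np.nan,
                    "d1": np.nan,
                    "r_squared": np.nan,
                    "converged": False,
                    "error": str(exc),
                }
            )
    cols = ["plot_id", "K", "g", "d0", "a", "d1", "r_squared", "converged", "error"]
    return pd.DataFrame(rows, columns=cols)
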