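"""Marginal yield analysis: difference quotients and the two marginal models.

The marginal yield dY/dX (kg grain per kg nutrient) is approximated between
adjacent rates as the difference quotient (Y[i+1] - Y[i]) / (X[i+1] - X[i]),
assigned to the upper endpoint X[i+1] of the interval. Two models of how the
marginal yield declines with rate are fitted:

* linear, ``dY/dX = a + b X`` -- the assumption implicit in a quadratic
  yield curve (a = b1, b = 2 b2); and
* exponential, ``dY/dX = A [1 - c (s0 + X)] exp(-c X)`` -- the derivative of
  the non-structural response curve, which keeps the early near-linear drop
  but lets the decline flatten at high rates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import (
    DEFAULT_C_BOUNDS,
    DEFAULT_GRID_SIZE,
    FitError,
    FitStatistics,
    NSFMParameters,
    fit_statistics,
    separable_exp_fit,
)
from .trials import FertilizerTrial

__all__ = [
    "MarginalSeries",
    "LinearMarginalFit",
    "ExpMarginalFit",
    "marginal_series",
    "fit_marginal_linear",
    "fit_marginal_exp",
]


@dataclass(frozen=True)
class MarginalSeries:
    """Difference quotients dY/dX with their assigned (upper-endpoint) rates."""

    x: tuple[float, ...]
    dydx: tuple[float, ...]
    source_trial: str

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class LinearMarginalFit:
    """OLS line dY/dX = a + b X (kg/kg and (kg/kg) per (kg/hm2))."""

    a: float
    b: float
    stats: FitStatistics


@dataclass(frozen=True)
class ExpMarginalFit:
    """Exponential marginal model dY/dX = A [1 - c (s0 + X)] exp(-c X)."""

    params: NSFMParameters
    stats: FitStatistics
    flags: tuple[str, ...] = ()


def marginal_series(trial: FertilizerTrial) -> MarginalSeries:
    """Per-interval yield increase per unit nutrient for one trial.

    The quotient over interval i is assigned to the interval's upper rate
    X[i+1]; this is the convention under which the fitted line's intercept
    matches published marginal analyses of these trials (a midpoint or
    lower-endpoint assignment shifts the intercept by b dX/2 or b dX for
    equally spaced designs). Unequal spacing is handled by dividing by the
    actual rate difference.
    """
    x = np.asarray(trial.rates, dtype=float)
    y = np.asarray(trial.yields, dtype=float)
    d = np.diff(y) / np.diff(x)
    return MarginalSeries(
        x=tuple(x[1:]), dydx=tuple(d), source_trial=trial.trial_id
    )


def fit_marginal_linear(series: MarginalSeries) -> LinearMarginalFit:
    """Ordinary least squares of dY/dX on rate."""
    x = np.asarray(series.x, dtype=float)
    d = np.asarray(series.dydx, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two marginal points")
    if np.ptp(x) == 0:
        raise FitError(f"{series.source_trial}: all rates identical")
    design = np.column_stack([np.ones_like(x), x])
    (a, b), _, _, _ = np.linalg.lstsq(design, d, rcond=None)
    pred = a + b * x
    if len(x) > 2:
        stats = fit_statistics(d, pred, p=2)
    else:
        # exact interpolation: two points, two parameters
        sse = float(np.sum((d - pred) ** 2))
        sst = float(np.sum((d - d.mean()) ** 2))
        stats = FitStatistics(
            n=2, p=2, sse=sse, sst=sst, r2=1.0, f=float("inf"), s=0.0
        )
    return LinearMarginalFit(a=float(a), b=float(b), stats=stats)


def fit_marginal_exp(
    series: MarginalSeries,
    c_bounds: tuple[float, float] = DEFAULT_C_BOUNDS,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> ExpMarginalFit:
    """Variable-projection fit of the exponential marginal model.

    For fixed c the model is linear in ``(u, v) = (A (1 - c s0), A c)`` via
    ``dY/dX = (u - v X) exp(-c X)``; the SSE is profiled over c and the
    original parameters recovered as ``A = v / c``, ``s0 = 1/c - u/v``.
    Requires at least four points (three parameters plus one residual df).
    """
    x = np.asarray(series.x, dtype=float)
    d = np.asarray(series.dydx, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least four marginal points")
    # basis (e^{-cx}, x e^{-cx}) with coefficients (u, -v)
    u, mv, c, sse, at_bound = separable_exp_fit(
        x, d, c_bounds=c_bounds, grid_size=grid_size
    )
    v = -mv
    if v <= 0:
        raise FitError(
            f"{series.source_trial}: marginal decline coefficient v <= 0"
        )
    params = NSFMParameters(A=v / c, c=c, s0=1.0 / c - u / v)
    pred = (u + mv * x) * np.exp(-c * x)
    stats = fit_statistics(d, pred, p=3)
    flags = ("c_at_bound",) if at_bound else ()
    return ExpMarginalFit(params=params, stats=stats, flags=flags)
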