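"""Yield-response models and their estimators.

Two unary dose-response curves for grain yield Y (kg/hm2) against nutrient
application rate X (kg/hm2):

* the classical quadratic polynomial ``Y = b0 + b1 X + b2 X^2`` (QPFM), and
* the non-structural exponential model ``Y = A (s0 + X) exp(-c X)`` (NSFM),
  where ``s0`` is the soil nutrient supply expressed in fertilizer-equivalent
  kg/hm2, ``c > 0`` (hm2/kg) controls the diminishing-returns decay, and
  ``A`` converts soil-equivalent nutrient into yield.

The NSFM is fitted by separable (variable-projection) least squares: for a
fixed decay ``c`` the model ``Y = (p + q X) exp(-c X)`` is linear in
``(p, q) = (A s0, A)``, so the sum of squares is profiled over ``c`` with a
dense log-spaced grid followed by bounded 1-D refinement. This is
deterministic and global over the searched interval, with no dependence on
starting values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sps

from .trials import FertilizerTrial

__all__ = [
    "QPFMParameters",
    "NSFMParameters",
    "FitStatistics",
    "FitResult",
    "FitError",
    "predict_qpfm",
    "predict_nsfm",
    "fit_qpfm",
    "fit_nsfm",
    "fit_statistics",
    "taylor_qpfm_of_nsfm",
    "DEFAULT_C_BOUNDS",
    "DEFAULT_GRID_SIZE",
]

#: default search interval for the decay coefficient c (hm2/kg); covers the
#: 1.9e-3 .. 7.4e-3 range seen in field trials with a wide margin
DEFAULT_C_BOUNDS = (1e-5, 5e-2)
DEFAULT_GRID_SIZE = 400


class FitError(RuntimeError):
    """A model fit failed (rank deficiency, inadmissible parameters...)."""


@dataclass(frozen=True)
class QPFMParameters:
    """Quadratic polynomial coefficients: Y = b0 + b1 X + b2 X^2."""

    b0: float
    b1: float
    b2: float


@dataclass(frozen=True)
class NSFMParameters:
    """Exponential response parameters: Y = A (s0 + X) exp(-c X).

    ``A`` > 0 (kg yield per kg soil-equivalent nutrient), ``c`` > 0 (hm2/kg),
    ``s0`` any real (kg/hm2; negative values signal poor identifiability and
    are flagged by the fitters, not rejected here). The antiderivative's
    integration constant is identically zero, so Y -> 0 as (s0 + X) -> 0.
    """

    A: float
    c: float
    s0: float

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"c must be positive, got {self.c}")


@dataclass(frozen=True)
class FitStatistics:
    """Goodness-of-fit summary for a fitted response model.

    ``s = sqrt(sse / (n - p))`` is the residual standard deviation and
    ``f = (r2 / (1 - r2)) * (n - p) / (p - 1)`` the regression-vs-residual
    mean-square ratio on (p - 1, n - p) degrees of freedom.
    """

    n: int
    p: int
    sse: float
    sst: float
    r2: float
    f: float
    s: float

    def p_value(self) -> float:
        """Upper-tail probability of ``f`` under F(p-1, n-p)."""
        return float(sps.f.sf(self.f, self.p - 1, self.n - self.p))

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value() < alpha

    @property
    def stars(self) -> str:
        """'**' below the 0.01 level, '*' below 0.05, '' otherwise."""
        pv = self.p_value()
        return "**" if pv < 0.01 else "*" if pv < 0.05 else ""


@dataclass(frozen=True)
class FitResult:
    """Parameters plus statistics; unpacks as ``params, stats = result``."""

    params: QPFMParameters | NSFMParameters
    stats: FitStatistics
    flags: tuple[str, ...] = ()

    def __iter__(self):
        return iter((self.params, self.stats))


def predict_qpfm(params: QPFMParameters, X) -> np.ndarray | float:
    X = np.asarray(X, dtype=float)
    out = params.b0 + params.b1 * X + params.b2 * X**2
    return float(out) if out.ndim == 0 else out


def predict_nsfm(params: NSFMParameters, X) -> np.ndarray | float:
    X = np.asarray(X, dtype=float)
    out = params.A * (params.s0 + X) * np.exp(-params.c * X)
    return float(out) if out.ndim == 0 else out


def fit_statistics(observed, predicted, p: int) -> FitStatistics:
    """Residual statistics for ``n`` observations under a ``p``-parameter fit.

    Requires n > p (at least one residual degree of freedom).
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    n = y.size
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    f = (r2 / (1.0 - r2)) * (n - p) / (p - 1) if r2 < 1.0 else math.inf
    s = math.sqrt(sse / (n - p))
    return FitStatistics(n=n, p=p, sse=sse, sst=sst, r2=r2, f=f, s=s)


def fit_qpfm(trial: FertilizerTrial) -> FitResult:
    """Ordinary least squares of yields on (1, X, X^2).

    Solved by orthogonal decomposition (``numpy.linalg.lstsq``), not normal
    equations. Requires at least four distinct rates.
    """
    x = np.asarray(trial.rates, dtype=float)
    y = np.asarray(trial.yields, dtype=float)
    design = np.column_stack([np.ones_like(x), x, x**2])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3:
        raise FitError(f"{trial.trial_id}: rank-deficient quadratic design")
    params = QPFMParameters(*map(float, coef))
    stats = fit_statistics(y, design @ coef, p=3)
    return FitResult(params=params, stats=stats)


def _profiled_linear(x: np.ndarray, y: np.ndarray, c: float):
    """Least-squares (p, q) of y ~ (p + q x) e^(-c x); returns (sse, p, q)."""
    e = np.exp(-c * x)
    design = np.column_stack([e, x * e])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), float(coef[0]), float(coef[1])


def separable_exp_fit(
    x,
    y,
    c_bounds: tuple[float, float] = DEFAULT_C_BOUNDS,
    grid_size: int = DEFAULT_GRID_SIZE,
    include_c: float | None = None,
):
    """Variable-projection fit of ``y = (p + q x) exp(-c x)``.

    Profiles the SSE over a log-spaced grid of ``c`` in ``c_bounds``
    (widened if needed so that ``include_c`` is covered), then refines the
    minimiser inside the bracketing grid cell with bounded scalar
    minimisation. Returns ``(p, q, c, sse, at_bound)`` where ``at_bound``
    marks a profile minimum pinned to an end of the searched interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo, hi = c_bounds
    if not (0 < lo < hi):
        raise ValueError("c_bounds must satisfy 0 < lo < hi")
    if include_c is not None and include_c > 0:
        lo, hi = min(lo, include_c), max(hi, include_c)
    grid = np.logspace(math.log10(lo), math.log10(hi), grid_size)
    sses = np.array([_profiled_linear(x, y, c)[0] for c in grid])
    i = int(np.argmin(sses))
    at_bound = i in (0, grid_size - 1)
    lo_b = grid[max(i - 1, 0)]
    hi_b = grid[min(i + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        lambda c: _profiled_linear(x, y, c)[0],
        bounds=(lo_b, hi_b),
        method="bounded",
        options={"xatol": 1e-12},
    )
    c = float(res.x) if res.fun <= sses[i] else float(grid[i])
    sse, p, q = _profiled_linear(x, y, c)
    return p, q, c, sse, at_bound


def fit_nsfm(
    trial: FertilizerTrial,
    c_bounds: tuple[float, float] = DEFAULT_C_BOUNDS,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> FitResult:
    """Nonlinear least squares of the exponential response model.

    Uses the separable structure ``Y = (p + q X) exp(-c X)`` with
    ``(p, q) = (A s0, A)``; the searched ``c`` interval is widened, if
    necessary, to cover the quadratic-seeded value ``c0 = -b2 / b1`` implied
    by the second-order series of the model. A fit with ``A <= 0`` is
    rejected; a profile optimum pinned at a ``c`` bound is flagged
    ``c_at_bound``, and a negative recovered ``s0`` is flagged
    ``negative_s0``.
    """
    x = np.asarray(trial.rates, dtype=float)
    y = np.asarray(trial.yields, dtype=float)

    include_c = None
    try:
        qp, _ = fit_qpfm(trial)
        if qp.b1 > 0 and qp.b2 < 0:
            include_c = -qp.b2 / qp.b1
    except FitError:
        pass

    p, q, c, sse, at_bound = separable_exp_fit(
        x, y, c_bounds=c_bounds, grid_size=grid_size, include_c=include_c
    )
    if q <= 0:
        raise FitError(
            f"{trial.trial_id}: fitted conversion coefficient A={q:.4g} <= 0"
        )
    params = NSFMParameters(A=q, c=c, s0=p / q)
    stats = fit_statistics(y, predict_nsfm(params, x), p=3)
    flags = []
    if at_bound:
        flags.append("c_at_bound")
    if params.s0 < 0:
        flags.append("negative_s0")
    return FitResult(params=params, stats=stats, flags=tuple(flags))


def taylor_qpfm_of_nsfm(params: NSFMParameters) -> QPFMParameters:
    """Second-order series of the exponential model about X = 0.

    Truncating ``exp(-cX)`` after its linear term maps the exponential model
    onto the quadratic ``Y = A s0 + A (1 - c s0) X - A c X^2``, showing the
    quadratic polynomial to be a small-(cX) special case. The truncation
    remainder grows with c X, which is where the two models part ways.
    """
    return QPFMParameters(
        b0=params.A * params.s0,
        b1=params.A * (1.0 - params.c * params.s0),
        b2=-params.A * params.c,
    )
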