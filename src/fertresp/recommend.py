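"""Recommended fertilization rates and quadratic-model typicality checks.

Two recommended rates are derived from a fitted response curve:

* the agronomic maximum ``X_max`` at which predicted yield peaks
  (``1/c - s0`` for the exponential model, ``-b1 / (2 b2)`` for the
  quadratic); and
* the economic optimum ``X_eco`` at which the marginal yield equals the
  nutrient/product price ratio ``beta = Px / Py``. For the exponential model
  ``X_eco = 1 / (c + beta / Y_eco) - s0`` with ``Y_eco`` unknown a priori; it
  is resolved by fixed-point iteration started from ``Y_max``, which
  typically settles in 3-5 rounds.

A fitted quadratic is *typical* when it obeys the agronomic sign and range
conditions (positive linear term, negative quadratic term, interior maximum
and recommended rates inside the tested design); otherwise its
recommendations are unreliable extrapolations.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .models import NSFMParameters, QPFMParameters, FitStatistics, predict_nsfm, predict_qpfm
from .trials import FertilizerTrial

__all__ = [
    "PriceContext",
    "Recommendation",
    "TypicalityReport",
    "ConvergenceError",
    "xmax_nsfm",
    "xeco_nsfm",
    "xmax_qpfm",
    "xeco_qpfm",
    "classify_qpfm",
]

DEFAULT_TOL = 0.01  # kg/hm2, far below agronomic relevance
DEFAULT_MAX_ITER = 50


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge; carries the iterate trace."""

    def __init__(self, message: str, trace: tuple[float, ...]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class PriceContext:
    """Market prices: px per kg nutrient, py per kg product (same currency)."""

    px: float
    py: float

    def __post_init__(self) -> None:
        if self.px <= 0 or self.py <= 0:
            raise ValueError("prices must be positive")

    @property
    def beta(self) -> float:
        """Price ratio px/py, in kg product per kg nutrient."""
        return self.px / self.py


def _beta_of(prices: "PriceContext | float") -> float:
    """Price ratio from a PriceContext or a bare non-negative beta."""
    beta = prices.beta if isinstance(prices, PriceContext) else float(prices)
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return beta


@dataclass(frozen=True)
class Recommendation:
    """Recommended rates (kg/hm2) and the yields they achieve."""

    x_max: float
    y_max: float
    x_eco: float | None = None
    y_eco: float | None = None
    beta: float | None = None
    n_iterations: int = 0
    converged: bool = True
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class TypicalityReport:
    """Sign/range diagnostics for a fitted quadratic response model."""

    monomial_positive: bool
    quadratic_negative: bool
    max_in_range: bool
    rates_in_design: bool
    typical: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "typical",
            self.monomial_positive
            and self.quadratic_negative
            and self.max_in_range
            and self.rates_in_design,
        )


def xmax_nsfm(params: NSFMParameters) -> Recommendation:
    """Agronomic maximum for the exponential model: X_max = 1/c - s0.

    A negative X_max (soil already supplies more than the optimum; seen on
    high-fertility plots) is reported as-is with a ``negative_rate`` flag
    rather than clipped, preserving the agronomic signal.
    """
    x_max = 1.0 / params.c - params.s0
    flags = ("negative_rate",) if x_max < 0 else ()
    return Recommendation(
        x_max=x_max, y_max=float(predict_nsfm(params, x_max)), flags=flags
    )


def xeco_nsfm(
    params: NSFMParameters,
    prices: PriceContext | float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> Recommendation:
    """Economic optimum by fixed-point iteration.

    Starts from ``Y_max`` and repeats ``X <- 1/(c + beta/Y) - s0``,
    ``Y <- predict(X)`` until successive rates differ by less than ``tol``
    (default 0.01 kg/hm2). At the fixed point the marginal yield equals
    beta exactly. ``beta = 0`` reduces to the agronomic maximum in one step.
    """
    beta = _beta_of(prices)
    base = xmax_nsfm(params)
    y = base.y_max
    x_prev = base.x_max
    trace = [x_prev]
    for k in range(1, max_iter + 1):
        x = 1.0 / (params.c + beta / y) - params.s0
        y = float(predict_nsfm(params, x))
        trace.append(x)
        if abs(x - x_prev) < tol:
            flags = ("negative_rate",) if x < 0 else ()
            return Recommendation(
                x_max=base.x_max,
                y_max=base.y_max,
                x_eco=x,
                y_eco=y,
                beta=beta,
                n_iterations=k,
                converged=True,
                flags=flags,
            )
        x_prev = x
    raise ConvergenceError(
        f"economic-rate iteration did not converge in {max_iter} steps",
        tuple(trace),
    )


def xmax_qpfm(params: QPFMParameters) -> Recommendation:
    """Agronomic maximum for the quadratic model: X_max = -b1 / (2 b2)."""
    if params.b2 >= 0:
        raise ValueError("no interior maximum: b2 must be negative")
    x_max = -params.b1 / (2.0 * params.b2)
    flags = ("negative_rate",) if x_max < 0 else ()
    return Recommendation(
        x_max=x_max, y_max=float(predict_qpfm(params, x_max)), flags=flags
    )


def xeco_qpfm(params: QPFMParameters, prices: PriceContext | float) -> Recommendation:
    """Economic optimum for the quadratic model, in closed form.

    Setting the marginal yield b1 + 2 b2 X equal to beta gives
    ``X_eco = (beta - b1) / (2 b2)``; a negative solution is clipped to 0
    and flagged.
    """
    if params.b2 >= 0:
        raise ValueError("no interior maximum: b2 must be negative")
    base = xmax_qpfm(params)
    beta = _beta_of(prices)
    x_eco = (beta - params.b1) / (2.0 * params.b2)
    flags: tuple[str, ...] = ()
    if x_eco < 0:
        x_eco = 0.0
        flags = ("clipped_to_zero",)
    return Recommendation(
        x_max=base.x_max,
        y_max=base.y_max,
        x_eco=x_eco,
        y_eco=float(predict_qpfm(params, x_eco)),
        beta=beta,
        n_iterations=1,
        converged=True,
        flags=flags,
    )


def classify_qpfm(
    params: QPFMParameters,
    stats: FitStatistics,
    trial: FertilizerTrial,
    prices: PriceContext | float | None = None,
) -> TypicalityReport:
    """Check the four typicality conditions of a fitted quadratic model.

    (1) b1 > 0; (2) b2 < 0; (3) the interior maximum falls inside the tested
    rate range; (4) the recommended rates (X_max, and X_eco when prices are
    given) lie within the design range. The range in (3) is read as the
    span of tested application rates, matching the design-scope wording of
    condition (4).
    """
    lo, hi = trial.rates[0], trial.rates[-1]
    monomial_positive = params.b1 > 0
    quadratic_negative = params.b2 < 0
    if quadratic_negative:
        x_max = -params.b1 / (2.0 * params.b2)
        max_in_range = lo <= x_max <= hi
        rates_in_design = max_in_range
        if prices is not None:
            x_eco = (_beta_of(prices) - params.b1) / (2.0 * params.b2)
            rates_in_design = rates_in_design and lo <= x_eco <= hi
    else:
        max_in_range = False
        rates_in_design = False
    return TypicalityReport(
        monomial_positive=monomial_positive,
        quadratic_negative=quadratic_negative,
        max_in_range=max_in_range,
        rates_in_design=rates_in_design,
    )
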