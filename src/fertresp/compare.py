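"""Batch model comparison across trials and published-table reproduction.

Fits both response models to every trial, pairs their recommended rates,
and summarises agreement (Pearson correlation of recommended rates, mean
exponential/quadratic rate ratios per nutrient). Published coefficient
tables for 18 rice and 9 winter-wheat trials are bundled so the comparisons
can also be run directly from reported coefficients when raw yields are not
available.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import (
    FitResult,
    FitError,
    NSFMParameters,
    QPFMParameters,
    fit_nsfm,
    fit_qpfm,
)
from .recommend import PriceContext, xeco_nsfm, xeco_qpfm, xmax_nsfm, xmax_qpfm
from .trials import FertilizerTrial

__all__ = [
    "ComparisonRow",
    "CorrelationSummary",
    "compare_trials",
    "pearson_r",
    "recommendation_correlation",
    "ratio_summary",
    "published_fits",
    "published_marginal_fits",
    "published_coefficient_pairs",
    "check_f_consistency",
]


@dataclass(frozen=True)
class ComparisonRow:
    """Per-trial comparison of the exponential and quadratic fits."""

    trial_id: str
    nutrient: str
    nsfm: FitResult | None
    qpfm: FitResult | None
    x_max_nsfm: float | None = None
    x_max_qpfm: float | None = None
    x_eco_nsfm: float | None = None
    x_eco_qpfm: float | None = None
    nsfm_significant: bool = False
    qpfm_significant: bool = False
    error: str | None = None


@dataclass(frozen=True)
class CorrelationSummary:
    """Pearson correlation of recommended rates across paired fits."""

    r: float
    n: int
    which: str
    inclusion_rule: str = "all pairs"

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of range: {self.r}")


def compare_trials(
    trials: Iterable[FertilizerTrial],
    prices: PriceContext | float | None = None,
) -> list[ComparisonRow]:
    """Fit both models to each trial and compute recommended rates.

    Per-trial fit failures become rows carrying an ``error`` message rather
    than aborting the batch. Significance flags use the 0.05 level of the
    F test on (2, n-3) degrees of freedom.
    """
    rows = []
    for t in trials:
        try:
            nres = fit_nsfm(t)
            qres = fit_qpfm(t)
        except FitError as exc:
            rows.append(
                ComparisonRow(
                    trial_id=t.trial_id,
                    nutrient=t.nutrient,
                    nsfm=None,
                    qpfm=None,
                    error=str(exc),
                )
            )
            continue
        x_eco_n = x_eco_q = None
        x_max_q = None
        if qres.params.b2 < 0:
            x_max_q = xmax_qpfm(qres.params).x_max
            if prices is not None:
                x_eco_q = xeco_qpfm(qres.params, prices).x_eco
        if prices is not None:
            x_eco_n = xeco_nsfm(nres.params, prices).x_eco
        rows.append(
            ComparisonRow(
                trial_id=t.trial_id,
                nutrient=t.nutrient,
                nsfm=nres,
                qpfm=qres,
                x_max_nsfm=xmax_nsfm(nres.params).x_max,
                x_max_qpfm=x_max_q,
                x_eco_nsfm=x_eco_n,
                x_eco_qpfm=x_eco_q,
                nsfm_significant=nres.stats.significant(0.05),
                qpfm_significant=qres.stats.significant(0.05),
            )
        )
    return rows


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in at least one input")
    return float(sps.pearsonr(x, y).statistic)


def recommendation_correlation(
    coeffs: Sequence[tuple[NSFMParameters, QPFMParameters]],
    which: str = "max",
    prices: PriceContext | float | None = None,
    inclusion_rule: str = "all pairs",
) -> CorrelationSummary:
    """Correlation of recommended rates between the two models.

    ``coeffs`` pairs fitted (or published) exponential and quadratic
    coefficients per trial; no raw yield data are needed. ``which='eco'``
    requires prices.
    """
    if which not in ("max", "eco"):
        raise ValueError("which must be 'max' or 'eco'")
    if which == "eco" and prices is None:
        raise ValueError("economic rates require prices")
    xs, ys = [], []
    for npar, qpar in coeffs:
        if which == "max":
            xs.append(xmax_nsfm(npar).x_max)
            ys.append(xmax_qpfm(qpar).x_max)
        else:
            xs.append(xeco_nsfm(npar, prices).x_eco)
            ys.append(xeco_qpfm(qpar, prices).x_eco)
    return CorrelationSummary(
        r=pearson_r(xs, ys),
        n=len(xs),
        which=which,
        inclusion_rule=inclusion_rule,
    )


def ratio_summary(
    rows: Iterable[ComparisonRow],
    which: str = "max",
    method: str = "mean_of_ratios",
) -> dict[str, float]:
    """Per-nutrient mean ratio of exponential- to quadratic-recommended rates.

    ``method`` selects the aggregation: ``mean_of_ratios`` averages per-trial
    ratios, ``ratio_of_means`` divides the group means. (Reported summary
    percentages in the source tables are reproducible only approximately and
    do not disambiguate the aggregation, so both are offered.)
    """
    if method not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError("unknown aggregation method")
    groups: dict[str, list[tuple[float, float]]] = {}
    for row in rows:
        a = row.x_max_nsfm if which == "max" else row.x_eco_nsfm
        b = row.x_max_qpfm if which == "max" else row.x_eco_qpfm
        if a is None or b is None:
            continue
        groups.setdefault(row.nutrient, []).append((a, b))
    out = {}
    for nutrient, pairs in groups.items():
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        if method == "mean_of_ratios":
            out[nutrient] = float(np.mean(a / b))
        else:
            out[nutrient] = float(a.sum() / b.sum())
    return out


# -- published reference tables -------------------------------------------

def _read_data(name: str) -> pd.DataFrame:
    with resources.files("fertresp.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def published_fits(which: str = "rice") -> pd.DataFrame:
    """Published per-trial coefficients and fit statistics.

    ``which='rice'`` returns the 18 rice trials (8 with 8 rates, 10 with
    4-7 rates); ``which='wheat'`` the 9 winter-wheat trials. Columns carry
    the exponential parameters (A, c_e3 = c x 1000, s0), quadratic
    parameters (b0, b1, b2), and the reported n, F, R2, S and significance
    star counts for both models, exactly as printed in the source tables.
    """
    df = _read_data("published_fits.csv")
    if which not in ("rice", "wheat"):
        raise ValueError("which must be 'rice' or 'wheat'")
    return df[df["crop"] == which].reset_index(drop=True)


def published_marginal_fits() -> pd.DataFrame:
    """Published marginal-model fits (linear and exponential) for the three
    8-level rice trials."""
    return _read_data("published_marginal.csv")


def published_coefficient_pairs(
    df: pd.DataFrame,
) -> list[tuple[NSFMParameters, QPFMParameters]]:
    """Parameter pairs from a published-fits table (c recovered from c_e3)."""
    return [
        (
            NSFMParameters(A=r.A, c=r.c_e3 * 1e-3, s0=r.s0),
            QPFMParameters(b0=r.b0, b1=r.b1, b2=r.b2),
        )
        for r in df.itertuples()
    ]


def check_f_consistency(
    n: int,
    p: int,
    r2_printed: float,
    f_printed: float,
    r2_decimals: int = 3,
) -> bool:
    """Is a printed F value consistent with its printed R2 and sample size?

    Uses F = (R2 / (1 - R2)) (n - p) / (p - 1) over the interval of R2
    values that display as ``r2_printed`` (allowing either rounding or
    truncation of the underlying value, i.e. R2 in
    [printed - 0.5 ulp, printed + 1 ulp]).
    """
    ulp = 10.0 ** (-r2_decimals)
    lo = max(r2_printed - 0.5 * ulp, 0.0)
    hi = min(r2_printed + ulp, 1.0 - 1e-12)
    dfac = (n - p) / (p - 1)
    f_lo = (lo / (1 - lo)) * dfac
    f_hi = (hi / (1 - hi)) * dfac
    return f_lo * 0.995 <= f_printed <= f_hi * 1.005
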