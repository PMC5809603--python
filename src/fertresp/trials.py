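"""Fertilizer-trial containers, CSV input/output and bundled reference trials.

A trial is one site x nutrient dose-response series: an ordered set of
application rates (kg/hm2) with the mean grain yield observed at each rate,
optionally with per-rate standard deviations over field replicates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FertilizerTrial",
    "load_trials",
    "write_trials",
    "builtin_trials",
    "oxide_to_element",
    "to_nutrient_basis",
    "FERTILIZER_GRADE",
    "CSV_COLUMNS",
]

CSV_COLUMNS = [
    "trial_id",
    "site",
    "crop",
    "nutrient",
    "rate_kg_hm2",
    "yield_kg_hm2",
    "yield_sd_kg_hm2",
]

CROPS = ("rice", "wheat", "other")
NUTRIENTS = ("N", "P2O5", "K2O", "urea", "CS", "other")

# standard atomic masses (IUPAC 2021, g/mol)
_M_P, _M_K, _M_O = 30.973761998, 39.0983, 15.999

#: kg of elemental nutrient per kg of oxide
OXIDE_FACTORS = {
    "P2O5": 2 * _M_P / (2 * _M_P + 5 * _M_O),
    "K2O": 2 * _M_K / (2 * _M_K + _M_O),
}

#: nutrient mass fraction of fertilizer products, and the nutrient delivered
FERTILIZER_GRADE = {
    "urea": (0.46, "N"),  # urea, 46% N
    "CS": (0.12, "P2O5"),  # calcium superphosphate, 12% P2O5
}


class TrialDataError(ValueError):
    """Invalid trial data (schema, ordering or range violations)."""


@dataclass(frozen=True)
class FertilizerTrial:
    """One dose-response series of mean yields against application rates.

    Rates must be strictly increasing and non-negative; at least four rates
    are required so that a three-parameter response model retains a residual
    degree of freedom. Yields are replicate means, all positive.
    """

    trial_id: str
    site: str
    crop: str
    nutrient: str
    rates: tuple[float, ...]
    yields: tuple[float, ...]
    yield_sd: tuple[float, ...] | None = None
    n_reps: int | None = None
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        object.__setattr__(self, "yields", tuple(float(y) for y in self.yields))
        if self.yield_sd is not None:
            object.__setattr__(
                self, "yield_sd", tuple(float(s) for s in self.yield_sd)
            )
        if self.crop not in CROPS:
            raise TrialDataError(f"{self.trial_id}: unknown crop {self.crop!r}")
        if self.nutrient not in NUTRIENTS:
            raise TrialDataError(
                f"{self.trial_id}: unknown nutrient {self.nutrient!r}"
            )
        if len(self.rates) != len(self.yields):
            raise TrialDataError(
                f"{self.trial_id}: {len(self.rates)} rates vs "
                f"{len(self.yields)} yields"
            )
        if len(self.rates) < 4:
            raise TrialDataError(
                f"{self.trial_id}: needs at least 4 rates, got {len(self.rates)}"
            )
        if self.rates[0] < 0:
            raise TrialDataError(f"{self.trial_id}: negative application rate")
        if any(b <= a for a, b in zip(self.rates, self.rates[1:])):
            raise TrialDataError(
                f"{self.trial_id}: rates must be strictly increasing"
            )
        if any(y <= 0 for y in self.yields):
            raise TrialDataError(f"{self.trial_id}: all yields must be positive")
        if self.yield_sd is not None:
            if len(self.yield_sd) != len(self.rates):
                raise TrialDataError(
                    f"{self.trial_id}: yield_sd length mismatch"
                )
            if any(s < 0 for s in self.yield_sd):
                raise TrialDataError(f"{self.trial_id}: negative yield SD")
        if self.n_reps is not None and self.n_reps < 1:
            raise TrialDataError(f"{self.trial_id}: n_reps must be >= 1")

    @property
    def n_rates(self) -> int:
        return len(self.rates)


def load_trials(path: str | Path, **read_csv_kwargs) -> list[FertilizerTrial]:
    """Read trials from a CSV file (one row per trial_id x rate).

    The header must contain the columns in :data:`CSV_COLUMNS`
    (``yield_sd_kg_hm2`` may be empty). Rows are grouped by ``trial_id`` in
    order of first appearance and sorted by rate within each trial. Duplicate
    (trial_id, rate) pairs are rejected with the offending row numbers.
    """
    df = pd.read_csv(path, **read_csv_kwargs)
    missing = [c for c in CSV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise TrialDataError(f"missing required columns: {missing}")
    if "yield_sd_kg_hm2" not in df.columns:
        df["yield_sd_kg_hm2"] = float("nan")
    if df.empty:
        return []

    dup = df.duplicated(subset=["trial_id", "rate_kg_hm2"], keep=False)
    if dup.any():
        rows = [i + 2 for i in df.index[dup]]  # +2: header + 1-based
        raise TrialDataError(f"duplicate (trial_id, rate) at csv rows {rows}")

    trials = []
    for tid in df["trial_id"].drop_duplicates():
        sub = df[df["trial_id"] == tid].sort_values("rate_kg_hm2")
        sds = sub["yield_sd_kg_hm2"].astype(float)
        trials.append(
            FertilizerTrial(
                trial_id=str(tid),
                site=str(sub["site"].iloc[0]),
                crop=str(sub["crop"].iloc[0]),
                nutrient=str(sub["nutrient"].iloc[0]),
                rates=tuple(sub["rate_kg_hm2"].astype(float)),
                yields=tuple(sub["yield_kg_hm2"].astype(float)),
                yield_sd=None if sds.isna().all() else tuple(sds),
            )
        )
    return trials


def write_trials(trials: Iterable[FertilizerTrial], path: str | Path) -> None:
    """Write trials to CSV in the :data:`CSV_COLUMNS` schema (round-trips
    with :func:`load_trials`)."""
    records = []
    for t in trials:
        for i, (x, y) in enumerate(zip(t.rates, t.yields)):
            records.append(
                {
                    "trial_id": t.trial_id,
                    "site": t.site,
                    "crop": t.crop,
                    "nutrient": t.nutrient,
                    "rate_kg_hm2": x,
                    "yield_kg_hm2": y,
                    "yield_sd_kg_hm2": t.yield_sd[i]
                    if t.yield_sd is not None
                    else float("nan"),
                }
            )
    pd.DataFrame.from_records(records, columns=CSV_COLUMNS).to_csv(
        path, index=False
    )


def _data_path(name: str):
    return resources.files("fertresp.data").joinpath(name)


def builtin_trials(which: str) -> list[FertilizerTrial]:
    """Bundled reference trials.

    ``rice_table1``: three 8-level rice dose-response trials from Fujian
    province (N at Datian, P2O5 at Nan'an, K2O at Datian), with per-rate SDs
    over three replicates.

    ``wheat_table4``: nine historical winter-wheat trials from northern China
    (5-8 rates each; trials use N, urea, P2O5 or calcium superphosphate, the
    latter two dosed in product mass -- see :func:`to_nutrient_basis`).
    Three transcription issues in the source table are resolved in favour of
    values that make its own fitted-coefficient table reproducible, with the
    printed values kept in trial metadata:

    * W9's yield at 450 kg/hm2 is stored as 1455 (printed 14550, an evident
      decimal slip amid yields of 480-2355);
    * W5-W7 rates are stored as the even design 0, 33.75, 67.5, 101.25, 135
      (printed rounded to 0, 34, 68, 101, 135);
    * W8 rates are stored as the even design 0, 37.5, ..., 187.5 (printed
      rounded to 0, 38, 75, 113, 150, 188).
    """
    if which == "rice_table1":
        trials = load_trials(_data_path("rice_trials.csv"))
        return [
            FertilizerTrial(
                **{**t.__dict__, "n_reps": 3, "meta": {"levels": "8"}}
            )
            for t in trials
        ]
    if which == "wheat_table4":
        trials = load_trials(_data_path("wheat_trials.csv"))
        printed_rates = {
            "W5": "0,34,68,101,135",
            "W6": "0,34,68,101,135",
            "W7": "0,34,68,101,135",
            "W8": "0,38,75,113,150,188",
        }
        out = []
        for t in trials:
            meta = {}
            if t.trial_id == "W9":
                meta["printed_yield_at_450"] = "14550"
                meta["stored_yield_at_450"] = "1455"
            if t.trial_id in printed_rates:
                meta["printed_rates"] = printed_rates[t.trial_id]
            out.append(FertilizerTrial(**{**t.__dict__, "meta": meta}))
        return out
    raise ValueError(f"unknown builtin trial set {which!r}")


def to_nutrient_basis(trial: FertilizerTrial) -> FertilizerTrial:
    """Re-express a fertilizer-product trial on its nutrient basis.

    Trials dosed in product mass (urea, calcium superphosphate) have their
    rates multiplied by the product's nutrient grade (46% N for urea, 12%
    P2O5 for calcium superphosphate) and relabelled with the delivered
    nutrient. Trials already on a nutrient basis are returned unchanged.
    Model coefficients fitted on the two bases map into each other
    (A and c scale by 1/grade, s0 by grade), but published coefficient
    tables for product-dosed trials are on the nutrient basis, so comparing
    against them requires this conversion.
    """
    if trial.nutrient not in FERTILIZER_GRADE:
        return trial
    grade, nutrient = FERTILIZER_GRADE[trial.nutrient]
    meta = dict(trial.meta)
    meta["rate_basis"] = f"converted from {trial.nutrient} at grade {grade}"
    return FertilizerTrial(
        trial_id=trial.trial_id,
        site=trial.site,
        crop=trial.crop,
        nutrient=nutrient,
        rates=tuple(r * grade for r in trial.rates),
        yields=trial.yields,
        yield_sd=trial.yield_sd,
        n_reps=trial.n_reps,
        meta=meta,
    )


def oxide_to_element(amount: float, label: str) -> float:
    """Convert an oxide mass (kg of P2O5 or K2O) to elemental nutrient (kg).

    Multiplies by 2 M(P)/M(P2O5) or 2 M(K)/M(K2O) from standard atomic
    masses (0.4364 and 0.8302 respectively).
    """
    if label not in OXIDE_FACTORS:
        raise ValueError(f"unsupported oxide label {label!r}")
    if amount < 0 or not math.isfinite(amount):
        raise ValueError("amount must be a finite non-negative mass")
    return amount * OXIDE_FACTORS[label]
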