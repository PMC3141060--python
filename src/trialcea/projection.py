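"""Lifetime extrapolation and discounting (the reference case).

Subjects alive at one year post-enrolment are projected over their
remaining life expectancy from an age-, sex- and race/ethnicity-specific
life table.  Each projected year accrues a fixed utility (default 0.6) and
a fixed annual healthcare cost, both discounted at 3%/year with the first
projected year discounted one full period (end-of-year convention).
Decedents within the first year accrue no projected tail.

A small synthetic Gompertz-Makeham life table with the required
(age band, sex, race) schema is bundled so the pipeline runs without any
external download; real life tables in the same CSV schema
(age, sex, race, expectancy_years) can be dropped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources as _ilres
from typing import Optional

import numpy as np
import pandas as pd

from .costing import CostStream
from .outcomes import EffectStream

logger = logging.getLogger(__name__)

RACE_FALLBACK = "other"
DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class ReferenceCaseParams:
    """Reference-case projection parameters."""
    utility_beyond_one_year: float = 0.6      # utility weight per projected year
    annual_cost_beyond_one_year: float = 5000.0  # $/year, 2010 dollars
    discount_rate: float = 0.03               # per year, costs and effects
    life_expectancy_multiplier: float = 1.0   # scales life-table expectancy

    def __post_init__(self) -> None:
        if not 0.0 <= self.utility_beyond_one_year <= 1.0:
            raise ValueError("utility beyond one year must lie in [0, 1]")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be >= 0")
        if self.life_expectancy_multiplier <= 0:
            raise ValueError("life expectancy multiplier must be > 0")
        if self.annual_cost_beyond_one_year < 0:
            raise ValueError("annual cost must be >= 0")

    def replace(self, **overrides) -> "ReferenceCaseParams":
        base = {
            "utility_beyond_one_year": self.utility_beyond_one_year,
            "annual_cost_beyond_one_year": self.annual_cost_beyond_one_year,
            "discount_rate": self.discount_rate,
            "life_expectancy_multiplier": self.life_expectancy_multiplier,
        }
        base.update(overrides)
        return ReferenceCaseParams(**base)


@dataclass
class LifeTable:
    """Remaining life expectancy keyed by (age band, sex, race/ethnicity)."""
    frame: pd.DataFrame  # columns: age, sex, race, expectancy_years

    def __post_init__(self) -> None:
        required = {"age", "sex", "race", "expectancy_years"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        if (self.frame["expectancy_years"] < 0).any():
            raise ValueError("life expectancy must be >= 0")
        self._bands = np.sort(self.frame["age"].unique())
        self._lookup = {
            (int(r.age), r.sex, r.race): float(r.expectancy_years)
            for r in self.frame.itertuples()
        }

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def expectancy(self, age: float, sex: str, race: str) -> float:
        """Nearest-band lookup with clamping and a race fallback category."""
        if age > self._bands[-1] or age < self._bands[0]:
            logger.warning("age %.1f outside life-table range; clamping", age)
        idx = np.clip(np.searchsorted(self._bands, age, side="right") - 1,
                      0, len(self._bands) - 1)
        band = int(self._bands[idx])
        key = (band, sex, race)
        if key not in self._lookup:
            key = (band, sex, RACE_FALLBACK)
        if key not in self._lookup:
            raise KeyError(f"life table has no row for {key}")
        return self._lookup[key]


def remaining_life_expectancy(age: float, sex: str, race: str,
                              table: LifeTable) -> float:
    return table.expectancy(age, sex, race)


def synthetic_life_table(ages: Optional[np.ndarray] = None) -> LifeTable:
    """Build the bundled synthetic Gompertz-Makeham life table.

    Synthetic: hazard h(x) = A + R * exp(alpha * x) with sex- and
    race-specific level parameters chosen to give plausible US-like
    expectancies (e.g. ~30 remaining years at age 50).  It is a stand-in
    with the correct schema and monotonicity, not an official life table.
    """
    if ages is None:
        ages = np.arange(0, 105, 5)
    alpha = 0.095
    A = 2e-4
    base_R = {"F": 1.6e-5, "M": 2.6e-5}
    race_mult = {"white": 1.0, "black": 1.35, "hispanic": 0.85, "other": 0.95}
    grid = np.arange(0.0, 120.0, 0.1)
    rows = []
    for sex, R0 in base_R.items():
        for race, mult in race_mult.items():
            R = R0 * mult
            for age in ages:
                x = age + grid
                cumhaz = A * grid + (R / alpha) * (np.exp(alpha * x)
                                                   - np.exp(alpha * age))
                surv = np.exp(-cumhaz)
                le = float(np.trapezoid(surv, grid))
                rows.append({"age": int(age), "sex": sex, "race": race,
                             "expectancy_years": round(le, 3)})
    return LifeTable(pd.DataFrame(rows))


def default_life_table() -> LifeTable:
    path = _ilres.files("trialcea.data") / "life_table_synthetic.csv"
    return LifeTable.from_csv(path)


def discounted_annuity(annual_amount: float, years: float, rate: float) -> float:
    """Present value of ``annual_amount`` per year over ``years`` years.

    End-of-year convention: year t is discounted by (1+rate)^-t; a
    fractional final year accrues pro rata at the next period's factor.
    Equals ``annual_amount * years`` when the rate is zero.
    """
    if years < 0:
        raise ValueError("duration must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    whole = int(np.floor(years))
    frac = years - whole
    if rate == 0:
        return annual_amount * years
    # -expm1(-n*log1p(r))/r is the annuity factor, stable for tiny rates
    log1pr = np.log1p(rate)
    pv = annual_amount * (-np.expm1(-whole * log1pr)) / rate
    if frac > 0:
        pv += frac * annual_amount * np.exp(-(whole + 1) * log1pr)
    return float(pv)


def project_patient(patient, effect: EffectStream, cost: CostStream,
                    params: ReferenceCaseParams, table: LifeTable
                    ) -> tuple[float, float, float]:
    """Lifetime discounted QALYs, lifetime cost ($), and life expectancy (years).

    Decedents within year one keep their one-year accruals.  Survivors add
    a discounted tail: the life-table remaining expectancy at next year's
    age, scaled by the multiplier, valued at the post-year-1 utility and
    annual cost.  The returned life expectancy is undiscounted
    (1 year + projected remaining years, or survival time for decedents).
    """
    one_year_qalys = effect.qa_days_one_year / DAYS_PER_YEAR
    if not patient.alive_at_one_year:
        life_exp = (patient.death_day or 0.0) / DAYS_PER_YEAR
        return one_year_qalys, cost.total_one_year, life_exp
    le_tail = params.life_expectancy_multiplier * remaining_life_expectancy(
        patient.age + 1.0, patient.sex, patient.race, table)
    qalys = one_year_qalys + discounted_annuity(
        params.utility_beyond_one_year, le_tail, params.discount_rate)
    lifetime_cost = cost.total_one_year + discounted_annuity(
        params.annual_cost_beyond_one_year, le_tail, params.discount_rate)
    return qalys, lifetime_cost, 1.0 + le_tail
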