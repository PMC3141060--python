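"""Per-patient cost streams in 2010 US dollars.

Hospital costs come from billed charges scaled by department-specific
cost-to-charge ratios.  Post-discharge direct medical costs are unit cost
weights times resource-use counts, with two composite formulas: home oxygen
(fixed first-day charge plus a daily rate) and rehospitalization (a base
daily rate plus ICU and ventilator per-day increments).  Lost wages are
valued at the median US daily income and reported separately from direct
medical costs.  A consumer-price-index table converts amounts from other
years into 2010 dollars.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from importlib import resources as _ilres
from typing import Mapping, Optional

import pandas as pd

from .cohort import ResourceUse

#: direct-medical post-discharge categories (lost wages excluded)
DIRECT_CATEGORIES = ("home_oxygen", "home_help", "rehab", "snf_vent",
                     "rehospitalization", "ed_visits", "dr_visits",
                     "medications")


@dataclass(frozen=True)
class CostWeights:
    """Unit cost weights for post-discharge resource use ($, 2010)."""
    home_oxygen_first_day: float = 600.0
    home_oxygen_other_days: float = 6.50
    home_help: float = 100.0          # per day
    rehab: float = 800.0              # per day
    snf_vent: float = 1500.0          # per day
    ed_visit: float = 800.0           # per visit
    dr_visit: float = 200.0           # per visit
    rehosp_base: float = 1500.0       # per hospital day
    rehosp_icu_increment: float = 1100.0   # 2600 - 1500, per ICU day
    rehosp_vent_increment: float = 200.0   # 2800 - 2600, per ventilated day
    medications: float = 10.0         # per medication-day
    lost_work: float = 200.0          # per lost work day (median US daily income)

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"cost weight {f.name} must be >= 0")

    def scaled(self, **factors: float) -> "CostWeights":
        """Return a copy with named weights multiplied by the given factors."""
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        for name, factor in factors.items():
            if name not in values:
                raise KeyError(f"unknown cost weight: {name}")
            values[name] *= factor
        return CostWeights(**values)

    @classmethod
    def from_csv(cls, path) -> "CostWeights":
        df = pd.read_csv(path)
        return cls(**dict(zip(df["weight"], df["dollars"].astype(float))))


def default_cost_weights() -> CostWeights:
    path = _ilres.files("trialcea.data") / "cost_weights.csv"
    return CostWeights.from_csv(path)


@dataclass
class CostStream:
    """Accrued costs for one patient over the first year ($, 2010)."""
    hospital: float
    post_discharge_by_category: dict[str, float]
    lost_wages: float
    lifetime: Optional[float] = None  # filled by the projection stage

    @property
    def post_discharge_total(self) -> float:
        return sum(self.post_discharge_by_category.values())

    @property
    def total_one_year(self) -> float:
        return self.hospital + self.post_discharge_total + self.lost_wages


@dataclass(frozen=True)
class CPITable:
    """Consumer-price-index factors to express a year's dollars in 2010 dollars."""
    factors: Mapping[int, float]

    def __post_init__(self) -> None:
        base = self.factors.get(2010)
        if base is None or abs(base - 1.0) > 1e-9:
            raise ValueError("CPI factor for 2010 must equal 1")

    @classmethod
    def from_csv(cls, path) -> "CPITable":
        df = pd.read_csv(path)
        return cls({int(y): float(f)
                    for y, f in zip(df["year"], df["factor_to_2010"])})


def default_cpi_table() -> CPITable:
    path = _ilres.files("trialcea.data") / "cpi_us_2010.csv"
    return CPITable.from_csv(path)


def index_to_2010(amount: float, year: int, cpi: CPITable) -> float:
    """Express ``amount`` (dollars of ``year``) in 2010 dollars."""
    if year not in cpi.factors:
        raise KeyError(f"year {year} not present in CPI table")
    return amount * cpi.factors[year]


def hospital_cost(department_charges: Mapping[str, float],
                  cost_to_charge: Mapping[str, float],
                  fallback_ratio: Optional[float] = None) -> float:
    """Hospital cost as the sum of charges scaled by department ratios."""
    total = 0.0
    for dept, charge in department_charges.items():
        ratio = cost_to_charge.get(dept, fallback_ratio)
        if ratio is None:
            raise KeyError(
                f"no cost-to-charge ratio for department {dept!r} "
                "and no whole-hospital fallback supplied"
            )
        total += charge * ratio
    if total < 0:
        raise ValueError("hospital cost must be non-negative")
    return total


def home_oxygen_cost(days: int, weights: CostWeights) -> float:
    """First day at a fixed charge, subsequent days at a daily rate."""
    if days < 0:
        raise ValueError("oxygen days must be >= 0")
    if days == 0:
        return 0.0
    return weights.home_oxygen_first_day + weights.home_oxygen_other_days * (days - 1)


def rehospitalization_cost(total_days: int, icu_days: int, vent_days: int,
                           weights: CostWeights) -> float:
    """Base rate per day plus per-day ICU and ventilator increments."""
    if min(total_days, icu_days, vent_days) < 0:
        raise ValueError("rehospitalization day counts must be >= 0")
    if icu_days > total_days or vent_days > total_days:
        raise ValueError("ICU/ventilator days cannot exceed total days")
    return (total_days * weights.rehosp_base
            + icu_days * weights.rehosp_icu_increment
            + vent_days * weights.rehosp_vent_increment)


def post_discharge_cost(resources: ResourceUse,
                        weights: CostWeights) -> dict[str, float]:
    """Direct medical cost per category; lost wages under a separate key."""
    return {
        "home_oxygen": home_oxygen_cost(resources.home_oxygen_days, weights),
        "home_help": resources.home_help_days * weights.home_help,
        "rehab": resources.rehab_days * weights.rehab,
        "snf_vent": resources.snf_vent_days * weights.snf_vent,
        "rehospitalization": rehospitalization_cost(
            resources.rehosp_total_days, resources.rehosp_icu_days,
            resources.rehosp_vent_days, weights),
        "ed_visits": resources.ed_visits * weights.ed_visit,
        "dr_visits": resources.dr_visits * weights.dr_visit,
        "medications": resources.medication_days * weights.medications,
        "lost_wages": resources.lost_work_days * weights.lost_work,
    }


def cost_stream(patient, weights: CostWeights) -> CostStream:
    """Assemble one patient's first-year cost stream."""
    cats = post_discharge_cost(patient.resources, weights)
    lost = cats.pop("lost_wages")
    return CostStream(hospital=patient.hospital_cost,
                      post_discharge_by_category=cats,
                      lost_wages=lost)
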