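"""Synthetic two-arm cohort generator.

The real trial data (PAC vs. CVC monitoring in acute lung injury) are not
publicly available, so every downstream stage of the pipeline is exercised on
synthetic cohorts that reproduce the published statistical structure:

* survival from a two-piece exponential whose piece hazards are solved
  exactly from the two published Kaplan-Meier anchors per arm (day 60 and
  day 365);
* heavy-right-tailed hospital costs from a moment-matched log-normal;
* utility trajectories on [0, 1] observed at four interview waves
  (2/6/9/12 months), improving from ~0.5 at two months and plateauing by
  nine months, with realistic interview non-response and proxy interviews;
* post-discharge resource-use counts as prevalence Bernoulli gates times a
  heavy-tailed positive part (negative-binomial for counts, log-normal for
  day totals).

All randomness flows through one :class:`numpy.random.Generator` seeded from
``CohortConfig.seed``, so cohorts are byte-identical for identical configs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

ARMS = ("PAC", "CVC")
#: interview waves at 2, 6, 9 and 12 months (30.4375 days/month), in days
INTERVIEW_DAYS = (61, 183, 274, 365)
HORIZON_DAYS = 365
DEFAULT_SEED = 20110721

SEXES = ("F", "M")
RACES = ("white", "black", "hispanic", "other")
DIAGNOSES = ("pneumonia", "sepsis", "aspiration", "trauma", "other")
FLUID_STRATEGIES = ("liberal", "conservative")

#: resource categories priced per day (positive part drawn log-normal)
_DAY_CATEGORIES = ("home_oxygen_days", "home_help_days", "rehab_days",
                   "snf_vent_days", "rehosp_total_days", "lost_work_days")
#: resource categories that are visit/item counts (positive part negative-binomial)
_COUNT_CATEGORIES = ("ed_visits", "dr_visits", "medications")

#: days of medication supply per reported medication
MEDICATION_DAYS_PER_ITEM = 30


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveUtilityParams:
    """Median and dispersion (SD scale) of utility at one interview wave."""
    median: float
    dispersion: float = 0.25


@dataclass(frozen=True)
class ResourceCategoryParams:
    """Prevalence gate and positive-part moments for one resource category.

    ``kind`` selects the positive-part family: ``"count"`` draws a shifted
    negative binomial (visit/item counts), ``"days"`` a rounded log-normal
    (day totals).  Moments refer to users only (the positive part).
    """
    prevalence: float
    mean: float
    sd: float
    kind: str  # "count" | "days"


@dataclass(frozen=True)
class ArmParams:
    """Arm-level generator parameters."""
    s60: float                     # survival probability at day 60
    s365: float                    # survival probability at day 365
    hospital_cost_mean_k: float    # $k, 2010 dollars
    hospital_cost_sd_k: float      # $k
    los_mean: float                # hospital length of stay, days
    los_sd: float
    utility_waves: tuple[WaveUtilityParams, ...]
    resources: dict[str, ResourceCategoryParams]


def _pac_resources() -> dict[str, ResourceCategoryParams]:
    return {
        "home_oxygen_days": ResourceCategoryParams(0.314, 90.4, 109.4, "days"),
        "rehab_days": ResourceCategoryParams(0.343, 72.9, 94.3, "days"),
        "rehosp_total_days": ResourceCategoryParams(0.481, 20.2, 28.5, "days"),
        "ed_visits": ResourceCategoryParams(0.586, 4.3, 4.5, "count"),
        "dr_visits": ResourceCategoryParams(0.967, 20.3, 22.0, "count"),
        "medications": ResourceCategoryParams(0.881, 18.6, 15.9, "count"),
        "lost_work_days": ResourceCategoryParams(0.5, 90.0, 90.0, "days"),
        "home_help_days": ResourceCategoryParams(0.0, 0.0, 0.0, "days"),
        "snf_vent_days": ResourceCategoryParams(0.0, 0.0, 0.0, "days"),
    }


def _cvc_resources() -> dict[str, ResourceCategoryParams]:
    return {
        "home_oxygen_days": ResourceCategoryParams(0.292, 86.8, 108.7, "days"),
        "rehab_days": ResourceCategoryParams(0.292, 54.0, 68.4, "days"),
        "rehosp_total_days": ResourceCategoryParams(0.425, 17.7, 23.0, "days"),
        "ed_visits": ResourceCategoryParams(0.532, 3.1, 3.1, "count"),
        "dr_visits": ResourceCategoryParams(0.982, 19.4, 30.6, "count"),
        "medications": ResourceCategoryParams(0.918, 17.7, 15.9, "count"),
        "lost_work_days": ResourceCategoryParams(0.5, 90.0, 90.0, "days"),
        "home_help_days": ResourceCategoryParams(0.0, 0.0, 0.0, "days"),
        "snf_vent_days": ResourceCategoryParams(0.0, 0.0, 0.0, "days"),
    }


def default_arm_params() -> dict[str, ArmParams]:
    """Published arm-level calibration: KM anchors, cost moments, utilities."""
    return {
        "PAC": ArmParams(
            s60=0.738, s365=0.644,
            hospital_cost_mean_k=96.8, hospital_cost_sd_k=86.8,
            los_mean=24.4, los_sd=19.2,
            utility_waves=(WaveUtilityParams(0.47), WaveUtilityParams(0.56),
                           WaveUtilityParams(0.61), WaveUtilityParams(0.61)),
            resources=_pac_resources(),
        ),
        "CVC": ArmParams(
            s60=0.749, s365=0.681,
            hospital_cost_mean_k=89.2, hospital_cost_sd_k=74.5,
            los_mean=23.8, los_sd=19.8,
            utility_waves=(WaveUtilityParams(0.51), WaveUtilityParams(0.60),
                           WaveUtilityParams(0.66), WaveUtilityParams(0.66)),
            resources=_cvc_resources(),
        ),
    }


@dataclass
class CohortConfig:
    """Full generator configuration for a two-arm cohort."""
    n_per_arm: int = 300
    arms: dict[str, ArmParams] = field(default_factory=default_arm_params)
    interview_completion_probs: tuple[float, ...] = (0.72, 0.72, 0.72, 0.72)
    proxy_fraction: float = 0.25
    rehosp_icu_frac: float = 0.3   # ICU share of rehospitalization days
    rehosp_vent_frac: float = 0.5  # ventilated share of ICU days
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if len(self.interview_completion_probs) != len(INTERVIEW_DAYS):
            raise ValueError("one completion probability per interview wave")
        for p in (*self.interview_completion_probs, self.proxy_fraction,
                  self.rehosp_icu_frac, self.rehosp_vent_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for arm, ap in self.arms.items():
            solve_piecewise_hazards(ap.s60, ap.s365)  # validates anchors
            if ap.hospital_cost_sd_k < 0:
                raise ValueError(f"{arm}: hospital cost SD must be >= 0")
            for w in ap.utility_waves:
                if not 0.0 <= w.median <= 1.0:
                    raise ValueError(f"{arm}: utility median outside [0, 1]")
            for name, rp in ap.resources.items():
                if not 0.0 <= rp.prevalence <= 1.0:
                    raise ValueError(f"{arm}/{name}: prevalence outside [0, 1]")
                if rp.sd < 0 or rp.mean < 0:
                    raise ValueError(f"{arm}/{name}: negative moments")


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass
class ResourceUse:
    """Post-discharge resource use for one subject (non-negative counts)."""
    home_oxygen_days: int = 0
    home_help_days: int = 0
    rehab_days: int = 0
    snf_vent_days: int = 0
    rehosp_total_days: int = 0
    rehosp_icu_days: int = 0
    rehosp_vent_days: int = 0
    ed_visits: int = 0
    dr_visits: int = 0
    medication_days: int = 0
    lost_work_days: int = 0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.rehosp_icu_days > self.rehosp_total_days:
            raise ValueError("rehosp_icu_days exceeds rehosp_total_days")
        if self.rehosp_vent_days > self.rehosp_total_days:
            raise ValueError("rehosp_vent_days exceeds rehosp_total_days")


@dataclass
class PatientRecord:
    """One subject: arm, covariates, survival, hospital cost, utilities, resources."""
    id: str
    arm: str
    age: float
    sex: str
    race: str
    apache3: float
    fluid_strategy: str
    tidal_volume: float          # mL/kg predicted body weight
    delay_to_protocol: float     # hours from diagnosis to protocol start
    diagnosis: str
    death_day: Optional[float]   # days from enrolment, None if alive at censor
    censor_day: float            # 365 if followed to one year
    discharged_alive: bool
    hospital_cost: float         # 2010 dollars
    utilities: list[tuple[int, float, bool]]  # (day, utility, proxy flag)
    resources: ResourceUse

    def __post_init__(self) -> None:
        if self.death_day is not None and self.death_day < 0:
            raise ValueError("death_day must be >= 0")
        if self.hospital_cost < 0:
            raise ValueError("hospital_cost must be >= 0")
        for day, u, _ in self.utilities:
            if not 0.0 <= u <= 1.0:
                raise ValueError("utility outside [0, 1]")
            if self.death_day is not None and day >= self.death_day:
                raise ValueError("utility recorded at or after death")

    @property
    def alive_at_one_year(self) -> bool:
        return self.death_day is None or self.death_day > HORIZON_DAYS


# ---------------------------------------------------------------------------
# survival model
# ---------------------------------------------------------------------------

def solve_piecewise_hazards(s60: float, s365: float) -> tuple[float, float]:
    """Invert the two KM anchors into two constant piece hazards (per day).

    The survival model is exponential with hazard ``h1`` on (0, 60] and
    ``h2`` on (60, 365], so ``exp(-60*h1) = s60`` and
    ``exp(-60*h1 - 305*h2) = s365``.
    """
    if not (0.0 < s365 <= s60 <= 1.0):
        raise ValueError(
            f"inconsistent survival anchors: need 0 < S(365)={s365} "
            f"<= S(60)={s60} <= 1"
        )
    h1 = -np.log(s60) / 60.0
    h2 = (np.log(s60) - np.log(s365)) / 305.0
    return float(h1), float(h2)


def sample_survival_days(s60: float, s365: float, size: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw survival times (days); ``inf`` means alive beyond day 365."""
    h1, h2 = solve_piecewise_hazards(s60, s365)
    u = rng.random(size)
    t = np.full(size, np.inf)
    early = u > s60
    if h1 > 0:
        t[early] = -np.log(u[early]) / h1
    late = (~early) & (u > s365)
    if h2 > 0:
        t[late] = 60.0 + (-np.log(u[late]) - 60.0 * h1) / h2
    return t


# ---------------------------------------------------------------------------
# elementary samplers
# ---------------------------------------------------------------------------

def lognormal_from_moments(mean: float, sd: float, size: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Log-normal draws matched by method of moments to (mean, sd)."""
    if mean <= 0:
        return np.zeros(size)
    if sd == 0:
        return np.full(size, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _beta_utility(median: float, dispersion: float, size: int,
                  rng: np.random.Generator) -> np.ndarray:
    # Beta parameterized by mean ~ median; concentration from the dispersion,
    # capped so both shape parameters stay positive.
    m = min(max(median, 1e-3), 1 - 1e-3)
    var = min(dispersion ** 2, 0.95 * m * (1 - m))
    kappa = max(m * (1 - m) / var - 1.0, 0.05)
    return rng.beta(m * kappa, (1 - m) * kappa, size)


def _positive_count(mean: float, sd: float, size: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Shifted negative-binomial counts >= 1 with target user-level moments."""
    m = max(mean - 1.0, 1e-6)  # shift so the support starts at 1
    var = max(sd ** 2, m + 1e-6)
    if var <= m * (1 + 1e-9):
        return 1 + rng.poisson(m, size)
    r = m * m / (var - m)
    p = r / (r + m)
    return 1 + rng.negative_binomial(r, p, size)


def _positive_days(mean: float, sd: float, size: int,
                   rng: np.random.Generator) -> np.ndarray:
    draws = lognormal_from_moments(mean, sd, size, rng)
    return np.maximum(np.rint(draws).astype(int), 1)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sample_covariates(n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Baseline covariates matched to the published baseline table."""
    return {
        "age": np.clip(rng.normal(50.0, 16.0, n), 18.0, 90.0),
        "sex": rng.choice(SEXES, n, p=(0.47, 0.53)),
        "race": rng.choice(RACES, n, p=(0.68, 0.205, 0.095, 0.02)),
        "apache3": np.clip(rng.normal(94.0, 31.0, n), 10.0, 250.0),
        "fluid_strategy": rng.choice(FLUID_STRATEGIES, n, p=(0.5, 0.5)),
        "tidal_volume": np.clip(rng.normal(7.16, 1.54, n), 3.0, 15.0),
        "delay_to_protocol": np.clip(rng.normal(24.1, 14.4, n), 0.5, 96.0),
        "diagnosis": rng.choice(DIAGNOSES, n, p=(0.455, 0.22, 0.155, 0.075, 0.095)),
    }


def _sample_resources(params: dict[str, ResourceCategoryParams],
                      icu_frac: float, vent_frac: float,
                      rng: np.random.Generator) -> ResourceUse:
    values: dict[str, int] = {}
    for name in (*_DAY_CATEGORIES, *_COUNT_CATEGORIES):
        rp = params.get(name)
        if rp is None or rp.prevalence <= 0 or rng.random() >= rp.prevalence:
            values[name] = 0
        elif rp.kind == "count":
            values[name] = int(_positive_count(rp.mean, rp.sd, 1, rng)[0])
        else:
            values[name] = int(_positive_days(rp.mean, rp.sd, 1, rng)[0])
    total = values["rehosp_total_days"]
    icu = int(rng.binomial(total, icu_frac)) if total else 0
    vent = int(rng.binomial(icu, vent_frac)) if icu else 0
    meds = values.pop("medications")
    return ResourceUse(
        home_oxygen_days=values["home_oxygen_days"],
        home_help_days=values["home_help_days"],
        rehab_days=values["rehab_days"],
        snf_vent_days=values["snf_vent_days"],
        rehosp_total_days=total,
        rehosp_icu_days=icu,
        rehosp_vent_days=vent,
        ed_visits=values["ed_visits"],
        dr_visits=values["dr_visits"],
        medication_days=meds * MEDICATION_DAYS_PER_ITEM,
        lost_work_days=values["lost_work_days"],
    )


def generate_arm(arm: str, config: CohortConfig,
                 rng: np.random.Generator) -> list[PatientRecord]:
    """Generate one arm of ``config.n_per_arm`` patients."""
    ap = config.arms[arm]
    n = config.n_per_arm
    cov = _sample_covariates(n, rng)
    t_death = sample_survival_days(ap.s60, ap.s365, n, rng)
    costs = lognormal_from_moments(ap.hospital_cost_mean_k * 1e3,
                                   ap.hospital_cost_sd_k * 1e3, n, rng)
    los = lognormal_from_moments(ap.los_mean, ap.los_sd, n, rng)

    patients = []
    for i in range(n):
        death = None if np.isinf(t_death[i]) or t_death[i] > HORIZON_DAYS \
            else float(t_death[i])
        discharged = bool(death is None or death > los[i])
        utilities: list[tuple[int, float, bool]] = []
        if discharged:
            for w, day in enumerate(INTERVIEW_DAYS):
                alive_at_wave = death is None or death > day
                if not alive_at_wave:
                    continue
                if rng.random() < config.interview_completion_probs[w]:
                    wp = ap.utility_waves[w]
                    u = float(_beta_utility(wp.median, wp.dispersion, 1, rng)[0])
                    proxy = bool(rng.random() < config.proxy_fraction)
                    utilities.append((day, u, proxy))
            resources = _sample_resources(ap.resources, config.rehosp_icu_frac,
                                          config.rehosp_vent_frac, rng)
        else:
            resources = ResourceUse()
        patients.append(PatientRecord(
            id=f"{arm}-{i:05d}",
            arm=arm,
            age=float(cov["age"][i]),
            sex=str(cov["sex"][i]),
            race=str(cov["race"][i]),
            apache3=float(cov["apache3"][i]),
            fluid_strategy=str(cov["fluid_strategy"][i]),
            tidal_volume=float(cov["tidal_volume"][i]),
            delay_to_protocol=float(cov["delay_to_protocol"][i]),
            diagnosis=str(cov["diagnosis"][i]),
            death_day=death,
            censor_day=float(HORIZON_DAYS),
            discharged_alive=discharged,
            hospital_cost=float(costs[i]),
            utilities=utilities,
            resources=resources,
        ))
    return patients


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate the full two-arm cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients: list[PatientRecord] = []
    for arm in ARMS:
        patients.extend(generate_arm(arm, config, rng))
    return patients


# ---------------------------------------------------------------------------
# I/O: CSV (wide utilities) and JSON (nested records)
# ---------------------------------------------------------------------------

_RESOURCE_FIELDS = tuple(ResourceUse.__dataclass_fields__)


def cohort_to_dataframe(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    """One row per patient; utilities widened to u_day<d>/proxy_day<d> columns."""
    rows = []
    for p in patients:
        row: dict = {
            "id": p.id, "arm": p.arm, "age": p.age, "sex": p.sex,
            "race": p.race, "apache3": p.apache3,
            "fluid_strategy": p.fluid_strategy, "tidal_volume": p.tidal_volume,
            "delay_to_protocol": p.delay_to_protocol, "diagnosis": p.diagnosis,
            "death_day": p.death_day if p.death_day is not None else np.nan,
            "censor_day": p.censor_day,
            "discharged_alive": p.discharged_alive,
            "hospital_cost": p.hospital_cost,
        }
        by_day = {d: (u, proxy) for d, u, proxy in p.utilities}
        for d in INTERVIEW_DAYS:
            u, proxy = by_day.get(d, (np.nan, False))
            row[f"u_day{d}"] = u
            row[f"proxy_day{d}"] = proxy
        for f in _RESOURCE_FIELDS:
            row[f] = getattr(p.resources, f)
        rows.append(row)
    return pd.DataFrame(rows)


def dataframe_to_cohort(df: pd.DataFrame) -> list[PatientRecord]:
    patients = []
    for _, row in df.iterrows():
        utilities = []
        for d in INTERVIEW_DAYS:
            u = row[f"u_day{d}"]
            if pd.notna(u):
                utilities.append((d, float(u), bool(row[f"proxy_day{d}"])))
        death = None if pd.isna(row["death_day"]) else float(row["death_day"])
        patients.append(PatientRecord(
            id=str(row["id"]), arm=str(row["arm"]), age=float(row["age"]),
            sex=str(row["sex"]), race=str(row["race"]),
            apache3=float(row["apache3"]),
            fluid_strategy=str(row["fluid_strategy"]),
            tidal_volume=float(row["tidal_volume"]),
            delay_to_protocol=float(row["delay_to_protocol"]),
            diagnosis=str(row["diagnosis"]), death_day=death,
            censor_day=float(row["censor_day"]),
            discharged_alive=bool(row["discharged_alive"]),
            hospital_cost=float(row["hospital_cost"]),
            utilities=utilities,
            resources=ResourceUse(**{f: int(row[f]) for f in _RESOURCE_FIELDS}),
        ))
    return patients


def write_cohort_csv(patients: Sequence[PatientRecord], path) -> None:
    cohort_to_dataframe(patients).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    # round_trip parser: float cells reproduce the written values exactly
    return dataframe_to_cohort(pd.read_csv(path, float_precision="round_trip"))


def write_cohort_json(patients: Sequence[PatientRecord], path) -> None:
    records = []
    for p in patients:
        d = asdict(p)
        d["utilities"] = [list(t) for t in p.utilities]
        records.append(d)
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def read_cohort_json(path) -> list[PatientRecord]:
    with open(path) as fh:
        records = json.load(fh)
    patients = []
    for d in records:
        d["utilities"] = [tuple(t) for t in d["utilities"]]
        d["resources"] = ResourceUse(**d["resources"])
        patients.append(PatientRecord(**d))
    return patients
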