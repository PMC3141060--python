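"""Survival curves and one-year quality-adjusted survival.

Quality-adjusted survival over the first year is the area under each
patient's utility curve: utilities observed at interval interviews are
joined by linear interpolation (trapezoid rule), the first observed value
is carried back to enrolment (optionally zero until hospital discharge),
the last observed value is carried forward to the one-year horizon, and
utility drops to zero at death.  Survival is estimated with the
Kaplan-Meier product-limit estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import HORIZON_DAYS, INTERVIEW_DAYS, PatientRecord

HOSPITAL_PHASE_MODES = ("carry_back", "zero_until_discharge")


@dataclass
class SurvivalCurve:
    """Kaplan-Meier estimate: step function over event days."""
    days: np.ndarray       # ordered distinct event times
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray    # number at risk at each event time

    def survival_at(self, day: float) -> float:
        """S(day); 1 before the first event (S(0) = 1)."""
        idx = np.searchsorted(self.days, day, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], event_flags: Sequence[bool]) -> SurvivalCurve:
    """Product-limit survival estimate; ties resolve deaths before censorings."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_flags, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and event flags must have equal length")
    if np.any(times < 0):
        raise ValueError("survival times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_["KM_estimate"]
    days = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    keep = days > 0  # drop the S(0)=1 baseline row; survival_at handles t<first
    at_risk = np.array([kmf.event_table.loc[d, "at_risk"] if d in kmf.event_table.index
                        else np.nan for d in days[keep]], dtype=float)
    return SurvivalCurve(days=days[keep], survival=surv[keep], at_risk=at_risk)


def survival_curve_frame(curve: SurvivalCurve) -> pd.DataFrame:
    return pd.DataFrame({"day": curve.days, "survival": curve.survival,
                         "at_risk": curve.at_risk})


@dataclass
class UtilityTrajectory:
    """Interview utilities for one patient, with death day and horizon."""
    points: list[tuple[float, float]]        # (day, utility), days increasing
    death_day: Optional[float] = None
    horizon: float = float(HORIZON_DAYS)

    def __post_init__(self) -> None:
        end = self.end_day
        last = -np.inf
        for day, u in self.points:
            if day <= last:
                raise ValueError("utility days must be strictly increasing")
            if not 0.0 <= u <= 1.0:
                raise ValueError("utility outside [0, 1]")
            if day > end:
                raise ValueError("utility point after death/horizon")
            last = day

    @property
    def end_day(self) -> float:
        """Last day utility can accrue: min(death, horizon)."""
        if self.death_day is None:
            return self.horizon
        return min(self.death_day, self.horizon)


@dataclass
class EffectStream:
    """Quality-adjusted survival for one patient."""
    qa_days_one_year: float
    life_years_one_year: float
    lifetime_qalys: Optional[float] = None   # filled by the projection stage
    imputed: bool = False                    # utility trajectory was imputed


def utility_auc(traj: UtilityTrajectory, hospital_phase: str = "carry_back",
                discharge_day: Optional[float] = None) -> float:
    """Area under the interpolated utility curve, in quality-adjusted days.

    Trapezoid rule between observed points; first value carried back to
    day 0 (or utility held at zero until ``discharge_day`` when
    ``hospital_phase="zero_until_discharge"``); last value carried forward
    to ``min(death_day, horizon)``; utility is zero from death onward.
    """
    if hospital_phase not in HOSPITAL_PHASE_MODES:
        raise ValueError(f"unknown hospital_phase mode: {hospital_phase}")
    end = traj.end_day
    if end <= 0:
        return 0.0
    if not traj.points:
        raise ValueError("empty utility trajectory: impute before integrating")

    days = [d for d, _ in traj.points]
    vals = [u for _, u in traj.points]
    xs: list[float] = []
    ys: list[float] = []
    start = 0.0
    if hospital_phase == "zero_until_discharge" and discharge_day:
        d0 = min(discharge_day, days[0], end)
        if d0 > 0:
            xs += [0.0, d0, d0]
            ys += [0.0, 0.0, vals[0]]
            start = d0
    if start < days[0]:
        xs += [start]
        ys += [vals[0]]  # carry-back
    for d, u in zip(days, vals):
        xs.append(min(d, end))
        ys.append(u)
    if days[-1] < end:
        xs.append(end)
        ys.append(vals[-1])  # carry-forward
    return float(np.trapezoid(ys, xs))


def arm_median_trajectories(patients: Sequence[PatientRecord]
                            ) -> dict[str, list[tuple[float, float]]]:
    """Per-arm median observed utility at each interview wave.

    Used to impute trajectories for patients with no completed interview;
    waves with no observations in an arm fall back to the overall median of
    that arm's observed utilities (0.5 when an arm has none at all).
    """
    out: dict[str, list[tuple[float, float]]] = {}
    arms = sorted({p.arm for p in patients})
    for arm in arms:
        by_wave: dict[int, list[float]] = {d: [] for d in INTERVIEW_DAYS}
        all_vals: list[float] = []
        for p in patients:
            if p.arm != arm:
                continue
            for day, u, _ in p.utilities:
                by_wave.setdefault(day, []).append(u)
                all_vals.append(u)
        overall = float(np.median(all_vals)) if all_vals else 0.5
        out[arm] = [(float(d), float(np.median(v)) if v else overall)
                    for d, v in sorted(by_wave.items())]
    return out


def one_year_effect(patient: PatientRecord,
                    median_trajectory: Optional[list[tuple[float, float]]] = None,
                    hospital_phase: str = "carry_back",
                    discharge_day: Optional[float] = None) -> EffectStream:
    """One-year quality-adjusted days and life-years for one patient."""
    if patient.death_day is None and patient.censor_day < HORIZON_DAYS:
        raise ValueError(
            f"patient {patient.id}: vital status unresolved at one year "
            f"(censored day {patient.censor_day})"
        )
    death = patient.death_day
    end = min(death, HORIZON_DAYS) if death is not None else HORIZON_DAYS
    points = [(float(d), u) for d, u, _ in patient.utilities if d <= end]
    imputed = False
    if not points:
        if end == 0:
            return EffectStream(0.0, 0.0)
        if median_trajectory is None:
            raise ValueError(
                f"patient {patient.id} has no completed interview and no "
                "imputation trajectory was supplied"
            )
        points = [(d, u) for d, u in median_trajectory if d <= end]
        if not points:
            points = [(end, median_trajectory[0][1])]
        imputed = True
    traj = UtilityTrajectory(points=points, death_day=death)
    qa_days = utility_auc(traj, hospital_phase=hospital_phase,
                          discharge_day=discharge_day)
    return EffectStream(qa_days_one_year=qa_days,
                        life_years_one_year=end / HORIZON_DAYS,
                        imputed=imputed)


def cohort_effects(patients: Sequence[PatientRecord],
                   hospital_phase: str = "carry_back"
                   ) -> tuple[list[EffectStream], int]:
    """Effect streams for a cohort; returns (streams, number imputed)."""
    medians = arm_median_trajectories(patients)
    streams = [one_year_effect(p, medians.get(p.arm), hospital_phase)
               for p in patients]
    return streams, sum(s.imputed for s in streams)
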