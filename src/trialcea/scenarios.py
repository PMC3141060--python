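"""Subgroup and one-way sensitivity analyses.

Subgroups re-run the full bootstrap PSA on pre-specified strata of the
cohort (sex, age bands, ethnicity, fluid strategy, APACHE III cut at 90,
tidal volume cut at 6.9 mL/kg, delay-to-protocol cut at 21.5 h, and
diagnosis selections; ties go to the lower stratum).  One-way sensitivity
scenarios re-project the whole cohort under modified reference-case
parameters or scaled cost weights and report the shift in incremental cost
and QALYs versus the reference run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import cea
from .cohort import PatientRecord
from .costing import CostWeights, cost_stream
from .outcomes import EffectStream
from .projection import LifeTable, ReferenceCaseParams, project_patient


@dataclass(frozen=True)
class SubgroupSpec:
    """A named stratum: a predicate over the per-patient results frame."""
    name: str
    predicate: Callable[[pd.DataFrame], pd.Series]


def default_subgroups() -> list[SubgroupSpec]:
    """Pre-specified strata; diagnosis rows are overlapping selections."""
    return [
        SubgroupSpec("all", lambda d: pd.Series(True, index=d.index)),
        SubgroupSpec("age<45", lambda d: d["age"] < 45),
        SubgroupSpec("age45-64", lambda d: (d["age"] >= 45) & (d["age"] <= 64)),
        SubgroupSpec("age>64", lambda d: d["age"] > 64),
        SubgroupSpec("female", lambda d: d["sex"] == "F"),
        SubgroupSpec("male", lambda d: d["sex"] == "M"),
        SubgroupSpec("white", lambda d: d["race"] == "white"),
        SubgroupSpec("black", lambda d: d["race"] == "black"),
        SubgroupSpec("hispanic", lambda d: d["race"] == "hispanic"),
        SubgroupSpec("fluid_liberal", lambda d: d["fluid_strategy"] == "liberal"),
        SubgroupSpec("fluid_conservative",
                     lambda d: d["fluid_strategy"] == "conservative"),
        SubgroupSpec("apache<=90", lambda d: d["apache3"] <= 90),
        SubgroupSpec("apache>90", lambda d: d["apache3"] > 90),
        SubgroupSpec("tidal<=6.9", lambda d: d["tidal_volume"] <= 6.9),
        SubgroupSpec("tidal>6.9", lambda d: d["tidal_volume"] > 6.9),
        SubgroupSpec("delay<=21.5h", lambda d: d["delay_to_protocol"] <= 21.5),
        SubgroupSpec("delay>21.5h", lambda d: d["delay_to_protocol"] > 21.5),
        SubgroupSpec("sepsis", lambda d: d["diagnosis"] == "sepsis"),
        SubgroupSpec("pneumonia", lambda d: d["diagnosis"] == "pneumonia"),
        SubgroupSpec("aspiration", lambda d: d["diagnosis"] == "aspiration"),
    ]


def run_subgroups(results: pd.DataFrame,
                  specs: Optional[Sequence[SubgroupSpec]] = None,
                  n_trials: int = cea.DEFAULT_N_TRIALS, seed: int = 0,
                  wtp_k: float = 50.0) -> pd.DataFrame:
    """One full bootstrap PSA per subgroup, with the same base seed.

    Columns mirror the headline subgroup table: stratum size, incremental
    cost ($k) and QALYs, the percentage of trials with the treatment
    inferior (dominated quadrant) and the percentage acceptable at the
    willingness-to-pay threshold.  Strata empty in either arm are skipped.
    """
    logger = logging.getLogger(__name__)
    if specs is None:
        specs = default_subgroups()
    rows = []
    for spec in specs:
        mask = spec.predicate(results)
        sub = results[mask]
        if (sub["arm"] == "PAC").sum() == 0 or (sub["arm"] == "CVC").sum() == 0:
            logger.warning("subgroup %s empty in one arm; skipped", spec.name)
            continue
        cloud = cea.bootstrap_psa(sub, n_trials=n_trials, seed=seed)
        quad = cea.quadrant_probs(cloud)
        accept = 1.0 - cea.threshold_exceed_probs(cloud, [wtp_k])[wtp_k]
        rows.append({
            "subgroup": spec.name,
            "n": int(len(sub)),
            "delta_cost_k": float(cloud.delta_cost.mean()),
            "delta_qaly": float(cloud.delta_effect.mean()),
            "pct_trials_inferior": 100.0 * quad["dominated"],
            f"pct_trials_below_{int(wtp_k)}k": 100.0 * accept,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScenarioSpec:
    """Named parameter overrides for a one-way sensitivity re-run.

    ``param_overrides`` set reference-case parameters to absolute values;
    ``param_factors`` multiply the reference value; ``weight_factors``
    multiply individual cost weights (the physician-reimbursement scenario
    scales the doctor-visit weight as its closest implementable surrogate).
    """
    name: str
    param_overrides: dict = field(default_factory=dict)
    param_factors: dict = field(default_factory=dict)
    weight_factors: dict = field(default_factory=dict)


def built_in_scenarios() -> list[ScenarioSpec]:
    return [
        ScenarioSpec("reference"),
        ScenarioSpec("life_expectancy_x0.5",
                     param_overrides={"life_expectancy_multiplier": 0.5}),
        ScenarioSpec("utility_x0.75",
                     param_factors={"utility_beyond_one_year": 0.75}),
        ScenarioSpec("utility_x1.25",
                     param_factors={"utility_beyond_one_year": 1.25}),
        ScenarioSpec("discount_5pct", param_overrides={"discount_rate": 0.05}),
        ScenarioSpec("annual_cost_x0.5",
                     param_factors={"annual_cost_beyond_one_year": 0.5}),
        ScenarioSpec("annual_cost_x2",
                     param_factors={"annual_cost_beyond_one_year": 2.0}),
        ScenarioSpec("physician_cost_x0.5", weight_factors={"dr_visit": 0.5}),
        ScenarioSpec("physician_cost_x2", weight_factors={"dr_visit": 2.0}),
    ]


def _project_frame(patients: Sequence[PatientRecord],
                   effects: Sequence[EffectStream],
                   weights: CostWeights, params: ReferenceCaseParams,
                   table: LifeTable) -> pd.DataFrame:
    rows = []
    for p, eff in zip(patients, effects):
        cost = cost_stream(p, weights)
        qalys, lifetime_cost, le = project_patient(p, eff, cost, params, table)
        rows.append({"id": p.id, "arm": p.arm,
                     "lifetime_cost": lifetime_cost, "lifetime_qalys": qalys})
    return pd.DataFrame(rows)


def run_sensitivity(patients: Sequence[PatientRecord],
                    effects: Sequence[EffectStream],
                    weights: CostWeights, params: ReferenceCaseParams,
                    table: LifeTable,
                    scenarios: Optional[Sequence[ScenarioSpec]] = None,
                    n_trials: int = cea.DEFAULT_N_TRIALS,
                    seed: int = 0) -> pd.DataFrame:
    """One-way sensitivity table: incremental estimates and % change vs.
    the first (reference) scenario."""
    if scenarios is None:
        scenarios = built_in_scenarios()
    rows = []
    ref_dc = ref_de = None
    for spec in scenarios:
        overrides = dict(spec.param_overrides)
        for name, factor in spec.param_factors.items():
            overrides[name] = getattr(params, name) * factor
        sc_params = params.replace(**overrides)
        sc_weights = weights.scaled(**spec.weight_factors) \
            if spec.weight_factors else weights
        frame = _project_frame(patients, effects, sc_weights, sc_params, table)
        cloud = cea.bootstrap_psa(frame, n_trials=n_trials, seed=seed)
        dc = float(cloud.delta_cost.mean())
        de = float(cloud.delta_effect.mean())
        if ref_dc is None:  # first scenario is the reference
            ref_dc, ref_de = dc, de
        rows.append({
            "scenario": spec.name,
            "delta_cost_k": dc,
            "delta_qaly": de,
            "pct_change_cost": 100.0 * (dc - ref_dc) / abs(ref_dc)
            if ref_dc else np.nan,
            "pct_change_qaly": 100.0 * (de - ref_de) / abs(ref_de)
            if ref_de else np.nan,
        })
    return pd.DataFrame(rows)
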