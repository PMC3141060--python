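"""End-to-end reference-case run: generator -> costing -> outcomes ->
projection -> PSA -> subgroups/sensitivity, with reproducible outputs.

Monetary outputs in the summary tables are thousands of 2010 dollars ($k),
matching the convention of the published tables; per-patient exports keep
raw dollars.  Every run writes a manifest (config hash, seed, package
version); re-running the same configuration reproduces all numeric outputs
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__, cea, scenarios as scen
from .cohort import (CohortConfig, PatientRecord, cohort_to_dataframe,
                     generate_cohort, read_cohort_csv)
from .costing import (CostWeights, cost_stream, default_cost_weights)
from .outcomes import cohort_effects, km_estimate, survival_curve_frame
from .projection import (LifeTable, ReferenceCaseParams, default_life_table,
                         project_patient)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full reference-case run."""
    cohort_csv: Optional[str] = None       # pre-built cohort; else generate
    n_per_arm: int = 300
    cohort_seed: int = 20110721
    cost_weights_csv: Optional[str] = None
    life_table_csv: Optional[str] = None
    params: ReferenceCaseParams = field(default_factory=ReferenceCaseParams)
    n_trials: int = cea.DEFAULT_N_TRIALS
    psa_seed: int = 0
    wtp_grid: tuple[float, ...] = cea.DEFAULT_WTP_GRID
    wtp_thresholds: tuple[float, ...] = (50.0, 100.0)
    run_subgroups: bool = True
    run_sensitivity: bool = True
    hospital_phase: str = "carry_back"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "params" in raw:
            raw["params"] = ReferenceCaseParams(**raw["params"])
        for key in ("wtp_grid", "wtp_thresholds"):
            if key in raw:
                raw[key] = tuple(float(x) for x in raw[key])
        return cls(**raw)

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


@dataclass
class ResultBundle:
    """All outputs of a reference-case run."""
    patients: list[PatientRecord]
    results: pd.DataFrame          # per-patient streams and projections
    cloud: cea.PSACloud
    icer: cea.IcerResult
    quadrants: dict[str, float]
    threshold_probs: dict[float, float]
    ceac: cea.CEACurve
    ellipse: cea.Ellipse
    survival: dict[str, pd.DataFrame]
    subgroup_table: Optional[pd.DataFrame]
    sensitivity_table: Optional[pd.DataFrame]
    n_imputed_utilities: int
    n_winsorized_costs: int
    manifest: dict


def build_patient_results(patients: list[PatientRecord],
                          weights: CostWeights,
                          params: ReferenceCaseParams,
                          table: LifeTable,
                          hospital_phase: str = "carry_back",
                          ) -> tuple[pd.DataFrame, list, int]:
    """Per-patient cost/effect streams and lifetime projections.

    Returns (frame, effect streams, number of imputed utility trajectories).
    The frame carries covariates for subgroup analysis, all first-year cost
    components in dollars, and the projected lifetime cost and QALYs.
    """
    effects, n_imputed = cohort_effects(patients, hospital_phase)
    rows = []
    for p, eff in zip(patients, effects):
        cost = cost_stream(p, weights)
        qalys, lifetime_cost, le = project_patient(p, eff, cost, params, table)
        eff.lifetime_qalys = qalys
        cost.lifetime = lifetime_cost
        # conservation check: the stream total must equal the sum of parts
        recomputed = (cost.hospital + sum(cost.post_discharge_by_category.values())
                      + cost.lost_wages)
        if abs(recomputed - cost.total_one_year) > 1e-6:
            raise AssertionError(f"cost conservation violated for {p.id}")
        row = {
            "id": p.id, "arm": p.arm, "age": p.age, "sex": p.sex,
            "race": p.race, "apache3": p.apache3,
            "fluid_strategy": p.fluid_strategy,
            "tidal_volume": p.tidal_volume,
            "delay_to_protocol": p.delay_to_protocol,
            "diagnosis": p.diagnosis,
            "death_day": p.death_day,
            "hospital_cost": cost.hospital,
            "post_discharge_cost": cost.post_discharge_total,
            "lost_wages": cost.lost_wages,
            "total_one_year_cost": cost.total_one_year,
            "lifetime_cost": lifetime_cost,
            "qa_days_one_year": eff.qa_days_one_year,
            "life_years_one_year": eff.life_years_one_year,
            "lifetime_qalys": qalys,
            "life_expectancy_years": le,
            "utilities_imputed": eff.imputed,
        }
        for cat, value in cost.post_discharge_by_category.items():
            row[f"cost_{cat}"] = value
        rows.append(row)
    return pd.DataFrame(rows), effects, n_imputed


def run_reference_case(config: RunConfig,
                       outdir: Optional[str | Path] = None) -> ResultBundle:
    """Execute the full pipeline; optionally write all artifacts to ``outdir``."""
    weights = (CostWeights.from_csv(config.cost_weights_csv)
               if config.cost_weights_csv else default_cost_weights())
    table = (LifeTable.from_csv(config.life_table_csv)
             if config.life_table_csv else default_life_table())

    if config.cohort_csv:
        logger.info("stage cohort: reading %s", config.cohort_csv)
        patients = read_cohort_csv(config.cohort_csv)
    else:
        logger.info("stage cohort: generating %d patients/arm (seed %d)",
                    config.n_per_arm, config.cohort_seed)
        patients = generate_cohort(CohortConfig(n_per_arm=config.n_per_arm,
                                                seed=config.cohort_seed))

    results, effects, n_imputed = build_patient_results(
        patients, weights, config.params, table, config.hospital_phase)
    logger.info("stage outcomes: %d imputed utility trajectories", n_imputed)

    # winsorization count for the run log: patients whose lifetime cost sits
    # above their arm's 95th percentile in the point-estimate cohort
    n_winsorized = 0
    for arm in results["arm"].unique():
        costs = results.loc[results["arm"] == arm, "lifetime_cost"]
        n_winsorized += int((costs > costs.quantile(0.95)).sum())
    logger.info("stage cea: %d lifetime costs above the in-arm P95", n_winsorized)

    cloud = cea.bootstrap_psa(results, n_trials=config.n_trials,
                              seed=config.psa_seed)
    icer = cea.icer_result(cloud)
    quadrants = cea.quadrant_probs(cloud)
    thresholds = cea.threshold_exceed_probs(cloud, config.wtp_thresholds)
    curve = cea.ceac(cloud, config.wtp_grid)
    ellipse = cea.confidence_ellipse(cloud, 0.95)

    survival = {}
    for arm in ("PAC", "CVC"):
        sub = [p for p in patients if p.arm == arm]
        times = [p.death_day if p.death_day is not None else p.censor_day
                 for p in sub]
        events = [p.death_day is not None for p in sub]
        survival[arm] = survival_curve_frame(km_estimate(times, events))

    subgroup_table = None
    if config.run_subgroups:
        subgroup_table = scen.run_subgroups(results, n_trials=config.n_trials,
                                            seed=config.psa_seed)
    sensitivity_table = None
    if config.run_sensitivity:
        sensitivity_table = scen.run_sensitivity(
            patients, effects, weights, config.params, table,
            n_trials=config.n_trials, seed=config.psa_seed)

    manifest = {
        "package": "trialcea",
        "version": __version__,
        "config_sha256": config.digest(),
        "cohort_seed": config.cohort_seed,
        "psa_seed": config.psa_seed,
        "n_trials": config.n_trials,
        "n_patients": len(patients),
        "n_imputed_utilities": n_imputed,
        "n_winsorized_costs": n_winsorized,
    }
    bundle = ResultBundle(
        patients=patients, results=results, cloud=cloud, icer=icer,
        quadrants=quadrants, threshold_probs=thresholds, ceac=curve,
        ellipse=ellipse, survival=survival, subgroup_table=subgroup_table,
        sensitivity_table=sensitivity_table,
        n_imputed_utilities=n_imputed, n_winsorized_costs=n_winsorized,
        manifest=manifest,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: ResultBundle, outdir: str | Path) -> None:
    """Write every artifact of a run as CSV/JSON under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_to_dataframe(bundle.patients).to_csv(out / "cohort.csv", index=False)
    bundle.results.to_csv(out / "patient_results.csv", index=False)
    bundle.cloud.to_frame().to_csv(out / "psa_cloud.csv", index=False)
    bundle.ceac.to_frame().to_csv(out / "ceac.csv", index=False)
    for arm, frame in bundle.survival.items():
        frame.to_csv(out / f"survival_{arm}.csv", index=False)
    if bundle.subgroup_table is not None:
        bundle.subgroup_table.to_csv(out / "subgroups.csv", index=False)
    if bundle.sensitivity_table is not None:
        bundle.sensitivity_table.to_csv(out / "sensitivity.csv", index=False)
    summary = {
        "icer": {
            "mean_delta_cost_k": bundle.icer.mean_delta_cost,
            "mean_delta_effect_qaly": bundle.icer.mean_delta_effect,
            "classification": bundle.icer.classification,
            "icer_k_per_qaly": bundle.icer.icer,
        },
        "quadrant_probabilities": bundle.quadrants,
        "wtp_exceedance_probabilities":
            {f"{k:g}": v for k, v in bundle.threshold_probs.items()},
        "ceac_limit": cea.ceac_limit(bundle.cloud),
        "confidence_ellipse": {
            "center_effect_qaly": bundle.ellipse.center[0],
            "center_cost_k": bundle.ellipse.center[1],
            "semi_axes": list(bundle.ellipse.semi_axes),
            "orientation_rad": bundle.ellipse.orientation,
            "level": bundle.ellipse.level,
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=1)
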