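"""Kaplan-Meier estimation and quality-adjusted survival (utility AUC)."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trialcea.cohort import CohortConfig, generate_cohort
from trialcea.outcomes import (UtilityTrajectory, cohort_effects,
                               km_estimate, one_year_effect, utility_auc)


def km_oracle(times, events):
    """Hand-rolled product-limit estimator (deaths before censorings at ties).

    Returns {event_day: S(day)} over distinct death days.
    """
    n = len(times)
    order = sorted(range(n), key=lambda i: (times[i], not events[i]))
    s = 1.0
    out = {}
    at_risk = n
    i = 0
    while i < len(order):
        t = times[order[i]]
        deaths = censored = 0
        while i < len(order) and times[order[i]] == t:
            if events[order[i]]:
                deaths += 1
            else:
                censored += 1
            i += 1
        if deaths:
            s *= 1.0 - deaths / at_risk
            out[t] = s
        at_risk -= deaths + censored
    return out


class TestKaplanMeier:
    def test_hand_example(self):
        curve = km_estimate([1, 2, 3], [True, False, True])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(2.5) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_all_censored_is_flat_one(self):
        curve = km_estimate([10, 20, 30], [False, False, False])
        for d in (0, 5, 30, 100):
            assert curve.survival_at(d) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_exhaustive_four_patient_configurations(self):
        """Estimator matches the hand product-limit computation on every
        permutation of times x event-flag combination for 4 patients."""
        base_times = [1.0, 2.0, 2.0, 3.0]
        for times in set(itertools.permutations(base_times)):
            for flags in itertools.product([True, False], repeat=4):
                if not any(flags):
                    continue  # flat S == 1, covered above
                expected = km_oracle(list(times), list(flags))
                curve = km_estimate(list(times), list(flags))
                for day, s in expected.items():
                    assert curve.survival_at(day) == pytest.approx(s), \
                        (times, flags)

    def test_synthetic_arm_matches_configured_anchor(self):
        """KM survival at one year on an n=5000 synthetic PAC arm recovers
        the configured anchor within 3 Monte-Carlo SEs."""
        cohort = generate_cohort(CohortConfig(n_per_arm=5000, seed=5))
        pac = [p for p in cohort if p.arm == "PAC"]
        times = [p.death_day if p.death_day is not None else p.censor_day
                 for p in pac]
        events = [p.death_day is not None for p in pac]
        curve = km_estimate(times, events)
        target = 0.644
        se = np.sqrt(target * (1 - target) / 5000)
        assert abs(curve.survival_at(365) - target) < 3 * se


class TestUtilityAUC:
    def test_perfect_health_survivor_bound(self):
        traj = UtilityTrajectory([(61, 1.0)], death_day=None)
        assert utility_auc(traj) == pytest.approx(365.0)

    def test_death_at_day_zero(self):
        traj = UtilityTrajectory([], death_day=0.0)
        assert utility_auc(traj) == 0.0

    def test_two_segment_trapezoid(self):
        """Carry-back then linear interpolation: 61*0.4 + 304*0.5 = 176.4."""
        traj = UtilityTrajectory([(61, 0.4), (365, 0.6)], death_day=None)
        assert utility_auc(traj) == pytest.approx(61 * 0.4 + 304 * 0.5)

    def test_point_after_death_rejected(self):
        with pytest.raises(ValueError):
            UtilityTrajectory([(100, 0.5)], death_day=90.0)

    def test_zero_until_discharge_mode(self):
        traj = UtilityTrajectory([(61, 0.4)], death_day=None)
        auc = utility_auc(traj, hospital_phase="zero_until_discharge",
                          discharge_day=30.0)
        # zero for 30 days, 0.4 from discharge through day 365
        assert auc == pytest.approx((365 - 30) * 0.4)

    @given(st.lists(st.tuples(st.floats(1.0, 364.0), st.floats(0.0, 1.0)),
                    min_size=1, max_size=6,
                    unique_by=lambda t: round(t[0], 3)),
           st.one_of(st.none(), st.floats(30.0, 365.0)))
    @settings(max_examples=60, deadline=None)
    def test_matches_fine_grid_riemann_sum(self, raw_points, death):
        """Trapezoid AUC agrees with a 0.01-day Riemann sum to 1e-6 relative."""
        end = 365.0 if death is None else min(death, 365.0)
        points = sorted((d, u) for d, u in raw_points if d <= end)
        if not points:
            return
        traj = UtilityTrajectory(points, death_day=death)
        auc = utility_auc(traj)

        n_cells = max(int(end / 0.01), 1000)  # cell width <= 0.01 day
        edges = np.linspace(0.0, end, n_cells + 1)
        mids = (edges[:-1] + edges[1:]) / 2
        width = end / n_cells
        days = np.array([d for d, _ in points])
        vals = np.array([u for _, u in points])
        xs = np.concatenate([[0.0], days, [end]])
        ys = np.concatenate([[vals[0]], vals, [vals[-1]]])
        riemann = float(np.interp(mids, xs, ys).sum() * width)
        assert auc == pytest.approx(riemann, rel=1e-6, abs=1e-4)

    def test_bounded_by_survival_time(self, small_cohort):
        effects, _ = cohort_effects(small_cohort)
        for p, e in zip(small_cohort, effects):
            end = min(p.death_day, 365) if p.death_day is not None else 365
            assert 0.0 <= e.qa_days_one_year <= end + 1e-9


class TestOneYearEffect:
    def test_survivor_constant_half_utility(self):
        p = _patient(utilities=[(61, 0.5, False), (365, 0.5, False)])
        eff = one_year_effect(p)
        assert eff.qa_days_one_year == pytest.approx(182.5)
        assert eff.life_years_one_year == 1.0

    def test_decedent_rectangle(self):
        p = _patient(death_day=100.0, utilities=[(61, 0.6, False)])
        eff = one_year_effect(p)
        assert eff.qa_days_one_year == pytest.approx(60.0)  # 100 x 0.6
        assert eff.life_years_one_year == pytest.approx(100 / 365)

    def test_no_interviews_uses_median_trajectory(self):
        p = _patient(utilities=[])
        eff = one_year_effect(p, median_trajectory=[(61.0, 0.5), (365.0, 0.5)])
        assert eff.imputed
        assert eff.qa_days_one_year == pytest.approx(182.5)

    def test_no_interviews_no_imputation_raises(self):
        with pytest.raises(ValueError, match="no completed interview"):
            one_year_effect(_patient(utilities=[]))

    def test_unresolved_vital_status_raises(self):
        p = _patient(censor_day=200.0)
        with pytest.raises(ValueError, match="unresolved"):
            one_year_effect(p)

    def test_cohort_mean_recovers_generator_targets(self):
        """Mean one-year QA-days per arm sits in the plausible band implied
        by the configured utility medians and mortality (parameter recovery)."""
        cohort = generate_cohort(CohortConfig(n_per_arm=1500, seed=13))
        effects, _ = cohort_effects(cohort)
        for arm, (lo, hi) in (("PAC", (100, 200)), ("CVC", (110, 215))):
            qa = np.array([e.qa_days_one_year
                           for p, e in zip(cohort, effects) if p.arm == arm])
            assert lo < qa.mean() < hi
        # CVC is configured with higher utilities and survival
        pac = np.mean([e.qa_days_one_year for p, e in zip(cohort, effects)
                       if p.arm == "PAC"])
        cvc = np.mean([e.qa_days_one_year for p, e in zip(cohort, effects)
                       if p.arm == "CVC"])
        assert cvc > pac


def _patient(death_day=None, censor_day=365.0, utilities=(),
             discharged=True):
    from trialcea.cohort import PatientRecord, ResourceUse
    return PatientRecord(
        id="T-0", arm="PAC", age=50.0, sex="F", race="white", apache3=90.0,
        fluid_strategy="liberal", tidal_volume=7.0, delay_to_protocol=20.0,
        diagnosis="sepsis", death_day=death_day, censor_day=censor_day,
        discharged_alive=discharged, hospital_cost=0.0,
        utilities=list(utilities), resources=ResourceUse(),
    )
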