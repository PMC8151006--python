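"""Annual-cycle engine: trajectories, cohort aggregation, pairing."""

import numpy as np
import pytest

from tabsim import Individual, run_cohort, simulate_individual, build_state_risk_table
from tabsim.conditions import AGE_BANDS
from tabsim.risk import StateRiskTable, annual_probability


def flat_table(rate: float, case_fatality: float, conditions=("ami",)) -> StateRiskTable:
    """A table with one uniform rate everywhere, for transparent scalar tests."""
    C = len(conditions)
    shape = (C, 2, len(AGE_BANDS))
    return StateRiskTable(
        conditions=tuple(conditions),
        rate=np.full(shape + (3,), rate),
        case_fatality=np.full(shape, case_fatality),
        population_rate=np.full(shape, rate),
        qol_decrement=np.full(C, 0.2),
    )


def stream(seed=0):
    return np.random.Generator(np.random.Philox(key=seed))


class TestSimulateIndividual:
    def test_null_risks_give_full_life_years_and_nothing_else(self):
        ind = Individual(0, "male", 40, "never")
        simulate_individual(ind, flat_table(0.0, 0.5), None, 10, stream())
        assert ind.accrued_life_years == 10
        assert ind.accrued_qalys == 10
        assert ind.accrued_cost == 0
        assert ind.disease_history == {}
        assert ind.alive

    def test_certain_fatal_event_kills_after_one_full_cycle(self):
        # probability ~1 and case fatality 1: one accrued life-year, then death
        ind = Individual(0, "female", 50, "current")
        traj = simulate_individual(ind, flat_table(50.0, 1.0), None, 10, stream())
        assert not ind.alive
        assert ind.accrued_life_years == 1.0
        assert traj[0]["died"] and traj[0]["cause"] == "ami"
        assert len([r for r in traj if r["died"]]) == 1

    def test_dead_individuals_accrue_nothing_further(self):
        ind = Individual(0, "male", 60, "current")
        simulate_individual(ind, flat_table(50.0, 1.0), None, 10, stream())
        assert (ind.accrued_life_years, ind.accrued_qalys) == (1.0, 1.0)

    def test_fixed_seed_reproduces_trajectory(self):
        t1 = simulate_individual(
            Individual(0, "male", 45, "current"), flat_table(0.05, 0.3), None, 10, stream(42)
        )
        t2 = simulate_individual(
            Individual(0, "male", 45, "current"), flat_table(0.05, 0.3), None, 10, stream(42)
        )
        assert t1 == t2

    def test_age_below_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            simulate_individual(
                Individual(0, "male", 20, "never"), flat_table(0.0, 0.5), None, 5, stream()
            )

    def test_quality_decrement_applies_in_years_after_onset(self):
        rng = stream(3)
        ind = Individual(0, "male", 40, "current")
        traj = simulate_individual(ind, flat_table(50.0, 0.0), None, 3, rng)
        # event certain in year 1, survival certain (cf 0): later years lose 0.2
        assert traj[0]["qaly"] == 1.0
        assert traj[1]["qaly"] == pytest.approx(0.8)
        assert ind.accrued_qalys == pytest.approx(1.0 + 0.8 + 0.8)


class TestRunCohort:
    def test_same_seed_gives_identical_results(self, ar, risk):
        table = build_state_risk_table(ar, risk)
        a = run_cohort(3000, 17, ar, table, risk, horizon=5)
        b = run_cohort(3000, 17, ar, table, risk, horizon=5)
        assert a.by_year_sex.equals(b.by_year_sex)
        assert a.events.equals(b.events)

    def test_counts_respect_cohort_bounds(self, ar, risk):
        table = build_state_risk_table(ar, risk)
        res = run_cohort(5000, 1, ar, table, risk, horizon=10)
        assert res.by_year_sex["deaths"].sum() <= res.cohort_size
        per_year = res.by_year_sex.groupby("year")["person_years"].sum()
        assert (per_year <= res.cohort_size).all()
        assert (res.by_year_sex.select_dtypes("number") >= 0).all().all()
        assert (res.events.select_dtypes("number") >= 0).all().all()

    def test_person_years_shrink_as_cohort_depletes(self, ar, risk):
        table = build_state_risk_table(ar, risk)
        res = run_cohort(20000, 2, ar, table, risk, horizon=10)
        per_year = res.by_year_sex.groupby("year")["person_years"].sum()
        assert per_year.is_monotonic_decreasing

    def test_all_current_cohort_suffers_more_events_than_all_never(self, ar, risk):
        table = build_state_risk_table(ar, risk)
        never = {"male": (0.0, 0.0, 1.0), "female": (0.0, 0.0, 1.0)}
        current = {"male": (1.0, 0.0, 0.0), "female": (1.0, 0.0, 0.0)}
        res_nev = run_cohort(50000, 5, ar, table, risk, state_distribution=never)
        res_cur = run_cohort(50000, 5, ar, table, risk, state_distribution=current)
        assert res_cur.events["events"].sum() > res_nev.events["events"].sum()
        # pathwise dominance: every condition weakly worse under smoking
        nev = res_nev.events_by_condition()
        cur = res_cur.events_by_condition()
        assert (cur >= nev).all()

    def test_first_cycle_event_counts_match_binomial_expectation(self, ar, risk):
        """Empirical year-1 rates within 3 binomial SEs of the table probabilities."""
        table = build_state_risk_table(ar, risk)
        never = {"male": (0.0, 0.0, 1.0), "female": (0.0, 0.0, 1.0)}
        res = run_cohort(50000, 9, ar, table, risk, state_distribution=never, horizon=1)
        probs = annual_probability(table.rate[..., 2])  # never-smoker column
        y1 = res.events[res.events.year == 1]
        for si, sex in enumerate(("male", "female")):
            n_sex = res.sex_counts[sex]
            for ci, cond in enumerate(table.conditions):
                p = probs[ci, si, 0]
                got = int(y1[(y1.sex == sex) & (y1.condition == cond)]["events"].iloc[0])
                se = np.sqrt(n_sex * p * (1 - p))
                assert abs(got - n_sex * p) <= 3 * se + 1

    def test_invalid_cohort_size_rejected(self, ar, risk):
        table = build_state_risk_table(ar, risk)
        with pytest.raises(ValueError, match="cohort size"):
            run_cohort(0, 1, ar, table, risk)

    def test_standard_errors_reported_for_core_outcomes(self, ar, risk):
        from tabsim.economics import cost_model_from_country

        table = build_state_risk_table(ar, risk)
        cm = cost_model_from_country(ar)
        res = run_cohort(2000, 1, ar, table, risk, horizon=3, cost_model=cm)
        for key in ("deaths_per_person", "life_years_per_person", "cost_per_person"):
            assert res.mc_standard_errors[key] > 0

    def test_long_export_format_round_trips_totals(self, ar, risk):
        table = build_state_risk_table(ar, risk)
        res = run_cohort(2000, 1, ar, table, risk, horizon=3)
        long = res.to_long_frame()
        deaths = long[(long.outcome == "deaths")]["value"].sum()
        assert deaths == res.total("deaths")
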