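"""Individual-based annual-cycle simulation of smoking-related disease.

Hypothetical cohorts of adults aged 35+ are followed in yearly cycles.
Each cycle an individual can suffer acute events (myocardial infarction,
stroke, pneumonia, a COPD event) and cancer onsets, each sampled from the
smoking-state-specific annual probabilities; events are fatal with their
case-fatality probability; background (non-modelled-cause) mortality is
applied afterwards from the residual life table. Survivors carry their
disease history, which drives follow-up costs and quality-of-life
decrements in later years.

Accounting is full-cycle: an individual alive at the start of a cycle
accrues the whole year of life (and its quality-adjusted fraction and
costs); death takes effect at the end of the cycle.

Randomness is counter-based (Philox keyed by the run seed) and the draw
layout is fixed per (individual, year, hazard) regardless of who is alive
or what policy is in force, so a baseline and a policy run with the same
seed are common-random-number paired: an individual experiences the same
luck in both runs and run differences estimate policy effects with far
lower variance. Smoking state is assigned each year by inverting the
year's (current, former, never) distribution on a single per-individual
uniform, so a prevalence reduction moves the marginal individuals to
lower-risk states and leaves everyone else untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from tabsim.conditions import AGE_BANDS, SEXES, condition
from tabsim.parameters import CountryParameters, RiskParameters
from tabsim.policy import PolicyYearState
from tabsim.risk import StateRiskTable, annual_probability, apply_intensity_adjustment

_N_BANDS = len(AGE_BANDS)


@dataclass
class Individual:
    """One simulated person."""

    id: int
    sex: str
    age: float
    smoking_state: str  # never | current | former
    alive: bool = True
    disease_history: dict[str, int] = field(default_factory=dict)  # condition -> onset year
    accrued_life_years: float = 0.0
    accrued_qalys: float = 0.0
    accrued_cost: float = 0.0


@dataclass
class SimulationResult:
    """Aggregated outcomes of one cohort run.

    ``by_year_sex`` holds deaths, person-years, quality-adjusted years and
    costs per (year, sex); ``events`` holds per-condition event counts,
    condition-attributed deaths and condition-years (years lived with the
    condition). Hospitalizations are reported equal to acute event counts.
    """

    by_year_sex: pd.DataFrame
    events: pd.DataFrame
    cohort_size: int
    seed: int
    horizon: int
    conditions: tuple[str, ...]
    mc_standard_errors: dict[str, float]
    sex_counts: dict[str, int]

    def total(self, outcome: str) -> float:
        return float(self.by_year_sex[outcome].sum())

    def events_by_condition(self) -> pd.Series:
        return self.events.groupby("condition", sort=False)["events"].sum()

    def deaths_by_condition(self) -> pd.Series:
        return self.events.groupby("condition", sort=False)["condition_deaths"].sum()

    def condition_years_by_condition(self) -> pd.Series:
        return self.events.groupby("condition", sort=False)["condition_years"].sum()

    def to_long_frame(self) -> pd.DataFrame:
        """Long (year, sex, outcome, value) export format."""
        core = self.by_year_sex.melt(
            id_vars=["year", "sex"], var_name="outcome", value_name="value"
        )
        ev = self.events.melt(
            id_vars=["year", "sex", "condition"], var_name="outcome", value_name="value"
        )
        ev["outcome"] = ev["outcome"] + ":" + ev.pop("condition")
        return pd.concat([core, ev], ignore_index=True)

    def meta(self) -> tuple[int, int, int]:
        return (self.cohort_size, self.seed, self.horizon)


def _cost_arrays(conditions: Sequence[str], cost_model) -> tuple[np.ndarray, np.ndarray]:
    acute = np.zeros(len(conditions))
    follow = np.zeros(len(conditions))
    if cost_model is not None:
        for i, c in enumerate(conditions):
            acute[i] = cost_model.acute_cost.get(c, 0.0)
            follow[i] = cost_model.followup_cost.get(c, 0.0)
    return acute, follow


def _constant_schedule(
    distribution: dict[str, tuple[float, float, float]], horizon: int
) -> list[PolicyYearState]:
    return [PolicyYearState(t, distribution, 0.0) for t in range(1, horizon + 1)]


def run_cohort(
    n: int,
    seed: int,
    params: CountryParameters,
    risks: StateRiskTable,
    risk_params: RiskParameters | None = None,
    state_distribution: dict[str, tuple[float, float, float]] | None = None,
    horizon: int = 10,
    schedule: Sequence[PolicyYearState] | None = None,
    cost_model=None,
    discount_rate: float = 0.0,
) -> SimulationResult:
    """Simulate a cohort of ``n`` individuals for ``horizon`` annual cycles.

    ``schedule`` (one :class:`PolicyYearState` per year) supplies per-year
    smoking-state distributions and the consumption reduction among
    continuing smokers; without one, ``state_distribution`` (default: the
    country baseline) is held constant — the status-quo/baseline run.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    if schedule is None:
        dist = state_distribution or params.state_distribution()
        schedule = _constant_schedule(dist, horizon)
    if len(schedule) < horizon:
        raise ValueError("schedule shorter than horizon")

    conds = risks.conditions
    C = len(conds)
    cancer_mask = np.array([condition(c).kind == "cancer" for c in conds])
    acute_cost, follow_cost = _cost_arrays(conds, cost_model)
    qol = risks.qol_decrement

    rng = np.random.Generator(np.random.Philox(key=seed))

    # --- initialize cohort (3 uniforms per individual) ---
    u_init = rng.random((n, 3))
    weights = np.concatenate(
        [np.asarray(params.age_sex_structure[s], dtype=float) for s in SEXES]
    )
    cum = np.cumsum(weights / weights.sum())
    cell = np.searchsorted(cum, u_init[:, 0], side="right")
    cell = np.minimum(cell, 2 * _N_BANDS - 1)
    sex_idx = cell // _N_BANDS  # 0 male, 1 female
    band0 = cell % _N_BANDS
    band_width = np.where(band0 == _N_BANDS - 1, 10.0, 5.0)  # open-ended 85+ band
    age = np.array(AGE_BANDS)[band0] + u_init[:, 1] * band_width
    u_state = u_init[:, 2]  # one persistent uniform drives state assignment

    alive = np.ones(n, dtype=bool)
    has_cond = np.zeros((n, C), dtype=bool)

    # per-individual accumulators (for Monte Carlo standard errors)
    ind_life = np.zeros(n)
    ind_qaly = np.zeros(n)
    ind_cost = np.zeros(n)
    ind_died = np.zeros(n, dtype=bool)
    ind_events = np.zeros(n)

    bg = np.array([params.background_mortality[s] for s in SEXES])  # (2, B)

    rows = []
    ev_rows = []
    adjusted_cache: dict[float, np.ndarray] = {}

    for t in range(1, horizon + 1):
        ystate = schedule[t - 1]
        red = float(ystate.consumption_reduction)
        if red not in adjusted_cache:
            table_t = (
                apply_intensity_adjustment(risks, risk_params, red)
                if (red > 0 and risk_params is not None)
                else risks
            )
            adjusted_cache[red] = annual_probability(table_t.rate)  # (C, 2, B, 3)
        prob_t = adjusted_cache[red]

        # state assignment by inverse CDF of this year's distribution
        state_idx = np.full(n, 2, dtype=np.int64)  # never
        for si, sex in enumerate(SEXES):
            p_cur, p_for, _ = ystate.distribution[sex]
            mask = sex_idx == si
            state_idx[mask & (u_state < p_cur + p_for)] = 1
            state_idx[mask & (u_state < p_cur)] = 0

        band = np.clip((age - AGE_BANDS[0]) // 5, 0, _N_BANDS - 1).astype(np.int64)

        u = rng.random((n, C + 1))  # drawn for everyone, alive or not (CRN layout)

        p_ind = prob_t[:, sex_idx, band, state_idx].T  # (n, C)
        cf_ind = risks.case_fatality[:, sex_idx, band].T  # (n, C)

        eligible = alive[:, None] & ~(has_cond & cancer_mask[None, :])
        events = (u[:, :C] < p_ind) & eligible
        fatal = (u[:, :C] < p_ind * cf_ind) & events

        # full-cycle accrual for everyone alive at cycle start
        active = has_cond & alive[:, None]  # condition-years: held at start of year
        qaly_frac = np.clip(1.0 - active @ qol, 0.0, 1.0) * alive
        year_cost = events @ acute_cost + active @ follow_cost
        disc = 1.0 / (1.0 + discount_rate) ** (t - 1)

        fatal_any = fatal.any(axis=1)
        bg_dead = alive & (u[:, C] < bg[sex_idx, band]) & ~fatal_any
        new_dead = fatal_any | bg_dead

        # death attribution: first fatal condition in adjudication order
        first_fatal = np.argmax(fatal, axis=1)

        for si, sex in enumerate(SEXES):
            m = sex_idx == si
            rows.append(
                {
                    "year": t,
                    "sex": sex,
                    "deaths": int(new_dead[m].sum()),
                    "background_deaths": int(bg_dead[m].sum()),
                    "person_years": float(alive[m].sum()),
                    "qalys": float(qaly_frac[m].sum()),
                    "cost": float((year_cost[m] * disc).sum()),
                }
            )
            for ci, cname in enumerate(conds):
                ev_rows.append(
                    {
                        "year": t,
                        "sex": sex,
                        "condition": cname,
                        "events": int(events[m, ci].sum()),
                        "condition_deaths": int(
                            (fatal_any[m] & (first_fatal[m] == ci) & fatal[m, ci]).sum()
                        ),
                        "condition_years": float(active[m, ci].sum()),
                    }
                )

        ind_life += alive
        ind_qaly += qaly_frac
        ind_cost += year_cost * disc
        ind_events += events.sum(axis=1)
        ind_died |= new_dead

        has_cond |= events
        alive &= ~new_dead
        age += 1.0

    by_year_sex = pd.DataFrame(rows)
    ev = pd.DataFrame(ev_rows)
    se = {
        "deaths_per_person": float(ind_died.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "life_years_per_person": float(ind_life.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "qalys_per_person": float(ind_qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "cost_per_person": float(ind_cost.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "events_per_person": float(ind_events.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
    }
    sex_counts = {s: int((sex_idx == si).sum()) for si, s in enumerate(SEXES)}
    return SimulationResult(
        by_year_sex=by_year_sex,
        events=ev,
        cohort_size=n,
        seed=seed,
        horizon=horizon,
        conditions=conds,
        mc_standard_errors=se,
        sex_counts=sex_counts,
    )


def simulate_individual(
    ind: Individual,
    risks: StateRiskTable,
    risk_params: RiskParameters | None,
    horizon: int,
    rng_stream: np.random.Generator,
    cost_model=None,
    background_mortality: dict[str, list[float]] | None = None,
) -> list[dict]:
    """Follow one individual for ``horizon`` cycles; returns the trajectory.

    The individual is mutated in place (ages, accrues outcomes, may die).
    Each trajectory row records the year, age, smoking state, new events,
    and whether the individual died that cycle. Without a
    ``background_mortality`` life table only the modelled diseases can
    kill, which makes single trajectories easy to reason about in tests.
    Deterministic given the generator's state.
    """
    if not ind.alive:
        raise ValueError("individual must be alive at entry")
    if ind.age < AGE_BANDS[0]:
        raise ValueError(f"age {ind.age} outside risk-table support (>= {AGE_BANDS[0]})")
    conds = risks.conditions
    C = len(conds)
    si = SEXES.index(ind.sex)
    state_i = {"current": 0, "former": 1, "never": 2}[ind.smoking_state]
    acute_cost, follow_cost = _cost_arrays(conds, cost_model)
    prob = annual_probability(risks.rate)

    trajectory = []
    for t in range(1, horizon + 1):
        u = rng_stream.random(C + 1)
        if not ind.alive:
            continue
        band = int(np.clip((ind.age - AGE_BANDS[0]) // 5, 0, _N_BANDS - 1))
        new_events, died_of = [], None
        qaly = 1.0
        cost = 0.0
        for ci, cname in enumerate(conds):
            if cname in ind.disease_history:
                qaly -= risks.qol_decrement[ci]
                cost += follow_cost[ci]
        qaly = max(0.0, qaly)
        for ci, cname in enumerate(conds):
            already = cname in ind.disease_history
            if already and condition(cname).kind == "cancer":
                continue
            p = prob[ci, si, band, state_i]
            if u[ci] < p:
                new_events.append(cname)
                cost += acute_cost[ci]
                ind.disease_history.setdefault(cname, t)
                if u[ci] < p * risks.case_fatality[ci, si, band] and died_of is None:
                    died_of = cname
        bg_q = (
            background_mortality[ind.sex][band] if background_mortality is not None else 0.0
        )
        ind.accrued_life_years += 1.0
        ind.accrued_qalys += qaly
        ind.accrued_cost += cost
        died = died_of is not None
        if not died and u[C] < bg_q:
            died = True
            died_of = "background"
        trajectory.append(
            {
                "year": t,
                "age": ind.age,
                "smoking_state": ind.smoking_state,
                "events": new_events,
                "died": died,
                "cause": died_of,
                "qaly": qaly,
                "cost": cost,
            }
        )
        if died:
            ind.alive = False
        ind.age += 1.0
    return trajectory
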