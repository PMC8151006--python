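"""Derivation of smoking-state-specific annual risks.

National statistics report population-average rates. Given smoking
prevalence and the relative risks of current and former smokers, the
never-smoker baseline rate r_ns solves

    rate_pop = p_cur * rr_cur * r_ns + p_for * rr_for * r_ns
               + (1 - p_cur - p_for) * r_ns

so r_ns = rate_pop / (p_cur * rr_cur + p_for * rr_for + (1 - p_cur - p_for)),
and the state-specific rates are rr * r_ns. Mixing the state rates back with
the prevalences reproduces the population rate exactly — the conservation
property every table built here satisfies.

For acute events the population *event* rate is back-calculated from the
cause-specific mortality rate and the event's case fatality; cancers use
incidence directly when available (falling back to the same mortality /
case-fatality arithmetic when a country table has mortality only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tabsim.conditions import AGE_BANDS, SEXES, condition
from tabsim.parameters import CountryParameters, RiskParameters

#: Smoking-state axis order used throughout the package.
STATES = ("current", "former", "never")


def nonsmoker_baseline_rate(rate_pop, p_cur, p_for, rr_cur, rr_for):
    """Never-smoker event rate implied by a population rate and prevalence mix.

    All arguments broadcast; rates are events per person-year.
    """
    rate_pop = np.asarray(rate_pop, dtype=float)
    p_cur = np.asarray(p_cur, dtype=float)
    p_for = np.asarray(p_for, dtype=float)
    rr_cur = np.asarray(rr_cur, dtype=float)
    rr_for = np.asarray(rr_for, dtype=float)
    if np.any(rate_pop < 0):
        raise ValueError("population rate must be >= 0")
    if np.any(p_cur < 0) or np.any(p_for < 0) or np.any(p_cur + p_for > 1):
        raise ValueError("prevalences must be >= 0 and sum to <= 1")
    if np.any(rr_for < 1) or np.any(rr_cur < rr_for):
        raise ValueError("need rr_cur >= rr_for >= 1")
    denom = p_cur * rr_cur + p_for * rr_for + (1.0 - p_cur - p_for)
    if np.any(denom <= 0):
        raise ValueError("mixture denominator must be positive")
    out = rate_pop / denom
    return float(out) if out.ndim == 0 else out


def intensity_adjusted_rr(rr_cur, rr_for, consumption_reduction, excess_fraction):
    """Relative risk of a smoker who cut consumption by ``consumption_reduction``.

    Cutting down removes ``consumption_reduction * excess_fraction`` of the
    current-vs-former excess risk: rr_cur - red * frac * (rr_cur - rr_for).
    The result always stays in [rr_for, rr_cur].
    """
    rr_cur = np.asarray(rr_cur, dtype=float)
    rr_for = np.asarray(rr_for, dtype=float)
    red = np.asarray(consumption_reduction, dtype=float)
    frac = np.asarray(excess_fraction, dtype=float)
    if np.any((red < 0) | (red > 1)) or np.any((frac < 0) | (frac > 1)):
        raise ValueError("consumption_reduction and excess_fraction must be in [0, 1]")
    if np.any(rr_cur < rr_for):
        raise ValueError("need rr_cur >= rr_for")
    out = rr_cur - red * frac * (rr_cur - rr_for)
    return float(out) if out.ndim == 0 else out


def annual_probability(rate):
    """Rate (events/person-year) to annual event probability, 1 - exp(-rate)."""
    return -np.expm1(-np.asarray(rate, dtype=float))


@dataclass
class StateRiskTable:
    """Annual event rates per (condition, sex, age band, smoking state).

    ``rate`` has shape (C, 2, B, 3) with the sex axis ordered (male, female)
    and the state axis ordered (current, former, never). ``case_fatality``
    has shape (C, 2, B). ``population_rate`` (C, 2, B) is the rate the table
    was derived from, kept for conservation checks and calibration.
    """

    conditions: tuple[str, ...]
    rate: np.ndarray
    case_fatality: np.ndarray
    population_rate: np.ndarray
    qol_decrement: np.ndarray  # (C,)

    def __post_init__(self) -> None:
        C, S, B = len(self.conditions), len(SEXES), len(AGE_BANDS)
        assert self.rate.shape == (C, S, B, len(STATES))
        assert self.case_fatality.shape == (C, S, B)
        # never <= former <= current in every cell
        cur, for_, nev = self.rate[..., 0], self.rate[..., 1], self.rate[..., 2]
        if np.any(nev - for_ > 1e-12) or np.any(for_ - cur > 1e-12):
            raise ValueError("state rates must satisfy never <= former <= current")

    def probability(self) -> np.ndarray:
        """Annual event probabilities, same shape as ``rate``."""
        return annual_probability(self.rate)

    def condition_index(self, name: str) -> int:
        return self.conditions.index(name)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view (condition, sex, age_band, state rates) for export."""
        rows = []
        for ci, cond in enumerate(self.conditions):
            for si, sex in enumerate(SEXES):
                for bi, band in enumerate(AGE_BANDS):
                    rows.append(
                        {
                            "condition": cond,
                            "sex": sex,
                            "age_band": band,
                            "rate_population": self.population_rate[ci, si, bi],
                            "rate_current": self.rate[ci, si, bi, 0],
                            "rate_former": self.rate[ci, si, bi, 1],
                            "rate_nonsmoker": self.rate[ci, si, bi, 2],
                            "case_fatality": self.case_fatality[ci, si, bi],
                        }
                    )
        return pd.DataFrame(rows)


def _population_event_rate(
    params: CountryParameters, risk: RiskParameters, cond_name: str
) -> dict[str, float] | None:
    """Population event rate per person-year for one condition, or None."""
    kind = condition(cond_name).kind
    cf = float(risk.case_fatality.get(cond_name, 0.0))
    if kind == "cancer" and cond_name in params.cancer_incidence:
        return {s: v / 1e4 for s, v in params.cancer_incidence[cond_name].items()}
    if cond_name in params.mortality_rates:
        by_sex = params.mortality_rates[cond_name]
        out = {}
        for sex, mort in by_sex.items():
            mort = mort / 1e4
            if mort > 0 and cf <= 0:
                raise ValueError(
                    f"case_fatality for {cond_name} is 0 but mortality is nonzero; "
                    "cannot back-calculate the event rate"
                )
            out[sex] = mort / cf if mort > 0 else 0.0
        return out
    return None


def build_state_risk_table(
    params: CountryParameters,
    risk: RiskParameters,
    scaling_factors: dict[tuple[str, str], float] | None = None,
) -> StateRiskTable:
    """Build the per-state annual risk table for a country.

    ``scaling_factors`` maps (condition, sex) to a multiplicative factor on
    the population rate (the calibration hook). Conditions are included when
    the country table has a rate for them *and* the risk table covers them.
    """
    conds = [c for c in params.modelled_conditions() if c in risk.rr_current]
    C, S, B = len(conds), len(SEXES), len(AGE_BANDS)
    rate = np.zeros((C, S, B, len(STATES)))
    cf_arr = np.zeros((C, S, B))
    pop_rate = np.zeros((C, S, B))
    qol = np.zeros(C)

    for ci, cond_name in enumerate(conds):
        rr_c = float(risk.rr_current[cond_name])
        rr_f = float(risk.rr_former.get(cond_name, 1.0))
        qol[ci] = float(risk.qol_decrement.get(cond_name, 0.0))
        per_sex = _population_event_rate(params, risk, cond_name)
        for si, sex in enumerate(SEXES):
            r_pop = float(per_sex.get(sex, 0.0))
            if scaling_factors:
                r_pop *= float(scaling_factors.get((cond_name, sex), 1.0))
            p_cur = params.smoking_prevalence[sex]
            p_for = params.former_prevalence[sex]
            r_ns = nonsmoker_baseline_rate(r_pop, p_cur, p_for, rr_c, rr_f)
            # Uniform across age bands unless an age-resolved table is supplied.
            rate[ci, si, :, 0] = rr_c * r_ns
            rate[ci, si, :, 1] = rr_f * r_ns
            rate[ci, si, :, 2] = r_ns
            pop_rate[ci, si, :] = r_pop
            cf_arr[ci, si, :] = float(risk.case_fatality.get(cond_name, 0.0))

    return StateRiskTable(
        conditions=tuple(conds),
        rate=rate,
        case_fatality=cf_arr,
        population_rate=pop_rate,
        qol_decrement=qol,
    )


def apply_intensity_adjustment(
    table: StateRiskTable,
    risk: RiskParameters,
    consumption_reduction: float,
) -> StateRiskTable:
    """Return a table whose current-smoker rates reflect reduced consumption.

    The never/former rates and the derivation baseline are untouched; only
    the current-smoker relative risk is pulled toward the former-smoker
    level by the condition-specific excess-risk fraction.
    """
    if consumption_reduction == 0:
        return table
    new_rate = table.rate.copy()
    for ci, cond_name in enumerate(table.conditions):
        rr_c = float(risk.rr_current[cond_name])
        rr_f = float(risk.rr_former.get(cond_name, 1.0))
        frac = float(risk.excess_risk_reduction[cond_name])
        rr_adj = intensity_adjusted_rr(rr_c, rr_f, consumption_reduction, frac)
        r_ns = table.rate[ci, :, :, 2]
        new_rate[ci, :, :, 0] = rr_adj * r_ns
    return StateRiskTable(
        conditions=table.conditions,
        rate=new_rate,
        case_fatality=table.case_fatality,
        population_rate=table.population_rate,
        qol_decrement=table.qol_decrement,
    )
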