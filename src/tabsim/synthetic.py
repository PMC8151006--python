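"""Self-consistent synthetic countries with known ground truth.

The generator draws never-smoker rates, relative risks and prevalences,
then *forward-computes* the population-level rates a national statistics
office would observe as the prevalence-weighted mixture

    rate_pop = p_cur * rr_cur * r_ns + p_for * rr_for * r_ns
               + (1 - p_cur - p_for) * r_ns.

Because the country table is built from that mixture, every downstream
derivation is testable against truth: the risk engine must invert the
mixture back to r_ns exactly, and calibration against a noise-free
reference must recover unit scaling factors (parameter recovery).

For acute conditions the drawn base rate is the never-smoker *mortality*
rate; for cancers it is the never-smoker *incidence*. The matching
reference mortality for cancers is incidence x case fatality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tabsim.conditions import AGE_BANDS, CONDITION_NAMES, SEXES, condition
from tabsim.parameters import (
    CountryParameters,
    RiskParameters,
    default_age_sex_structure,
    default_background_mortality,
)

#: Bounds for generated current-smoking prevalence.
PREVALENCE_BOUNDS = (0.05, 0.40)
#: Bounds for generated relative risks (cardiovascular- to lung-cancer-scale).
RR_BOUNDS = (1.5, 20.0)
#: Never-smoker base rate bounds, per person-year (2-20 per 10,000).
BASE_RATE_BOUNDS = (2e-4, 2e-3)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated country."""

    seed: int
    true_rr: dict[str, float]
    true_rr_former: dict[str, float]
    true_case_fatality: dict[str, float]
    true_qol_decrement: dict[str, float]
    true_prevalence: dict[str, tuple[float, float]]  # sex -> (current, former)
    #: never-smoker base rate per (condition, sex), repeated over age bands
    true_nonsmoker_rates: dict[tuple[str, str], list[float]] = field(default_factory=dict)
    #: forward-computed population rate per (condition, sex)
    implied_population_rates: dict[tuple[str, str], float] = field(default_factory=dict)

    def risk_parameters(self) -> RiskParameters:
        return RiskParameters(
            rr_current=dict(self.true_rr),
            rr_former=dict(self.true_rr_former),
            case_fatality=dict(self.true_case_fatality),
            qol_decrement=dict(self.true_qol_decrement),
        )

    def mortality_reference(self) -> dict[tuple[str, str], float]:
        """Condition-specific mortality per person-year implied by truth."""
        out = {}
        for (cond_name, sex), rate in self.implied_population_rates.items():
            if condition(cond_name).kind == "cancer":
                out[(cond_name, sex)] = rate * self.true_case_fatality[cond_name]
            else:
                out[(cond_name, sex)] = rate
        return out


def generate_country(
    seed: int,
    scale: int = 100_000,
    conditions: tuple[str, ...] = CONDITION_NAMES,
) -> tuple[CountryParameters, SyntheticTruth]:
    """Generate a valid synthetic country and the truth that produced it.

    ``scale`` is the notional population size (>= 1000 for stable rates).
    Deterministic given ``seed``: all draws come from one Philox stream
    keyed by it.
    """
    if scale < 1000:
        raise ValueError(f"scale must be >= 1000 for stable rates, got {scale}")
    rng = np.random.Generator(np.random.Philox(key=seed))

    prevalence: dict[str, tuple[float, float]] = {}
    for sex in SEXES:
        p_cur = float(rng.uniform(*PREVALENCE_BOUNDS))
        p_for = float(p_cur * rng.uniform(0.3, 0.7))
        prevalence[sex] = (p_cur, p_for)

    rr_cur = {c: float(rng.uniform(*RR_BOUNDS)) for c in conditions}
    rr_for = {c: 1.0 + (rr_cur[c] - 1.0) * float(rng.uniform(0.2, 0.5)) for c in conditions}
    cf = {c: float(rng.uniform(0.05, 0.9)) for c in conditions}
    qol = {c: float(rng.uniform(0.05, 0.4)) for c in conditions}

    truth = SyntheticTruth(
        seed=seed,
        true_rr=rr_cur,
        true_rr_former=rr_for,
        true_case_fatality=cf,
        true_qol_decrement=qol,
        true_prevalence=prevalence,
    )

    mortality_rates: dict[str, dict[str, float]] = {}
    cancer_incidence: dict[str, dict[str, float]] = {}
    for cond_name in conditions:
        kind = condition(cond_name).kind
        for sex in SEXES:
            r_ns = float(rng.uniform(*BASE_RATE_BOUNDS))
            p_cur, p_for = prevalence[sex]
            implied = (
                p_cur * rr_cur[cond_name] * r_ns
                + p_for * rr_for[cond_name] * r_ns
                + (1.0 - p_cur - p_for) * r_ns
            )
            truth.true_nonsmoker_rates[(cond_name, sex)] = [r_ns] * len(AGE_BANDS)
            truth.implied_population_rates[(cond_name, sex)] = implied
            if kind == "cancer":
                cancer_incidence.setdefault(cond_name, {})[sex] = implied * 1e4
                # mortality row kept too: it is what vital statistics report
                mortality_rates.setdefault(cond_name, {})[sex] = implied * cf[cond_name] * 1e4
            else:
                mortality_rates.setdefault(cond_name, {})[sex] = implied * 1e4

    gdp_pc = float(rng.uniform(3000, 15000))
    event_costs = {c: round(gdp_pc * float(rng.uniform(0.2, 2.5)), 2) for c in conditions}
    ban_level = str(rng.choice(["absent", "partial", "comprehensive"]))
    compliance = None if ban_level == "absent" else round(float(rng.uniform(0.5, 1.0)), 2)

    params = CountryParameters(
        country_code="ZZ",
        population_total=int(scale),
        smoking_prevalence={s: prevalence[s][0] for s in SEXES},
        former_prevalence={s: prevalence[s][1] for s in SEXES},
        mortality_rates=mortality_rates,
        cancer_incidence=cancer_incidence,
        event_costs=event_costs,
        ppp_rate=float(rng.uniform(1.0, 20.0)),
        gdp_per_capita=gdp_pc,
        age_sex_structure=default_age_sex_structure(),
        background_mortality=default_background_mortality(),
        cpi_series={2015: 100.0, 2018: 100.0},
        health_expenditure_share=float(rng.uniform(0.04, 0.09)),
        price_year=2015,
        ban_level=ban_level,
        compliance=compliance,
        assumptions=["synthetic country generated from known truth"],
        metadata={"synthetic": True, "seed": int(seed)},
    )
    return params, truth


def generate_reference_mortality(
    truth: SyntheticTruth,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> dict[tuple[str, str], float]:
    """Reference mortality table: implied rates with lognormal noise.

    ``noise_sd`` is the standard deviation of log-rates (a relative error
    scale); 0 returns the implied rates exactly. Deterministic given
    ``seed`` (defaults to the truth's own seed).
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    base = truth.mortality_reference()
    if noise_sd == 0:
        return base
    rng = np.random.Generator(np.random.Philox(key=truth.seed if seed is None else seed))
    return {k: v * float(np.exp(rng.normal(0.0, noise_sd))) for k, v in base.items()}
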