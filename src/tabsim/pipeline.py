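"""Orchestration of the base-case workflow: runs, impact ladders, reports.

The base case compares, per country, the burden predicted under no
advertising ban with the burden under (i) the current policy (status
quo), (ii) full compliance with the current ban level (step 1) and
(iii) a comprehensive ban at 100% compliance (step 2). Steps are
successive effectiveness values applied to the same baseline with the
same seed (common random numbers), and impacts are differences between
consecutive runs, so the rows are incremental and sum to the
full-implementation total.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from tabsim.calibration import calibrate
from tabsim.economics import CostModel, cost_model_from_country
from tabsim.impact import ImpactSummary, aggregate_totals, compute_impact
from tabsim.microsim import SimulationResult, run_cohort
from tabsim.parameters import (
    CountryParameters,
    RiskParameters,
    bundled_country,
    default_risk_parameters,
    load_country_parameters,
)
from tabsim.policy import (
    BanLevel,
    CENTRAL_EFFECTIVENESS,
    PolicyDefinition,
    policy_schedule,
    status_quo_effectiveness,
)
from tabsim.risk import build_state_risk_table
from tabsim.synthetic import generate_country, generate_reference_mortality


class ConvergenceError(RuntimeError):
    """Calibration failed to reach tolerance within the iteration budget."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: config + seed fully determine it."""

    countries: list[str] = field(default_factory=lambda: ["ar", "bo", "br", "cl", "co", "mx", "pe"])
    cohort_size: int = 200_000
    seed: int = 1
    horizon: int = 10
    output_dir: str = "results"
    ban_level_override: str | None = None
    compliance_override: float | None = None
    apply_markup: bool = True
    discount_rate: float = 0.0
    parameter_files: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config_country(config: RunConfig, code: str) -> CountryParameters:
    if code in config.parameter_files:
        params = load_country_parameters(config.parameter_files[code])
    else:
        params = bundled_country(code)
    if config.ban_level_override is not None:
        params.ban_level = config.ban_level_override
    if config.compliance_override is not None:
        params.compliance = config.compliance_override
    params.validate()
    return params


def run_policy(
    params: CountryParameters,
    risk: RiskParameters,
    em: float,
    n: int,
    seed: int,
    horizon: int = 10,
    cost_model: CostModel | None = None,
    discount_rate: float = 0.0,
) -> SimulationResult:
    """One cohort run under effectiveness ``em`` (0 = no-policy baseline)."""
    table = build_state_risk_table(params, risk)
    if cost_model is None:
        cost_model = cost_model_from_country(params)
    schedule = policy_schedule(params, em, horizon=horizon)
    return run_cohort(
        n=n,
        seed=seed,
        params=params,
        risks=table,
        risk_params=risk,
        horizon=horizon,
        schedule=schedule,
        cost_model=cost_model,
        discount_rate=discount_rate,
    )


def country_effectiveness_ladder(params: CountryParameters) -> list[tuple[str, float]]:
    """(step, Em) pairs for the incremental ladder of one country.

    Status quo uses the country's current level x compliance; step 1 takes
    the current level to 100% compliance (absent-ban countries move to a
    partial ban); step 2 is the comprehensive ban at 100% compliance.
    Steps that do not increase Em are dropped (their increment is zero).
    """
    policy = PolicyDefinition.from_country(params)
    em_sq = status_quo_effectiveness(policy)
    level1 = BanLevel.PARTIAL if policy.ban_level is BanLevel.ABSENT else policy.ban_level
    em1 = CENTRAL_EFFECTIVENESS[level1]
    em2 = CENTRAL_EFFECTIVENESS[BanLevel.COMPREHENSIVE]
    # no effective current ban: nothing to attribute to the status quo
    ladder = [("status_quo", em_sq)] if em_sq > 0 else []
    if em1 > em_sq:
        ladder.append(("step1", em1))
    if em2 > ladder[-1][1]:
        ladder.append(("step2", em2))
    return ladder


def country_impact_ladder(
    params: CountryParameters,
    risk: RiskParameters,
    n: int,
    seed: int,
    horizon: int = 10,
    apply_markup: bool = True,
    discount_rate: float = 0.0,
) -> list[ImpactSummary]:
    """Incremental impact rows for one country (paired seeds throughout)."""
    cost_model = cost_model_from_country(params)
    population = {s: params.population_35plus(s) for s in ("male", "female")}
    runs: dict[float, SimulationResult] = {}

    def run(em: float) -> SimulationResult:
        if em not in runs:
            runs[em] = run_policy(
                params, risk, em, n, seed, horizon, cost_model, discount_rate
            )
        return runs[em]

    summaries = []
    prev_em = 0.0
    for step, em in country_effectiveness_ladder(params):
        summaries.append(
            compute_impact(
                baseline=run(prev_em),
                policy=run(em),
                costs=cost_model,
                population_by_sex=population,
                country=params.country_code,
                step=step,
                apply_markup=apply_markup,
            )
        )
        prev_em = em
    return summaries


# -- command implementations (the CLI wraps these thinly) ----------------


def _write_run_log(config: RunConfig, outdir: Path, started: float, extra=None) -> None:
    log = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "runtime_seconds": round(time.time() - started, 3),
    }
    if extra:
        log.update(extra)
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")


def cmd_simulate(config: RunConfig, risk: RiskParameters | None = None) -> Path:
    """Status-quo cohort runs per country; writes long CSV + JSON summaries."""
    started = time.time()
    risk = risk or default_risk_parameters()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for code in config.countries:
        params = load_config_country(config, code)
        em = status_quo_effectiveness(PolicyDefinition.from_country(params))
        result = run_policy(
            params, risk, em, config.cohort_size, config.seed, config.horizon,
            discount_rate=config.discount_rate,
        )
        result.to_long_frame().to_csv(outdir / f"simulate_{code}.csv", index=False)
        summary = {
            "country": params.country_code,
            "em": em,
            "cohort_size": result.cohort_size,
            "seed": result.seed,
            "deaths": result.total("deaths"),
            "person_years": result.total("person_years"),
            "qalys": result.total("qalys"),
            "cost_local": result.total("cost"),
            "mc_standard_errors": result.mc_standard_errors,
        }
        (outdir / f"simulate_{code}.json").write_text(json.dumps(summary, indent=2) + "\n")
    _write_run_log(config, outdir, started)
    return outdir


def cmd_impact(config: RunConfig, risk: RiskParameters | None = None) -> pd.DataFrame:
    """The base-case impact ladder for every country, plus totals.

    Writes ``impact_rows.csv`` (one row per country and step, in the
    reporting layout: deaths, MI, stroke, COPD, cancer, life-years, I$)
    and ``impact_totals.csv``; returns the rows.
    """
    started = time.time()
    risk = risk or default_risk_parameters()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_rows: list[ImpactSummary] = []
    for code in config.countries:
        params = load_config_country(config, code)
        all_rows.extend(
            country_impact_ladder(
                params,
                risk,
                n=config.cohort_size,
                seed=config.seed,
                horizon=config.horizon,
                apply_markup=config.apply_markup,
                discount_rate=config.discount_rate,
            )
        )
    rows = pd.DataFrame([s.as_row() for s in all_rows])
    totals = aggregate_totals(all_rows)
    rows.to_csv(outdir / "impact_rows.csv", index=False)
    totals.to_csv(outdir / "impact_totals.csv")
    rows.to_json(outdir / "impact_rows.json", orient="records", indent=2)
    _write_run_log(config, outdir, started)
    return rows


def cmd_calibrate(
    config: RunConfig,
    risk: RiskParameters | None = None,
    reference: dict[str, dict] | None = None,
    tolerance: float = 0.10,
    strict: bool = False,
):
    """Calibrate each country's risks to reference mortality.

    ``reference`` maps country code to a {(condition, sex): rate} table;
    without one, each country's own input mortality is the reference (a
    self-consistency pass: the mixture derivation must reproduce the
    inputs, so factors stay 1). Reports are written as CSV + JSON; with
    ``strict`` a non-converged country raises :class:`ConvergenceError`.
    """
    started = time.time()
    risk = risk or default_risk_parameters()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports = {}
    for code in config.countries:
        params = load_config_country(config, code)
        if reference and code in reference:
            ref = reference[code]
        else:
            ref = _self_reference(params, risk)
        _scaled, report = calibrate(params, risk, ref, tolerance=tolerance)
        report.table.to_csv(outdir / f"calibration_{code}.csv", index=False)
        (outdir / f"calibration_{code}.json").write_text(
            json.dumps(
                {
                    "country": params.country_code,
                    "converged": report.converged,
                    "iterations": report.iterations,
                    "tolerance": report.tolerance,
                    "r2_origin": report.r2_origin,
                },
                indent=2,
            )
            + "\n"
        )
        report.scatter_data().to_csv(outdir / f"calibration_{code}_scatter.csv", index=False)
        reports[code] = report
        if strict and not report.converged:
            raise ConvergenceError(f"calibration for {code} did not converge")
    _write_run_log(config, outdir, started)
    return reports


def _self_reference(params: CountryParameters, risk: RiskParameters) -> dict:
    ref = {}
    for cond_name in params.modelled_conditions():
        if cond_name not in risk.rr_current:
            continue
        for sex, rate in params.mortality_rates.get(cond_name, {}).items():
            ref[(cond_name, sex)] = rate / 1e4
    return ref


def cmd_synth(seed: int, scale: int, output_dir: str) -> tuple[Path, Path]:
    """Emit a synthetic country parameter file and its truth file."""
    from tabsim.parameters import write_country_parameters

    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    params, truth = generate_country(seed=seed, scale=scale)
    params_path = outdir / f"synthetic_{seed}.yaml"
    write_country_parameters(params, params_path)
    truth_doc = {
        "seed": truth.seed,
        "true_rr": truth.true_rr,
        "true_rr_former": truth.true_rr_former,
        "true_case_fatality": truth.true_case_fatality,
        "true_qol_decrement": truth.true_qol_decrement,
        "true_prevalence": {s: list(v) for s, v in truth.true_prevalence.items()},
        "true_nonsmoker_rates": {
            f"{c}:{s}": v[0] for (c, s), v in truth.true_nonsmoker_rates.items()
        },
        "implied_population_rates": {
            f"{c}:{s}": v for (c, s), v in truth.implied_population_rates.items()
        },
        "reference_mortality": {
            f"{c}:{s}": v for (c, s), v in generate_reference_mortality(truth).items()
        },
    }
    truth_path = outdir / f"synthetic_{seed}_truth.yaml"
    import yaml

    truth_path.write_text(yaml.safe_dump(truth_doc, sort_keys=False))
    return params_path, truth_path
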