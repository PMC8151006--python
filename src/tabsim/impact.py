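"""Averted-burden summaries from paired baseline/policy runs.

Health impact is the difference between the baseline (no-ban) burden and
the policy run's burden, scaled from the simulated cohort to the national
population aged 35+, with a passive-smoking/perinatal markup (the model
does not simulate those pathways directly, so their burden is added as a
fixed proportional markup: +13.6% for men, +12% for women). Life-years
gained decompose into a premature-death component (PYLL: person-years
added) and a quality-of-life component (YLL-QL: quality-adjusted years
added beyond the person-years added). Costs averted are reported in
international dollars.

Country results stack into the incremental policy ladder: status quo
(current policy vs no policy), step 1 (full compliance with the current
ban level) and step 2 (comprehensive ban, 100% compliance); each step's
numbers add to the previous ones, so the full-implementation total is the
sum of every row.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from tabsim.conditions import CONDITION_BY_NAME
from tabsim.economics import CostModel
from tabsim.microsim import SimulationResult

#: Additional burden from passive smoking and perinatal effects.
MARKUP_MALE = 0.136
MARKUP_FEMALE = 0.12

STEPS = ("status_quo", "step1", "step2")

_COLUMNS = ("deaths", "mi", "stroke", "copd", "cancer", "other", "life_years", "costs_i_dollars")


def passive_perinatal_markup(value: float, sex: str) -> float:
    """Scale a burden quantity up for passive-smoking/perinatal effects."""
    if value < 0:
        raise ValueError(f"burden quantity must be >= 0, got {value}")
    if sex == "male":
        return value * (1.0 + MARKUP_MALE)
    if sex == "female":
        return value * (1.0 + MARKUP_FEMALE)
    raise ValueError(f"unknown sex {sex!r}")


@dataclass
class ImpactSummary:
    """Averted burden for one (country, step), national scale."""

    country: str
    step: str
    deaths: float
    mi: float
    stroke: float
    copd: float
    cancer: float
    other: float
    life_years: float  # = pyll + yll_ql
    pyll: float
    yll_ql: float
    costs_i_dollars: float

    def as_row(self) -> dict:
        return asdict(self)


def compute_impact(
    baseline: SimulationResult,
    policy: SimulationResult,
    costs: CostModel,
    population_by_sex: Mapping[str, float] | None = None,
    country: str = "",
    step: str = "status_quo",
    apply_markup: bool = True,
) -> ImpactSummary:
    """Difference between a baseline and a policy run, nationally scaled.

    Both runs must share cohort size, seed and horizon (common-random-number
    pairing); ``population_by_sex`` maps sex to the national population 35+
    it represents (omit for raw cohort-scale differences).
    """
    if baseline.meta() != policy.meta():
        raise ValueError(
            f"runs are not paired: baseline meta {baseline.meta()} != policy {policy.meta()}"
        )
    if baseline.conditions != policy.conditions:
        raise ValueError("runs cover different condition sets")
    if step not in STEPS:
        raise ValueError(f"step must be one of {STEPS}, got {step!r}")

    def sex_scale(sex: str) -> float:
        if population_by_sex is None:
            return 1.0
        return population_by_sex[sex] / baseline.sex_counts[sex]

    def sex_markup(sex: str) -> float:
        return passive_perinatal_markup(1.0, sex) if apply_markup else 1.0

    col_tot = {c: 0.0 for c in ("mi", "stroke", "copd", "cancer", "other")}
    deaths = pyll = yll_ql = cost_local = 0.0

    base_core = baseline.by_year_sex.groupby("sex").sum(numeric_only=True)
    pol_core = policy.by_year_sex.groupby("sex").sum(numeric_only=True)
    base_ev = baseline.events.groupby(["sex", "condition"], sort=False)["events"].sum()
    pol_ev = policy.events.groupby(["sex", "condition"], sort=False)["events"].sum()

    for sex in base_core.index:
        if baseline.sex_counts.get(sex, 0) == 0:
            continue
        f = sex_scale(sex) * sex_markup(sex)
        b, p = base_core.loc[sex], pol_core.loc[sex]
        deaths += (b["deaths"] - p["deaths"]) * f
        d_py = (p["person_years"] - b["person_years"]) * f
        d_qaly = (p["qalys"] - b["qalys"]) * f
        pyll += d_py
        yll_ql += d_qaly - d_py
        cost_local += (b["cost"] - p["cost"]) * f
        for cond_name in baseline.conditions:
            diff = (base_ev[sex][cond_name] - pol_ev[sex][cond_name]) * f
            col = CONDITION_BY_NAME[cond_name].report_column
            col_tot[col] += diff

    return ImpactSummary(
        country=country,
        step=step,
        deaths=deaths,
        mi=col_tot["mi"],
        stroke=col_tot["stroke"],
        copd=col_tot["copd"],
        cancer=col_tot["cancer"],
        other=col_tot["other"],
        life_years=pyll + yll_ql,
        pyll=pyll,
        yll_ql=yll_ql,
        costs_i_dollars=costs.in_international_dollars(cost_local),
    )


def _to_frame(summaries) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        df = summaries.copy()
    else:
        df = pd.DataFrame([s.as_row() for s in summaries])
    for col in _COLUMNS:
        if col not in df.columns:
            df[col] = 0.0
    return df


def aggregate_totals(summaries: Iterable[ImpactSummary] | pd.DataFrame) -> pd.DataFrame:
    """Step totals and the full-implementation grand total.

    Rows are incremental: the status-quo total sums the status-quo rows
    only, while the comprehensive-ban ("full") total sums every row —
    status quo plus step 1 plus step 2.
    """
    df = _to_frame(summaries)
    if df.empty:
        zero = {c: 0.0 for c in _COLUMNS}
        return pd.DataFrame(
            [{"total": t, **zero} for t in ("status_quo", "step1", "step2", "full")]
        ).set_index("total")
    dup = df.duplicated(subset=["country", "step"])
    if dup.any():
        pairs = df.loc[dup, ["country", "step"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (country, step) rows: {pairs}")
    cols = list(_COLUMNS)
    rows = {}
    for step in STEPS:
        rows[step] = df.loc[df["step"] == step, cols].sum()
    rows["full"] = df[cols].sum()
    return pd.DataFrame(rows).T.rename_axis("total")


def reported_impact_rows() -> pd.DataFrame:
    """The published per-country, per-step 10-year impact rows.

    Columns: country, step, deaths, mi, stroke, copd, cancer, life_years,
    costs_i_dollars. These are inputs for aggregation arithmetic and
    presentation-layer comparisons.
    """
    text = (resources.files("tabsim") / "data" / "table3_reported.csv").read_text()
    return pd.read_csv(io.StringIO(text))
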