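"""Calibration of modelled mortality to national reference rates.

The model's predicted condition-specific mortality is compared with
national statistics; predictions within 10% of the reference are
acceptable, and larger deviations are removed by scaling the condition's
risk inputs multiplicatively (factor = reference / predicted, re-projected
each round) until every included condition is inside the band or the
iteration budget is exhausted. COPD mortality is excluded from the
comparison by default because national statistics are agreed to
underestimate it. Goodness of fit is additionally summarised by the
squared correlation of a least-squares line through the origin fitted to
predicted-vs-observed points.

Calibration runs against deterministic expected-value projections
(probability-weighted cohort arithmetic) so the 10% criterion is stable;
stochastic microsimulation runs can then be verified against the
calibrated table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from tabsim.conditions import SEXES, condition
from tabsim.parameters import CountryParameters, RiskParameters
from tabsim.risk import StateRiskTable, build_state_risk_table

RateTable = Mapping[tuple[str, str], float]  # (condition, sex) -> rate

DEFAULT_TOLERANCE = 0.10
DEFAULT_EXCLUDE = ("copd",)


def predict_mortality(
    params: CountryParameters,
    risk: RiskParameters,
    scaling_factors: Mapping[tuple[str, str], float] | None = None,
) -> dict[tuple[str, str], float]:
    """Expected condition-specific mortality per person-year, first cycle.

    Probability-weighted arithmetic over the starting population: for each
    (condition, sex), the age-structure-weighted mixture of state-specific
    event rates times case fatality. With unit scaling factors this
    reproduces the country's input mortality exactly (mixture
    conservation), which is what makes the calibration loop linear.
    """
    table = build_state_risk_table(params, risk, dict(scaling_factors or {}))
    out: dict[tuple[str, str], float] = {}
    for ci, cond_name in enumerate(table.conditions):
        for si, sex in enumerate(SEXES):
            p_cur, p_for, p_nev = params.state_distribution()[sex]
            weights = np.asarray(params.age_sex_structure[sex], dtype=float)
            weights = weights / weights.sum()
            mix = (
                p_cur * table.rate[ci, si, :, 0]
                + p_for * table.rate[ci, si, :, 1]
                + p_nev * table.rate[ci, si, :, 2]
            )
            cf = table.case_fatality[ci, si, :]
            out[(cond_name, sex)] = float(np.sum(weights * mix * cf))
    return out


def compare_rates(
    predicted: RateTable,
    reference: RateTable,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE,
) -> dict[tuple[str, str], float]:
    """Relative deviations (predicted - reference) / reference per cell.

    Cells whose reference rate is zero cannot be compared; they are
    excluded with a warning. ``exclude`` drops whole conditions (COPD by
    default).
    """
    out: dict[tuple[str, str], float] = {}
    for key, ref in reference.items():
        cond_name, _sex = key
        if cond_name in exclude or key not in predicted:
            continue
        pred = predicted[key]
        if ref == 0:
            if pred != 0:
                warnings.warn(
                    f"reference rate is 0 for {key} but prediction is {pred}; cell excluded"
                )
            continue
        out[key] = (pred - ref) / ref
    return out


def goodness_of_fit_r2_origin(predicted, observed) -> float:
    """Squared correlation of the least-squares line through the origin.

    Slope b = sum(p*o) / sum(p^2); returns 1 - sum((o - b*p)^2) / sum(o^2).
    Scale-invariant in the predictions: observed = c * predicted gives 1.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size < 2:
        raise ValueError("predicted and observed must be equal-length vectors (>= 2)")
    sp2 = float(np.sum(p * p))
    if sp2 == 0:
        raise ValueError("all predicted values are zero; through-origin fit undefined")
    so2 = float(np.sum(o * o))
    if so2 == 0:
        raise ValueError("all observed values are zero; r2 undefined")
    b = float(np.sum(p * o)) / sp2
    return 1.0 - float(np.sum((o - b * p) ** 2)) / so2


@dataclass
class CalibrationReport:
    """Outcome of a calibration pass."""

    table: pd.DataFrame  # per (condition, sex): predicted, reference, deviation, factor
    converged: bool
    iterations: int
    tolerance: float
    r2_origin: float
    excluded: tuple[str, ...] = field(default_factory=tuple)

    def scatter_data(self) -> pd.DataFrame:
        """Predicted vs observed points for goodness-of-fit plotting."""
        return self.table[["condition", "sex", "predicted", "reference"]].copy()


def calibrate(
    params: CountryParameters,
    risk: RiskParameters,
    reference: RateTable,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = 10,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE,
    predictor: Callable[[Mapping[tuple[str, str], float]], RateTable] | None = None,
) -> tuple[StateRiskTable, CalibrationReport]:
    """Scale per-(condition, sex) risks until predictions match references.

    Each round multiplies every out-of-band cell's factor by
    reference / predicted and re-projects. With the deterministic
    expected-value predictor the projection is linear in the factor, so
    one round suffices; a stochastic predictor may take several. Cells
    already inside the band keep factor 1 (an in-tolerance table is left
    untouched). Non-convergence is reported, not raised.

    Returns the scaled :class:`StateRiskTable` and a
    :class:`CalibrationReport`.
    """
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    for key, ref in reference.items():
        _check_reference_key(key)
        if ref < 0:
            raise ValueError(f"reference rate for {key} is negative")
    if predictor is None:
        predictor = lambda factors: predict_mortality(params, risk, factors)  # noqa: E731

    factors: dict[tuple[str, str], float] = {}
    iterations = 0
    predicted = dict(predictor(factors))
    deviations = compare_rates(predicted, reference, exclude=exclude)
    while iterations < max_iter and any(abs(d) > tolerance for d in deviations.values()):
        iterations += 1
        for key, dev in deviations.items():
            if abs(dev) > tolerance and predicted[key] > 0:
                factors[key] = factors.get(key, 1.0) * reference[key] / predicted[key]
        predicted = dict(predictor(factors))
        deviations = compare_rates(predicted, reference, exclude=exclude)

    converged = all(abs(d) <= tolerance for d in deviations.values())
    rows = []
    for (cond_name, sex), dev in sorted(deviations.items()):
        rows.append(
            {
                "condition": cond_name,
                "sex": sex,
                "predicted": predicted[(cond_name, sex)],
                "reference": reference[(cond_name, sex)],
                "deviation": dev,
                "factor": factors.get((cond_name, sex), 1.0),
            }
        )
    table = pd.DataFrame(rows)
    r2 = (
        goodness_of_fit_r2_origin(table["predicted"], table["reference"])
        if len(table) >= 2
        else float("nan")
    )
    report = CalibrationReport(
        table=table,
        converged=converged,
        iterations=iterations,
        tolerance=tolerance,
        r2_origin=r2,
        excluded=exclude,
    )
    scaled = build_state_risk_table(params, risk, factors)
    return scaled, report


def _check_reference_key(key: tuple[str, str]) -> None:
    cond_name, sex = key
    condition(cond_name)
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r} in reference key {key}")
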