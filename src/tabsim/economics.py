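"""Cost handling: CPI adjustment, PPP conversion, GDP-ratio extrapolation.

Event costs are estimated in local currency at a stated price year,
inflated with national consumer price indices, and converted to
international dollars (I$) with 2018 purchasing-power-parity exchange
rates. Where a country lacks a cost estimate for an event, the cost is
extrapolated as the average (event cost / GDP per capita) ratio of the
reference countries, applied to the target country's GDP per capita.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from tabsim.parameters import CountryParameters

#: Share of a published combined (first + following years) cost figure that
#: is treated as the acute, event-year cost; the remainder becomes the
#: annual follow-up cost. The split is an assumption — sources publish
#: combined figures only — and is configurable per CostModel.
DEFAULT_ACUTE_SHARE = 0.8


def cpi_adjust(amount: float, cpi_from: float, cpi_to: float) -> float:
    """Re-express a local-currency amount in another year's prices."""
    if cpi_from <= 0 or cpi_to <= 0:
        raise ValueError(f"CPI indices must be positive (got {cpi_from}, {cpi_to})")
    return amount * cpi_to / cpi_from


def to_international_dollars(amount_local: float, ppp_rate: float) -> float:
    """Convert local currency to I$ at a PPP rate (local currency per I$)."""
    if ppp_rate <= 0:
        raise ValueError(f"ppp_rate must be positive, got {ppp_rate}")
    return amount_local / ppp_rate


def extrapolate_event_cost(
    reference: Sequence[tuple[float, float]], gdp_target: float
) -> float:
    """Cost for a country without data, from reference (cost, GDP pc) pairs.

    Returns mean_i(cost_i / gdp_i) * gdp_target — the average share of GDP
    per capita an event costs in the reference countries, applied to the
    target economy.
    """
    if not reference:
        raise ValueError("reference list must be non-empty")
    ratios = []
    for cost, gdp in reference:
        if gdp <= 0:
            raise ValueError(f"reference GDP per capita must be positive, got {gdp}")
        ratios.append(cost / gdp)
    return sum(ratios) / len(ratios) * gdp_target


@dataclass
class CostModel:
    """Per-condition acute and annual follow-up costs, local currency.

    ``acute_cost`` accrues in the year of the event; ``followup_cost``
    accrues each subsequent year lived with the condition.
    """

    acute_cost: dict[str, float]
    followup_cost: dict[str, float]
    price_year: int
    ppp_rate: float
    cpi_series: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ppp_rate <= 0:
            raise ValueError(f"ppp_rate must be positive, got {self.ppp_rate}")
        for name, cost in {**self.acute_cost, **self.followup_cost}.items():
            if cost < 0:
                raise ValueError(f"cost for {name} is negative: {cost}")

    def adjust_to_year(self, year: int) -> "CostModel":
        """CPI-adjust every cost from ``price_year`` to ``year``'s prices."""
        cpi_from = self.cpi_series.get(self.price_year)
        cpi_to = self.cpi_series.get(year)
        if cpi_from is None or cpi_to is None:
            raise KeyError(
                f"cpi_series lacks index for {self.price_year} or {year}"
            )
        return CostModel(
            acute_cost={c: cpi_adjust(v, cpi_from, cpi_to) for c, v in self.acute_cost.items()},
            followup_cost={
                c: cpi_adjust(v, cpi_from, cpi_to) for c, v in self.followup_cost.items()
            },
            price_year=year,
            ppp_rate=self.ppp_rate,
            cpi_series=dict(self.cpi_series),
        )

    def in_international_dollars(self, amount_local: float) -> float:
        return to_international_dollars(amount_local, self.ppp_rate)


def cost_model_from_country(
    params: CountryParameters,
    acute_share: float = DEFAULT_ACUTE_SHARE,
    fill_missing: bool = True,
    reference_countries: Sequence[CountryParameters] = (),
) -> CostModel:
    """Build a CostModel from a country table's published cost rows.

    Published figures combine first and following years, so each is split
    ``acute_share`` : ``1 - acute_share`` into event-year and annual
    follow-up components. A separate published annual cardiovascular
    follow-up row, when present, replaces the split follow-up for the
    cardiovascular conditions. Missing conditions are optionally filled by
    GDP-ratio extrapolation from reference country tables.
    """
    if not 0.0 <= acute_share <= 1.0:
        raise ValueError(f"acute_share = {acute_share} outside [0, 1]")
    acute: dict[str, float] = {}
    follow: dict[str, float] = {}
    costs = dict(params.event_costs)
    cv_follow = costs.pop("cardiovascular_followup_annual", None)
    for cond_name, combined in costs.items():
        acute[cond_name] = combined * acute_share
        follow[cond_name] = combined * (1.0 - acute_share)
    if cv_follow is not None:
        for cv in ("ami", "other_cvd"):
            if cv in acute:
                acute[cv] = costs[cv]  # combined figure kept acute; follow-up published
                follow[cv] = cv_follow
    if fill_missing and reference_countries:
        for cond_name in set().union(*(rc.event_costs for rc in reference_countries)):
            if cond_name in acute or cond_name == "cardiovascular_followup_annual":
                continue
            ref = [
                (rc.event_costs[cond_name], rc.gdp_per_capita)
                for rc in reference_countries
                if cond_name in rc.event_costs
            ]
            combined = extrapolate_event_cost(ref, params.gdp_per_capita)
            acute[cond_name] = combined * acute_share
            follow[cond_name] = combined * (1.0 - acute_share)
    return CostModel(
        acute_cost=acute,
        followup_cost=follow,
        price_year=params.price_year,
        ppp_rate=params.ppp_rate,
        cpi_series=dict(params.cpi_series),
    )
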