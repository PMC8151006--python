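"""Advertising-ban policy layer: effectiveness, prevalence shift, scenarios.

A ban level (absent / partial / comprehensive) has a central effectiveness
Em — the relative reduction in per-capita tobacco consumption it produces
at full compliance (0%, 1% and 9% respectively). Actual effectiveness is
Em = level effectiveness x compliance. A fraction Ip of the consumption
reduction manifests as lower smoking prevalence:

    prevalence_post = prevalence_pre - Em * Ip * prevalence_pre

and the remainder as fewer cigarettes among continuing smokers, which
feeds the intensity adjustment of current-smoker relative risks.

The ten-year scenario path starts short-term (Ip = 0.5, quitting only, the
prevalence decrement becomes former smokers), phases in the intensity
benefit linearly over years 1-5, then moves linearly to the long-term
scenario by year 10 (Ip = 0.75, the former-smoker pool held at baseline,
the decrement feeding the never/non-smoker pool).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from tabsim.parameters import CountryParameters


class BanLevel(str, enum.Enum):
    ABSENT = "absent"
    PARTIAL = "partial"
    COMPREHENSIVE = "comprehensive"


#: Central effectiveness (relative consumption reduction at 100% compliance).
CENTRAL_EFFECTIVENESS = {
    BanLevel.ABSENT: 0.00,
    BanLevel.PARTIAL: 0.01,
    BanLevel.COMPREHENSIVE: 0.09,
}

#: Effectiveness ranges for sensitivity sweeps.
EFFECTIVENESS_RANGE = {
    BanLevel.ABSENT: (0.0, 0.0),
    BanLevel.PARTIAL: (0.0, 0.136),
    BanLevel.COMPREHENSIVE: (0.05, 0.235),
}

#: Share of the consumption reduction attributed to continuing smokers
#: cutting down (the other half comes through prevalence).
CONTINUING_SMOKER_SHARE = 0.5

#: Short/long-term Ip values: share of consumption reduction hitting prevalence.
IP_SHORT_TERM = 0.5
IP_MID_TERM = 0.5  # mid-term scenario keeps the short-term prevalence effect
IP_LONG_TERM = 0.75


@dataclass(frozen=True)
class PolicyDefinition:
    """A ban level plus the compliance achieved with it."""

    ban_level: BanLevel
    compliance: float
    central_effectiveness: dict[BanLevel, float] = field(
        default_factory=lambda: dict(CENTRAL_EFFECTIVENESS)
    )
    effectiveness_range: dict[BanLevel, tuple[float, float]] = field(
        default_factory=lambda: dict(EFFECTIVENESS_RANGE)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.compliance <= 1.0:
            raise ValueError(f"compliance = {self.compliance} outside [0, 1]")
        for level, (lo, hi) in self.effectiveness_range.items():
            central = self.central_effectiveness[level]
            if not lo <= central <= hi:
                raise ValueError(
                    f"effectiveness range {lo}-{hi} for {level} excludes central {central}"
                )

    @classmethod
    def from_country(cls, params: CountryParameters) -> "PolicyDefinition":
        """The status-quo policy recorded in a country's parameter table."""
        level = BanLevel(params.ban_level)
        compliance = params.compliance if params.compliance is not None else 0.0
        return cls(ban_level=level, compliance=compliance)


def status_quo_effectiveness(policy: PolicyDefinition) -> float:
    """Em achieved by a policy: level effectiveness times compliance."""
    return policy.central_effectiveness[policy.ban_level] * policy.compliance


def post_prevalence(prev_pre: float, em: float, ip: float) -> float:
    """Smoking prevalence after an intervention with effectiveness ``em``.

    prevalence_post = prevalence_pre * (1 - em * ip); never negative, never
    above the pre-intervention prevalence.
    """
    for name, v in (("prev_pre", prev_pre), ("em", em), ("ip", ip)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} = {v} outside [0, 1]")
    return prev_pre - em * ip * prev_pre


class ReallocationMode(str, enum.Enum):
    TO_FORMER = "to_former"
    TO_NONSMOKER = "to_nonsmoker"


@dataclass(frozen=True)
class ScenarioYear:
    year: int
    ip: float
    intensity_weight: float  # 0 = no intensity benefit, 1 = full
    reallocation_mode: ReallocationMode

    @property
    def intensity_adjustment_active(self) -> bool:
        return self.intensity_weight > 0


@dataclass(frozen=True)
class ScenarioPath:
    years: tuple[ScenarioYear, ...]

    def __getitem__(self, year: int) -> ScenarioYear:
        if not 1 <= year <= len(self.years):
            raise KeyError(f"year {year} outside path 1..{len(self.years)}")
        return self.years[year - 1]

    def ip(self, year: int) -> float:
        return self[year].ip


def build_scenario_path(horizon: int = 10) -> ScenarioPath:
    """The year-by-year Ip / intensity / reallocation schedule.

    Years 1-5 interpolate from the short-term to the mid-term scenario
    (Ip stays at 0.5; the intensity benefit ramps 0 -> 1); years 6-10
    interpolate Ip linearly from 0.5 to 0.75 and switch the prevalence
    decrement from the former-smoker to the never-smoker pool. Horizons
    beyond 10 hold the long-term scenario.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    years = []
    for t in range(1, horizon + 1):
        if t <= 5:
            ip = IP_SHORT_TERM + (IP_MID_TERM - IP_SHORT_TERM) * (t - 1) / 4.0
            weight = (t - 1) / 4.0
            mode = ReallocationMode.TO_FORMER
        elif t <= 10:
            ip = IP_MID_TERM + (IP_LONG_TERM - IP_MID_TERM) * (t - 5) / 5.0
            weight = 1.0
            mode = ReallocationMode.TO_NONSMOKER
        else:
            ip, weight, mode = IP_LONG_TERM, 1.0, ReallocationMode.TO_NONSMOKER
        years.append(ScenarioYear(t, ip, weight, mode))
    return ScenarioPath(tuple(years))


def reallocate_prevalence(
    base: tuple[float, float, float],
    prev_post: float,
    mode: ReallocationMode | str,
) -> tuple[float, float, float]:
    """Distribute a prevalence reduction across (current, former, never).

    ``to_former``: quitters join the former-smoker pool. ``to_nonsmoker``:
    the former pool stays at its baseline share and the never/non-smoker
    pool absorbs the decrement (the long-term, lower-initiation story).
    Total mass is conserved exactly.
    """
    mode = ReallocationMode(mode)
    p_cur, p_for, p_nev = base
    total = p_cur + p_for + p_nev
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"state distribution sums to {total}, not 1")
    if prev_post > p_cur + 1e-12:
        raise ValueError(f"prev_post {prev_post} exceeds baseline prevalence {p_cur}")
    decrement = p_cur - prev_post
    if mode is ReallocationMode.TO_FORMER:
        return (prev_post, p_for + decrement, p_nev)
    return (prev_post, p_for, p_nev + decrement)


@dataclass(frozen=True)
class PolicyYearState:
    """Everything the engine needs about the policy in one simulated year."""

    year: int
    distribution: dict[str, tuple[float, float, float]]  # per sex
    consumption_reduction: float  # among continuing smokers


def policy_schedule(
    params: CountryParameters,
    em: float,
    path: ScenarioPath | None = None,
    horizon: int = 10,
    continuing_smoker_share: float = CONTINUING_SMOKER_SHARE,
) -> list[PolicyYearState]:
    """Per-year state distributions and intensity inputs for a policy run.

    Each year's prevalence shift is applied to the *baseline* prevalence
    (scenarios describe displacement from baseline, not compounding), and
    the consumption cut among continuing smokers is em x share x the year's
    intensity phase-in weight.
    """
    if path is None:
        path = build_scenario_path(horizon)
    baseline = params.state_distribution()
    out = []
    for t in range(1, horizon + 1):
        sy = path[min(t, len(path.years))]
        dist = {}
        for sex, base in baseline.items():
            prev_post = post_prevalence(base[0], em, sy.ip)
            dist[sex] = reallocate_prevalence(base, prev_post, sy.reallocation_mode)
        reduction = em * continuing_smoker_share * sy.intensity_weight
        out.append(PolicyYearState(t, dist, reduction))
    return out
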