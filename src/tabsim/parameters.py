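"""Country parameter tables: typed containers, validation, and YAML I/O.

A :class:`CountryParameters` holds one country's demography, smoking
prevalence, cause-specific mortality, event costs and macroeconomic
conversion factors — everything the simulation needs for that country.
Values that national statistics typically publish (prevalence, crude
mortality per 10,000, costs, PPP rates) are stored exactly as printed in
their sources; quantities the sources do not publish (age structure,
former-smoker prevalence, background mortality) are filled with documented
defaults and flagged in the ``assumptions`` list so downstream reports can
distinguish data from assumption.

Relative risks, case fatalities and quality-of-life decrements are a
separate :class:`RiskParameters` object: they come from the epidemiological
literature rather than from any single country table, and the package
defaults are illustrative magnitudes meant for synthetic and comparative
runs, not country-validated estimates.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

from tabsim.conditions import AGE_BANDS, CONDITION_BY_NAME, SEXES, condition

SCHEMA_VERSION = 1

#: Share of the total population aged >= 35, used to scale cohort results to
#: national counts when a country table does not provide it directly.
DEFAULT_SHARE_35PLUS = 0.40

#: Former-smoker prevalence default as a multiple of current prevalence.
DEFAULT_FORMER_RATIO = 0.5


class ParameterError(ValueError):
    """A required field is missing or malformed."""


class RangeError(ParameterError):
    """A field value lies outside its admissible range."""


def _require(mapping: Mapping[str, Any], key: str, context: str) -> Any:
    if key not in mapping:
        raise ParameterError(f"missing required field {key!r} in {context}")
    return mapping[key]


def _check_fraction(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise RangeError(f"{name} = {value} outside [0, 1]")
    return value


def _check_nonneg(name: str, value: float) -> float:
    value = float(value)
    if value < 0:
        raise RangeError(f"{name} = {value} is negative")
    return value


def default_age_sex_structure(male_share: float = 0.48) -> dict[str, list[float]]:
    """A generic ageing-population pyramid over the 35+ five-year bands.

    Weights decline geometrically with age, which is a reasonable stand-in
    for Latin American adult populations when a census table is not used.
    """
    raw = [0.86**i for i in range(len(AGE_BANDS))]
    total = sum(raw)
    shape = [w / total for w in raw]
    return {
        "male": [male_share * w for w in shape],
        "female": [(1.0 - male_share) * w for w in shape],
    }


def default_background_mortality() -> dict[str, list[float]]:
    """Annual residual (non-modelled-cause) death probability per sex and band.

    A Gompertz-like schedule: roughly doubling every decade from ~0.2% at
    35-39 to ~20% at 85+, women about 20% lower.
    """
    male = [0.002 * (1.55**i) for i in range(len(AGE_BANDS))]
    female = [q * 0.8 for q in male]
    return {"male": male, "female": female}


@dataclass
class CountryParameters:
    """All model inputs for one country.

    Units follow the source tables: ``mortality_rates`` and
    ``cancer_incidence`` are per 10,000 person-years; prevalences and shares
    are fractions in [0, 1]; ``event_costs`` are in the currency and price
    year given; ``ppp_rate`` is local currency per international dollar.
    """

    country_code: str
    population_total: int
    smoking_prevalence: dict[str, float]  # per sex, fraction
    former_prevalence: dict[str, float]  # per sex, fraction
    mortality_rates: dict[str, dict[str, float]]  # condition -> sex -> per 10,000
    event_costs: dict[str, float]  # condition/row -> money (see cost_unit)
    ppp_rate: float  # local currency per I$ (2018)
    gdp_per_capita: float  # USD
    age_sex_structure: dict[str, list[float]] = field(default_factory=default_age_sex_structure)
    cancer_incidence: dict[str, dict[str, float]] = field(default_factory=dict)
    background_mortality: dict[str, list[float]] = field(default_factory=default_background_mortality)
    cpi_series: dict[int, float] = field(default_factory=dict)
    health_expenditure_share: float = 0.0
    share_35plus: float = DEFAULT_SHARE_35PLUS
    price_year: int = 2015
    cost_unit: str = "printed"  # units of event_costs as printed in the source
    ban_level: str = "absent"
    compliance: float | None = None
    assumptions: list[str] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        if int(self.population_total) < 1:
            raise RangeError(f"population_total = {self.population_total} < 1")
        for sex in SEXES:
            if sex not in self.smoking_prevalence:
                raise ParameterError(f"missing required field smoking_prevalence[{sex!r}]")
            p_cur = _check_fraction(f"smoking_prevalence[{sex}]", self.smoking_prevalence[sex])
            p_for = _check_fraction(
                f"former_prevalence[{sex}]", self.former_prevalence.get(sex, 0.0)
            )
            if p_cur + p_for > 1.0:
                raise RangeError(
                    f"smoking + former prevalence for {sex} = {p_cur + p_for} > 1"
                )
        total = 0.0
        for sex in SEXES:
            weights = self.age_sex_structure.get(sex)
            if weights is None or len(weights) != len(AGE_BANDS):
                raise ParameterError(
                    f"age_sex_structure[{sex!r}] must have {len(AGE_BANDS)} band weights"
                )
            for w in weights:
                total += _check_nonneg(f"age_sex_structure[{sex}]", w)
        if abs(total - 1.0) > 1e-9:
            raise RangeError(f"age_sex_structure sums to {total}, not 1 within 1e-9")
        for cond, by_sex in self.mortality_rates.items():
            for sex, rate in by_sex.items():
                _check_nonneg(f"mortality_rates[{cond}][{sex}]", rate)
        for cond, by_sex in self.cancer_incidence.items():
            for sex, rate in by_sex.items():
                _check_nonneg(f"cancer_incidence[{cond}][{sex}]", rate)
        for name, cost in self.event_costs.items():
            _check_nonneg(f"event_costs[{name}]", cost)
        if float(self.ppp_rate) <= 0:
            raise RangeError(f"ppp_rate = {self.ppp_rate} must be > 0")
        _check_nonneg("gdp_per_capita", self.gdp_per_capita)
        _check_fraction("health_expenditure_share", self.health_expenditure_share)
        _check_fraction("share_35plus", self.share_35plus)
        if self.compliance is not None:
            _check_fraction("compliance", self.compliance)
        for sex in SEXES:
            qs = self.background_mortality.get(sex)
            if qs is None or len(qs) != len(AGE_BANDS):
                raise ParameterError(
                    f"background_mortality[{sex!r}] must have {len(AGE_BANDS)} values"
                )
            for q in qs:
                _check_fraction(f"background_mortality[{sex}]", q)

    # -- derived views -------------------------------------------------

    def modelled_conditions(self) -> list[str]:
        """Conditions this country has rates for, in adjudication order.

        Acute conditions need a mortality row; cancers use an incidence row
        when present, else fall back to their mortality row.
        """
        names = []
        for cond in CONDITION_BY_NAME.values():
            if cond.kind == "acute" and cond.name in self.mortality_rates:
                names.append(cond.name)
            elif cond.kind == "cancer" and (
                cond.name in self.cancer_incidence or cond.name in self.mortality_rates
            ):
                names.append(cond.name)
        return names

    def population_35plus(self, sex: str | None = None) -> float:
        total = self.population_total * self.share_35plus
        if sex is None:
            return total
        sex_share = sum(self.age_sex_structure[sex])
        return total * sex_share

    def state_distribution(self) -> dict[str, tuple[float, float, float]]:
        """Baseline (current, former, never) probabilities per sex."""
        out = {}
        for sex in SEXES:
            p_cur = self.smoking_prevalence[sex]
            p_for = self.former_prevalence[sex]
            out[sex] = (p_cur, p_for, 1.0 - p_cur - p_for)
        return out

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = {
            "schema_version": self.schema_version,
            "country_code": self.country_code,
            "population_total": int(self.population_total),
            "smoking_prevalence": dict(self.smoking_prevalence),
            "former_prevalence": dict(self.former_prevalence),
            "mortality_rates": {c: dict(v) for c, v in self.mortality_rates.items()},
            "cancer_incidence": {c: dict(v) for c, v in self.cancer_incidence.items()},
            "event_costs": dict(self.event_costs),
            "ppp_rate": self.ppp_rate,
            "gdp_per_capita": self.gdp_per_capita,
            "age_sex_structure": {s: list(v) for s, v in self.age_sex_structure.items()},
            "background_mortality": {s: list(v) for s, v in self.background_mortality.items()},
            "cpi_series": {int(k): float(v) for k, v in self.cpi_series.items()},
            "health_expenditure_share": self.health_expenditure_share,
            "share_35plus": self.share_35plus,
            "price_year": self.price_year,
            "cost_unit": self.cost_unit,
            "ban_level": self.ban_level,
            "compliance": self.compliance,
            "assumptions": list(self.assumptions),
            "metadata": copy.deepcopy(self.metadata),
        }
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "CountryParameters":
        data = dict(data)
        context = f"country parameters ({data.get('country_code', '?')})"
        known = {
            "schema_version",
            "country_code",
            "population_total",
            "smoking_prevalence",
            "former_prevalence",
            "mortality_rates",
            "cancer_incidence",
            "event_costs",
            "ppp_rate",
            "gdp_per_capita",
            "age_sex_structure",
            "background_mortality",
            "cpi_series",
            "health_expenditure_share",
            "share_35plus",
            "price_year",
            "cost_unit",
            "ban_level",
            "compliance",
            "assumptions",
            "metadata",
        }
        metadata = dict(data.get("metadata") or {})
        # Unknown top-level fields survive a round trip as metadata.
        for key in set(data) - known:
            metadata[key] = data.pop(key)

        assumptions = list(data.get("assumptions") or [])
        kwargs: dict[str, Any] = {
            "country_code": _require(data, "country_code", context),
            "population_total": int(_require(data, "population_total", context)),
            "smoking_prevalence": dict(_require(data, "smoking_prevalence", context)),
            "event_costs": dict(_require(data, "event_costs", context)),
            "ppp_rate": float(_require(data, "ppp_rate", context)),
            "gdp_per_capita": float(_require(data, "gdp_per_capita", context)),
            "mortality_rates": {
                c: dict(v) for c, v in dict(_require(data, "mortality_rates", context)).items()
            },
            "metadata": metadata,
        }

        if data.get("former_prevalence"):
            kwargs["former_prevalence"] = dict(data["former_prevalence"])
        else:
            kwargs["former_prevalence"] = {
                s: DEFAULT_FORMER_RATIO * float(p)
                for s, p in kwargs["smoking_prevalence"].items()
            }
            assumptions.append(
                f"former_prevalence defaulted to {DEFAULT_FORMER_RATIO} x current prevalence"
            )
        if data.get("age_sex_structure"):
            kwargs["age_sex_structure"] = {
                s: [float(w) for w in v] for s, v in data["age_sex_structure"].items()
            }
        else:
            kwargs["age_sex_structure"] = default_age_sex_structure()
            assumptions.append("age_sex_structure defaulted to generic 35+ pyramid")
        if data.get("background_mortality"):
            kwargs["background_mortality"] = {
                s: [float(q) for q in v] for s, v in data["background_mortality"].items()
            }
        else:
            kwargs["background_mortality"] = default_background_mortality()
            assumptions.append("background_mortality defaulted to Gompertz-like schedule")

        kwargs["cancer_incidence"] = {
            c: dict(v) for c, v in (data.get("cancer_incidence") or {}).items()
        }
        for key in (
            "cpi_series",
            "health_expenditure_share",
            "share_35plus",
            "price_year",
            "cost_unit",
            "ban_level",
            "compliance",
            "schema_version",
        ):
            if data.get(key) is not None:
                kwargs[key] = data[key]
        if "cpi_series" in kwargs:
            kwargs["cpi_series"] = {int(k): float(v) for k, v in kwargs["cpi_series"].items()}
        kwargs["assumptions"] = assumptions
        return cls(**kwargs)


def load_country_parameters(source: str | Path) -> CountryParameters:
    """Read a country parameter file (YAML) and validate it."""
    path = Path(source)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ParameterError(f"{path} does not contain a parameter mapping")
    return CountryParameters.from_dict(data)


def write_country_parameters(params: CountryParameters, sink: str | Path) -> Path:
    """Write a validated CountryParameters back to YAML. Round-trip lossless."""
    params.validate()
    path = Path(sink)
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
    return path


# -- bundled fixtures ---------------------------------------------------


def _fixture_dir():
    return resources.files("tabsim") / "data" / "countries"


def bundled_country_codes() -> list[str]:
    return sorted(p.name[:-5] for p in _fixture_dir().iterdir() if p.name.endswith(".yaml"))


def bundled_country(code: str) -> CountryParameters:
    """Load one of the seven bundled country tables by ISO code (e.g. 'br')."""
    path = _fixture_dir() / f"{code.lower()}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"no bundled country {code!r}; available: {bundled_country_codes()}"
        ) from None
    return CountryParameters.from_dict(yaml.safe_load(text))


# -- risk parameters ----------------------------------------------------

#: Excess-risk reduction when a heavy smoker becomes a low-intensity smoker,
#: relative to the smoker/former-smoker risk gap: condition-specific for lung
#: cancer, ischemic heart disease and COPD; 75% for everything else.
EXCESS_RISK_REDUCTION_DEFAULTS = {
    "lung_cancer": 0.82,
    "ami": 0.57,
    "copd": 0.80,
}
EXCESS_RISK_REDUCTION_OTHER = 0.75


@dataclass
class RiskParameters:
    """Per-condition epidemiological parameters.

    ``rr_current``/``rr_former`` are relative risks vs never smokers;
    ``case_fatality`` is the probability an event (or a cancer diagnosis
    year) is fatal; ``qol_decrement`` is the annual utility loss while
    living with the condition; ``excess_risk_reduction`` drives the
    smoking-intensity adjustment.
    """

    rr_current: dict[str, float]
    rr_former: dict[str, float]
    case_fatality: dict[str, float]
    qol_decrement: dict[str, float]
    excess_risk_reduction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond in self.rr_current:
            rr_c = float(self.rr_current[cond])
            rr_f = float(self.rr_former.get(cond, 1.0))
            if rr_c < 1.0 or rr_f < 1.0:
                raise RangeError(f"relative risks for {cond} must be >= 1 (got {rr_c}, {rr_f})")
            if rr_f > rr_c:
                raise RangeError(
                    f"rr_former ({rr_f}) > rr_current ({rr_c}) for {cond}"
                )
            cf = float(self.case_fatality.get(cond, 0.0))
            _check_fraction(f"case_fatality[{cond}]", cf)
            _check_fraction(f"qol_decrement[{cond}]", self.qol_decrement.get(cond, 0.0))
        for cond, frac in self.excess_risk_reduction.items():
            _check_fraction(f"excess_risk_reduction[{cond}]", frac)
        for cond in self.rr_current:
            self.excess_risk_reduction.setdefault(
                cond,
                EXCESS_RISK_REDUCTION_DEFAULTS.get(cond, EXCESS_RISK_REDUCTION_OTHER),
            )

    def conditions(self) -> list[str]:
        return list(self.rr_current)


#: Illustrative default magnitudes (literature-scale, not country-validated):
#: (rr_current, rr_former, case_fatality, qol_decrement).
_DEFAULT_RISK_ROWS = {
    "ami": (2.5, 1.3, 0.35, 0.12),
    "other_cvd": (2.0, 1.2, 0.30, 0.10),
    "stroke": (2.2, 1.2, 0.25, 0.25),
    "pneumonia_influenza": (1.8, 1.2, 0.20, 0.05),
    "copd": (10.0, 5.0, 0.08, 0.22),
    "lung_cancer": (15.0, 4.0, 0.85, 0.45),
    "mouth_cancer": (4.0, 1.8, 0.40, 0.30),
    "esophageal_cancer": (4.5, 2.0, 0.75, 0.40),
    "stomach_cancer": (2.0, 1.3, 0.65, 0.35),
    "pancreatic_cancer": (2.2, 1.3, 0.90, 0.45),
    "kidney_cancer": (1.8, 1.2, 0.40, 0.30),
    "bladder_cancer": (3.0, 1.9, 0.30, 0.25),
    "laryngeal_cancer": (6.0, 2.5, 0.35, 0.30),
    "leukemia": (1.5, 1.2, 0.55, 0.40),
    "cervical_cancer": (1.6, 1.2, 0.45, 0.30),
}


def default_risk_parameters(conditions: Iterable[str] | None = None) -> RiskParameters:
    """Default RiskParameters covering the full condition registry.

    Magnitudes are illustrative (cardiovascular RRs ~2, COPD ~10, lung
    cancer ~15); any serious country analysis should supply its own table.
    """
    names = list(conditions) if conditions is not None else list(_DEFAULT_RISK_ROWS)
    for n in names:
        condition(n)  # raise early on unknown names
    return RiskParameters(
        rr_current={n: _DEFAULT_RISK_ROWS[n][0] for n in names},
        rr_former={n: _DEFAULT_RISK_ROWS[n][1] for n in names},
        case_fatality={n: _DEFAULT_RISK_ROWS[n][2] for n in names},
        qol_decrement={n: _DEFAULT_RISK_ROWS[n][3] for n in names},
    )
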