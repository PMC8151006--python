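"""Registry of modelled smoking-related conditions.

The model covers the classic smoking-attributable disease set: acute
cardiovascular and respiratory events, COPD, lung cancer and nine other
neoplasms. Each condition is either event-like ("acute": annual event risk
is back-calculated from cause-specific mortality and case fatality) or
incidence-based ("cancer": onset risk comes from cancer incidence directly).

The registry order is the fixed within-year adjudication order: when several
conditions strike the same individual in the same annual cycle, they are
applied in this order before death adjudication.
"""

from __future__ import annotations

from dataclasses import dataclass

SEXES = ("male", "female")

#: Lower edges of the 5-year age bands, 35-39 through 85+.
AGE_BANDS = (35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85)


@dataclass(frozen=True)
class Condition:
    name: str
    kind: str  # "acute" | "cancer"
    label: str
    #: Table-3 style reporting column this condition rolls up into.
    report_column: str


#: Adjudication order: cardiovascular first, then respiratory, then neoplasms.
CONDITIONS = (
    Condition("ami", "acute", "Acute myocardial infarction", "mi"),
    Condition("other_cvd", "acute", "Other cardiovascular causes", "mi"),
    Condition("stroke", "acute", "Cerebrovascular disease", "stroke"),
    Condition("pneumonia_influenza", "acute", "Pneumonia, influenza", "other"),
    Condition("copd", "acute", "COPD", "copd"),
    Condition("lung_cancer", "cancer", "Lung cancer", "cancer"),
    Condition("mouth_cancer", "cancer", "Mouth and oropharyngeal cancer", "cancer"),
    Condition("esophageal_cancer", "cancer", "Esophageal cancer", "cancer"),
    Condition("stomach_cancer", "cancer", "Stomach cancer", "cancer"),
    Condition("pancreatic_cancer", "cancer", "Pancreatic cancer", "cancer"),
    Condition("kidney_cancer", "cancer", "Kidney cancer", "cancer"),
    Condition("bladder_cancer", "cancer", "Bladder cancer", "cancer"),
    Condition("laryngeal_cancer", "cancer", "Laryngeal cancer", "cancer"),
    Condition("leukemia", "cancer", "Leukemia", "cancer"),
    Condition("cervical_cancer", "cancer", "Cervical cancer", "cancer"),
)

CONDITION_NAMES = tuple(c.name for c in CONDITIONS)
CONDITION_BY_NAME = {c.name: c for c in CONDITIONS}


def condition(name: str) -> Condition:
    try:
        return CONDITION_BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown condition {name!r}; known: {CONDITION_NAMES}") from None


def age_band_index(age: float) -> int:
    """Index of the 5-year band containing ``age`` (35+; 85+ is open-ended)."""
    if age < AGE_BANDS[0]:
        raise ValueError(f"age {age} below modelled range (>= {AGE_BANDS[0]})")
    for i in range(len(AGE_BANDS) - 1, -1, -1):
        if age >= AGE_BANDS[i]:
            return i
    raise AssertionError("unreachable")
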