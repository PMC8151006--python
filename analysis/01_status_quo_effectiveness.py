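"""Status-quo effectiveness per country and the incremental policy ladder.

Combines each bundled country's advertising-ban level and compliance into
the effectiveness Em (absolute prevalence-reduction fraction of the
consumption effect), and lists the Em each country would reach at step 1
(full compliance with its current ban level) and step 2 (comprehensive ban,
100% compliance). Writes results/effectiveness.csv.
"""

from pathlib import Path

import pandas as pd

from tabsim import PolicyDefinition, bundled_country, bundled_country_codes, status_quo_effectiveness
from tabsim.pipeline import country_effectiveness_ladder

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for code in bundled_country_codes():
    params = bundled_country(code)
    policy = PolicyDefinition.from_country(params)
    em_sq = status_quo_effectiveness(policy)
    ladder = dict(country_effectiveness_ladder(params))
    rows.append(
        {
            "country": params.country_code,
            "ban_level": params.ban_level,
            "compliance": params.compliance,
            "em_status_quo_pct": 100 * em_sq,
            "em_step1_pct": 100 * ladder.get("step1", em_sq),
            "em_step2_pct": 100 * ladder.get("step2", max(ladder.values(), default=em_sq)),
        }
    )

df = pd.DataFrame(rows)
df.to_csv(OUT / "effectiveness.csv", index=False)
print(df.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
print(
    "\nComprehensive-ban countries (BR, CO) reach Em = 9% at full compliance; "
    "partial-ban countries sit at 1% x compliance; absent-ban countries (MX, PE) "
    "contribute nothing until they legislate."
)
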