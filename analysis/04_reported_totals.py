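"""Aggregation identities over the published per-country impact rows.

The published per-country rows are incremental: step 1 adds to the status
quo, step 2 adds to both. This script recomputes the status-quo and
full-implementation totals from the bundled row table and prints them next
to the published grand totals. Six of the seven columns agree exactly; the
deaths column sums to 106,488 under the incremental rule while the
published grand total prints 98,132 — an internal inconsistency of the
source table, reported here and left unresolved.
"""

from pathlib import Path

from tabsim import aggregate_totals, reported_impact_rows

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = reported_impact_rows()
totals = aggregate_totals(rows)
totals.to_csv(OUT / "reported_totals.csv")

published_full = {
    "deaths": 98132, "mi": 311239, "stroke": 90868, "copd": 196848,
    "cancer": 48720, "life_years": 3006636, "costs_i_dollars": 15659778000,
}
published_sq = {
    "deaths": 50108, "mi": 199052, "stroke": 46570, "copd": 92912,
    "cancer": 25713, "life_years": 1634731, "costs_i_dollars": 7207693000,
}

print(f"{'column':>16} {'recomputed SQ':>15} {'published SQ':>13} "
      f"{'recomputed full':>16} {'published full':>15}")
for col, pub in published_full.items():
    sq = totals.loc["status_quo", col]
    full = totals.loc["full", col]
    flag = "" if full == pub else "  <- source-table inconsistency"
    print(f"{col:>16} {sq:>15,.0f} {published_sq[col]:>13,} {full:>16,.0f} {pub:>15,}{flag}")
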