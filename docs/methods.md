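# Methods

## Model overview

`tabsim` is an individual-based state-transition model run as a
first-order Monte Carlo simulation with annual cycles. A simulated person
carries sex, age, a smoking state (never / former / current), a disease
history, and accumulators for life-years, quality-adjusted life-years and
costs. Each cycle the person may suffer acute events (myocardial
infarction, other cardiovascular events, stroke, pneumonia/influenza, a
COPD event) and cancer onsets (lung cancer plus nine other
smoking-related neoplasms); events are fatal with a condition-specific
case fatality, and a residual life table supplies background mortality
from non-modelled causes. Survivors carry their conditions, which drive
annual follow-up costs and quality-of-life decrements in later years.

The modelled population is adults aged 35+, in eleven 5-year bands
(35–39 … 85+). Cohort results are scaled to the national population 35+
per sex for reporting.

## Risk derivation (mixture inversion)

Vital statistics report *population-average* rates that mix smokers and
non-smokers. With current/former prevalence p_c, p_f and relative risks
RR_c ≥ RR_f ≥ 1, the never-smoker rate is

    rate_ns = rate_pop / (p_c·RR_c + p_f·RR_f + (1 − p_c − p_f))

and state rates are RR·rate_ns. This inversion conserves the input
exactly: re-mixing the state rates with the prevalences reproduces
rate_pop to 1e-12, which is asserted for every bundled-country cell.

Acute conditions enter as events: the population *event* rate is
mortality ÷ case fatality (so "case fatality 1" collapses events to
deaths). Cancers use incidence directly where a table provides it; the
bundled countries publish lung-cancer mortality only, so for them the
cancer pathway falls back to the same mortality ÷ case-fatality
arithmetic. Rates are converted to annual probabilities by
1 − exp(−rate), which stays in [0, 1) and is monotone — a
competing-risks-friendly convention.

Published country tables give prevalence per sex only; the engine spreads
it uniformly across age bands unless an age-resolved table is supplied.
The same applies to mortality rows. Former-smoker relative risk is held
constant over time since quitting (no decay curve is modelled).

## Policy effectiveness

A ban level carries a central effectiveness — the relative reduction in
per-capita consumption at full compliance: 0% (absent or media-only
bans), 1% (partial), 9% (comprehensive, including point-of-sale display).
Sensitivity ranges of 0–13.6% (partial) and 5–23.5% (comprehensive) are
carried for sweeps; the base case always uses the central values.
Realised effectiveness is Em = central × compliance, exactly
multiplicative in compliance.

A fraction Ip of the consumption effect appears as reduced prevalence:

    Prevalence_post = Prevalence_pre · (1 − Em·Ip)

applied to the *baseline* prevalence each year (scenarios describe
displacement from baseline, not compounding). The other share of the
consumption effect — taken as half, configurable — reduces cigarettes
among continuing smokers and feeds the intensity adjustment:

    RR_adj = RR_c − reduction · excess_fraction · (RR_c − RR_f)

with excess fractions of 0.82 (lung cancer), 0.57 (ischemic heart
disease), 0.80 (COPD) and 0.75 otherwise. RR_adj always stays in
[RR_f, RR_c]; never- and former-smoker rates are untouched.

### Scenario path (10 years)

* Year 1 (short term): Ip = 0.5, no intensity benefit, quitters join the
  former-smoker pool.
* Years 1–5: linear interpolation to the mid-term scenario — Ip stays at
  0.5 (the mid-term scenario keeps the short-term prevalence effect; its
  addition is the intensity benefit, whose weight ramps 0 → 1 linearly).
* Years 6–10: Ip interpolates linearly from 0.5 to 0.75 (so Ip(8) =
  0.65), the former-smoker pool is held at its baseline share and the
  prevalence decrement grows the never-smoker pool (lower initiation).
  The reallocation mode switches categorically at year 6.
* Horizons beyond 10 hold the long-term scenario.

Both reallocation modes conserve total probability mass exactly.

## Simulation conventions

* **Full-cycle accounting.** A person alive at cycle start accrues the
  whole year (life-year, quality-adjusted fraction, follow-up costs);
  death takes effect at cycle end. A certain fatal event in year 1 thus
  yields exactly one accrued life-year.
* **Within-year adjudication.** Multiple distinct conditions may strike
  in one year; they are applied in the fixed registry order
  (cardiovascular, respiratory, neoplasms), and a death is attributed to
  the first fatal condition in that order. At most one event per
  condition per cycle; cancer onsets occur at most once per lifetime,
  acute events may recur across years. Background mortality is
  adjudicated after disease fatality.
* **Event/fatality sampling.** One uniform per condition per year: an
  event occurs when u < p, and is fatal when u < p·cf — the nested
  threshold gives the correct joint distribution with a single draw.
* **Quality of life.** The year's utility is 1 minus the summed
  decrements of conditions held at the start of the year, floored at 0;
  a condition's decrement therefore starts the year after onset.
* **Common random numbers.** Randomness is counter-based (Philox keyed by
  the run seed) with a fixed draw layout per (individual, year, hazard),
  consumed regardless of vital status or policy. Baseline and policy runs
  with the same seed are therefore paired: smoking state is assigned each
  year by inverting the year's (current, former, never) distribution on a
  single persistent per-individual uniform, so a prevalence reduction
  moves exactly the marginal individuals into lower-risk states and a
  zero-effectiveness policy reproduces the baseline bit for bit. Averted
  deaths are consequently monotone in Em pathwise. Individual event
  categories can still dip slightly negative at small Em: a person saved
  from a fatal cardiac event lives on to accrue later events of other
  kinds (competing risks).
* **Hospitalizations** are reported equal to acute event counts; no
  separate rate is modelled.
* **Monte Carlo error.** Per-outcome standard errors come from
  between-individual variance (sd/√n); the deaths-per-person SE scales as
  n^(−1/2), verified over three doublings of n.

## Economics

Costs accrue in local currency: the acute cost in the event year and the
annual follow-up cost in each subsequent year with the condition. The
total is exactly Σ events × acute + Σ condition-years × follow-up (an
accounting identity asserted against a brute-force ledger). Published
figures combine first and following years, so each is split 80/20 into
acute and annual follow-up components — an assumption, configurable via
`acute_share`; a separately published annual cardiovascular follow-up row
replaces the split for the cardiovascular conditions. CPI adjustment is
amount × CPI_to / CPI_from; conversion to 2018 international dollars
divides by the PPP rate (local currency per I$). Countries without a cost
estimate for an event get the mean (cost / GDP per capita) ratio of the
reference economies (Argentina, Chile, Mexico) applied to their own GDP
per capita — linear in the target GDP. No discounting by default (a
configurable annual rate exists for sensitivity analysis).

The unit of the published cost figures is ambiguous in the sources;
the bundled files store the printed numbers with a `cost_unit` flag, and
no exact-arithmetic check depends on resolving it.

## Impact aggregation

Impact = baseline burden − policy burden, per sex, scaled by national
population 35+ / cohort size, then marked up +13.6% (men) / +12% (women)
for passive smoking and perinatal effects — applied uniformly to deaths,
events, life-years and costs (switchable). Life-years gained decompose as
PYLL (person-years added) + YLL-QL (quality-adjusted years added beyond
person-years); their sum equals the QALY difference.

Countries report an incremental ladder — status quo, step 1 (full
compliance with the current level; absent-ban countries move to a partial
ban), step 2 (comprehensive ban, 100% compliance) — implemented as
successive Em values on the same baseline with paired seeds, so the rows
telescope: the full-implementation total is the sum of all rows. Ladder
steps that do not increase Em are dropped (their increment is zero),
which reproduces the published 17-row layout for the seven countries.
The published full-implementation deaths total (98,132) does not equal
the column sum under the stated incremental rule (106,488) while the six
other columns sum exactly; the package records the recomputed sum and
leaves the discrepancy unresolved.

## Calibration

Predicted condition-specific mortality is compared with reference rates
as relative deviations; within ±10% is acceptable. Out-of-band cells get
a multiplicative factor reference/predicted on the condition's population
rate, re-projected each round. Calibration runs against deterministic
expected-value projections (age-structure-weighted mixture × case
fatality over the starting population), which are linear in the factor —
so recovery is exact in one round and a noise-free synthetic reference
returns unit factors; stochastic runs can then be verified against the
calibrated table. Factors are per (condition, sex); age bands share a
factor. COPD is excluded from the comparison by default (its mortality is
systematically under-recorded in national statistics), includable by
flag. Zero-reference cells are excluded with a warning. Goodness of fit
is summarised by R² of a least-squares line through the origin
(b = Σpo/Σp²; R² = 1 − Σ(o − bp)²/Σo²), which is scale-invariant in the
predictions. Non-convergence within the iteration budget is reported,
not raised (the CLI maps it to exit code 3 in strict mode).

## Synthetic data

`generate_country` draws prevalences (0.05–0.40), relative risks
(1.5–20, spanning cardiovascular to lung-cancer magnitudes), former-smoker
RRs between 1 and RR_c, case fatalities, quality decrements, GDP-scaled
event costs and a ban policy from one Philox stream keyed by the seed,
then forward-computes the population rates as the exact mixture — so
generated tables satisfy every country-table invariant and calibration
recovery is testable without any external data. Base rates are constant
across age bands (matching the uniform-spread convention for published
tables). `generate_reference_mortality` multiplies the implied mortality
by lognormal noise (sd of log-rates = `noise_sd`; 0 returns the implied
rates exactly).

What the generator does *not* emulate: age gradients in rates and
prevalence, correlation structure between conditions, cohort trends, or
any real country's joint distribution. Passing synthetic tests therefore
demonstrates the correctness of the machinery (inversion, simulation,
calibration, accounting), not the realism of any particular country
estimate.

## Parameters and defaults

| Parameter | Default | Why |
|---|---|---|
| Central effectiveness (absent/partial/comprehensive) | 0 / 0.01 / 0.09 | literature-review central estimators |
| Ip short / mid / long term | 0.5 / 0.5 / 0.75 | scenario definitions |
| Continuing-smoker share of consumption effect | 0.5 | half of consumption reduction via prevalence, half via intensity |
| Excess-risk reduction (lung / IHD / COPD / other) | 0.82 / 0.57 / 0.80 / 0.75 | low- vs high-intensity smoker risk gap |
| Markup male / female | 13.6% / 12% | passive smoking + perinatal burden |
| Former prevalence | 0.5 × current | not published; flagged assumption |
| Population share 35+ | 0.40 | not published; flagged assumption |
| Acute share of combined cost | 0.8 | published figures combine years; flagged assumption |
| Calibration tolerance | 10% | acceptability criterion |
| Cohort size | 200,000 default; 10,000–80,000 in tests and analyses | desk-scale runs resolve the orderings and identities under test |
| Discount rate | 0 | no discounting stated; configurable |
| Relative risks / case fatalities / QoL decrements | illustrative magnitudes in `default_risk_parameters()` | not published in the country tables; config-supplied for real analyses |

## Known limitations

* Country-level results with the default risk parameters are
  illustrative: the underlying relative risks, case fatalities, life
  tables and quality weights are inputs the user must supply for
  substantive estimates.
* No initiation-rate dynamics in youth (the prevalence shift folds all
  effects together), no dose-response beyond the single intensity
  adjustment, no co-morbidity interactions, no indirect or productivity
  costs, no price-elasticity/tax modelling (elasticities are carried as
  inert metadata), no within-cancer progression stages (cancer fatality
  is resolved in the onset year).
* Demography, economics and health-system characteristics are held fixed
  over the 10-year horizon.
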