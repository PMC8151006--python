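# Bolivia — model inputs (published country tables; rates per 10,000 person-years, prevalences as fractions)
schema_version: 1
country_code: BO
population_total: 10724705
smoking_prevalence:
  male: 0.201
  female: 0.177
mortality_rates:
  ami:
    male: 8.4
    female: 5.5
  other_cvd:
    male: 0.9
    female: 0.5
  stroke:
    male: 8.4
    female: 8.0
  pneumonia_influenza:
    male: 17.4
    female: 15.9
  copd:
    male: 1.1
    female: 1.3
  lung_cancer:
    male: 3.7
    female: 3.1
event_costs:
  ami: 5114
  other_cvd: 3835
  cardiovascular_followup_annual: 2024
  stroke: 5232
  pneumonia_influenza: 276
  copd: 3969
  lung_cancer: 8862
  mouth_cancer: 6381
  esophageal_cancer: 7444
  stomach_cancer: 7267
  pancreatic_cancer: 6026
  kidney_cancer: 6381
ppp_rate: 2.6
gdp_per_capita: 3095
cpi_series:
  2015: 100.0
  2018: 100.0
health_expenditure_share: 0.063
price_year: 2015
cost_unit: printed
ban_level: partial
compliance: 0.55
assumptions:
- cpi_series flat at 100 (national CPI indices not bundled)
- ppp_rate 2.6 boliviano per I$ assumed (not in published key)
metadata:
  country_name: Bolivia
  population_year: 2015
  tax_revenue_usd_millions: 21.5
  gdp_usd_millions: 33197
  price_elasticity_of_demand: -0.85
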