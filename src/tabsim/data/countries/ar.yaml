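# Argentina — model inputs (published country tables; rates per 10,000 person-years, prevalences as fractions)
schema_version: 1
country_code: AR
population_total: 43416755
smoking_prevalence:
  male: 0.234
  female: 0.186
mortality_rates:
  ami:
    male: 46.1
    female: 33.1
  other_cvd:
    male: 118.7
    female: 104.5
  stroke:
    male: 52.5
    female: 43.9
  pneumonia_influenza:
    male: 104.4
    female: 72.4
  copd:
    male: 4.3
    female: 1.9
  lung_cancer:
    male: 15.6
    female: 4.6
event_costs:
  ami: 3242
  other_cvd: 2432
  cardiovascular_followup_annual: 1283
  stroke: 4294
  pneumonia_influenza: 217
  copd: 4394
  lung_cancer: 17392
  mouth_cancer: 12523
  esophageal_cancer: 14610
  stomach_cancer: 14262
  pancreatic_cancer: 11827
  kidney_cancer: 12523
ppp_rate: 14.09
gdp_per_capita: 13432
cpi_series:
  2015: 100.0
  2018: 100.0
health_expenditure_share: 0.048
price_year: 2015
cost_unit: printed
ban_level: partial
compliance: 0.75
assumptions:
- cpi_series flat at 100 (national CPI indices not bundled)
metadata:
  country_name: Argentina
  population_year: 2015
  tax_revenue_usd_millions: 1926.2
  gdp_usd_millions: 583168.6
  price_elasticity_of_demand: -0.299
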