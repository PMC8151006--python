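# Chile — model inputs (published country tables; rates per 10,000 person-years, prevalences as fractions)
schema_version: 1
country_code: CL
population_total: 17948141
smoking_prevalence:
  male: 0.352
  female: 0.313
mortality_rates:
  ami:
    male: 8.3
    female: 4.9
  other_cvd:
    male: 7.4
    female: 8.4
  stroke:
    male: 9.8
    female: 9.6
  pneumonia_influenza:
    male: 4.2
    female: 4.0
  copd:
    male: 3.7
    female: 2.8
  lung_cancer:
    male: 3.9
    female: 2.2
event_costs:
  ami: 3944
  other_cvd: 2702
  cardiovascular_followup_annual: 1444
  stroke: 4431
  pneumonia_influenza: 235
  copd: 6133
  lung_cancer: 21727
  mouth_cancer: 15644
  esophageal_cancer: 18251
  stomach_cancer: 17816
  pancreatic_cancer: 14774
  kidney_cancer: 15644
ppp_rate: 2.2
gdp_per_capita: 13384
cpi_series:
  2015: 100.0
  2018: 100.0
health_expenditure_share: 0.078
price_year: 2015
cost_unit: printed
ban_level: partial
compliance: 0.8
assumptions:
- cpi_series flat at 100 (national CPI indices not bundled)
metadata:
  country_name: Chile
  population_year: 2015
  tax_revenue_usd_millions: 1346.5
  gdp_usd_millions: 240215.7
  price_elasticity_of_demand: -0.45
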