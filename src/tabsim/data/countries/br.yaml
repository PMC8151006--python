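# Brazil — model inputs (published country tables; rates per 10,000 person-years, prevalences as fractions)
schema_version: 1
country_code: BR
population_total: 207847528
smoking_prevalence:
  male: 0.18
  female: 0.113
mortality_rates:
  ami:
    male: 16.0
    female: 11.0
  other_cvd:
    male: 3.8
    female: 2.9
  stroke:
    male: 8.8
    female: 7.9
  pneumonia_influenza:
    male: 9.1
    female: 8.5
  copd:
    male: 6.6
    female: 4.5
  lung_cancer:
    male: 4.3
    female: 2.5
event_costs:
  ami: 5006
  other_cvd: 1881
  cardiovascular_followup_annual: 409
  stroke: 4304
  pneumonia_influenza: 361
  copd: 4824
  lung_cancer: 12279
  mouth_cancer: 9602
  esophageal_cancer: 12161
  stomach_cancer: 15074
  pancreatic_cancer: 11616
  kidney_cancer: 4632
ppp_rate: 2.77
gdp_per_capita: 8539
cpi_series:
  2015: 100.0
  2018: 100.0
health_expenditure_share: 0.083
price_year: 2015
cost_unit: printed
ban_level: comprehensive
compliance: 0.9
assumptions:
- cpi_series flat at 100 (national CPI indices not bundled)
metadata:
  country_name: Brazil
  population_year: 2015
  tax_revenue_usd_millions: 9511
  gdp_usd_millions: 1774725
  price_elasticity_of_demand: -0.48
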