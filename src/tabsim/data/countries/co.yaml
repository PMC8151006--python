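# Colombia — model inputs (published country tables; rates per 10,000 person-years, prevalences as fractions)
schema_version: 1
country_code: CO
population_total: 48228704
smoking_prevalence:
  male: 0.201
  female: 0.099
mortality_rates:
  ami:
    male: 19.0
    female: 13.7
  other_cvd:
    male: 2.3
    female: 1.7
  stroke:
    male: 8.5
    female: 9.3
  pneumonia_influenza:
    male: 3.6
    female: 3.1
  copd:
    male: 7.9
    female: 5.8
  lung_cancer:
    male: 3.3
    female: 1.9
event_costs:
  ami: 3835
  other_cvd: 1534
  cardiovascular_followup_annual: 34795
  stroke: 2174
  pneumonia_influenza: 325
  copd: 3463
  lung_cancer: 10499
  mouth_cancer: 7560
  esophageal_cancer: 8820
  stomach_cancer: 8610
  pancreatic_cancer: 7140
  kidney_cancer: 7560
ppp_rate: 412.36
gdp_per_capita: 6056
cpi_series:
  2015: 100.0
  2018: 100.0
health_expenditure_share: 0.072
price_year: 2015
cost_unit: printed
ban_level: comprehensive
compliance: 0.75
assumptions:
- cpi_series flat at 100 (national CPI indices not bundled)
metadata:
  country_name: Colombia
  population_year: 2015
  tax_revenue_usd_millions: 174
  gdp_usd_millions: 292080.1
  price_elasticity_of_demand: -0.78
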