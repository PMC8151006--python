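# Peru — model inputs (published country tables; rates per 10,000 person-years, prevalences as fractions)
schema_version: 1
country_code: PE
population_total: 31376670
smoking_prevalence:
  male: 0.235
  female: 0.153
mortality_rates:
  ami:
    male: 74.6
    female: 57.3
  other_cvd:
    male: 51.8
    female: 57.2
  stroke:
    male: 52.6
    female: 50.7
  pneumonia_influenza:
    male: 221.0
    female: 199.0
  copd:
    male: 33.2
    female: 25.3
  lung_cancer:
    male: 13.5
    female: 10.4
event_costs:
  ami: 2663
  other_cvd: 1850
  cardiovascular_followup_annual: 1171
  stroke: 5058
  pneumonia_influenza: 174
  copd: 4363
  lung_cancer: 14081
  mouth_cancer: 9251
  esophageal_cancer: 11828
  stomach_cancer: 11546
  pancreatic_cancer: 9575
  kidney_cancer: 10138
ppp_rate: 1.74
gdp_per_capita: 6122
cpi_series:
  2015: 100.0
  2018: 100.0
health_expenditure_share: 0.055
price_year: 2015
cost_unit: printed
ban_level: absent
compliance: null
assumptions:
- cpi_series flat at 100 (national CPI indices not bundled)
metadata:
  country_name: Peru
  population_year: 2015
  tax_revenue_usd_millions: 73.5
  gdp_usd_millions: 192083.7
  price_elasticity_of_demand: -0.7
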