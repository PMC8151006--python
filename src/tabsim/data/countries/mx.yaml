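# Mexico — model inputs (published country tables; rates per 10,000 person-years, prevalences as fractions)
schema_version: 1
country_code: MX
population_total: 127017224
smoking_prevalence:
  male: 0.198
  female: 0.064
mortality_rates:
  ami:
    male: 19.9
    female: 13.9
  other_cvd:
    male: 2.2
    female: 3.1
  stroke:
    male: 8.1
    female: 8.1
  pneumonia_influenza:
    male: 4.0
    female: 3.1
  copd:
    male: 7.5
    female: 5.6
  lung_cancer:
    male: 2.5
    female: 1.2
event_costs:
  ami: 4848.6
  other_cvd: 3190.4
  cardiovascular_followup_annual: 1240.6
  stroke: 4119.1
  pneumonia_influenza: 1309.9
  copd: 9236.2
  lung_cancer: 13792.6
  mouth_cancer: 9930.6
  esophageal_cancer: 11585.7
  stomach_cancer: 11309.9
  pancreatic_cancer: 9378.9
  kidney_cancer: 9930.6
ppp_rate: 1328.53
gdp_per_capita: 9009
cpi_series:
  2015: 100.0
  2018: 100.0
health_expenditure_share: 0.063
price_year: 2015
cost_unit: printed
ban_level: absent
compliance: null
assumptions:
- cpi_series flat at 100 (national CPI indices not bundled)
metadata:
  country_name: Mexico
  population_year: 2015
  tax_revenue_usd_millions: 2237.4
  gdp_usd_millions: 1144331.3
  price_elasticity_of_demand: -0.45
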