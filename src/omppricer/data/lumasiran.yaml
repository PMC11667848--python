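# Lumasiran (RNAi therapy for primary hyperoxaluria type 1) case fixture.
#
# Minimum-/maximum-scenario input columns for the four cost-based pricing
# models, transcribed from the published scenario tables. Lump sums are the
# printed "~"-rounded values, already in EUR. Column orientation follows the
# tables: a parameter inversely proportional to the price (prevalence,
# treatment rate, patent years, ...) takes its highest value in the minimum
# column.
#
# The USD->EUR rate is the 2021 annual average (ECB reference); the source
# tables print EUR values only, so the rate is exercised only for inputs
# flagged `currency: USD`.
metadata:
  medicine: lumasiran
  indication: primary hyperoxaluria type 1 (PH1)
  source_tables: NCP, AIM, DCF and ROROR minimum/maximum scenario tables
constants:
  eu_population: 447000000
  eu_attribution_share: 0.3585
  usd_to_eur_rate: 0.8458
  reporting_rounding: 1000
ncp:
  min:
    prevalence_per_million: 2.9
    treatment_rate: 0.70
    patent_years: 14
    rd_cost_total: 830000000
    cogs_ppppy: 38000
    marketing_fraction: 0.30
    profit_margin: 0.20
  max:
    prevalence_per_million: 1.6
    treatment_rate: 0.50
    patent_years: 10
    rd_cost_total: 1100000000
    cogs_ppppy: 38000
    marketing_fraction: 0.30
    profit_margin: 0.40
aim:
  min:
    prevalence_per_million: 2.9
    treatment_rate: 0.70
    market_share: 1.00
    patent_years: 14
    rd_cost_total: 800000000
    production_overhead_ppppy: 3000
    sales_fraction: 0.15
    basic_profit: 0.08
    innovation_bonus: 0.05
    bonus_convention: additive
  max:
    prevalence_per_million: 1.6
    treatment_rate: 0.50
    market_share: 0.50
    patent_years: 10
    rd_cost_total: 1100000000
    production_overhead_ppppy: 9000
    sales_fraction: 0.20
    basic_profit: 0.08
    innovation_bonus: 0.40
    bonus_convention: additive
dcf:
  min:
    prevalence_per_million: 2.9
    incidence_per_million: 0.15
    response_rate: 1.00
    failure_rate: 0.00
    adverse_event_rate: 0.00
    contraindication_rate: 0.00
    restriction_prevalent: 0.45   # prior liver transplantation 30% + fully pyridoxine responsive 15%
    restriction_incident: 0.15    # fully pyridoxine responsive 15%
    population_growth: 0.00
    uptake_cap: 0.50
    uptake_ramp_years: 0
    patent_years: 14
    rd_lumpsum_total: 637000000
    drug_cost_fraction_of_revenue: 0.40
    cost_of_capital: 0.09
    innovation_premium: 0.05
  max:
    prevalence_per_million: 1.6
    incidence_per_million: 0.18
    response_rate: 0.95
    failure_rate: 0.05
    adverse_event_rate: 0.05
    contraindication_rate: 0.05
    restriction_prevalent: 0.50   # + additional 5% partially pyridoxine responsive untreated
    restriction_incident: 0.20
    population_growth: 0.01
    uptake_cap: 0.50
    uptake_ramp_years: 0
    patent_years: 10
    rd_lumpsum_total: 637000000
    drug_cost_fraction_of_revenue: 0.40
    cost_of_capital: 0.12
    innovation_premium: 0.15
roror:
  min:
    prevalence_per_million: 2.9
    treatment_rate: 0.70
    patent_years: 14
    rd_cost_total: 830000000
    production_cost_ppppy: 38000
    wacc: 0.08
    gdp_deflator: 0.019
    years_until_approval: 6
    profit_margin: 0.05
  max:
    prevalence_per_million: 1.6
    treatment_rate: 0.50
    patent_years: 10
    rd_cost_total: 1100000000
    production_cost_ppppy: 38000
    wacc: 0.14
    gdp_deflator: 0.065
    years_until_approval: 15
    profit_margin: 0.15
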