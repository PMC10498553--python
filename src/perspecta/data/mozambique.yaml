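# Mozambique HIV treatment case: base-case values and PSA ranges.
# Scalar leaves are either a bare number (point value) or {min, mode, max}
# (PERT range, sampled as a lambda=4 beta in the PSA). All currency in 2020
# USD. Categorical distributions are normalized at load.
parameters:
  # --- epidemiology ---
  mortality_rate_by_cd4_untreated:   # per 100 person-years, untreated HIV
    gt500:    {min: 0.1,  mode: 0.6,  max: 2.0}
    c350_500: {min: 0.8,  mode: 1.6,  max: 3.0}
    c200_349: {min: 2.8,  mode: 4.2,  max: 5.7}
    lt200:    {min: 13.2, mode: 21.2, max: 41.5}
  cd4_decline_no_art: {min: 50, mode: 60, max: 80}          # cells/uL/year
  cd4_decline_on_art_failing: {min: 0, mode: 14, max: 20}   # cells/uL/year
  cd4_gain_on_art: {min: 170, mode: 205, max: 250}          # cells/uL/year
  ltfu_12m_risk_1month: {min: 0.12, mode: 0.20, max: 0.32}
  ltfu_rate_community_3m: {min: 1.59, mode: 5.1, max: 8.61} # per 100 py
  or_ltfu_3m: {min: 0.76, mode: 0.79, max: 0.82}            # 2-year OR vs 1-month
  or_ltfu_6m: {min: 0.31, mode: 0.41, max: 0.54}
  reengage_12m_with_tracing: {min: 0.30, mode: 0.371, max: 0.44}
  reengage_12m_without_tracing: {min: 0.08, mode: 0.151, max: 0.22}
  pct_first_line: {min: 0.75, mode: 0.95, max: 0.98}
  pct_dolutegravir: 0.99
  second_line_failure_rate: {min: 13, mode: 15, max: 18}    # per 100 py
  annual_switch_risk_dtg: {min: 0.0, mode: 0.0025, max: 0.005}
  annual_switch_risk_efv: {min: 0.020, mode: 0.025, max: 0.033}
  discount_rate: 0.05
  # --- health effects (DALY weight for one year, by CD4 band) ---
  daly_weight_on_art:
    gt500: 0.078
    c350_500: 0.1
    c200_349: 0.15
    lt200: 0.2
  daly_weight_off_art:
    gt500: 0.012
    c350_500: 0.27
    c200_349: 0.377
    lt200: 0.58
  # --- costs (2020 USD) ---
  facility_cost_1m_annual: {min: 104, mode: 134, max: 163}  # excl. ARVs
  community_cost_3m_annual: {min: 125, mode: 160, max: 226} # excl. ARVs
  arv_cost_monthly_dtg: 5.55
  arv_cost_monthly_efv: 6.40
  arv_cost_monthly_second_line: 23.15
  vl_test_cost_annual: {min: 20, mode: 26, max: 43}
  case_mgmt_cost_monthly: {min: 25, mode: 37.97, max: 50}
  chapa_cost_per_hour: {min: 0.05, mode: 0.28, max: 1.00}
  transit_time_distribution:  # round trip by chapa
    lt60min: 0.51
    m60_240: 0.43
    gt240min: 0.06
  walk_roundtrip_hours: {min: 1, mode: 6, max: 24}
  pct_travel_by_chapa: {min: 0.33, mode: 0.575, max: 0.66}
  brigade_distance_fraction: {min: 0.15, mode: 0.33, max: 0.50}
  wait_time_hours: {min: 0.25, mode: 1, max: 4}
  oop_health_expenditure_annual: 4.14
  net_national_income_pc: 393
  gdp_pc: 467
  # --- populations ---
  age_distribution:          # starting ages 15-80; the >80 mass is folded
    a15_19: 0.0438           # into 75-80; normalized at load
    a20_24: 0.0992
    a25_29: 0.1525
    a30_34: 0.1637
    a35_39: 0.1582
    a40_44: 0.1422
    a45_49: 0.1089
    a50_54: 0.0558
    a55_59: 0.0331
    a60_64: 0.0197
    a65_69: 0.0118
    a70_74: 0.0065
    a75_80: 0.0047
  cd4_distribution_at_init:  # at ART initiation
    gt500: 0.31
    c350_500: 0.19
    c200_349: 0.23
    lt200: 0.27
  n_plhiv: 1970000

strategies:
  - clinical_1m
  - clinical_3m
  - clinical_6m
  - clinical_3m_case_mgmt
  - community_3m
  - mixed_6m_community_3m

run:
  n_individuals: 200000
  horizon_years: 100
  cycle_months: 1
  seed: 1
  psa_draws: 1000
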