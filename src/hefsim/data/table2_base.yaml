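# Base-case parameter registry for the Cambodia diabetes / Health Equity Fund
# microsimulation. Point values are the base case; distribution specs feed the
# probabilistic sensitivity analysis only. A bare number is shorthand for a
# point-mass parameter.
meta:
  currency: "USD (2019)"
  description: >
    Unit costs, epidemiological rates, care-delivery probabilities and Health
    Equity Fund (HEF) scheme parameters for a cohort aged 25-69 in Cambodia.
    Cost distributions are lognormal on the same scale as the point value,
    except per-day complication drug costs whose lognormals are specified on
    the annualized (x365) scale.
  notes:
    - "All cost parameters are per instance (per visit, per day, per episode) unless the name says annual."
    - "Probabilities are annual unless stated otherwise."
    - "The mortality schedule is a synthetic Gompertz schedule scaled so that its 25-69 band mean equals the all-cause mortality scalar 0.046; swap in an observed schedule if one is available."

costs:
  diagnostics: {family: lognormal, p1: -0.232, p2: 0.809, point_value: 1.10}   # FPG test, per use
  laboratory: {family: lognormal, p1: -0.024, p2: 0.857, point_value: 1.41}    # lab services, per use
  oad_annual: {family: lognormal, p1: 3.245, p2: 0.406, point_value: 27.86}    # oral anti-diabetic, per patient-year
  insulin_annual: {family: lognormal, p1: 4.816, p2: 0.195, point_value: 125.80}
  outpatient_visit:
    health_center: {family: lognormal, p1: 1.299, p2: 0.496, point_value: 4.15}
    cpa1: {family: lognormal, p1: 2.298, p2: 0.268, point_value: 10.32}
    cpa2: {family: lognormal, p1: 1.754, p2: 0.408, point_value: 6.28}
    cpa3: {family: lognormal, p1: 3.791, p2: 0.059, point_value: 44.40}
  inpatient_per_day:
    health_center: {family: lognormal, p1: 1.479, p2: 0.408, point_value: 4.77}
    cpa1: {family: lognormal, p1: 4.083, p2: 0.115, point_value: 59.73}
    cpa2: {family: lognormal, p1: 3.378, p2: 0.115, point_value: 29.53}
    cpa3: {family: lognormal, p1: 3.703, p2: 0.115, point_value: 40.85}

transport:
  outpatient: {family: lognormal, p1: -0.138, p2: 0.330, point_value: 0.92}
  inpatient: {family: lognormal, p1: 2.453, p2: 0.068, point_value: 11.65}

discount_rate: 0.03

population:
  all_cause_mortality: 0.046        # mean annual probability, ages 25-69
  diabetes_incidence: 0.001         # annual, among non-diabetics
  diabetes_prevalence: 0.062        # baseline
  diabetes_mortality: 0.030         # annual, diabetes-attributable
  income: {family: gamma, p1: 0.5, p2: 11566.32, point_value: 5783.16}  # annual household income
  age_min: 25
  age_max: 69
  sex_ratio: 0.5                    # share male at baseline
  mortality_schedule:               # annual death probability by 5-year band
    - {age_lo: 25, age_hi: 30, male: 0.00893, female: 0.00660}
    - {age_lo: 30, age_hi: 35, male: 0.01268, female: 0.00937}
    - {age_lo: 35, age_hi: 40, male: 0.01799, female: 0.01330}
    - {age_lo: 40, age_hi: 45, male: 0.02553, female: 0.01887}
    - {age_lo: 45, age_hi: 50, male: 0.03622, female: 0.02677}
    - {age_lo: 50, age_hi: 55, male: 0.05140, female: 0.03799}
    - {age_lo: 55, age_hi: 60, male: 0.07294, female: 0.05392}
    - {age_lo: 60, age_hi: 65, male: 0.10351, female: 0.07651}
    - {age_lo: 65, age_hi: 70, male: 0.14689, female: 0.10857}
    - {age_lo: 70, age_hi: 75, male: 0.20845, female: 0.15407}
    - {age_lo: 75, age_hi: 80, male: 0.29581, female: 0.21864}
    - {age_lo: 80, age_hi: 85, male: 0.41977, female: 0.31026}
    - {age_lo: 85, age_hi: 90, male: 0.59568, female: 0.44028}
    - {age_lo: 90, age_hi: 95, male: 0.70000, female: 0.62479}
    - {age_lo: 95, age_hi: 100, male: 0.70000, female: 0.70000}

dw_uncomplicated: 0.049             # disability weight, uncomplicated diabetes
dw_undiagnosed_counts: true         # undiagnosed diabetics also carry the 0.049 weight

complications:
  - name: nephropathy
    incidence: 0.0100
    rr_therapy: 0.30
    disability_weight: 0.569
    case_fatality: 0.311
    cost: {family: lognormal, p1: 8.733, p2: 0.219, point_value: 6358}   # hemodialysis, annual
    cost_unit: per_year
    cost_setting: outpatient
    acute: false
  - name: retinopathy
    incidence: 0.0212
    rr_therapy: 0.68
    disability_weight: 0.184
    case_fatality: 0.0
    cost: {family: lognormal, p1: 5.792, p2: 0.115, point_value: 330}    # intravitreal injection, annual
    cost_unit: per_year
    cost_setting: outpatient
    acute: false
  - name: neuropathy
    incidence: 0.0466
    rr_therapy: 0.94
    disability_weight: 0.133
    case_fatality: 0.0
    cost: {family: lognormal, p1: 6.862, p2: 0.029, point_value: 2.62}   # acetylsalicylic acid, per day
    cost_unit: per_day
    cost_setting: outpatient
    acute: false
  - name: angina_pectoris
    incidence: 0.0067
    rr_therapy: 0.68
    disability_weight: 0.080
    case_fatality: 0.0
    cost: {family: lognormal, p1: 7.855, p2: 0.29, point_value: 7.07}    # beta blocker, per day
    cost_unit: per_day
    cost_setting: outpatient
    acute: false
  - name: pvd
    incidence: 0.0085
    rr_therapy: 0.74
    disability_weight: 0.014
    case_fatality: 0.002
    cost: {family: lognormal, p1: 7.855, p2: 0.29, point_value: 7.07}
    cost_unit: per_day
    cost_setting: outpatient
    acute: false
  - name: mi
    incidence: 0.174                # stored verbatim; see consistency_report warning
    rr_therapy: 0.39
    disability_weight: 0.432
    case_fatality: 0.707
    cost: {family: lognormal, p1: 7.855, p2: 0.29, point_value: 7.07}
    cost_unit: per_day
    cost_setting: inpatient
    acute: true
  - name: stroke
    incidence: 0.0053
    rr_therapy: 0.59
    disability_weight: 0.588
    case_fatality: 0.693
    cost: {family: lognormal, p1: 6.862, p2: 0.029, point_value: 2.62}
    cost_unit: per_day
    cost_setting: inpatient
    acute: true
  - name: heart_failure
    incidence: 0.0033
    rr_therapy: 0.68
    disability_weight: 0.179
    case_fatality: 0.0              # no published value; conservative default
    cost: {family: lognormal, p1: 7.855, p2: 0.29, point_value: 7.07}
    cost_unit: per_day
    cost_setting: inpatient
    acute: false

care:
  p_diagnosis: {family: beta, p1: 8.241, p2: 14.057, point_value: 0.370}
  p_outpatient_non_hef: {family: beta, p1: 0.916, p2: 4.412, point_value: 0.117}
  p_outpatient_hef: {family: beta, p1: 0.420, p2: 3.171, point_value: 0.172}
  p_inpatient: {family: beta, p1: 8.850, p2: 581.150, point_value: 0.015}
  provider_shares:
    health_center: {family: beta, p1: 9.755, p2: 107.796, point_value: 0.114}
    cpa1: {family: beta, p1: 10.943, p2: 574.050, point_value: 0.025}
    cpa2: {family: beta, p1: 11.862, p2: 557.843, point_value: 0.030}
    cpa3: {family: beta, p1: 7.304, p2: 190.218, point_value: 0.042}
  p_oad: 0.224
  p_insulin: 0.017
  p_combo: 0.07
  p_oad_to_insulin: 0.04
  p_adherence: 0.125
  rr_diet: 0.90
  los_days: 5

hef:
  eligibility_percentile: 0.20      # one of {0.20, 0.30}
  enrollment: 0.75
  subsidy_rate: 1.00                # one of {0.80, 1.00}
  utilization: 1.00

strategy_effects:
  rr_diagnosis: {family: normal, p1: 1.5, p2: 0.1, point_value: 1.5}
  rr_care_seeking: {family: normal, p1: 2.0, p2: 0.1, point_value: 2.0}
  rr_complication_care: {family: normal, p1: 2.0, p2: 0.1, point_value: 2.0}
  adherence_covered: 0.40

life_expectancy:
  male: 67
  female: 71

poverty_line_daily: 1.90
horizon_years: 45
national_population: 16000000
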