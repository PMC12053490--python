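# Base-case model configuration.
# Units are stated per field; currency values are GBP at the stated price year.
# Parameter means/s.e. follow the trial-derived point estimates the model is
# built around; unit costs are representative UK reference costs supplied here
# as plain inputs (replace with your own costing exercise as needed).
price_year: 2022
currency: GBP

cohort:
  n_patients: 680          # patients in a simulated trial
  mean_age: 62.9           # years
  sd_age: 12.6             # years
  prop_large_wound: 0.377  # wound area > 25 cm^2
  prop_inpatient: 0.831
  prop_tissue_loss: 0.784
  prop_history: 0.168
  prop_male: 0.5
  allocation_ratio: 0.5    # proportion assigned to NPWT

econ:
  horizon_cycles: 360          # 30 years of monthly cycles
  cycle_days: 30.4375          # 365.25 / 12
  discount_rate_annual: 0.035  # applied to costs and QALYs
  start_age: 62.9              # years
  prop_male: 0.5
  wtp_grid: [20000.0, 30000.0] # GBP per QALY
  half_cycle_correction: false

effectiveness:
  hr: 1.07                   # pooled hazard ratio, NPWT vs standard
  posterior_draws_path: null # CSV of posterior log-HR draws (optional)
  baseline_hazard: null      # per-cycle healing hazard; null -> calibrate
  calibration:
    target_cum_healed: 0.55  # healed fraction in the standard arm ...
    target_cycle: 12         # ... at this cycle

mortality:
  smr: 13.3                # standardized mortality ratio vs general population
  smr_se: 1.45             # ~ smr / sqrt(observed deaths)
  life_table_path: null    # null -> bundled synthetic life table

utility:
  decrement: 0.0095        # utility lost per month while unhealed
  decrement_se: 0.004
  population_model:        # quadratic-in-age, sex-adjusted utility regression
    intercept: 0.9508566   # (published UK general-population coefficients)
    male_coef: 0.0212126
    age_coef: -0.0002587
    age2_coef: -0.0000332

costs:
  npwt_daily: [30.61, 0.18]         # GBP per day on NPWT
  sd_daily: [4.17, 0.11]            # GBP per day on standard dressings
  npwt_duration_days: [46.6, 4.12]  # days on NPWT before switching
  medication_monthly: [6.18, 0.65]  # GBP per month while unhealed
  healed_monthly_cost: 0.0          # healed patients are discharged
  unit_costs:                       # GBP per event / visit / night
    gp_surgery: 41.0
    gp_home: 100.0
    nurse_surgery: 14.0
    nurse_home: 54.0
    dressing_change: 40.0
    outpatient_diabetic_foot: 180.0
    outpatient_podiatry: 120.0
    outpatient_dressing_clinic: 150.0
    outpatient_other: 180.0
    day_admission: 742.0
    inpatient_night: 700.0
    ae_visit: 215.0

resource_use:              # monthly [mean, se] while unhealed
  multiplier: 1.0          # scales every mean (scenario hook)
  npwt:
    gp_surgery: [0.11, 0.03]
    gp_home: [0.05, 0.01]
    nurse_surgery: [1.39, 0.22]
    nurse_home: [3.65, 0.35]
    dressing_change: [14.67, 2.44]
  standard:
    gp_surgery: [0.13, 0.05]
    gp_home: [0.07, 0.04]
    nurse_surgery: [1.26, 0.19]
    nurse_home: [3.89, 0.45]
    dressing_change: [12.82, 2.24]
  shared:                  # treatment-independent secondary care
    outpatient_diabetic_foot: [0.24, 0.02]
    outpatient_podiatry: [0.06, 0.01]
    outpatient_dressing_clinic: [0.01, 0.001]
    outpatient_other: [0.01, 0.001]
    day_admission: [0.01, 0.001]
    inpatient_night: [0.74, 0.13]
    ae_visit: [0.02, 0.001]

psa:
  n_iterations: 1000
  seed: 1

scenarios:
  no_excess_mortality:
    mortality.smr: 1.0
  undiscounted:
    econ.discount_rate_annual: 0.0
  half_cycle:
    econ.half_cycle_correction: true
  doubled_resource_use:
    resource_use.multiplier: 2.0
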