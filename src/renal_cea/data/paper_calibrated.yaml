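model:
  cohort_size: 1000.0
  start_age: 40.0
  horizon: 45
  cycle_length: 1.0
  discount_rate: 0.03
  wtpt: 45000.0
  initial_occupancy:
    HD: 0.0
    PD: 0.0
    Tx: 1.0
    LRHD: 0.0
    LRPD: 0.0
    D: 0.0
  seed: 20120816
transitions:
  HD:
    PD: 0.02
    Tx: 0.05
  PD:
    HD: 0.05
    Tx: 0.06
  tx_exit_to_hd: 0.035
  tx_exit_to_pd: 0.0035
  lr_tunnel: true
costs:
  first_year:
    HD: 2545.0
    PD: 1819.0
    Tx: 36772.0
    LRHD: 6627.0
    LRPD: 3748.0
    D: 0.0
  prevalence:
    HD: 31912.0
    PD: 24996.0
    Tx: 6030.0
    LRHD: 31912.0
    LRPD: 24996.0
    D: 0.0
  components:
    HD:
      hospitalization_days: 800.0
      rHuEPO: 500.0
      iv_iron: 200.0
      access_or_surgery: 900.0
      other: 145.0
    PD:
      hospitalization_days: 300.0
      rHuEPO: 500.0
      iv_iron: 200.0
      access_or_surgery: 700.0
      other: 119.0
utilities:
  HD: 0.69
  PD: 0.69
  Tx: 0.81
  LRHD: 0.53
  LRPD: 0.53
  D: 0.0
mortality:
  q0: 0.022
  growth: 0.075
  lr_first_year_survival: 0.73
uplifts:
  hospitalization: 0.97
  rhuepo: 0.69
  iv_iron: 0.47
  nonscheduled_start: true
  surcharge:
    LRHD: 2867.0
    LRPD: 1199.0
psa:
  replicates: 1000
  relative_sd: 0.1
  wtpt_grid:
    start: 0.0
    stop: 90000.0
    step: 1000.0
productivity:
  loss_per_death_year: 29345.0
  working_age_limit: 67.0
  enabled: false
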