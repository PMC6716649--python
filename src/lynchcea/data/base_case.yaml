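# Base-case model inputs. Unit suffixes: _per_1000py = events per 1000
# person-years; _gbp = 2016/17 pounds sterling. Age-indexed tables are
# anchor points, interpolated linearly with flat extrapolation.
population:
  n_probands: 1000
  relatives_per_proband: 6
  proband_age_years: 60.0
  relative_age_years: 54.0
  relative_age_weights:
    25: 0.08
    35: 0.13
    45: 0.19
    55: 0.22
    65: 0.19
    75: 0.13
    85: 0.06
  relative_female_share: 0.5
  horizon_age_years: 100.0
  cycle_length_months: 1.0
epidemiology:
  prevalence_ls: 0.039
  prevalence_ls_by_age:
    40: 0.095
    45: 0.08
    50: 0.066
    55: 0.052
    60: 0.039
    65: 0.024
    70: 0.016
    75: 0.011
    80: 0.0075
    85: 0.005
  overall_gene_mix:
    MLH1: 0.169
    MSH2: 0.246
    MSH6: 0.477
    PMS2: 0.108
  gene_mix_by_age:
    40:
      MLH1: 0.256684
      MSH2: 0.280279
      MSH6: 0.40713
      PMS2: 0.055907
    45:
      MLH1: 0.210195
      MSH2: 0.28489
      MSH6: 0.440632
      PMS2: 0.064283
    50:
      MLH1: 0.17
      MSH2: 0.286
      MSH6: 0.471
      PMS2: 0.073
    55:
      MLH1: 0.136
      MSH2: 0.284
      MSH6: 0.498
      PMS2: 0.082
    60:
      MLH1: 0.11011
      MSH2: 0.285285
      MSH6: 0.514515
      PMS2: 0.09009
    65:
      MLH1: 0.088
      MSH2: 0.292
      MSH6: 0.523
      PMS2: 0.097
    70:
      MLH1: 0.069
      MSH2: 0.305
      MSH6: 0.526
      PMS2: 0.1
    75:
      MLH1: 0.052
      MSH2: 0.321
      MSH6: 0.524
      PMS2: 0.103
    80:
      MLH1: 0.039
      MSH2: 0.339
      MSH6: 0.519
      PMS2: 0.103
    85:
      MLH1: 0.029125
      MSH2: 0.356474
      MSH6: 0.511843
      PMS2: 0.102558
  ec_mortality_rate_ls_per_1000py: 4.0
  ec_mortality_sporadic_per_1000py_by_age:
    40: 26.4
    50: 33.0
    60: 43.0
    70: 58.0
    80: 78.0
    85: 92.1
  ec_mortality_window_years: 5.0
  crc_incidence_ls_surveilled_per_1000py:
    MLH1:
      25: 2.0
      35: 5.0
      45: 9.0
      55: 12.0
      65: 14.0
      75: 15.0
      100: 15.0
    MSH2:
      25: 1.5
      35: 3.5
      45: 6.5
      55: 9.0
      65: 11.0
      75: 12.0
      100: 12.0
    MSH6:
      25: 0.2
      35: 0.8
      45: 2.0
      55: 3.5
      65: 5.0
      75: 6.0
      100: 6.0
    PMS2:
      25: 0.1
      35: 0.3
      45: 0.8
      55: 1.3
      65: 2.0
      75: 2.5
      100: 2.5
  surveillance_incidence_hr: 0.387
  crc_incidence_general_per_1000py_by_age:
    25: 0.05
    40: 0.25
    50: 0.6
    60: 1.4
    70: 2.6
    80: 3.8
    100: 4.5
  crc_mortality_per_1000py_by_age:
    stage_i_iii:
      40: 45.0
      60: 55.0
      70: 70.0
      80: 95.0
      100: 130.0
    stage_iv:
      40: 400.0
      60: 430.0
      80: 480.0
      100: 520.0
  crc_mortality_hr_ls_stage_i_iii: 0.66
  stage_distribution:
    surveilled:
    - 0.45
    - 0.31
    - 0.16
    - 0.08
    unsurveilled:
    - 0.23
    - 0.26
    - 0.31
    - 0.2
  life_table_per_1000py:
    female:
      0: 4.0
      10: 0.1
      20: 0.3
      30: 0.5
      40: 1.0
      50: 2.6
      55: 3.9
      60: 6.0
      65: 9.5
      70: 15.0
      75: 25.0
      80: 45.0
      85: 80.0
      90: 140.0
      95: 230.0
      100: 360.0
    male:
      0: 4.5
      10: 0.12
      20: 0.6
      30: 0.9
      40: 1.6
      50: 3.6
      55: 5.5
      60: 8.5
      65: 13.5
      70: 21.0
      75: 35.0
      80: 62.0
      85: 105.0
      90: 175.0
      95: 270.0
      100: 400.0
diagnostics:
  ihc:
    sensitivity: 0.944
    specificity: 0.748
    failure_rate: 0.037
  msi:
    sensitivity: 0.903
    specificity: 0.771
    failure_rate: 0.019
  p_mlh1_pattern_given_positive:
    ls_mlh1: 0.89
    ls_other: 0.006
    sporadic: 0.83
  methylation_after_dmlh1:
    sensitivity: 0.95
    specificity: 0.936
  methylation_after_msi:
    sensitivity: 0.95
    p_methylated_ls_other: 0.07142857142857142
    p_methylated_sporadic: 0.67
  germline_diagnostic_sensitivity: 0.9
  germline_diagnostic_specificity: 1.0
  predictive_test_accuracy: 1.0
  p_attend_counselling: 0.55
  p_decline_test_given_attend: 0.1
  failure_policy: refer
  relative_uptake: 1.0
  relative_uptake_pls: 0.2
utilities:
  baseline_by_age:
    female:
      16: 0.94
      25: 0.93
      35: 0.91
      45: 0.88
      55: 0.84
      65: 0.8
      75: 0.76
      85: 0.71
      100: 0.62
    male:
      16: 0.94
      25: 0.93
      35: 0.92
      45: 0.89
      55: 0.85
      65: 0.81
      75: 0.77
      85: 0.72
      100: 0.63
  stage_iv_multiplier: 0.79
costs_gbp:
  ihc: 210.0
  msi: 202.0
  methylation: 136.0
  counselling_offer: 27.0
  relative_referral: 36.0
  pretest_counselling_proband: 347.0
  pretest_counselling_relative: 172.0
  posttest_counselling: 133.0
  diagnostic_test: 755.0
  predictive_test: 166.0
  colonoscopy: 583.0
  colonoscopy_interval_years: 2.1
  crc_management_by_age:
    stage_i:
      50: 31500.0
      70: 28875.0
      85: 22750.0
    stage_ii:
      50: 43750.0
      70: 40250.0
      85: 31500.0
    stage_iii:
      50: 57750.0
      70: 52500.0
      85: 40250.0
    stage_iv:
      50: 50750.0
      70: 45500.0
      85: 35000.0
economics:
  discount_rate_annual: 0.035
  wtp_per_qaly_gbp: 20000.0
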