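config:
  cohort_size: 1000.0
  cycle_length: 1.0
  discount_rate: 0.03
  horizon_years: 6
costs:
  adt:
    basis: per_year
    sd: 1413.0
    unit_cost: 2370.0
  arpi:
    basis: per_year
    sd: 18886.0
    unit_cost: 8905.0
  biopsy:
    basis: per_event
    sd: 1540.0
    unit_cost: 1347.0
  chemo_cycle:
    basis: total_course
    sd: 9476.0
    unit_cost: 15519.0
  end_of_life:
    basis: total_course
    sd: 13179.0
    unit_cost: 13939.0
  immune:
    basis: per_year
    sd: 28046.0
    unit_cost: 104264.0
  lu_psma:
    basis: per_year
    sd: 36598.0
    unit_cost: 90106.0
  mri:
    basis: per_event
    sd: 169.0
    unit_cost: 406.0
  osteoprotective:
    basis: per_year
    sd: 1031.0
    unit_cost: 1058.0
  palliative:
    basis: total_course
    sd: 16067.0
    unit_cost: 27980.0
  parp:
    basis: per_year
    sd: 15444.0
    unit_cost: 51216.0
  plnd:
    basis: per_event
    sd: null
    unit_cost: 1500.0
  psa_test:
    basis: per_event
    sd: 12.0
    unit_cost: 29.0
  psma_pet:
    basis: per_event
    sd: 1209.0
    unit_cost: 1498.0
  ra223:
    basis: per_year
    sd: 5825.0
    unit_cost: 25692.0
  rp:
    basis: per_event
    sd: 3464.0
    unit_cost: 10832.0
  rt:
    basis: per_event
    sd: 3334.0
    unit_cost: 7726.0
  stockholm3:
    basis: per_event
    sd: null
    unit_cost: 400.0
  trus:
    basis: per_event
    sd: null
    unit_cost: 100.0
mix:
  adt_years: null
  arpi_fraction: 0.8
  arpi_years: 3.0
  calibration_multipliers:
    as_surveillance: 1.3159523797969317
    localized_adt: 1.0178577903579962
    metastatic_intensity: 6.730863579138854
  discontinuation_increment: 0.1
  discontinuation_year1: 0.3
  eol_fraction: 0.35
  eol_year: 6
  immune_fraction: 0.01
  immune_years: 3.0
  osteoprotective_fraction: 0.33
  palliative_fraction: 0.5
  palliative_year: 5
  parp_fraction: 0.09
  parp_years: 3.0
  psma_pet_at_diagnosis: true
  radiopharm_fraction: 0.3
  radiopharm_lu_split: 0.5
  radiopharm_window_years: 2
  taxane_only_fraction: 0.2
  triplet_given_arpi_fraction: 0.25
schedules:
  active_surveillance:
    biopsy_per_year:
    - 1
    - 0
    - 1
    - 0
    - 0
    - 0
    cum_progression:
      3: 0.25
      5: 0.35
    curative_adt_years: 0.5
    curative_mix:
      rp: 0.5
      rt_short_adt: 0.5
    mri_per_year:
    - 1
    - 0
    - 1
    - 0
    - 1
    - 0
    psa_per_year:
    - 3
    - 2
    - 2
    - 2
    - 2
    - 2
  localized:
    adt_long_years: 2.0
    adt_short_years: 0.5
    high_weights:
      rp_plnd: 0.5
      rt_long_adt: 0.5
    intermediate_fraction: 0.6
    intermediate_weights:
      rp: 0.5
      rt_short_adt: 0.5
strategies:
  diag_probs:
    biopsy_outcome:
      psa_mri:
        benign: 0.31606249926814434
        isup1: 0.19048085164949516
        isup2_5: 0.4005225339922648
        metastatic: 0.09293411509009579
      sthlm3_reflex:
        benign: 0.2960492980714352
        isup1: 0.10686407073001665
        isup2_5: 0.5159828534749312
        metastatic: 0.08110377772361686
      swop:
        benign: 0.07333496381138915
        isup1: 0.2677690524579686
        isup2_5: 0.4847060867885912
        metastatic: 0.174189896942051
    p_pirads_ge_3_given_referred:
      psa_mri: 0.39966870192769016
      sthlm3_reflex: 0.45
      swop: 0.75
    p_psa_ge_1_5: 0.44670833333333326
    p_psa_ge_3: 0.35
    p_sthlm3_ge_11_given_psa_1_5: 0.6697997585627353
    p_swop_referred_given_psa_ge_3: 0.2843093106615992
  swop_fn_progress_fraction: 0.1
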