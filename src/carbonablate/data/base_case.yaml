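# Base-case inputs: pulsed field ablation (PFA) vs cryoablation (CBA) for
# paroxysmal atrial fibrillation, European hospital perspective, 1-year
# horizon.  Units: days, minutes, proportions in [0, 1], kg CO2eq per
# resource unit.  Drug emission factors apply per minute of anesthesia
# time.  Distributions: beta for proportions, normal for continuous
# quantities; SD omitted means 10% of the mean.
arms:
  PFA:
    los_ward_days: 2.40
    icu_los_days: 1.00
    procedure_minutes: 65.77
    redo_rate: 0.1337
    er_visit_rate: 0.0149
    icu_admission_rate: 0.0075
    anesthesia_minutes: 64.91
    propofol_use: 0.99
    sufentanil_use: 0.7015
    sevoflurane_use: 0.1940
    pni_rate: 0.0
    trd_rate: 0.0024
    fap_rate: 0.0075
  CBA:
    los_ward_days: 2.41
    icu_los_days: 2.00
    procedure_minutes: 77.22
    redo_rate: 0.1647
    er_visit_rate: 0.0074
    icu_admission_rate: 0.0148
    anesthesia_minutes: 84.76
    propofol_use: 0.99
    sufentanil_use: 0.20
    sevoflurane_use: 0.6667
    pni_rate: 0.0063
    trd_rate: 0.0029
    fap_rate: 0.0074
care:
  pni_outpatient_frac: 0.569
  pni_visit_count: 4
  trd_critical_frac: 0.50
  trd_icu_los_days: 1.99
  fap_surgical_frac: 0.0168
  fap_repair_minutes: 69.70
  fap_repair_los_days: 11
emissions:
  bed_day: 38
  icu_day: 90
  ep_lab_hour: 24.06
  er_visit: 14
  outpatient_visit: 1.1
  propofol: 0.01
  sufentanil: 0.01
  sevoflurane: 0.25
  drug_time_basis: per_minute
uncertainty:
  PFA:
    los_ward_days: normal
    icu_los_days: normal
    procedure_minutes: normal
    redo_rate: beta
    er_visit_rate: beta
    icu_admission_rate: beta
    anesthesia_minutes: normal
    propofol_use: beta
    sufentanil_use: beta
    sevoflurane_use: beta
    pni_rate: beta
    trd_rate: beta
    fap_rate: beta
  CBA:
    los_ward_days: normal
    icu_los_days: normal
    procedure_minutes: normal
    redo_rate: beta
    er_visit_rate: beta
    icu_admission_rate: beta
    anesthesia_minutes: normal
    propofol_use: beta
    sufentanil_use: beta
    sevoflurane_use: beta
    pni_rate: beta
    trd_rate: beta
    fap_rate: beta
  care:
    pni_outpatient_frac: beta
    pni_visit_count: normal
    trd_critical_frac: beta
    trd_icu_los_days: normal
    fap_surgical_frac: beta
    fap_repair_minutes: normal
    fap_repair_los_days: normal
  emissions:
    bed_day: normal
    icu_day: normal
    ep_lab_hour: normal
    er_visit: normal
    outpatient_visit: normal
    propofol: normal
    sufentanil: normal
    sevoflurane: normal
cohort_size: 100
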