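# Parameter config schema

A parameter set is a single YAML (or JSON) document with four sections
plus an optional cohort size. The packaged base case
(`src/carbonablate/data/base_case.yaml`) is a complete example.

```yaml
arms:            # >= 2 arms, keyed by label ("PFA", "CBA", "RFA", ...)
  <label>:
    los_ward_days: float >= 0        # days, general ward/cardiology
    icu_los_days: float >= 0         # days, ICU stay if admitted
    procedure_minutes: float >= 0    # total EP-lab procedure time
    anesthesia_minutes: float >= 0
    redo_rate: proportion            # all proportions in [0, 1]
    er_visit_rate: proportion
    icu_admission_rate: proportion
    propofol_use: proportion
    sufentanil_use: proportion
    sevoflurane_use: proportion
    pni_rate: proportion             # permanent phrenic nerve injury
    trd_rate: proportion             # tamponade requiring drainage
    fap_rate: proportion             # femoral artery pseudoaneurysm
care:            # resource use per complication (arm-independent)
  pni_outpatient_frac: proportion
  pni_visit_count: float >= 0        # expected outpatient visits
  trd_critical_frac: proportion
  trd_icu_los_days: float >= 0
  fap_surgical_frac: proportion
  fap_repair_minutes: float >= 0
  fap_repair_los_days: float >= 0
emissions:       # kg CO2eq per resource unit
  bed_day: float >= 0
  icu_day: float >= 0
  ep_lab_hour: float >= 0
  er_visit: float >= 0
  outpatient_visit: float >= 0
  propofol: float >= 0               # per drug-time unit
  sufentanil: float >= 0
  sevoflurane: float >= 0
  drug_time_basis: per_minute | per_hour   # default per_minute
uncertainty:     # optional; scope is an arm label, "care" or "emissions"
  <scope>:
    <field>: beta | normal | fixed         # shorthand, SD = 10% of mean
    <field>: {kind: beta|normal|fixed, sd: float}  # explicit SD
cohort_size: number >= 0             # default 100
```

Validation rules:

* unknown keys anywhere are rejected, naming the offending path;
* proportions must lie in [0, 1]; durations and factors must be >= 0;
* `beta` requires mean in [0, 1] and, when sd > 0, sd^2 < mean(1-mean);
  `fixed` requires sd = 0; a beta with mean 0 or 1 degenerates to fixed;
* `uncertainty` entries must reference existing fields of their scope;
* percentages are stored as proportions (66.67% -> 0.6667).
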