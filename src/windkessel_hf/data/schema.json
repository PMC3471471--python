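{
  "cohort_table": {
    "description": "Grouped pre/post treatment blood pressures for dose-effect fitting",
    "columns": ["drug", "dose_mg_d", "sbp_pre", "dbp_pre", "sbp_post", "dbp_post", "n"],
    "units": {"dose_mg_d": "mg/day", "sbp_pre": "mmHg", "dbp_pre": "mmHg", "sbp_post": "mmHg", "dbp_post": "mmHg", "n": "count"}
  },
  "patient_table": {
    "description": "Per-patient inputs for prediction",
    "columns": ["id", "sbp", "dbp", "drug", "dose_mg_d", "ef_pct", "sw_J_beat", "hr_beat_min"],
    "units": {"sbp": "mmHg", "dbp": "mmHg", "dose_mg_d": "mg/day", "ef_pct": "%", "sw_J_beat": "J/beat", "hr_beat_min": "beats/min"}
  },
  "profile_table": {
    "description": "7-component hemodynamic profile (CII appended as 8th column on scoring)",
    "columns": ["map", "pp", "hr", "co", "sv", "ef", "sw"],
    "units": {"map": "mmHg", "pp": "mmHg", "hr": "beats/min", "co": "L/min", "sv": "mL", "ef": "%", "sw": "J/beat"}
  },
  "table1_cohorts": {
    "description": "Packaged fixture: baseline characteristics of 8 HF cohorts",
    "columns": ["group", "size", "male", "female", "age_years", "sbp_mmHg", "dbp_mmHg", "source"]
  },
  "table3_profiles": {
    "description": "Packaged fixture: worked per-patient example (baseline/simulated/measured columns)",
    "columns": ["drug", "dose_mg_d", "column", "sbp_mmHg", "dbp_mmHg", "map_mmHg", "pp_mmHg", "hr_beat_min", "co_L_min", "sv_mL", "ef_pct", "sw_J_beat", "cii", "source"]
  },
  "curve_json": {
    "description": "Fitted dose-effect curve",
    "fields": ["drug", "quantity", "e_max", "d50_mg_d", "fit_rss", "n_points"]
  },
  "surface_json": {
    "description": "Self-describing pressure mapping surface",
    "fields": ["kind", "bp_mode", "policy", "grid", "units", "values_row_major"]
  },
  "trace_text": {
    "description": "Pressure trace export",
    "columns": ["time_s", "pressure_mmHg"]
  }
}
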