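{
  "cohort_csv": {
    "description": "Patient-level first-day cohort table, one row per patient.",
    "columns": {
      "patient_id": "string identifier, first column",
      "group_label": "simulation truth: survivor | nonsurvivor (absent for real data)",
      "sex": "0 = female, 1 = male",
      "alt": "alanine aminotransferase, U/L",
      "ast": "aspartate transaminase, U/L",
      "alp": "alkaline phosphatase, U/L",
      "bilirubin": "total bilirubin, mg/dL",
      "albumin": "serum albumin, g/dL",
      "inr": "international normalized ratio",
      "urea": "blood urea, mg/dL",
      "creatinine": "serum creatinine, mg/dL",
      "sodium": "serum sodium, mEq/L",
      "chloride": "serum chloride, mEq/L",
      "phosphate": "serum phosphate, mg/dL",
      "bicarbonate": "serum bicarbonate, mEq/L",
      "lactate": "serum lactate, mmol/L",
      "ph": "arterial blood pH",
      "glucose": "blood glucose, mg/dL",
      "haemoglobin": "haemoglobin, g/dL",
      "platelets": "platelet count, 10^3/uL",
      "wbc": "white blood cell count, 10^3/uL",
      "temperature": "body temperature, Celsius",
      "heart_rate": "heart rate, beats/min",
      "map": "mean arterial blood pressure, mmHg",
      "resp_rate": "respiratory rate, breaths/min",
      "spo2": "oxygen saturation, %",
      "gcs": "Glasgow Coma Score total, 3-15",
      "age": "age, years",
      "event": "1 = death or liver transplant within follow-up, 0 = censored",
      "time": "days to event or censoring; censored rows have time == follow-up horizon",
      "sofa": "SOFA score (integer >= 0), computed",
      "kcc": "King's College Criteria count, 0-4, computed"
    },
    "sidecar": "<name>.csv.config.json echoes the full SimulationConfig including seed"
  },
  "raw_events_csv": {
    "description": "Long-format raw measurements, one per row.",
    "columns": {
      "patient_id": "string identifier",
      "variable": "variable name as in cohort_csv",
      "timestamp": "hours since ICU admission, >= 0",
      "value": "measurement value in the variable's units"
    }
  },
  "deviations_csv": {
    "description": "Patients x significant parenclitic axes.",
    "columns": {
      "patient_id": "index column",
      "δ-A/B": "one column per significant axis; deviation of B-on-A reference fit"
    }
  },
  "edge_list_tsv": {
    "columns": {"source": "variable", "target": "variable", "weight": "Pearson r or deviation"}
  },
  "communities_json": {
    "fields": {"k": "clique size", "communities": "list of sorted node lists (may overlap)"}
  }
}
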