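{
  "creatinine_molar_mass_g_per_mol": 113.12,
  "cockcroft_gault": {
    "citation": "Cockcroft DW, Gault MH. Prediction of creatinine clearance from serum creatinine. Nephron 1976;16:31-41.",
    "units": "mg/kg/day scaled by weight (kg)",
    "male_intercept_mg_per_kg_day": 28.0,
    "male_age_slope_mg_per_kg_day_per_year": 0.2,
    "female_factor": 0.85
  },
  "ix": {
    "citation": "Ix JH et al. Equations to estimate creatinine excretion rate: the CKD Epidemiology Collaboration. Clin J Am Soc Nephrol 2011;6:184-191.",
    "units": "mg/day",
    "intercept": 879.89,
    "weight_kg": 12.51,
    "age_years": -6.19,
    "female": -379.42,
    "black": 34.51,
    "note": "race term set to 0 when ethnicity is not recorded"
  }
}
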