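{
  "description": "Published summary values from the rPOXA 1B laccase storage-stability study, used as pipeline inputs and synthetic-data ground truth.",
  "initial_activity_UL": 16575.5,
  "initial_activity_sd_UL": 268.92,
  "specific_activity_U_mg": 758.71,
  "pilot_pooled_sd_UL": 96.6,
  "precision_UL": 21.8,
  "confidence": 0.95,
  "population_size": 1200,
  "n_batches": 3,
  "schedule_months": [1, 2, 3, 4, 5, 6, 8, 10, 12],
  "stability": {
    "temperatures_K": [240.98, 277.4, 297.53, 303.27, 309.58],
    "kd_per_month": [0.003, 0.015, 0.055, 0.135, 0.4],
    "Ed_J_mol": 41400.0
  },
  "kinetics": [
    {"temperature_K": 240.98, "months": 12, "vmax_mM_min": 0.0102, "vmax_sd": 0.0004, "km_mM": 0.0414, "km_sd": 0.0046},
    {"temperature_K": 277.4,  "months": 12, "vmax_mM_min": 0.0104, "vmax_sd": 0.0005, "km_mM": 0.0435, "km_sd": 0.0057},
    {"temperature_K": 297.53, "months": 6,  "vmax_mM_min": 0.0102, "vmax_sd": 0.0004, "km_mM": 0.0466, "km_sd": 0.0064},
    {"temperature_K": 303.27, "months": 6,  "vmax_mM_min": 0.0104, "vmax_sd": 0.0004, "km_mM": 0.0477, "km_sd": 0.0076},
    {"temperature_K": 309.58, "months": 4,  "vmax_mM_min": 0.0094, "vmax_sd": 0.0005, "km_mM": 0.1016, "km_sd": 0.0736},
    {"temperature_K": 314.79, "months": 1,  "vmax_mM_min": 0.0096, "vmax_sd": 0.0006, "km_mM": 0.1433, "km_sd": 0.1564}
  ]
}
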