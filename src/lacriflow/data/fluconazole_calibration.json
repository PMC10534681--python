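{
  "analyte": "fluconazole",
  "detector": "HPLC/UV 210 nm",
  "slope": 30676.0,
  "intercept": 2843.9,
  "range_low_ug_per_mL": 0.5,
  "range_high_ug_per_mL": 10.0,
  "lod_ug_per_mL": 0.007,
  "loq_ug_per_mL": 0.021,
  "extraction_volume_mL": 5.0,
  "note": "Linear UV response for fluconazole extracted from corneal tissue; donor concentration in the dynamic arm is 60 ug/mL."
}
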