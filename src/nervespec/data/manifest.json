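{
  "version": "synthetic-band-model-1.0",
  "units": "cm^-1 at reference concentration",
  "blood_reference": "blood_fraction 1.0 == 150 g hemoglobin / litre whole blood",
  "provenance": "SYNTHETIC tables: Gaussian band models at the canonical absorption-band positions of each chromophore, magnitudes on the scale of published compilations; generated by nervespec.chromophores.band_model, not digitised literature data.",
  "sampling": "400-1710 nm, 2 nm step; linearly interpolated to the 1 nm grid on load",
  "files": {
    "hb": "hb_synthetic.csv",
    "hbo2": "hbo2_synthetic.csv",
    "beta_carotene": "beta_carotene_synthetic.csv",
    "fat": "fat_synthetic.csv",
    "water": "water_synthetic.csv",
    "collagen": "collagen_synthetic.csv"
  }
}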