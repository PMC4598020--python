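{
  "description": "Bench water-extraction trial: a chamber filled with a known volume was emptied by the syringe procedure; the shortfall is the unaccounted volume.",
  "reference_volume_ml": 250.0,
  "n_trials": 30,
  "unaccounted_ml": {"min": 0.5, "max": 5.0, "mean": 2.0, "se": 0.4}
}
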