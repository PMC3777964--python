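{
  "comment": "True frameshifting efficiencies (%) used by the reporter simulator, set to the published dual-reporter measurements for these constructs; control is the in-frame Podo0 construct.",
  "n_replicates": 6,
  "cv": 0.1,
  "base_ratio": 30.0,
  "bgal_level": 1000.0,
  "constructs": {
    "Podo-1": {"true_efficiency_percent": 1.0},
    "IBV-Podo0": {"true_efficiency_percent": 0.3}
  }
}
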