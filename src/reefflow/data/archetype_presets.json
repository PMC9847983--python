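{
  "table": {
    "species_label": "Acropora hyacinthus",
    "h_cm": 3.4,
    "Ap_cm2": 76.7,
    "Af_cm2_by_theta": {"0": 17.1}
  },
  "massive": {
    "species_label": "Porites lobata",
    "h_cm": 5.1,
    "Ap_cm2": 50.7,
    "Af_cm2_by_theta": {"0": 29.9, "45": 33.6, "90": 38.1, "180": 29.6}
  },
  "branching": {
    "species_label": "Pocillopora edyouxi",
    "h_cm": 5.6,
    "Ap_cm2": 63.6,
    "Af_cm2_by_theta": {"0": 95.1}
  }
}
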