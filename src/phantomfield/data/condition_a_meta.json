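{
  "condition": "A",
  "reference": "C3",
  "pads": ["C3", "C4"],
  "diameter_mm": 240.80,
  "weight_kg": null,
  "temperature_C": 24.0,
  "resistance_kohm": null
}
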