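{
  "description": "Required top-level sections of a sipflow report.json",
  "required_sections": [
    "meta",
    "sex_intake",
    "sex_preference",
    "sex_polysubstance",
    "clustering",
    "cluster_intake",
    "cluster_preference",
    "cluster_polysubstance"
  ]
}
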