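{
  "required": {
    "run": {"required": {"seed": "number", "alpha": "number"}},
    "attrition": {},
    "forms": {},
    "orthologs": {},
    "bias_screen": {}
  },
  "form": {
    "required": {
      "n_loci_tested": "number",
      "contrasts": {},
      "patterns": {"required": {"counts": {}, "percent": {}}},
      "homeolog": {"required": {"class_counts": {}, "class_percent": {}}}
    }
  }
}
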