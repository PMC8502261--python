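{
  "type": "object",
  "required": ["cohorts", "combined", "cnvr_frequencies",
               "aneuploidy_groups", "qc"],
  "properties": {
    "cohorts": {"type": "object"},
    "combined": {
      "type": "object",
      "required": ["n", "any_large_cnv"],
      "properties": {
        "n": {"type": "integer"},
        "any_large_cnv": {
          "type": "object",
          "required": ["count", "percent"],
          "properties": {"count": {"type": "integer"},
                         "percent": {"type": "number"}}
        }
      }
    },
    "cnvr_frequencies": {"type": "array"},
    "aneuploidy_groups": {"type": "array"},
    "qc": {
      "type": "object",
      "required": ["n_failed_samples", "failed_samples"],
      "properties": {"n_failed_samples": {"type": "integer"},
                     "failed_samples": {"type": "array"}}
    }
  }
}
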