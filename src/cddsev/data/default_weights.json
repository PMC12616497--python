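{
  "description": "Published component weightings for the weighted-average global severity score (renormalized by their sum at load; the printed values sum to 0.999 after rounding).",
  "weights": {
    "motor": 0.467,
    "insomnia": 0.007,
    "sleepiness": 0.012,
    "seizures": 0.012,
    "alertness": 0.111,
    "comm_clinician": 0.105,
    "csbs": 0.142,
    "vision": 0.091,
    "feeding": 0.052
  }
}
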