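{
  "synthetic": true,
  "seed": 11,
  "n_individuals": 10,
  "n_cmr_rows": 67,
  "n_litters": 13,
  "n_litter_years": 37
}
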