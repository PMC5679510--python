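{
  "_comment": "Synthetic-organism presets. Order-1 transition matrices over (A,C,G,T); pos favors A/G after purines and C/T after pyrimidines at 0.25+/-0.04, alt is the complementary flip. The non-essential source is the divergence-mix (1-d)*pos + d*alt.",
  "pos_matrix": [
    [0.29, 0.21, 0.29, 0.21],
    [0.21, 0.29, 0.21, 0.29],
    [0.29, 0.21, 0.29, 0.21],
    [0.21, 0.29, 0.21, 0.29]
  ],
  "alt_matrix": [
    [0.21, 0.29, 0.21, 0.29],
    [0.29, 0.21, 0.29, 0.21],
    [0.21, 0.29, 0.21, 0.29],
    [0.29, 0.21, 0.29, 0.21]
  ],
  "initial_dist": [0.25, 0.25, 0.25, 0.25],
  "length_range": [300, 1500],
  "n_essential": 50,
  "n_non_essential": 150,
  "genome_length": 100000,
  "divergence": {"separable": 1.0, "weak": 0.3, "null": 0.0}
}
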