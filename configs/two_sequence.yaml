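# Two-sequence ambiguous-cue task: {A,F,B,D} at p=0.2 vs {A,F,C,E} at 0.8,
# with the probability-matching replay noise (sigma = 20 pA, fully shared
# sources within each subpopulation).
model:
  N_E: 900
  M: 6
  K_EE: 180
task:
  alphabet: [A, F, B, D, C, E]
  sequences:
    - [A, F, B, D]
    - [A, F, C, E]
  probs: [0.2, 0.8]
  N_e: 20
  L: 10
noise:
  kind: poisson
  sigma: 20.0
  c: 1.0
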