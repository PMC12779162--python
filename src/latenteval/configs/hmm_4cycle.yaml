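# Noisy 4-cycle HMM student-teacher study: a population of gradient-trained
# students is scored with co-smoothing, few-shot co-smoothing at the chosen
# k, ground-truth decoding errors, cross-decoding and cycle consistency.
kind: hmm_4cycle
seed: 0
dataset:
  M: 4
  eps: 0.01
  # held-out kept below the largest student M so that cycle consistency
  # retains resolution (see docs/methods.md)
  n_neurons: 28
  n_out: 8
  s_train: 300
  s_test: 100
  T: 10
students:
  Ms: [4, 5, 6, 8, 10, 12]
  seeds_per_M: 3
  algorithm: adam
  lr: 0.05
  n_iter: 500
fewshot:
  candidate_ks: [1, 2, 4, 8, 16, 32]
  max_resamples: 150
filter:
  relative: 0.9
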