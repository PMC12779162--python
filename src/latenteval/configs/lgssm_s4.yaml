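# Linear-Gaussian state-space replication: test log-likelihood vs k-shot
# linear-readout MSE and the two ground-truth decoding directions.
kind: lgssm_s4
seed: 0
dataset:
  M: 4
  n_neurons: 35
  n_out: 30
  s_train: 100
  s_test: 200
  T: 10
students:
  Ms: [2, 3, 4, 5, 6, 8]
  seeds_per_M: 2
  n_iter: 60
fewshot:
  k: 10
  s: 50
filter:
  ll_margin_per_trial: 2.0
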