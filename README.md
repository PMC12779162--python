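# latenteval

Prediction-based evaluation of neural latent-variable models (LVMs):
**co-smoothing**, **few-shot co-smoothing**, **cross-decoding** and **cycle
consistency**, together with self-contained Bernoulli-HMM and
linear-Gaussian state-space student–teacher sandboxes and the analytical
theory of why few-shot readouts discriminate extraneous latent structure.

## The problem

An LVM for trialised spike data is an encoder *f* mapping held-in neural
activity to latent trajectories ẑ, plus a decoder *g* mapping latents to
predicted firing rates of held-out neurons. The standard validation score is
co-smoothing: the normalised Poisson log-likelihood, in bits per spike, of
held-out activity predicted from held-in activity,

    Q = Σ_n [ L(R_n; X_n) − L(r̄_n; X_n) ] / (ln 2 · Σ_n μ_n)

where `L` is the Poisson log-likelihood, `r̄_n` neuron *n*'s mean rate and
`μ_n` its total spike count over the evaluated trials (so the mean-rate
predictor scores exactly 0). The trouble is that models with essentially
perfect Q can carry arbitrary *extraneous* dynamics — latent structure
absent from the system that generated the data. This package implements a
composite evaluation that exposes such structure:

- **Few-shot co-smoothing ⟨Q_k⟩** — with *f* and *g* frozen, a fresh readout
  *g′* to a reserved set of *k*-out neurons is re-estimated from only *k*
  trials (a ridge-penalised Poisson GLM, or the closed-form Bernoulli
  emission MLE for HMM posteriors), averaged over ⌊5·S_train/k⌋ resampled
  subsets. Extraneous latents dilute the small-sample estimate and depress
  the score; the effect is largest at small *k* and vanishes as *k* → ∞.
- **Cross-decoding D_{u→v}** — regress model *v*'s latents from model *u*'s
  (affine least squares and 1 − R² for dense latents; multinomial
  regression and mean KL for HMM posteriors). Across a population of
  high-Q models, the column mean ⟨D_{u→v}⟩_u proxies model *v*'s distance
  to the ground truth without requiring access to it.
- **Cycle consistency D_{r→ẑ}** — regress a model's latents from its own
  rate predictions; unexplained latent variance is extraneous by
  construction.
- **Theory** (`latenteval.theory`) — closed forms and Monte-Carlo
  simulators for three solvable few-shot settings: minimum-norm ridgeless
  regression (double descent at p = k), a two-bin Bernoulli-HMM toy
  (expected log-likelihood deficits 1/(2k) vs 1/k for a minimal vs a
  time-indexed student), and prototype learning (error H(SNR) with
  SNR = ½√(k/M)/σ²_ext).

## Worked example

Train a minimal (M = 4) and an overparameterised (M = 12) HMM student on
data from a noisy 4-cycle teacher, then score both:

```python
import numpy as np
from latenteval.cosmoothing import cosmoothing_score
from latenteval.fewshot import FewShotConfig, fewshot_cosmoothing
from latenteval.hmm import (fit_hmm, make_cycle_teacher, make_hmm_dataset,
                            predict_rates, smooth_dataset)
from latenteval.similarity import cross_decode_hmm

teacher = make_cycle_teacher(M=4, n_neurons=28, eps=1e-2, seed=0)
ds, _ = make_hmm_dataset(teacher, s_train=300, s_test=100, T=10, n_out=8, seed=1)
xi_teacher = smooth_dataset(teacher, ds)

for M in (4, 12):
    params, _ = fit_hmm(ds.spikes[ds.train_trials], M, lr=0.05, n_iter=500, seed=2)
    xi = smooth_dataset(params, ds)
    q = cosmoothing_score(predict_rates(params, xi.subset(ds.test_trials),
                                        ds.held_out_indices), ds).q_total
    d_ts = cross_decode_hmm(xi_teacher, xi, ds.train_trials, ds.test_trials, seed=0)
    line = f"M={M:2d}: Q = {q:.4f}  D_T->S = {d_ts:.4f} "
    for k in (4, 8, 64):
        rep = fewshot_cosmoothing(xi, ds, FewShotConfig(
            k=k, seed=0, decoder_kind="hmm_emission_mle",
            max_resamples=300, silent_neurons="skip"))
        line += f" <Q{k}>={rep.qk_mean:.4f}±{rep.qk_sem:.4f}"
    print(line)
```

Output:

```
M= 4: Q = 0.1901  D_T->S = 0.0886  <Q4>=0.0293±0.0065 <Q8>=0.1423±0.0030 <Q64>=0.1881±0.0002
M=12: Q = 0.1858  D_T->S = 0.4417  <Q4>=0.0164±0.0068 <Q8>=0.1374±0.0031 <Q64>=0.1870±0.0002
```

The two students are nearly indistinguishable by co-smoothing (Q ≈ 0.19),
but the overparameterised student carries extraneous structure — its
latents cannot be decoded from the teacher's (D_{T→S} = 0.44 vs 0.09) —
and the few-shot scores at small *k* expose exactly that, while the gap
closes by k = 64.

The same study at population scale (18 students, all four metrics, Spearman
correlations) runs from a bundled config:

```
latenteval run-experiment --config src/latenteval/configs/hmm_4cycle.yaml --out scratch/hmm_study
```

Other subcommands: `simulate-hmm`, `simulate-lgssm`, `fit-hmm`, `fit-lgssm`,
`eval-cosmooth`, `eval-fewshot`, `choose-k`, `crossdecode`,
`cycle-consistency`, `theory` (see `latenteval --help`).

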