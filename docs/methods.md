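# Methods

This note records the models, estimators, numerical conventions and design
choices behind `latenteval`, and what the synthetic sandboxes do and do not
establish about real neural data.

## Data model

A dataset is a tensor of non-negative integer spike counts with shape
`(trials S, time bins T, neurons N)`, a held-in/held-out partition of the
neuron axis, an optional list of *k*-out neurons reserved for few-shot
decoding (conventionally equal to the held-out set; never overlapping the
held-in set), and a train/test partition of the trial axis. Ragged trial
lengths are not supported. Containers are NPZ or HDF5 with identical
content; integer arrays round-trip bit-exactly.

Latent trajectories are either dense vectors (state-space posterior means)
or per-timestep probability simplices (HMM posteriors; each slice sums to 1
within 1e-8). Predicted rates are strictly positive expected counts per
bin; a floor of `1e-10` is applied before any logarithm so Poisson
log-likelihoods stay finite. The floor is the dominant penalty when a
decoder predicts (near-)zero rate for a bin that contains a spike — visible
as strongly negative few-shot scores at very small `k`.

## Co-smoothing

The score is the Poisson log-likelihood gain of the predicted rates over a
constant mean-rate baseline, pooled over neurons and converted to bits per
spike: `Q = Σ_n ΔL_n / (ln 2 · Σ_n μ_n)`. Conventions:

- the `log x!` term is omitted throughout (it cancels in the difference);
- the baseline mean `r̄_n` is computed on the evaluation trials themselves,
  which makes `Q = 0` exact for the mean-rate predictor (a train-set
  baseline is available as an option);
- normalisation pools all neurons into a single division by the total
  spike count — the benchmark "bits per spike" convention. A per-neuron
  variant (mean of `ΔL_n / μ_n`) is kept as a diagnostic because the
  score's definition is sometimes written per neuron; the pooled form is
  the default and the one all reported numbers use;
- neurons with zero spikes in the evaluation set are excluded from both
  sums; if all are silent the score is undefined and an error is raised.

## Few-shot co-smoothing

With the encoder frozen, a fresh readout to the *k*-out neurons is fitted
on each of `s` independently resampled *k*-trial subsets of the train set
and scored on the fixed test set; the report carries the per-subset scores,
their mean and standard error. Defaults: `s = ⌊5·S_train/k⌋` capped at
2000; Poisson-GLM ridge strength `alpha = 1e-3` with an unpenalised
intercept (the regulariser's sole role is to stabilise the small-sample
fit); latents enter the GLM as-is, without standardisation, so that *g′*
has the same linear–exponential–Poisson form as a typical decoder *g*.
Each resample derives its own child seed from the master seed, so any
single subset is reproducible in isolation. Subsets may overlap across
resamples (independent draws).

Silent neurons — *k*-out neurons with no spikes in a subset — are a hard
error by default because an intercept-only Poisson fit would diverge;
callers can opt into skip-and-record. The intended workflow is to avoid the
situation altogether by picking `k` with `choose_k`, which estimates the
silent-neuron frequency per candidate `k` over random probe subsets and
recommends the smallest `k` whose frequency is at (default) zero.

For Bernoulli HMM posteriors the readout has a closed form: the
posterior-weighted spike fraction per state,
`B̂[m,n] = Σ 1[x=1]·ξ[t,m] / Σ ξ[t,m]`. States with zero posterior mass in
the subset have no defined row; they are flagged and fall back to the
posterior-blind mean spike rate so downstream rate mixing stays finite.

## HMM sandbox

Teacher: a noisy M-cycle, `A[m,l] ∝ 1[l=(m+1) mod M] + ε` with `ε = 0.01`,
uniform initial distribution, and emission probabilities drawn once from
Uniform(0,1) and frozen by seed. Smoothing uses the scaled forward–backward
recursion (per-step normalisation, per-bin max-shift of the emission
log-likelihoods as an underflow guard); its exactness is certified against
exhaustive path enumeration on small instances. Held-out rates are the
posterior mixture of emission rows.

Students are fitted by maximum likelihood on all neurons of the train
trials. The default optimiser is full-batch first-order ascent with Adam
(learning rate 1e-2, 2000 iterations by default; the population experiment
uses 0.05/500): the gradients of the log-likelihood with respect to the
softmax (rows of `A`, `pi`) and sigmoid (`B`) parameterisations have closed
forms in the forward–backward posteriors, so no autodiff is involved. EM
(Baum–Welch, monotone by construction) is available via
`algorithm="em"` and is used where speed matters. Convergence is asserted
through the recorded negative-log-likelihood trace. Neither optimiser's
schedule is critical: recovery is checked by likelihood, not by parameter
identity (an M-state fit is identifiable only up to state permutation).

Traffic graphs summarise a fitted HMM as state/edge visitation fractions
under ancestral sampling, with edges below 0.01 marked pruned — a compact
way to see extraneous states and transitions.

## Linear-Gaussian sandbox

The LGSSM (`z_0 ~ N(μ0, Σ0)`, `z_t ~ N(F z_{t-1} + b, G)`,
`x_t ~ N(H z_t + c, R)`) uses the Kalman filter / RTS smoother for exact
inference; because the model is time-invariant and trials share a length,
covariance recursions are computed once per time step and shared across
trials. The log-likelihood comes from the filter's prediction-error
decomposition. Exactness is certified against dense joint-Gaussian
conditioning on small instances.

Students are fitted by EM with exact closed-form M-steps (initialised from
a PCA readout and damped-identity dynamics, with small seeded
perturbations); this optimises the same likelihood a gradient method
would, with a guaranteed non-increasing NLL trace, and requires no
autodiff. The random teacher uses rotation-like stable dynamics (spectral
radius 0.9), `G = 0.1 I`, dense Gaussian readout and `R = 0.5 I` — slow
mixing with moderate observation noise, so that smoothing is genuinely
informative. For this model class the replication reports test
log-likelihood (not Q) and k-shot ordinary-least-squares MSE (not Q_k),
with the posterior smoothed means as the per-trial latent summary.

## Similarity metrics

- Dense latents: affine least squares fitted on train trials, error
  `1 − R²` on test trials with R² averaged uniformly over target
  dimensions (variance-weighted averaging is an option). Constant target
  dimensions are scored `R² = 0` and flagged. The least-squares solve uses
  a relative singular-value cutoff of 1e-10 so near-collinear features
  (e.g. rank-deficient rate predictions) cannot blow up the out-of-sample
  error. The error is invariant to invertible affine reparameterisation of
  the source latents.
- Simplex latents: a multinomial logistic map fitted by penalised
  cross-entropy to states sampled from the target posteriors (one sample
  per trial–bin by default; classifier regularisation at the library
  default `C = 1`), error = mean KL(prediction ‖ target posterior) over
  test samples, both arguments clipped at 1e-12 (the KL is undefined at
  exact zeros; the alternative argument order is exposed as an option).
  A single-state source yields an intercept-only classifier; a
  single-state target is handled as a point-mass prediction.
- The cross-decoding matrix fills all ordered pairs and reports column
  means excluding the diagonal (self-decoding is trivially ~0 and would
  bias the proxy downward).
- Cycle consistency reuses the affine decoder, mapping a model's held-out
  rate predictions back to its latents.
- High-Q filtering supports an absolute threshold (`Q > q_min`) and a
  relative one (`Q > f · max Q`).

A structural caveat found while building the HMM population study: when
the decoder is linear in the latents and the number of held-out rates is
at least the latent dimensionality, the latents are *exactly* affinely
recoverable from the rates, so cycle consistency is identically zero
regardless of extraneous dynamics. The bundled experiment therefore keeps
the held-out population (8 neurons) below the largest student size (12
states); with many held-out neurons, rely on cross-decoding instead. The
CLI's dataset-simulation defaults (2000/100 trials, 20 held-in / 50
held-out, T = 10) are unchanged by this and match the scale used for the
likelihood-recovery checks.

## Theory

- **Ridgeless regression.** Asymptotic risk in the proportional limit
  `p/k → γ`: for `γ < 1`, bias 0 and variance `σ²_obs γ/(1−γ)`, with no
  dependence on the extraneous scale; for `γ > 1`, bias
  `γ(γ−1)/((γ−1) + 1/σ²_ext)²`. Two candidate expressions for the
  overparameterised variance circulate — `σ²_obs γ/(γ−1)` and
  `σ²_obs/(γ−1)` (the value obtained by substituting the fixed-point
  constant into the general variance formula); both are returned labelled,
  and the Monte-Carlo simulator adjudicates in favour of the substituted
  form (empirically ≈ 0.095 vs the candidates' 0.09 / 0.18 at p = 50,
  k = 25, σ_obs = 0.3). The simulator evaluates the test risk analytically
  given the fitted weights (`(ŵ₁−1)² + σ²_ext Σ_{j>1} ŵ_j²`), removing one
  Monte-Carlo layer, and decomposes bias/variance *conditionally on the
  design matrix* — the decomposition the theory uses; a marginal split
  would mix design fluctuations into the variance and spuriously couple it
  to σ_ext.
- **HMM toy.** T = 2 bins, stationary teacher with emission probability
  `B*`; the stationary two-state student shares data across time bins
  (estimator variance `B*(1−B*)/2k`, entries perfectly correlated) while
  the time-indexed student splits it (variance `B*(1−B*)/k`,
  independent). Both estimators are unbiased. With the per-trial test
  log-likelihood summed over the two bins, the second-order expected
  deficits are `1/(2k)` and `1/k`. The exact expectation (binomial
  enumeration over all outcomes) additionally captures two finite-k
  effects the quadratic theory misses: O(1/k²) Taylor corrections, and
  boundary outcomes `B̂ ∈ {0,1}` whose clipped logarithms (clip 1e-6)
  dominate at small k — at k = 8 the time-indexed student's exact deficit
  is nearly double the asymptote. Leading coefficients are therefore
  extracted from simulations by Richardson extrapolation in 1/k over a
  doubling grid.
- **Prototype learning.** Classes at ±½ along the signal axis with M
  class-specific extraneous dimensions of scale σ_ext; prototypes are
  k-sample class means and classification is by the midpoint sign rule.
  The error is `H(SNR)` with the manifold SNR evaluated from the
  construction's geometry (centroid distance normalised by the manifold
  radius `R² = M σ²_ext`, participation ratio `D = M`, zero radius
  asymmetry and signal-noise overlaps), reducing to
  `SNR = ½√(k/M)/σ²_ext`. The radius is the *unnormalised* mean squared
  manifold radius: normalising per ambient dimension (an alternative
  convention) disagrees with direct simulation by a factor ~2M. The
  square-root reading of the SNR denominator is validated against
  simulation; the no-root reading is exposed for comparison and rejected.

## Experiment recipes and problem sizes

The bundled HMM study trains 18 students (M ∈ {4,5,6,8,10,12} × 3 seeds,
Adam, 500 iterations) on 300 train / 100 test trials of T = 10 bins from
the 4-cycle teacher (20 held-in / 8 held-out neurons), evaluates Q, ⟨Q_k⟩
at the `choose_k` recommendation, both ground-truth decoding directions,
the cross-decoding matrix among high-Q students (relative filter 0.8–0.9)
and cycle consistency, and reports Spearman correlations. These sizes run
the full study in well under a minute on one CPU while reproducing the
qualitative pattern stably: D_{S→T} tracks Q tightly; among high-Q
students, ⟨Q_k⟩ correlates negatively with D_{T→S}, and the column mean
and cycle consistency correlate positively with it. Likelihood-recovery
checks use the larger 2000-trial scale. The LGSSM study (12 students,
M ∈ {2,…,8}) reports test log-likelihood and 10-shot MSE and shows the
same asymmetry. Reruns under a fixed master seed are byte-identical; all
stage seeds are spawned from it.

## What the sandboxes do and do not show

The generators reproduce the features the metrics rely on — trial
structure, stochastic emissions, latent dynamics, partitioned neuron
populations — under exactly known ground truth, which is what makes the
student–teacher comparisons possible at all. They do not emulate
non-stationarity across trials, behavioural covariates or inputs,
heterogeneous firing-rate distributions, spike-sorting artefacts, or model
mismatch between student and teacher classes. Passing tests therefore
establish the correctness of the metrics and the within-model-class
discrimination phenomenon, not that any particular `k` or filter threshold
transfers to a given real dataset — `choose_k` must be re-run per dataset,
and the few-shot comparison is meaningful between models sharing a decoder
architecture.

## Known limitations

- Few-shot readouts cover linear–exponential–Poisson, closed-form
  Bernoulli-emission, and linear-Gaussian decoders; bespoke multi-layer
  decoders would need their own few-shot procedure and scores are not
  comparable across decoder families.
- Cross-decoding depends on the jury: column means are meaningful only
  within a population of models trained on the same data, and degrade when
  every jury member shares the same extraneous structure.
- The cycle-consistency degeneracy described above applies to any linear
  decoder with at least as many predicted rates as latent dimensions.
- HMM training is non-convex: likelihood recovery is asserted via the best
  of a few seeded restarts, and individual fits can land in poor optima.
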