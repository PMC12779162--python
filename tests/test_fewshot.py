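import numpy as np
import pytest

from latenteval.cosmoothing import cosmoothing_score
from latenteval.datamodel import PosteriorLatents, SpikeDataset
from latenteval.fewshot import (
    FewShotConfig,
    SilentNeuronError,
    choose_k,
    default_n_resamples,
    fewshot_cosmoothing,
    fit_fewshot_glm,
    fit_hmm_fewshot_emissions,
    sample_k_subsets,
)
from latenteval.hmm import predict_rates, smooth_dataset


def test_default_resampling_rule():
    # 5 * S_train / k, floored
    assert default_n_resamples(800, 2) == 2000
    assert default_n_resamples(800, 3, cap=2000) == 1333
    assert default_n_resamples(800, 2, cap=500) == 500


def test_sample_k_subsets_contract():
    ids = np.arange(10, 30)
    subs = sample_k_subsets(ids, k=4, s=50, seed=0)
    assert len(subs) == 50
    for sub in subs:
        assert len(np.unique(sub)) == 4 and np.isin(sub, ids).all()
    again = sample_k_subsets(ids, k=4, s=50, seed=0)
    assert all(np.array_equal(a, b) for a, b in zip(subs, again))
    # k equal to the pool size -> every subset is the full pool
    full = sample_k_subsets(ids, k=20, s=3, seed=1)
    assert all(np.array_equal(np.sort(sub), ids) for sub in full)
    with pytest.raises(ValueError):
        sample_k_subsets(ids, k=21, s=1, seed=0)


def test_glm_intercept_only_fits_mean(rng):
    # constant latent: predicted rate must equal the neuron's mean count
    Z = PosteriorLatents(np.ones((6, 4, 1)), kind="dense")
    counts = rng.poisson(1.3, size=(6, 4, 2))
    counts[0, 0] = [1, 1]  # ensure non-silent
    dec = fit_fewshot_glm(Z, counts, alpha=0.0)
    rates = dec.predict(Z).rates
    np.testing.assert_allclose(rates[0, 0], counts.reshape(-1, 2).mean(axis=0), rtol=1e-5)


def test_glm_parameter_recovery(rng):
    w_true, b_true = np.array([0.8, -0.5]), -0.3
    Z = rng.normal(size=(400, 1, 2))
    lam = np.exp(Z @ w_true + b_true)
    counts = rng.poisson(lam)[:, :, None]
    dec = fit_fewshot_glm(PosteriorLatents(Z, kind="dense"), counts, alpha=1e-8)
    np.testing.assert_allclose(dec.coef[0], w_true, atol=0.08)
    assert dec.intercept[0] == pytest.approx(b_true, abs=0.08)


def test_glm_large_alpha_shrinks_to_subset_mean(rng):
    Z = rng.normal(size=(20, 5, 3))
    counts = rng.poisson(0.8, size=(20, 5, 1))
    counts[0, 0, 0] = max(counts[0, 0, 0], 1)
    dec = fit_fewshot_glm(PosteriorLatents(Z, kind="dense"), counts, alpha=1e6)
    np.testing.assert_allclose(dec.coef, 0.0, atol=1e-4)
    rates = dec.predict(PosteriorLatents(Z, kind="dense")).rates
    np.testing.assert_allclose(rates.mean(), counts.mean(), rtol=1e-3)


def test_glm_silent_neuron_policy(rng):
    Z = PosteriorLatents(rng.normal(size=(3, 2, 1)), kind="dense")
    counts = np.zeros((3, 2, 1), dtype=int)
    with pytest.raises(SilentNeuronError):
        fit_fewshot_glm(Z, counts)
    dec = fit_fewshot_glm(Z, counts, silent_neurons="skip")
    assert dec.skipped == [0]


def test_emission_mle_t2_toy_closed_form():
    # 4 trials, T=2, one neuron: 3 spikes at t=1, 1 spike at t=2
    counts = np.zeros((4, 2, 1), dtype=int)
    counts[:3, 0, 0] = 1
    counts[0, 1, 0] = 1
    stationary = PosteriorLatents(np.full((4, 2, 2), 0.5), kind="simplex")
    est = fit_hmm_fewshot_emissions(stationary, counts)
    np.testing.assert_allclose(est.bhat, 0.5)  # 0.5*(3+1) / (0.5*4*2)
    one_hot = np.zeros((4, 2, 2))
    one_hot[:, 0, 0] = 1.0
    one_hot[:, 1, 1] = 1.0
    est2 = fit_hmm_fewshot_emissions(PosteriorLatents(one_hot, kind="simplex"), counts)
    np.testing.assert_allclose(est2.bhat[:, 0], [0.75, 0.25])


def test_emission_mle_matches_closed_form_for_any_counts(rng):
    # property: for arbitrary posteriors/counts the estimator equals the
    # explicit weighted-fraction formula
    xi = rng.dirichlet(np.ones(3), size=(5, 4))[None].repeat(6, axis=0)
    xi = PosteriorLatents(xi.reshape(6, -1, 3)[:, :4], kind="simplex")
    counts = rng.integers(0, 2, size=(6, 4, 2))
    est = fit_hmm_fewshot_emissions(xi, counts)
    W = xi.values.reshape(-1, 3)
    X = counts.reshape(-1, 2)
    expect = (W.T @ X) / W.sum(axis=0)[:, None]
    np.testing.assert_allclose(est.bhat, expect, atol=1e-12)


def test_emission_mle_unbiased(rng):
    # E[Bhat] = B* under the generative model, checked by averaging
    b_star = 0.4
    k, reps = 3, 4000
    est_s = np.empty(reps)
    est_m = np.empty((reps, 2))
    stationary = PosteriorLatents(np.full((k, 2, 2), 0.5), kind="simplex")
    one_hot = np.zeros((k, 2, 2))
    one_hot[:, 0, 0] = 1.0
    one_hot[:, 1, 1] = 1.0
    time_indexed = PosteriorLatents(one_hot, kind="simplex")
    for r in range(reps):
        counts = (rng.random((k, 2, 1)) < b_star).astype(int)
        est_s[r] = fit_hmm_fewshot_emissions(stationary, counts).bhat[0, 0]
        est_m[r] = fit_hmm_fewshot_emissions(time_indexed, counts).bhat[:, 0]
    assert est_s.mean() == pytest.approx(b_star, abs=0.02)
    np.testing.assert_allclose(est_m.mean(axis=0), b_star, atol=0.02)


def test_emission_mle_flags_zero_mass_state():
    xi = np.zeros((2, 2, 2))
    xi[:, :, 0] = 1.0
    est = fit_hmm_fewshot_emissions(
        PosteriorLatents(xi, kind="simplex"), np.ones((2, 2, 1), dtype=int)
    )
    assert list(est.undefined_states) == [1]


def test_fewshot_cosmoothing_end_to_end(small_hmm_dataset):
    teacher, ds, _ = small_hmm_dataset
    xi = smooth_dataset(teacher, ds)
    cfg = FewShotConfig(k=8, s=20, seed=0, decoder_kind="hmm_emission_mle",
                        silent_neurons="skip")
    report = fewshot_cosmoothing(xi, ds, cfg)
    assert report.qk_samples.shape == (20,)
    assert report.qk_mean == pytest.approx(report.qk_samples.mean())
    assert report.qk_sem == pytest.approx(
        report.qk_samples.std(ddof=1) / np.sqrt(20)
    )
    # large-k limit: decoder fitted on the whole train set reproduces q
    full = FewShotConfig(k=len(ds.train_trials), s=2, seed=0,
                         decoder_kind="hmm_emission_mle", silent_neurons="skip")
    rep_full = fewshot_cosmoothing(xi, ds, full)
    assert rep_full.qk_mean == pytest.approx(rep_full.q, abs=1e-9)
    # teacher-smoothed latents with the refit decoder beat the mean baseline
    assert rep_full.qk_mean > 0


def test_fewshot_variance_shrinks_with_k(small_hmm_dataset):
    teacher, ds, _ = small_hmm_dataset
    xi = smooth_dataset(teacher, ds)
    stds = []
    for k in (4, 40):
        cfg = FewShotConfig(k=k, s=30, seed=0, decoder_kind="hmm_emission_mle",
                            silent_neurons="skip")
        stds.append(fewshot_cosmoothing(xi, ds, cfg).qk_samples.std(ddof=1))
    assert stds[1] < stds[0]


def test_fewshot_single_resample_flagged(small_hmm_dataset):
    teacher, ds, _ = small_hmm_dataset
    xi = smooth_dataset(teacher, ds)
    cfg = FewShotConfig(k=10, s=1, seed=0, decoder_kind="hmm_emission_mle",
                        silent_neurons="skip")
    report = fewshot_cosmoothing(xi, ds, cfg)
    assert not report.sem_defined and report.qk_sem == 0.0


def test_choose_k_toy_frequency():
    # 2 train trials; one neuron spikes only in trial 0 -> half of all
    # 1-trial subsets are silent (exhaustive probability 0.5)
    spikes = np.zeros((3, 2, 2), dtype=np.int64)
    spikes[0, :, 1] = 1
    spikes[:, :, 0] = 1
    ds = SpikeDataset(
        spikes=spikes,
        neuron_partition=np.array([0, 1], dtype=np.int8),
        kout_indices=np.array([1]),
        trial_partition=np.array([0, 0, 1], dtype=np.int8),
    )
    res = choose_k(ds, [1, 2], n_probe_subsets=2000, seed=0)
    assert res.frequencies[1] == pytest.approx(0.5, abs=0.05)
    assert res.frequencies[2] == 0.0
    assert res.k_star == 2


def test_choose_k_frequencies_non_increasing(small_hmm_dataset):
    _, ds, _ = small_hmm_dataset
    res = choose_k(ds, [1, 2, 4, 8, 16], n_probe_subsets=300, seed=0)
    freqs = [res.frequencies[k] for k in sorted(res.frequencies)]
    assert all(a >= b - 0.05 for a, b in zip(freqs, freqs[1:]))


def test_config_validation():
    with pytest.raises(ValueError):
        FewShotConfig(k=0)
    with pytest.raises(ValueError):
        FewShotConfig(k=2, alpha=-1.0)
    with pytest.raises(ValueError):
        FewShotConfig(k=2, decoder_kind="mystery")
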