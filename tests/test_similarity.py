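import numpy as np
import pytest
from scipy.special import rel_entr

from latenteval.datamodel import PosteriorLatents, RatePredictions
from latenteval.similarity import (
    cross_decode_hmm,
    cross_decode_linear,
    cross_decode_matrix,
    cycle_consistency,
    filter_high_cosmoothing,
)

TRAIN = np.arange(30)
TEST = np.arange(30, 40)


def _dense(rng, D, S=40, T=5):
    return PosteriorLatents(rng.normal(size=(S, T, D)), kind="dense")


def test_affine_target_is_fully_decodable(rng):
    Zu = _dense(rng, 3)
    W = rng.normal(size=(3, 2))
    Zv = PosteriorLatents(Zu.values @ W + 1.5, kind="dense")
    assert cross_decode_linear(Zu, Zv, TRAIN, TEST) == pytest.approx(0.0, abs=1e-10)


def test_self_decoding_is_zero(rng):
    Z = _dense(rng, 4)
    assert cross_decode_linear(Z, Z, TRAIN, TEST) == pytest.approx(0.0, abs=1e-6)


def test_independent_latents_are_undecodable(rng):
    Zu = _dense(rng, 3, S=200, T=10)
    Zv = _dense(rng, 3, S=200, T=10)
    D = cross_decode_linear(Zu, Zv, np.arange(150), np.arange(150, 200))
    assert D == pytest.approx(1.0, abs=0.05)


def test_nested_latents_realisable(rng):
    Zu = _dense(rng, 5)
    Zv = PosteriorLatents(Zu.values[:, :, :2], kind="dense")  # coordinates subset
    assert cross_decode_linear(Zu, Zv, TRAIN, TEST) == pytest.approx(0.0, abs=1e-10)


def test_invariance_to_affine_source_reparameterisation(rng):
    Zu = _dense(rng, 3)
    Zv = _dense(rng, 2)
    A = rng.normal(size=(3, 3)) + 3 * np.eye(3)  # invertible
    Zu2 = PosteriorLatents(Zu.values @ A + 0.7, kind="dense")
    d1 = cross_decode_linear(Zu, Zv, TRAIN, TEST)
    d2 = cross_decode_linear(Zu2, Zv, TRAIN, TEST)
    assert d1 == pytest.approx(d2, abs=1e-8)


def test_constant_target_dimension_flagged_as_zero_r2(rng):
    Zu = _dense(rng, 2)
    v = rng.normal(size=(40, 5, 2))
    v[:, :, 1] = 3.0  # constant dimension
    Zv = PosteriorLatents(v, kind="dense")
    D = cross_decode_linear(Zu, Zv, TRAIN, TEST)
    # dim 0 decodable ~0%, dim 1 scored R^2 = 0 -> D about 1 - (0 + 0)/2
    assert 0.4 < D < 1.1


def test_hmm_self_decoding_near_deterministic(rng):
    # near-one-hot posteriors: decoding a model from itself is near perfect
    states = rng.integers(0, 3, size=(40, 6))
    xi = np.full((40, 6, 3), 0.005)
    np.put_along_axis(xi, states[:, :, None], 0.99, axis=2)
    Z = PosteriorLatents(xi, kind="simplex")
    # weak regularisation so the classifier can match the sharp posteriors
    D = cross_decode_hmm(Z, Z, TRAIN, TEST, C=100.0, seed=0)
    assert D < 0.05


def test_hmm_uninformative_source_matches_marginal_oracle(rng):
    # constant source posteriors: the classifier can do no better than the
    # marginal of the target; D must approach mean KL(marginal || xi_v)
    S, T = 300, 4
    xi_u = PosteriorLatents(np.full((S, T, 2), 0.5), kind="simplex")
    p = rng.dirichlet(np.ones(3), size=(S, T))
    xi_v = PosteriorLatents(p, kind="simplex")
    train, test = np.arange(250), np.arange(250, S)
    D = cross_decode_hmm(xi_u, xi_v, train, test, seed=0)
    marginal = p[train].reshape(-1, 3).mean(axis=0)
    oracle = rel_entr(marginal[None, :], p[test].reshape(-1, 3)).sum(axis=1).mean()
    assert D == pytest.approx(oracle, rel=0.15)


def test_hmm_single_state_target_is_handled():
    xi_u = PosteriorLatents(np.random.default_rng(0).dirichlet([1, 1], size=(40, 5)), kind="simplex")
    xi_v = PosteriorLatents(np.ones((40, 5, 1)), kind="simplex")
    D = cross_decode_hmm(xi_u, xi_v, TRAIN, TEST, seed=0)
    assert np.isfinite(D) and D == pytest.approx(0.0, abs=1e-6)


def test_matrix_asymmetry_for_augmented_model(rng):
    S, T, D0 = 80, 5, 2
    base = rng.normal(size=(S, T, D0))
    noise = rng.normal(size=(S, T, 3))
    teacher = PosteriorLatents(base, kind="dense")
    augmented = PosteriorLatents(np.concatenate([base, noise], axis=2), kind="dense")
    other = PosteriorLatents(base @ rng.normal(size=(D0, D0)) + 0.2, kind="dense")
    train, test = np.arange(60), np.arange(60, 80)
    mat = cross_decode_matrix([teacher, augmented, other], train, test,
                              model_ids=["teacher", "augmented", "other"])
    d = {(u, v): mat.D[i, j] for i, u in enumerate(mat.model_ids)
         for j, v in enumerate(mat.model_ids)}
    # the augmented model decodes the teacher, not vice versa
    assert d[("augmented", "teacher")] == pytest.approx(0.0, abs=1e-8)
    assert d[("teacher", "augmented")] > 0.3
    # column-mean proxy ranks the minimal model better than the augmented one
    col = dict(zip(mat.model_ids, mat.column_means))
    assert col["teacher"] < col["augmented"]


def test_matrix_of_identical_models_is_zero(rng):
    Z = _dense(rng, 3)
    mat = cross_decode_matrix([Z, Z, Z], TRAIN, TEST)
    assert np.abs(mat.D).max() < 1e-8


def test_cycle_consistency_affine_latents(rng):
    R = RatePredictions(rng.uniform(0.1, 2.0, size=(40, 5, 6)))
    Z = PosteriorLatents(R.rates @ rng.normal(size=(6, 3)) - 0.4, kind="dense")
    assert cycle_consistency(R, Z, TRAIN, TEST) == pytest.approx(0.0, abs=1e-9)


def test_cycle_consistency_noise_dimension_analytic(rng):
    # one latent coordinate of pure noise: uniform-average R^2 loses exactly
    # that coordinate, so D ~ 1 / D_z
    S, T = 400, 5
    R = RatePredictions(rng.uniform(0.1, 2.0, size=(S, T, 6)))
    D_z = 4
    Z = np.concatenate(
        [R.rates @ rng.normal(size=(6, D_z - 1)), rng.normal(size=(S, T, 1))], axis=2
    )
    train, test = np.arange(300), np.arange(300, S)
    D = cycle_consistency(R, PosteriorLatents(Z, kind="dense"), train, test)
    assert D == pytest.approx(1.0 / D_z, abs=0.05)


def test_variance_weighted_aggregation_option(rng):
    Zu = _dense(rng, 3)
    v = rng.normal(size=(40, 5, 2))
    v[:, :, 0] = Zu.values @ rng.normal(size=3)  # decodable, high variance
    v[:, :, 1] = 0.01 * rng.normal(size=(40, 5))  # undecodable, tiny variance
    Zv = PosteriorLatents(v, kind="dense")
    d_uniform = cross_decode_linear(Zu, Zv, TRAIN, TEST, aggregate="uniform")
    d_weighted = cross_decode_linear(Zu, Zv, TRAIN, TEST, aggregate="variance_weighted")
    # weighting by variance discounts the tiny undecodable dimension
    assert d_weighted < d_uniform


def test_filter_rules():
    scores = {"a": 0.30, "b": 0.25, "c": 0.20}
    assert set(filter_high_cosmoothing(scores, {"relative": 0.8})) == {"a", "b"}
    assert set(filter_high_cosmoothing(scores, {"absolute": 0.034})) == {"a", "b", "c"}
    assert filter_high_cosmoothing({"a": 0.01}, {"absolute": 0.034}) == []
    with pytest.raises(ValueError):
        filter_high_cosmoothing(scores, {"quantile": 0.5})
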