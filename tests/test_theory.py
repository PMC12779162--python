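import numpy as np
import pytest

import _oracles
from latenteval.theory import (
    BCPLSetting,
    HMMToySetting,
    LRSetting,
    SingularRegimeError,
    bcpl_predict,
    gauss_tail,
    hmm_toy_expected_loss,
    lr_risk_limit,
    simulate_bcpl,
    simulate_hmm_toy,
    simulate_lr_risk,
    toy_estimator_moments,
)

# ---------------------------------------------------------------------------
# ridgeless least squares


def test_lr_limit_underparameterised_values():
    # gamma = 0.5, sigma_obs = 0.3 -> risk = 0.09, independent of sigma_ext
    for se in (0.0, 0.5, 10.0):
        out = lr_risk_limit(LRSetting(p=50, k=100, sigma_obs=0.3, sigma_ext=se))
        assert out["risk"] == pytest.approx(0.09)
        assert out["bias"] == 0.0
    # gamma -> 0 limit
    tiny = lr_risk_limit(LRSetting(p=2, k=10_000, sigma_obs=0.3, sigma_ext=1.0))
    assert tiny["risk"] < 1e-4


def test_lr_limit_overparameterised_bias():
    out = lr_risk_limit(LRSetting(p=50, k=25, sigma_obs=0.3, sigma_ext=1e6))
    g = 2.0
    assert out["bias"] == pytest.approx(g / (g - 1.0), rel=1e-4)
    assert out["variance_printed"] == pytest.approx(0.18)
    assert out["variance_substituted"] == pytest.approx(0.09)


def test_lr_limit_singular_regime():
    with pytest.raises(SingularRegimeError):
        lr_risk_limit(LRSetting(p=50, k=50, sigma_obs=0.3, sigma_ext=1.0))


def test_lr_sim_noiseless_scalar_is_exact():
    out = simulate_lr_risk(p=1, k=1, sigma_obs=0.0, sigma_ext=5.0, reps=10, seed=0)
    assert out["risk_mean"] == pytest.approx(0.0, abs=1e-20)


def test_minnorm_solution_matches_pinv_closed_form(rng):
    for _ in range(5):
        k, p = int(rng.integers(3, 12)), int(rng.integers(3, 12))
        Z = rng.normal(size=(k, p))
        y = rng.normal(size=k)
        w_lstsq = np.linalg.lstsq(Z, y, rcond=None)[0]
        np.testing.assert_allclose(w_lstsq, _oracles.minnorm_lstsq_by_pinv(Z, y), atol=1e-9)


def test_lr_double_descent_peak_near_interpolation():
    risks = {}
    for k in (100, 55, 25):
        risks[k] = simulate_lr_risk(50, k, 0.3, 1.0, reps=200, seed=k)["risk_mean"]
    # risk peaks near gamma = 1 (k ~ p = 50) and falls on both sides
    assert risks[55] > risks[100]
    assert risks[55] > risks[25]


def test_lr_sim_classical_ols_limits():
    # isotropic features (sigma_ext = 1), gamma < 1: the exact finite-sample
    # Gaussian-design OLS excess risk is sigma^2 p/(k-p-1)
    p, k = 20, 100
    out = simulate_lr_risk(p=p, k=k, sigma_obs=0.5, sigma_ext=1.0, reps=400, seed=3)
    exact = 0.25 * p / (k - p - 1)
    assert abs(out["risk_mean"] - exact) < 4 * out["risk_sem"]
    # sigma_ext = 0: the extraneous columns vanish, the problem is effectively
    # one-dimensional and the excess risk collapses to sigma^2/(k-2)
    out0 = simulate_lr_risk(p=p, k=k, sigma_obs=0.5, sigma_ext=0.0, reps=400, seed=3)
    assert abs(out0["risk_mean"] - 0.25 / (k - 2)) < 4 * out0["risk_sem"]


# ---------------------------------------------------------------------------
# HMM toy


def test_toy_estimator_moments():
    s = toy_estimator_moments(HMMToySetting(b_star=0.3, k=10, student="stationary_xi"))
    np.testing.assert_allclose(s["mean"], 0.3)
    np.testing.assert_allclose(s["cov"], 0.3 * 0.7 / 20 * np.ones((2, 2)))
    m = toy_estimator_moments(HMMToySetting(b_star=0.3, k=10, student="time_indexed_mu"))
    np.testing.assert_allclose(m["cov"], 0.3 * 0.7 / 10 * np.eye(2))


@pytest.mark.parametrize("student", ["stationary_xi", "time_indexed_mu"])
@pytest.mark.parametrize("k", [1, 3, 7, 20])
def test_toy_exact_loss_matches_outcome_enumeration(student, k, rng):
    # oracle: enumerate all (C1, C2) outcomes directly
    b = 0.37
    setting = HMMToySetting(b_star=b, k=k, student=student)
    out = hmm_toy_expected_loss(setting)
    from scipy.stats import binom
    from latenteval.theory import _toy_loss_term

    total = 0.0
    for c1 in range(k + 1):
        for c2 in range(k + 1):
            pr = binom.pmf(c1, k, b) * binom.pmf(c2, k, b)
            if student == "stationary_xi":
                bhat = (c1 + c2) / (2 * k)
                total += pr * 2 * _toy_loss_term(np.array(bhat), b)
            else:
                total += pr * (
                    _toy_loss_term(np.array(c1 / k), b)
                    + _toy_loss_term(np.array(c2 / k), b)
                )
    assert out["exact_expected_loss"] == pytest.approx(float(total), abs=1e-12)


def test_toy_simulation_agrees_with_exact_sum():
    for student in ("stationary_xi", "time_indexed_mu"):
        s = HMMToySetting(b_star=0.5, k=16, student=student)
        exact = hmm_toy_expected_loss(s)["exact_expected_loss"]
        sim = simulate_hmm_toy(s, reps=20_000, seed=0)
        assert abs(sim["loss_mean"] - exact) < 4 * sim["loss_sem"]


def test_toy_stationary_student_always_wins():
    # lower estimator variance -> higher expected test log-likelihood
    for k in (2, 8, 32, 128):
        good = hmm_toy_expected_loss(HMMToySetting(0.5, k, "stationary_xi"))
        bad = hmm_toy_expected_loss(HMMToySetting(0.5, k, "time_indexed_mu"))
        assert good["exact_expected_loss"] > bad["exact_expected_loss"]


def test_toy_gap_vanishes_at_large_k():
    k = 5000
    good = hmm_toy_expected_loss(HMMToySetting(0.5, k, "stationary_xi"))
    bad = hmm_toy_expected_loss(HMMToySetting(0.5, k, "time_indexed_mu"))
    L = good["loss_at_truth"]
    assert abs(good["exact_expected_loss"] - L) < 1e-3
    assert abs(bad["exact_expected_loss"] - L) < 1e-3


def test_toy_deficit_ratio_approaches_two():
    for k in (64, 256):
        good = hmm_toy_expected_loss(HMMToySetting(0.5, k, "stationary_xi"))
        bad = hmm_toy_expected_loss(HMMToySetting(0.5, k, "time_indexed_mu"))
        ratio = bad["exact_deficit"] / good["exact_deficit"]
        assert ratio == pytest.approx(2.0, rel=0.08)


# ---------------------------------------------------------------------------
# prototype learning


def test_bcpl_chance_level_and_monotonicity():
    assert gauss_tail(0.0) == pytest.approx(0.5)
    errs_k = [bcpl_predict(BCPLSetting(M=10, k=k, sigma_ext=1.0))["error"] for k in (1, 4, 16, 64)]
    assert all(a > b for a, b in zip(errs_k, errs_k[1:]))  # decreasing in k
    errs_s = [bcpl_predict(BCPLSetting(M=10, k=8, sigma_ext=s))["error"] for s in (0.5, 1.0, 2.0)]
    assert all(a < b for a, b in zip(errs_s, errs_s[1:]))  # increasing in noise


def test_bcpl_zero_noise_is_perfect():
    assert bcpl_predict(BCPLSetting(M=5, k=1, sigma_ext=0.0))["error"] == 0.0
    sim = simulate_bcpl(BCPLSetting(M=5, k=1, sigma_ext=0.0), reps=50, seed=0)
    assert sim["error_mean"] == 0.0


def test_bcpl_simulation_matches_prediction():
    for M, k, se in ((10, 10, 1.0), (5, 20, 1.5)):
        pred = bcpl_predict(BCPLSetting(M=M, k=k, sigma_ext=se))["error"]
        sim = simulate_bcpl(BCPLSetting(M=M, k=k, sigma_ext=se), reps=1500, seed=1)
        assert sim["error_mean"] == pytest.approx(pred, abs=0.04)


def test_bcpl_sqrt_denominator_reading_beats_plain():
    s = BCPLSetting(M=10, k=10, sigma_ext=1.0)
    sim = simulate_bcpl(s, reps=3000, seed=2)["error_mean"]
    err_sqrt = bcpl_predict(s, denominator="sqrt")["error"]
    err_plain = bcpl_predict(s, denominator="plain")["error"]
    assert abs(err_sqrt - sim) < abs(err_plain - sim)


def test_bcpl_gap_vanishes_at_large_k():
    small = simulate_bcpl(BCPLSetting(M=10, k=2, sigma_ext=1.0), reps=1000, seed=0)
    large = simulate_bcpl(BCPLSetting(M=10, k=500, sigma_ext=1.0), reps=300, seed=0)
    assert small["error_mean"] > 0.2
    assert large["error_mean"] < 0.02
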