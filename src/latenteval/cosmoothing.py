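"""Co-smoothing: normalised Poisson log-likelihood of held-out activity.

The score compares a model's predicted rates ``R`` for a set of target
neurons against the data, relative to a constant mean-rate baseline
``r̄_n``, in bits per spike::

    Q = sum_n [ L(R_n; X_n) - L(r̄_n; X_n) ] / (ln 2 * sum_n mu_n)

where ``L`` is the Poisson log-likelihood with the ``log x!`` term omitted
(it cancels in the difference) and ``mu_n`` is neuron *n*'s total spike
count over the evaluated trials and bins.  The normalisation pools all
neurons into a single division by the total spike count — the "bits per
spike" convention of the neural-latents benchmark; a per-neuron variant is
kept as a diagnostic.  With the baseline mean computed on the evaluation
trials themselves, a predictor that outputs each neuron's mean rate
everywhere scores exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import RATE_FLOOR, RatePredictions, SpikeDataset

__all__ = [
    "UndefinedScoreError",
    "CosmoothingScore",
    "poisson_loglik",
    "mean_rates",
    "cosmoothing_score",
    "mean_rate_predictions",
]

LN2 = float(np.log(2.0))


class UndefinedScoreError(ValueError):
    """All target neurons silent: the bits-per-spike score is undefined."""


@dataclass
class CosmoothingScore:
    """Co-smoothing result.

    ``q_total`` is the pooled bits-per-spike score; ``per_neuron`` holds the
    per-neuron diagnostic (each neuron's log-likelihood gain divided by its
    own spike count), NaN for silent neurons excluded from the pooled score.
    """

    q_total: float
    per_neuron: np.ndarray
    n_spikes_total: int


def poisson_loglik(rates: np.ndarray | RatePredictions, counts: np.ndarray) -> float:
    """Poisson log-likelihood ``sum(x log r - r)`` in nats.

    The ``log x!`` term is omitted; it is independent of the rates and
    cancels wherever two likelihoods of the same counts are compared.
    """
    r = rates.rates if isinstance(rates, RatePredictions) else np.asarray(rates, dtype=float)
    x = np.asarray(counts)
    if r.shape != x.shape:
        raise ValueError(f"shape mismatch: rates {r.shape} vs counts {x.shape}")
    r = np.maximum(r, RATE_FLOOR)
    return float(np.sum(x * np.log(r) - r))


def mean_rates(ds: SpikeDataset, trials: np.ndarray, neurons: np.ndarray) -> np.ndarray:
    """Mean count per bin, ``r̄_n``, over the given trials for each neuron."""
    trials = np.asarray(trials)
    neurons = np.asarray(neurons)
    if trials.size == 0 or neurons.size == 0:
        raise ValueError("trial and neuron subsets must be non-empty")
    return ds.spikes[np.ix_(trials, np.arange(ds.n_bins), neurons)].mean(axis=(0, 1))


def mean_rate_predictions(
    ds: SpikeDataset, trials: np.ndarray, neurons: np.ndarray
) -> RatePredictions:
    """The baseline predictor: each neuron's mean rate at every bin."""
    rbar = mean_rates(ds, trials, neurons)
    S, T = len(trials), ds.n_bins
    return RatePredictions(np.broadcast_to(rbar, (S, T, len(rbar))).copy())


def cosmoothing_score(
    rates: RatePredictions | np.ndarray,
    ds: SpikeDataset,
    eval_trials: np.ndarray | None = None,
    target_neurons: np.ndarray | None = None,
    baseline_trials: np.ndarray | None = None,
    normalisation: str = "pooled",
) -> CosmoothingScore:
    """Score rate predictions for ``target_neurons`` on ``eval_trials``.

    Defaults evaluate the held-out neurons on the test trials.  The
    mean-rate baseline is computed on the evaluation trials unless
    ``baseline_trials`` overrides it (e.g. with the train set).  Neurons
    with zero spikes in the evaluation set are excluded from both the
    numerator and the normalisation; if every neuron is silent the score is
    undefined and an error is raised.
    """
    if eval_trials is None:
        eval_trials = ds.test_trials
    if target_neurons is None:
        target_neurons = ds.held_out_indices
    eval_trials = np.asarray(eval_trials)
    target_neurons = np.asarray(target_neurons)
    r = rates.rates if isinstance(rates, RatePredictions) else np.asarray(rates, dtype=float)
    x = ds.spikes[np.ix_(eval_trials, np.arange(ds.n_bins), target_neurons)]
    if r.shape != x.shape:
        raise ValueError(f"rates shape {r.shape} does not cover evaluation block {x.shape}")
    r = np.maximum(r, RATE_FLOOR)

    rbar = mean_rates(ds, baseline_trials if baseline_trials is not None else eval_trials, target_neurons)
    rbar = np.maximum(rbar, RATE_FLOOR)

    # per-neuron log-likelihood difference, nats
    ll_model = np.sum(x * np.log(r) - r, axis=(0, 1))
    ll_base = np.sum(x * np.log(rbar)[None, None, :] - rbar[None, None, :], axis=(0, 1))
    delta = ll_model - ll_base
    mu = x.sum(axis=(0, 1))

    active = mu > 0
    if not active.any():
        raise UndefinedScoreError("every target neuron is silent on the evaluation trials")

    per_neuron = np.full(len(target_neurons), np.nan)
    per_neuron[active] = delta[active] / (LN2 * mu[active])

    if normalisation == "pooled":
        q = float(delta[active].sum() / (LN2 * mu[active].sum()))
    elif normalisation == "per_neuron":
        q = float(np.mean(per_neuron[active]))
    else:
        raise ValueError(f"unknown normalisation {normalisation!r}")
    return CosmoothingScore(q_total=q, per_neuron=per_neuron, n_spikes_total=int(mu.sum()))
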