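"""Bernoulli-emission HMM teacher/student machinery.

The sandbox models binary spike trains with a discrete latent chain: a
transition matrix ``A`` (M x M, row-stochastic), an emission matrix ``B``
(``B[m, n] = p(x_n = 1 | z = m)``) and an initial distribution ``pi``.  The
teacher of interest is a noisy M-cycle: ``A[m, l] ∝ 1[l = (m+1) mod M] + eps``
with uniform ``pi`` and i.i.d. Uniform(0,1) emissions, frozen by seed.

Smoothing — the posterior state distribution ``xi[t, m] = p(z_t = m | X)``
given the held-in neurons of a whole trial — is computed exactly with the
scaled forward-backward recursion, and held-out rates follow by mixing
emission rows: ``R[t, n] = sum_m B[m, n] xi[t, m]``.

Students are trained by maximum likelihood on the train trials, either by
full-batch first-order ascent (closed-form score gradients through
softmax/sigmoid parameterisations, Adam updates) or by EM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    HELD_IN,
    HELD_OUT,
    PosteriorLatents,
    RatePredictions,
    SpikeDataset,
    ValidationError,
)

__all__ = [
    "HMMParams",
    "TrafficGraph",
    "make_cycle_teacher",
    "sample_hmm",
    "make_hmm_dataset",
    "loglik",
    "smooth",
    "smooth_dataset",
    "predict_rates",
    "fit_hmm",
    "traffic_graph",
]

_STOCH_TOL = 1e-10


@dataclass
class HMMParams:
    """Transition matrix ``A``, Bernoulli emissions ``B``, initial ``pi``."""

    A: np.ndarray
    B: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        M = self.pi.shape[0]
        if self.A.shape != (M, M):
            raise ValidationError("A must be M x M")
        if self.B.ndim != 2 or self.B.shape[0] != M:
            raise ValidationError("B must be M x N")
        if np.abs(self.A.sum(axis=1) - 1.0).max() > _STOCH_TOL or self.A.min() < 0:
            raise ValidationError("rows of A must be probability vectors")
        if abs(self.pi.sum() - 1.0) > _STOCH_TOL or self.pi.min() < 0:
            raise ValidationError("pi must be a probability vector")
        if self.B.min() < 0 or self.B.max() > 1:
            raise ValidationError("B entries must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return self.pi.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.B.shape[1]


@dataclass
class TrafficGraph:
    """State/transition visitation fractions under ancestral sampling."""

    node_mass: np.ndarray
    edge_mass: np.ndarray
    prune_threshold: float
    pruned: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.pruned = self.edge_mass < self.prune_threshold


def make_cycle_teacher(
    M: int = 4, n_neurons: int = 70, eps: float = 1e-2, seed: int = 0
) -> HMMParams:
    """Noisy M-cycle teacher: on-cycle weight ``(1+eps)``, ``eps`` elsewhere.

    Rows are normalised to ``(1 + eps) / (1 + M eps)`` on the cycle successor
    and ``eps / (1 + M eps)`` off it; ``pi`` is uniform and ``B`` is sampled
    i.i.d. Uniform(0, 1) once, frozen by ``seed``.
    """
    if M < 2:
        raise ValueError("need at least two states")
    if eps <= 0:
        raise ValueError("eps must be > 0")
    A = np.full((M, M), eps)
    A[np.arange(M), (np.arange(M) + 1) % M] += 1.0
    A /= A.sum(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    B = rng.uniform(0.0, 1.0, size=(M, n_neurons))
    return HMMParams(A=A, B=B, pi=np.full(M, 1.0 / M))


def sample_hmm(
    params: HMMParams, S: int, T: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral sampling: binary observations ``(S,T,N)`` and states ``(S,T)``."""
    rng = np.random.default_rng(seed)
    M = params.n_states
    states = np.empty((S, T), dtype=np.int64)
    states[:, 0] = rng.choice(M, size=S, p=params.pi)
    cum = np.cumsum(params.A, axis=1)
    for t in range(1, T):
        u = rng.random(S)
        states[:, t] = (u[:, None] > cum[states[:, t - 1]]).sum(axis=1)
    x = (rng.random((S, T, params.n_neurons)) < params.B[states]).astype(np.int64)
    return x, states


def make_hmm_dataset(
    params: HMMParams,
    s_train: int,
    s_test: int,
    T: int,
    n_out: int,
    seed: int,
) -> tuple[SpikeDataset, np.ndarray]:
    """Sample a partitioned dataset in one call (k-out = held-out)."""
    ss = np.random.SeedSequence(seed)
    sample_seed, part_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    S = s_train + s_test
    x, states = sample_hmm(params, S, T, sample_seed)
    rng = np.random.default_rng(part_seed)
    out = np.sort(rng.choice(params.n_neurons, size=n_out, replace=False))
    labels = np.full(params.n_neurons, HELD_IN, dtype=np.int8)
    labels[out] = HELD_OUT
    trial_labels = np.r_[np.zeros(s_train, dtype=np.int8), np.ones(s_test, dtype=np.int8)]
    ds = SpikeDataset(
        spikes=x,
        neuron_partition=labels,
        kout_indices=out,
        trial_partition=trial_labels,
        seed=seed,
    )
    return ds, states


# ---------------------------------------------------------------------------
# exact inference

_B_CLIP = 1e-300


def _log_emission(params: HMMParams, x: np.ndarray, neurons: np.ndarray) -> np.ndarray:
    """log p(x_t | z_t = m) for every (trial, t, m); x is (S,T,len(neurons))."""
    B = params.B[:, neurons]
    logB = np.log(np.clip(B, _B_CLIP, None))
    log1mB = np.log(np.clip(1.0 - B, _B_CLIP, None))
    # (S,T,N) x (M,N) -> (S,T,M)
    return x @ logB.T + (1 - x) @ log1mB.T


def _forward_backward(
    params: HMMParams, logem: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward-backward, vectorised over trials.

    Returns ``(gamma, trans_counts, loglik, alpha_hat)`` where ``gamma`` is
    the (S,T,M) posterior, ``trans_counts`` the (M,M) expected transition
    counts summed over trials and time, and ``loglik`` the per-trial data
    log-likelihood.  Raises on a zero-likelihood observation.
    """
    S, T, M = logem.shape
    A = params.A
    shift = logem.max(axis=2, keepdims=True)
    em = np.exp(logem - shift)  # scaled emission likelihoods, max 1 per (i,t)

    alpha = np.empty((S, T, M))
    logc = np.empty((S, T))
    a = params.pi[None, :] * em[:, 0]
    c = a.sum(axis=1)
    if np.any(c <= 0.0):
        i = int(np.argmax(c <= 0.0))
        raise FloatingPointError(f"zero-likelihood observation at trial {i}, bin 0")
    alpha[:, 0] = a / c[:, None]
    logc[:, 0] = np.log(c)
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * em[:, t]
        c = a.sum(axis=1)
        if np.any(c <= 0.0):
            i = int(np.argmax(c <= 0.0))
            raise FloatingPointError(f"zero-likelihood observation at trial {i}, bin {t}")
        alpha[:, t] = a / c[:, None]
        logc[:, t] = np.log(c)

    beta = np.empty((S, T, M))
    beta[:, T - 1] = 1.0
    gamma = np.empty((S, T, M))
    gamma[:, T - 1] = alpha[:, T - 1]
    trans = np.zeros((M, M))
    for t in range(T - 2, -1, -1):
        w = em[:, t + 1] * beta[:, t + 1]  # (S,M)
        # pairwise posteriors for expected transition counts
        pair = alpha[:, t, :, None] * A[None] * w[:, None, :]
        norm = pair.sum(axis=(1, 2), keepdims=True)
        trans += (pair / norm).sum(axis=0)
        b = w @ A.T
        beta[:, t] = b / b.max(axis=1, keepdims=True)  # rescale; gamma normalised below
        g = alpha[:, t] * beta[:, t]
        gamma[:, t] = g / g.sum(axis=1, keepdims=True)

    loglik = logc.sum(axis=1) + shift.sum(axis=(1, 2))
    return gamma, trans, loglik, alpha


def loglik(
    params: HMMParams, x: np.ndarray, neurons: np.ndarray | None = None
) -> np.ndarray:
    """Per-trial log-likelihood of binary observations ``x`` (S,T,len(neurons))."""
    if neurons is None:
        neurons = np.arange(params.n_neurons)
    logem = _log_emission(params, np.asarray(x), np.asarray(neurons))
    _, _, ll, _ = _forward_backward(params, logem)
    return ll


def smooth(
    params: HMMParams, x: np.ndarray, neurons: np.ndarray | None = None
) -> PosteriorLatents:
    """Exact posterior state marginals ``xi[t, m] = p(z_t = m | X)``.

    ``x`` holds binary observations for the given neuron indices
    (default: all neurons of the model), shape ``(S, T, len(neurons))``.
    """
    if neurons is None:
        neurons = np.arange(params.n_neurons)
    x = np.asarray(x)
    logem = _log_emission(params, x, np.asarray(neurons))
    gamma, _, _, _ = _forward_backward(params, logem)
    return PosteriorLatents(values=gamma, kind="simplex")


def smooth_dataset(params: HMMParams, ds: SpikeDataset) -> PosteriorLatents:
    """Smooth every trial of a dataset from its held-in neurons."""
    hin = ds.held_in_indices
    return smooth(params, ds.spikes[:, :, hin], hin)


def predict_rates(
    params: HMMParams, xi: PosteriorLatents, target_neurons: np.ndarray
) -> RatePredictions:
    """Posterior-mixed emission probabilities ``R = xi @ B[:, targets]``."""
    if xi.kind != "simplex":
        raise ValueError("HMM rate prediction needs simplex latents")
    return RatePredictions(xi.values @ params.B[:, np.asarray(target_neurons)])


# ---------------------------------------------------------------------------
# training


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def fit_hmm(
    x: np.ndarray,
    M: int,
    algorithm: str = "adam",
    lr: float = 1e-2,
    n_iter: int = 2000,
    seed: int = 0,
    tol: float = 0.0,
) -> tuple[HMMParams, np.ndarray]:
    """Maximum-likelihood HMM fit to binary observations ``x`` (S,T,N).

    ``algorithm='adam'`` (default): full-batch ascent on the log-likelihood
    with closed-form gradients — expected-count statistics from
    forward-backward pushed through softmax rows (``A``, ``pi``) and a
    sigmoid (``B``) — and Adam updates.  ``algorithm='em'``: Baum-Welch with
    exact M-steps (monotone by construction).  Returns the parameters and
    the per-iteration negative log-likelihood trace (total over trials).
    """
    x = np.asarray(x)
    if not np.isin(x, [0, 1]).all():
        raise ValueError("Bernoulli HMM requires binary observations")
    S, T, N = x.shape
    rng = np.random.default_rng(seed)
    neurons = np.arange(N)

    if algorithm == "em":
        # init: perturbed-uniform A/pi, emissions around the data mean
        A = _softmax(rng.normal(scale=0.1, size=(M, M)))
        pi = _softmax(rng.normal(scale=0.1, size=M))
        mean = x.mean(axis=(0, 1))
        B = np.clip(mean[None, :] + rng.normal(scale=0.08, size=(M, N)), 0.02, 0.98)
        trace = np.empty(n_iter)
        for it in range(n_iter):
            params = HMMParams(A=A, B=B, pi=pi)
            logem = _log_emission(params, x, neurons)
            gamma, trans, ll, _ = _forward_backward(params, logem)
            trace[it] = -ll.sum()
            if not np.isfinite(trace[it]):
                raise FloatingPointError(f"EM diverged at iteration {it}")
            pi = gamma[:, 0].sum(axis=0)
            pi /= pi.sum()
            A = trans / np.maximum(trans.sum(axis=1, keepdims=True), 1e-300)
            occ = gamma.sum(axis=(0, 1))  # (M,)
            num = np.einsum("stm,stn->mn", gamma, x)
            B = np.clip(num / np.maximum(occ[:, None], 1e-300), 0.0, 1.0)
            if it > 0 and tol > 0 and trace[it - 1] - trace[it] < tol:
                trace = trace[: it + 1]
                break
        return HMMParams(A=A, B=B, pi=pi), trace

    if algorithm != "adam":
        raise ValueError(f"unknown algorithm {algorithm!r}")

    # unconstrained parameterisation
    thA = rng.normal(scale=0.1, size=(M, M))
    thpi = rng.normal(scale=0.1, size=M)
    mean = np.clip(x.mean(axis=(0, 1)), 1e-3, 1 - 1e-3)
    thB = np.log(mean / (1 - mean))[None, :] + rng.normal(scale=0.3, size=(M, N))

    mom = {k: 0.0 for k in ("A", "pi", "B")}
    vel = {k: 0.0 for k in ("A", "pi", "B")}
    b1, b2, eps_ = 0.9, 0.999, 1e-8
    trace = np.empty(n_iter)
    for it in range(n_iter):
        A = _softmax(thA)
        pi = _softmax(thpi)
        B = 1.0 / (1.0 + np.exp(-thB))
        params = HMMParams(A=A, B=B, pi=pi)
        logem = _log_emission(params, x, neurons)
        gamma, trans, ll, _ = _forward_backward(params, logem)
        trace[it] = -ll.sum()
        if not np.isfinite(trace[it]):
            raise FloatingPointError(f"gradient training diverged at iteration {it}")
        # closed-form score gradients through the reparameterisations
        gpi = gamma[:, 0].sum(axis=0) - S * pi
        gA = trans - trans.sum(axis=1, keepdims=True) * A
        occ = gamma.sum(axis=(0, 1))
        gB = np.einsum("stm,stn->mn", gamma, x) - occ[:, None] * B
        for key, th, g in (("A", thA, gA), ("pi", thpi, gpi), ("B", thB, gB)):
            mom[key] = b1 * mom[key] + (1 - b1) * g
            vel[key] = b2 * vel[key] + (1 - b2) * g * g
            mhat = mom[key] / (1 - b1 ** (it + 1))
            vhat = vel[key] / (1 - b2 ** (it + 1))
            th += lr * mhat / (np.sqrt(vhat) + eps_)  # ascent
    A = _softmax(thA)
    pi = _softmax(thpi)
    B = 1.0 / (1.0 + np.exp(-thB))
    return HMMParams(A=A, B=B, pi=pi), trace


def traffic_graph(
    params: HMMParams,
    S: int,
    T: int,
    seed: int,
    prune_threshold: float = 0.01,
) -> TrafficGraph:
    """Visitation fractions of states and ordered transitions after sampling."""
    _, states = sample_hmm(params, S, T, seed)
    M = params.n_states
    node = np.bincount(states.ravel(), minlength=M).astype(float)
    node /= node.sum()
    pairs = states[:, :-1] * M + states[:, 1:]
    edge = np.bincount(pairs.ravel(), minlength=M * M).astype(float).reshape(M, M)
    edge /= edge.sum()
    return TrafficGraph(node_mass=node, edge_mass=edge, prune_threshold=prune_threshold)
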