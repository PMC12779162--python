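"""Ground-truth-free proxies for extraneous latent structure.

Given a population of models that all predict held-out activity well, the
latents of each ordered pair are *cross-decoded*: a map is fitted from model
*u*'s latents to model *v*'s on train trials and its error ``D_{u->v}``
evaluated on test trials.  A model whose latents everyone can decode
(small column mean ``<D_{u->v}>_u``) carries little structure beyond what
the data demand; one that others cannot decode carries extraneous
structure.  Dense latents use an affine least-squares map and
``D = 1 - R^2`` (R-squared averaged uniformly over target dimensions);
simplex latents (HMM posteriors) use a softmax-linear classifier trained on
states sampled from the target posteriors, with ``D`` the mean KL
divergence from predicted to target distributions.

*Cycle consistency* applies the same regression from a model's own rate
predictions back to its latents: latent structure that its predictions
cannot explain is extraneous by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr
from sklearn.linear_model import LogisticRegression

from .datamodel import PosteriorLatents, RatePredictions

__all__ = [
    "CrossDecodeMatrix",
    "affine_r2",
    "cross_decode_linear",
    "cross_decode_hmm",
    "cross_decode_matrix",
    "cycle_consistency",
    "filter_high_cosmoothing",
]

KL_CLIP = 1e-12


@dataclass
class CrossDecodeMatrix:
    """Pairwise decoding errors with the column-mean extraneousness proxy."""

    D: np.ndarray
    column_means: np.ndarray
    model_ids: list

    def __post_init__(self) -> None:
        U = self.D.shape[0]
        if self.D.shape != (U, U) or len(self.model_ids) != U:
            raise ValueError("inconsistent matrix/model-id shapes")


def _flatten(values: np.ndarray, trials: np.ndarray) -> np.ndarray:
    v = values[np.asarray(trials)]
    return v.reshape(-1, v.shape[2])


def affine_r2(
    Z_train: np.ndarray,
    Y_train: np.ndarray,
    Z_test: np.ndarray,
    Y_test: np.ndarray,
    aggregate: str = "uniform",
) -> tuple[float, np.ndarray]:
    """Affine least-squares fit and aggregate test R-squared.

    ``aggregate='uniform'`` averages R-squared uniformly over target
    dimensions (the default used by every metric here);
    ``'variance_weighted'`` weights by each dimension's test variance.
    Target dimensions that are constant on the test trials have undefined
    R-squared; they are scored 0 and their indices returned as flags.
    """
    A = np.concatenate([Z_train, np.ones((len(Z_train), 1))], axis=1)
    # relative singular-value cutoff: near-collinear features (e.g. rates of
    # rank-deficient models) would otherwise blow up the out-of-sample error
    W = np.linalg.lstsq(A, Y_train, rcond=1e-10)[0]
    pred = np.concatenate([Z_test, np.ones((len(Z_test), 1))], axis=1) @ W
    sse = ((Y_test - pred) ** 2).sum(axis=0)
    sst = ((Y_test - Y_test.mean(axis=0)) ** 2).sum(axis=0)
    degenerate = np.flatnonzero(sst == 0)
    r2 = np.zeros(Y_test.shape[1])
    ok = sst > 0
    r2[ok] = 1.0 - sse[ok] / sst[ok]
    if aggregate == "uniform":
        agg = float(r2.mean())
    elif aggregate == "variance_weighted":
        agg = float(np.average(r2[ok], weights=sst[ok])) if ok.any() else 0.0
    else:
        raise ValueError(f"unknown aggregation {aggregate!r}")
    return agg, degenerate


def cross_decode_linear(
    Z_u: PosteriorLatents,
    Z_v: PosteriorLatents,
    train_trials: np.ndarray,
    test_trials: np.ndarray,
    aggregate: str = "uniform",
) -> float:
    """``D_{u->v} = 1 - R^2`` of an affine map u-latents -> v-latents."""
    if Z_u.n_trials != Z_v.n_trials:
        raise ValueError("latent trial axes must match")
    r2, _ = affine_r2(
        _flatten(Z_u.values, train_trials),
        _flatten(Z_v.values, train_trials),
        _flatten(Z_u.values, test_trials),
        _flatten(Z_v.values, test_trials),
        aggregate=aggregate,
    )
    return 1.0 - r2


def cross_decode_hmm(
    xi_u: PosteriorLatents,
    xi_v: PosteriorLatents,
    train_trials: np.ndarray,
    test_trials: np.ndarray,
    n_state_samples: int = 1,
    C: float = 1.0,
    seed: int = 0,
    direction: str = "pred_to_target",
) -> float:
    """Mean-KL decoding error between HMM posterior latents.

    Target states are sampled from ``xi_v`` per (trial, time) on the train
    split, a softmax-linear (multinomial logistic) classifier is fitted from
    ``xi_u``, and the error is the average of
    ``KL(p_t || xi_v,t)`` over test samples (``direction='target_to_pred'``
    swaps the arguments).  Both distributions are clipped at ``1e-12``
    before the elementwise relative entropy.
    """
    if xi_u.kind != "simplex" or xi_v.kind != "simplex":
        raise ValueError("HMM cross-decoding needs simplex latents")
    rng = np.random.default_rng(seed)
    Zu_tr = _flatten(xi_u.values, train_trials)
    Pv_tr = _flatten(xi_v.values, train_trials)
    Zu_te = _flatten(xi_u.values, test_trials)
    Pv_te = _flatten(xi_v.values, test_trials)
    Mv = Pv_tr.shape[1]

    # sample discrete targets from the posterior PMFs
    reps = max(1, int(n_state_samples))
    X = np.tile(Zu_tr, (reps, 1))
    P = np.tile(Pv_tr, (reps, 1))
    cum = P.cumsum(axis=1)
    y = (rng.random(len(P))[:, None] > cum).sum(axis=1)

    classes = np.unique(y)
    if len(classes) == 1:
        proba = np.full((len(Zu_te), Mv), KL_CLIP)
        proba[:, classes[0]] = 1.0
    else:
        clf = LogisticRegression(C=C, max_iter=1000)
        clf.fit(X, y)
        proba = np.full((len(Zu_te), Mv), 0.0)
        proba[:, clf.classes_] = clf.predict_proba(Zu_te)

    p = np.clip(proba, KL_CLIP, None)
    q = np.clip(Pv_te, KL_CLIP, None)
    if direction == "pred_to_target":
        kl = rel_entr(p, q).sum(axis=1)
    elif direction == "target_to_pred":
        kl = rel_entr(q, p).sum(axis=1)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(kl.mean())


def cross_decode_matrix(
    models: list[PosteriorLatents],
    train_trials: np.ndarray,
    test_trials: np.ndarray,
    model_ids: list | None = None,
    **hmm_opts,
) -> CrossDecodeMatrix:
    """All ordered pairwise decoding errors for a population of models.

    Simplex-vs-simplex pairs use the multinomial/KL decoder, everything
    else the affine/R-squared decoder.  Column means exclude the diagonal
    (self-decoding is trivially ~0 and would bias the proxy).
    """
    U = len(models)
    if U < 2:
        raise ValueError("need at least two models")
    if model_ids is None:
        model_ids = list(range(U))
    D = np.zeros((U, U))
    for u in range(U):
        for v in range(U):
            if u == v:
                continue
            if models[u].kind == "simplex" and models[v].kind == "simplex":
                D[u, v] = cross_decode_hmm(models[u], models[v], train_trials, test_trials, **hmm_opts)
            else:
                D[u, v] = cross_decode_linear(models[u], models[v], train_trials, test_trials)
    off = ~np.eye(U, dtype=bool)
    col = np.array([D[off[:, v], v].mean() for v in range(U)])
    return CrossDecodeMatrix(D=D, column_means=col, model_ids=list(model_ids))


def cycle_consistency(
    rates: RatePredictions | np.ndarray,
    latents: PosteriorLatents,
    train_trials: np.ndarray,
    test_trials: np.ndarray,
) -> float:
    """``D_{r->z} = 1 - R^2`` of an affine map from a model's own held-out
    rate predictions back to its latents.

    ``rates`` must cover every trial of ``latents`` so that the map can be
    fitted on train trials and evaluated on test trials.
    """
    r = rates.rates if isinstance(rates, RatePredictions) else np.asarray(rates, dtype=float)
    if r.shape[0] != latents.n_trials:
        raise ValueError("rates must cover the same trials as the latents")
    r2, _ = affine_r2(
        _flatten(r, train_trials),
        _flatten(latents.values, train_trials),
        _flatten(r, test_trials),
        _flatten(latents.values, test_trials),
    )
    return 1.0 - r2


def filter_high_cosmoothing(
    scores: dict,
    rule: dict,
) -> list:
    """Select the model ids whose co-smoothing passes the filter rule.

    ``rule`` is either ``{'absolute': q_min}`` (keep ``Q > q_min``) or
    ``{'relative': f}`` (keep ``Q > f * max(Q)``).  An empty selection is
    allowed; callers should treat it as a flag.
    """
    if len(scores) == 0:
        raise ValueError("need at least one score")
    if set(rule) == {"absolute"}:
        cut = float(rule["absolute"])
    elif set(rule) == {"relative"}:
        cut = float(rule["relative"]) * max(scores.values())
    else:
        raise ValueError("rule must be {'absolute': q} or {'relative': f}")
    return [m for m, q in scores.items() if q > cut]
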