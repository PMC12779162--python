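"""Linear-Gaussian state-space sandbox: sampling, exact smoothing, EM fitting.

Model::

    z_0 ~ N(mu0, Sigma0)
    z_t ~ N(F z_{t-1} + b, G)
    x_t ~ N(H z_t + c, R)

Latents are inferred with the Kalman filter / Rauch-Tung-Striebel smoother;
the per-trial log-likelihood comes from the filter's prediction-error
decomposition.  Because the model is time-invariant and trials share the
same length, all covariance recursions are data-independent and computed
once per time step, so the per-trial work is a small matrix-vector pass.

Students are fitted by EM with exact closed-form M-steps; the negative
log-likelihood trace is monotone non-increasing up to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import PosteriorLatents, ValidationError

__all__ = [
    "LGSSMParams",
    "make_random_teacher",
    "sample_lgssm",
    "kalman_filter_loglik",
    "kalman_smooth",
    "fit_lgssm",
    "fewshot_linear_readout",
]


def _check_psd(mat: np.ndarray, name: str, tol: float = 1e-8) -> None:
    if not np.allclose(mat, mat.T, atol=tol):
        raise ValidationError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -tol:
        raise ValidationError(f"{name} must be positive semi-definite")


@dataclass
class LGSSMParams:
    mu0: np.ndarray
    Sigma0: np.ndarray
    F: np.ndarray
    b: np.ndarray
    G: np.ndarray
    H: np.ndarray
    c: np.ndarray
    Rcov: np.ndarray

    def __post_init__(self) -> None:
        for name in ("mu0", "Sigma0", "F", "b", "G", "H", "c", "Rcov"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        M = self.mu0.shape[0]
        N = self.c.shape[0]
        if self.F.shape != (M, M) or self.G.shape != (M, M) or self.Sigma0.shape != (M, M):
            raise ValidationError("dynamics matrices must be M x M")
        if self.H.shape != (N, M) or self.Rcov.shape != (N, N):
            raise ValidationError("emission shapes inconsistent")
        for mat, name in ((self.Sigma0, "Sigma0"), (self.G, "G"), (self.Rcov, "Rcov")):
            _check_psd(mat, name)

    @property
    def n_states(self) -> int:
        return self.mu0.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.c.shape[0]


def make_random_teacher(M: int = 4, n_neurons: int = 35, seed: int = 0) -> LGSSMParams:
    """A random stable teacher: rotation-like dynamics, dense Gaussian readout.

    ``F`` is a random orthogonal matrix scaled to spectral radius 0.9 (stable
    but slowly mixing), process noise ``G = 0.1 I``, emissions
    ``H ~ N(0, 1/M)`` with observation noise ``R = 0.5 I``.
    """
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(M, M)))
    F = 0.9 * q
    H = rng.normal(scale=1.0 / np.sqrt(M), size=(n_neurons, M))
    return LGSSMParams(
        mu0=np.zeros(M),
        Sigma0=np.eye(M),
        F=F,
        b=np.zeros(M),
        G=0.1 * np.eye(M),
        H=H,
        c=np.zeros(n_neurons),
        Rcov=0.5 * np.eye(n_neurons),
    )


def sample_lgssm(
    params: LGSSMParams, S: int, T: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral Gaussian sampling -> observations (S,T,N) and latents (S,T,M)."""
    rng = np.random.default_rng(seed)
    M, N = params.n_states, params.n_neurons
    L0 = np.linalg.cholesky(params.Sigma0 + 1e-12 * np.eye(M))
    LG = np.linalg.cholesky(params.G + 1e-12 * np.eye(M))
    LR = np.linalg.cholesky(params.Rcov + 1e-12 * np.eye(N))
    z = np.empty((S, T, M))
    z[:, 0] = params.mu0 + rng.normal(size=(S, M)) @ L0.T
    for t in range(1, T):
        z[:, t] = z[:, t - 1] @ params.F.T + params.b + rng.normal(size=(S, M)) @ LG.T
    x = z @ params.H.T + params.c + rng.normal(size=(S, T, N)) @ LR.T
    return x, z


# ---------------------------------------------------------------------------
# exact inference


def _filter_pass(params: LGSSMParams, x: np.ndarray, H: np.ndarray, c: np.ndarray, Rcov: np.ndarray):
    """Shared-covariance Kalman filter over all trials at once."""
    S, T, _ = x.shape
    M = params.n_states
    F, b, G = params.F, params.b, params.G
    m_pred = np.empty((S, T, M))
    m_filt = np.empty((S, T, M))
    P_pred = np.empty((T, M, M))
    P_filt = np.empty((T, M, M))
    ll = np.zeros(S)
    mp = np.broadcast_to(params.mu0, (S, M)).copy()
    Pp = params.Sigma0.copy()
    for t in range(T):
        m_pred[:, t] = mp
        P_pred[t] = Pp
        Sm = H @ Pp @ H.T + Rcov
        Sm = 0.5 * (Sm + Sm.T)
        cho = np.linalg.cholesky(Sm + 1e-12 * np.eye(Sm.shape[0]))
        innov = x[:, t] - mp @ H.T - c
        sol = np.linalg.solve(cho, innov.T)  # (N,S)
        ll -= 0.5 * np.sum(sol**2, axis=0)
        ll -= np.log(np.diag(cho)).sum() + 0.5 * Sm.shape[0] * np.log(2 * np.pi)
        K = Pp @ H.T @ np.linalg.inv(Sm)
        mf = mp + innov @ K.T
        Pf = Pp - K @ H @ Pp
        Pf = 0.5 * (Pf + Pf.T)
        m_filt[:, t] = mf
        P_filt[t] = Pf
        mp = mf @ F.T + b
        Pp = F @ Pf @ F.T + G
        Pp = 0.5 * (Pp + Pp.T)
    return m_pred, P_pred, m_filt, P_filt, ll


def kalman_filter_loglik(
    params: LGSSMParams, x: np.ndarray, neurons: np.ndarray | None = None
) -> np.ndarray:
    """Per-trial log-likelihood via the prediction-error decomposition."""
    H, c, Rcov = _emission_subset(params, neurons)
    return _filter_pass(params, np.asarray(x, dtype=float), H, c, Rcov)[4]


def _emission_subset(params: LGSSMParams, neurons: np.ndarray | None):
    if neurons is None:
        return params.H, params.c, params.Rcov
    idx = np.asarray(neurons)
    return params.H[idx], params.c[idx], params.Rcov[np.ix_(idx, idx)]


def kalman_smooth(
    params: LGSSMParams,
    x: np.ndarray,
    neurons: np.ndarray | None = None,
    return_covs: bool = False,
):
    """RTS smoother: posterior means ``E[z_t | x_{1:T}]`` as dense latents.

    With ``return_covs=True`` also returns the (time-indexed, trial-shared)
    smoothed covariances, the lag-one covariances ``Cov(z_{t+1}, z_t | X)``
    and the per-trial log-likelihood — the sufficient statistics EM needs.
    """
    x = np.asarray(x, dtype=float)
    H, c, Rcov = _emission_subset(params, neurons)
    m_pred, P_pred, m_filt, P_filt, ll = _filter_pass(params, x, H, c, Rcov)
    S, T, _ = x.shape
    M = params.n_states
    F = params.F
    m_sm = np.empty((S, T, M))
    P_sm = np.empty((T, M, M))
    P_lag = np.empty((T - 1, M, M)) if T > 1 else np.empty((0, M, M))
    m_sm[:, T - 1] = m_filt[:, T - 1]
    P_sm[T - 1] = P_filt[T - 1]
    for t in range(T - 2, -1, -1):
        J = P_filt[t] @ F.T @ np.linalg.inv(P_pred[t + 1])
        m_sm[:, t] = m_filt[:, t] + (m_sm[:, t + 1] - m_pred[:, t + 1]) @ J.T
        P_sm[t] = P_filt[t] + J @ (P_sm[t + 1] - P_pred[t + 1]) @ J.T
        P_sm[t] = 0.5 * (P_sm[t] + P_sm[t].T)
        P_lag[t] = P_sm[t + 1] @ J.T  # Cov(z_{t+1}, z_t | X)
    latents = PosteriorLatents(values=m_sm, kind="dense")
    if return_covs:
        return latents, P_sm, P_lag, ll
    return latents


# ---------------------------------------------------------------------------
# EM training


def fit_lgssm(
    x: np.ndarray,
    M: int,
    n_iter: int = 100,
    seed: int = 0,
    diag_r: bool = False,
) -> tuple[LGSSMParams, np.ndarray]:
    """EM fit of an M-dimensional LGSSM to observations ``x`` (S,T,N).

    Initialisation projects the data onto its top-M principal components for
    ``H`` and perturbs the dynamics around a damped identity.  Returns the
    fitted parameters and the per-iteration total negative log-likelihood
    trace (non-increasing up to round-off).
    """
    x = np.asarray(x, dtype=float)
    S, T, N = x.shape
    rng = np.random.default_rng(seed)

    flat = x.reshape(-1, N)
    c = flat.mean(axis=0)
    xc = flat - c
    # PCA init for the readout
    _, sv, vt = np.linalg.svd(xc, full_matrices=False)
    comps = vt[:M]
    scale = sv[:M] / np.sqrt(len(flat))
    H = (comps.T * scale) + rng.normal(scale=0.05, size=(N, M))
    resid_var = np.maximum(xc.var(axis=0) - (H**2).sum(axis=1), 0.05)
    params = LGSSMParams(
        mu0=np.zeros(M),
        Sigma0=np.eye(M),
        F=0.8 * np.eye(M) + rng.normal(scale=0.05, size=(M, M)),
        b=np.zeros(M),
        G=0.2 * np.eye(M),
        H=H,
        c=c,
        Rcov=np.diag(resid_var),
    )

    jitter = 1e-9
    trace = np.empty(n_iter)
    for it in range(n_iter):
        latents, P_sm, P_lag, ll = kalman_smooth(params, x, return_covs=True)
        trace[it] = -ll.sum()
        if not np.isfinite(trace[it]):
            raise FloatingPointError(f"EM diverged at iteration {it}")
        m = latents.values  # (S,T,M)

        # sufficient statistics; covariances are trial-shared
        Ezz_t = np.einsum("stm,stl->tml", m, m) / S + P_sm  # E[z_t z_t^T], per t, /S later
        Ezz_t = Ezz_t  # (T,M,M) already trial-averaged in first term
        Ezz_lag = (
            np.einsum("stm,stl->tml", m[:, 1:], m[:, :-1]) / S + P_lag
            if T > 1
            else np.empty((0, M, M))
        )

        # initial state
        mu0 = m[:, 0].mean(axis=0)
        d0 = m[:, 0] - mu0
        Sigma0 = d0.T @ d0 / S + P_sm[0]
        Sigma0 = 0.5 * (Sigma0 + Sigma0.T) + jitter * np.eye(M)

        if T > 1:
            # dynamics: regress [z_{t-1}, 1] -> z_t using expected moments
            Szz_prev = Ezz_t[:-1].sum(axis=0)  # sum_t E[z_{t-1} z_{t-1}^T]
            Szz_cross = Ezz_lag.sum(axis=0)  # sum_t E[z_t z_{t-1}^T]
            sum_prev = m[:, :-1].mean(axis=0).sum(axis=0)  # sum_t E[z_{t-1}]
            sum_next = m[:, 1:].mean(axis=0).sum(axis=0)
            n_dyn = T - 1
            Amat = np.block(
                [[Szz_prev, sum_prev[:, None]], [sum_prev[None, :], np.array([[n_dyn]])]]
            )
            Bmat = np.concatenate([Szz_cross, sum_next[:, None]], axis=1)
            sol = np.linalg.solve(Amat + jitter * np.eye(M + 1), Bmat.T).T
            F, b = sol[:, :M], sol[:, M]
            Szz_next = Ezz_t[1:].sum(axis=0)
            G = (
                Szz_next
                - F @ Szz_cross.T
                - Szz_cross @ F.T
                - np.outer(b, sum_next)
                - np.outer(sum_next, b)
                + F @ Szz_prev @ F.T
                + F @ np.outer(sum_prev, b)
                + np.outer(b, sum_prev) @ F.T
                + n_dyn * np.outer(b, b)
            ) / n_dyn
            G = 0.5 * (G + G.T) + jitter * np.eye(M)
        else:
            F, b, G = params.F, params.b, params.G

        # emissions: regress [z_t, 1] -> x_t with expected moments
        Szz = Ezz_t.sum(axis=0)  # sum over t of E[z z^T], trial-averaged
        Sz = m.mean(axis=0).sum(axis=0)
        Sxz = np.einsum("stn,stm->nm", x, m) / S
        Sx = x.mean(axis=0).sum(axis=0)
        Amat = np.block([[Szz, Sz[:, None]], [Sz[None, :], np.array([[float(T)]])]])
        Bmat = np.concatenate([Sxz, Sx[:, None]], axis=1)
        sol = np.linalg.solve(Amat + jitter * np.eye(M + 1), Bmat.T).T
        Hn, cn = sol[:, :M], sol[:, M]
        Sxx = np.einsum("stn,stl->nl", x, x) / S
        Rn = (
            Sxx
            - Hn @ Sxz.T
            - Sxz @ Hn.T
            - np.outer(cn, Sx)
            - np.outer(Sx, cn)
            + Hn @ Szz @ Hn.T
            + Hn @ np.outer(Sz, cn)
            + np.outer(cn, Sz) @ Hn.T
            + T * np.outer(cn, cn)
        ) / T
        Rn = 0.5 * (Rn + Rn.T) + jitter * np.eye(N)
        if diag_r:
            Rn = np.diag(np.diag(Rn))

        params = LGSSMParams(
            mu0=mu0, Sigma0=Sigma0, F=F, b=b, G=G, H=Hn, c=cn, Rcov=Rn
        )
    return params, trace


# ---------------------------------------------------------------------------
# few-shot linear readout


def fewshot_linear_readout(
    latents: PosteriorLatents,
    targets: np.ndarray,
    train_trials: np.ndarray,
    test_trials: np.ndarray,
    k: int,
    s: int,
    seed: int,
) -> dict:
    """k-shot ordinary-least-squares readout from latents to targets.

    For each of ``s`` independently resampled k-trial subsets of
    ``train_trials``, fits an affine map from latents to the target signals
    (min-norm solution when under-determined) and records the mean squared
    error on ``test_trials``.  Returns the per-resample MSEs with their mean
    and standard error.
    """
    from .fewshot import sample_k_subsets  # local import, avoids cycle

    targets = np.asarray(targets, dtype=float)
    Z = latents.values
    subsets = sample_k_subsets(np.asarray(train_trials), k, s, seed)
    Zte = Z[np.asarray(test_trials)].reshape(-1, Z.shape[2])
    Xte = targets[np.asarray(test_trials)].reshape(-1, targets.shape[2])
    ones_te = np.ones((len(Zte), 1))
    mses = np.empty(len(subsets))
    for j, sub in enumerate(subsets):
        Ztr = Z[sub].reshape(-1, Z.shape[2])
        Xtr = targets[sub].reshape(-1, targets.shape[2])
        A = np.concatenate([Ztr, np.ones((len(Ztr), 1))], axis=1)
        W = np.linalg.lstsq(A, Xtr, rcond=None)[0]
        pred = np.concatenate([Zte, ones_te], axis=1) @ W
        mses[j] = np.mean((pred - Xte) ** 2)
    sem = float(mses.std(ddof=1) / np.sqrt(len(mses))) if len(mses) > 1 else 0.0
    return {
        "mse_samples": mses,
        "mse_mean": float(mses.mean()),
        "mse_sem": sem,
        "k": k,
        "s": len(subsets),
    }
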