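"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a quantity by a method unrelated to the package's
implementation path: exhaustive path enumeration for HMM smoothing, dense
joint-Gaussian conditioning for the RTS smoother, and the pseudoinverse
closed form for minimum-norm least squares.
"""

from itertools import product

import numpy as np


def hmm_posterior_by_enumeration(A, B, pi, x):
    """p(z_t = m | x) by summing over all M^T state paths. x is (T, N) binary."""
    A, B, pi, x = (np.asarray(a, dtype=float) for a in (A, B, pi, x))
    M = len(pi)
    T = x.shape[0]
    post = np.zeros((T, M))
    total = 0.0
    for path in product(range(M), repeat=T):
        pr = pi[path[0]]
        for t in range(1, T):
            pr *= A[path[t - 1], path[t]]
        for t in range(T):
            pr *= np.prod(B[path[t]] ** x[t] * (1 - B[path[t]]) ** (1 - x[t]))
        total += pr
        for t in range(T):
            post[t, path[t]] += pr
    return post / total


def lgssm_smoothed_means_by_joint_gaussian(params, x):
    """E[z_t | x_{1:T}] by conditioning the stacked joint Gaussian. x is (S,T,N)."""
    M = params.n_states
    S, T, _ = x.shape
    mz = np.empty((T, M))
    mz[0] = params.mu0
    for t in range(1, T):
        mz[t] = params.F @ mz[t - 1] + params.b
    Czz = np.empty((T, T, M, M))
    Czz[0, 0] = params.Sigma0
    for t in range(1, T):
        Czz[t, t] = params.F @ Czz[t - 1, t - 1] @ params.F.T + params.G
    for t in range(T):
        for u in range(t + 1, T):
            Czz[t, u] = Czz[t, t] @ np.linalg.matrix_power(params.F, u - t).T
            Czz[u, t] = Czz[t, u].T
    Z = Czz.transpose(0, 2, 1, 3).reshape(T * M, T * M)
    Hbig = np.kron(np.eye(T), params.H)
    Rbig = np.kron(np.eye(T), params.Rcov)
    mx = (mz @ params.H.T + params.c).ravel()
    Cxx = Hbig @ Z @ Hbig.T + Rbig
    K = Z @ Hbig.T @ np.linalg.inv(Cxx)
    out = np.empty((S, T, M))
    for i in range(S):
        out[i] = (mz.ravel() + K @ (x[i].ravel() - mx)).reshape(T, M)
    return out


def minnorm_lstsq_by_pinv(Z, y):
    """Minimum-l2-norm least-squares solution via the Moore-Penrose inverse."""
    return np.linalg.pinv(Z) @ y


def random_hmm(rng, M, N):
    A = rng.dirichlet(np.ones(M), size=M)
    pi = rng.dirichlet(np.ones(M))
    B = rng.random((M, N))
    return A, B, pi


def random_lgssm(rng, M, N):
    from latenteval.lgssm import LGSSMParams

    q, _ = np.linalg.qr(rng.normal(size=(M, M)))
    G0 = rng.normal(size=(M, M))
    R0 = rng.normal(size=(N, N))
    return LGSSMParams(
        mu0=rng.normal(size=M),
        Sigma0=np.eye(M),
        F=0.8 * q,
        b=0.1 * rng.normal(size=M),
        G=G0 @ G0.T / M + 0.1 * np.eye(M),
        H=rng.normal(size=(N, M)),
        c=rng.normal(size=N),
        Rcov=R0 @ R0.T / N + 0.1 * np.eye(N),
    )
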