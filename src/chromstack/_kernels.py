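"""Low-level scaled forward/backward and Viterbi recursions.

Written as plain nested loops so they compile under numba's nopython mode;
if numba is unavailable the pure-Python definitions are used unchanged
(slow but identical).  All recursions use per-bin scaling factors rather
than log-space arithmetic; the contract is agreement with exhaustive path
enumeration, which the test suite checks directly.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def forward_scaled(pi, A, B):
    """Scaled forward pass.

    B is the (T, K) matrix of per-bin state likelihoods (any positive
    rescaling per row is permitted by the caller provided it corrects the
    returned log-likelihood).  Returns (alpha_hat, scale, loglik).
    """
    T, K = B.shape
    alpha = np.empty((T, K))
    scale = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[0, k]
        s += alpha[0, k]
    scale[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += alpha[t - 1, i] * A[i, j]
            alpha[t, j] = acc * B[t, j]
            s += alpha[t, j]
        scale[t] = s
        for j in range(K):
            alpha[t, j] /= s
    loglik = 0.0
    for t in range(T):
        loglik += np.log(scale[t])
    return alpha, scale, loglik


@njit(cache=True)
def backward_scaled(A, B, scale):
    T, K = B.shape
    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(K):
            acc = 0.0
            for j in range(K):
                acc += A[i, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc / scale[t + 1]
    return beta


@njit(cache=True)
def expected_transitions(alpha, beta, A, B, scale):
    """Sum over t of the posterior transition matrix xi_t (unnormalized
    numerators already normalized by the scaled recursions)."""
    T, K = B.shape
    xi = np.zeros((K, K))
    for t in range(T - 1):
        for i in range(K):
            for j in range(K):
                xi[i, j] += alpha[t, i] * A[i, j] * B[t + 1, j] * beta[t + 1, j] / scale[t + 1]
    return xi


@njit(cache=True)
def viterbi_path(log_pi, log_A, logB):
    """Maximum-probability state path; ties resolved to the lowest index."""
    T, K = logB.shape
    delta = np.empty((T, K))
    back = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_pi[k] + logB[0, k]
    for t in range(1, T):
        for j in range(K):
            best = delta[t - 1, 0] + log_A[0, j]
            arg = 0
            for i in range(1, K):
                v = delta[t - 1, i] + log_A[i, j]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = i
            delta[t, j] = best + logB[t, j]
            back[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path
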