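"""Scaled HMM recursions for two states, JIT-compiled when numba is present.

All kernels take per-fish arrays: initial distribution (d0, d1), per-step
switching probabilities psi12 (state 1 -> 2) and psi21 (state 2 -> 1), and
the emission likelihood matrix b of shape (T, 2). The transition matrix
indexed t-1 (covariates at the previous step) governs the move into step t.
"""

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _jit(func):
        return _njit(cache=True)(func)

except Exception:  # pragma: no cover - numba always present in practice

    def _jit(func):
        return func


_TINY = 1e-300


def _forward_ll(d0, d1, psi12, psi21, b):
    T = b.shape[0]
    a0 = d0 * b[0, 0]
    a1 = d1 * b[0, 1]
    c = a0 + a1
    if c <= 0.0:
        return -np.inf
    ll = np.log(c)
    a0 /= c
    a1 /= c
    for t in range(1, T):
        p12 = psi12[t - 1]
        p21 = psi21[t - 1]
        n0 = (a0 * (1.0 - p12) + a1 * p21) * b[t, 0]
        n1 = (a0 * p12 + a1 * (1.0 - p21)) * b[t, 1]
        c = n0 + n1
        if c <= 0.0:
            return -np.inf
        ll += np.log(c)
        a0 = n0 / c
        a1 = n1 / c
    return ll


def _forward_alphas(d0, d1, psi12, psi21, b):
    """Normalized forward probabilities alpha-hat (T, 2) and log-likelihood."""
    T = b.shape[0]
    alpha = np.zeros((T, 2))
    a0 = d0 * b[0, 0]
    a1 = d1 * b[0, 1]
    c = a0 + a1
    ll = np.log(c) if c > 0.0 else -np.inf
    if c <= 0.0:
        c = _TINY
    alpha[0, 0] = a0 / c
    alpha[0, 1] = a1 / c
    for t in range(1, T):
        p12 = psi12[t - 1]
        p21 = psi21[t - 1]
        n0 = (alpha[t - 1, 0] * (1.0 - p12) + alpha[t - 1, 1] * p21) * b[t, 0]
        n1 = (alpha[t - 1, 0] * p12 + alpha[t - 1, 1] * (1.0 - p21)) * b[t, 1]
        c = n0 + n1
        if c > 0.0:
            ll += np.log(c)
        else:
            ll = -np.inf
            c = _TINY
        alpha[t, 0] = n0 / c
        alpha[t, 1] = n1 / c
    return alpha, ll


def _backward_betas(psi12, psi21, b):
    """Rescaled backward probabilities (T, 2); each row normalized to sum 1."""
    T = b.shape[0]
    beta = np.zeros((T, 2))
    beta[T - 1, 0] = 0.5
    beta[T - 1, 1] = 0.5
    for t in range(T - 2, -1, -1):
        p12 = psi12[t]
        p21 = psi21[t]
        e0 = b[t + 1, 0] * beta[t + 1, 0]
        e1 = b[t + 1, 1] * beta[t + 1, 1]
        n0 = (1.0 - p12) * e0 + p12 * e1
        n1 = p21 * e0 + (1.0 - p21) * e1
        c = n0 + n1
        if c <= 0.0:
            c = _TINY
        beta[t, 0] = n0 / c
        beta[t, 1] = n1 / c
    return beta


def _viterbi_path(d0, d1, psi12, psi21, b):
    """Most probable state path (0-based); ties prefer state index 0."""
    T = b.shape[0]
    back = np.zeros((T, 2), dtype=np.int64)
    v0 = np.log(max(d0 * b[0, 0], _TINY))
    v1 = np.log(max(d1 * b[0, 1], _TINY))
    for t in range(1, T):
        p12 = psi12[t - 1]
        p21 = psi21[t - 1]
        l11 = np.log(max(1.0 - p12, _TINY))
        l12 = np.log(max(p12, _TINY))
        l21 = np.log(max(p21, _TINY))
        l22 = np.log(max(1.0 - p21, _TINY))
        c00 = v0 + l11
        c10 = v1 + l21
        if c00 >= c10:
            n0 = c00
            back[t, 0] = 0
        else:
            n0 = c10
            back[t, 0] = 1
        c01 = v0 + l12
        c11 = v1 + l22
        if c01 >= c11:
            n1 = c01
            back[t, 1] = 0
        else:
            n1 = c11
            back[t, 1] = 1
        v0 = n0 + np.log(max(b[t, 0], _TINY))
        v1 = n1 + np.log(max(b[t, 1], _TINY))
    path = np.zeros(T, dtype=np.int64)
    path[T - 1] = 0 if v0 >= v1 else 1
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _ctcrw_filter_ll(y, f01, f11, q00, q01, q11, R, p00_init, p11_init):
    """Scalar-unrolled Kalman log-likelihood for one CTCRW axis.

    ``y`` are observations at every time; the transition arrays (length
    n-1) hold the per-gap state matrix entries F = [[1, f01], [0, f11]]
    and process noise Q = [[q00, q01], [q01, q11]]. The state prior at the
    first time is mean (y[0], 0) with diagonal covariance
    (p00_init, p11_init). Measurement variance is R; Joseph-form updates
    keep the covariance positive semidefinite when R ~ 0.
    """
    n = y.shape[0]
    a0 = y[0]
    a1 = 0.0
    p00 = p00_init
    p01 = 0.0
    p11 = p11_init
    ll = 0.0
    for i in range(n):
        if i > 0:
            f1 = f01[i - 1]
            f2 = f11[i - 1]
            a0 = a0 + f1 * a1
            a1 = f2 * a1
            n00 = p00 + 2.0 * f1 * p01 + f1 * f1 * p11 + q00[i - 1]
            n01 = f2 * (p01 + f1 * p11) + q01[i - 1]
            n11 = f2 * f2 * p11 + q11[i - 1]
            p00, p01, p11 = n00, n01, n11
        S = p00 + R
        if S <= 0.0:
            return -np.inf
        v = y[i] - a0
        ll += -0.5 * (np.log(2.0 * np.pi * S) + v * v / S)
        K0 = p00 / S
        K1 = p01 / S
        a0 = a0 + K0 * v
        a1 = a1 + K1 * v
        n00 = (1.0 - K0) * (1.0 - K0) * p00 + K0 * K0 * R
        n01 = (1.0 - K0) * (p01 - K1 * p00) + K0 * K1 * R
        n11 = p11 - 2.0 * K1 * p01 + K1 * K1 * p00 + K1 * K1 * R
        p00, p01, p11 = n00, n01, n11
    return ll


forward_ll = _jit(_forward_ll)
forward_alphas = _jit(_forward_alphas)
backward_betas = _jit(_backward_betas)
viterbi_path = _jit(_viterbi_path)
ctcrw_filter_ll = _jit(_ctcrw_filter_ll)
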