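"""Exact moments of the multivariate Ornstein-Uhlenbeck process.

The latent traits follow ``d eta = (A eta + b) dt + S dW`` with a stable
selection matrix A (all eigenvalue real parts negative).  Conditional on a
parent value ``eta_0``, the value after time t is Gaussian with

    mean      M(t) eta_0 + m(t),    M(t) = exp(A t),
                                    m(t) = A^{-1} (M(t) - I) b,
    covariance V(t),   vec(V) = (A (+) A)^{-1} (exp((A (+) A) t) - I) vec(S S'),

where ``(+)`` is the Kronecker sum.  Two implementations are provided: a
reference one using matrix exponentials (any D), and a fast eigendecomposition
path vectorised over many branch lengths (used by the samplers); they agree to
machine precision for diagonalisable A and are cross-checked in the tests.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm, solve_lyapunov

__all__ = [
    "check_stable",
    "ou_moments",
    "ou_moments_batch",
    "ou_stationary",
]


def check_stable(A: np.ndarray, tol: float = 0.0) -> None:
    """Raise if any eigenvalue of A has nonnegative real part."""
    ev = np.linalg.eigvals(np.asarray(A, dtype=float))
    if np.any(ev.real >= -tol):
        raise ValueError("selection matrix not mean-reverting (unstable A)")


def ou_moments(A, b, SSt, t: float):
    """Reference (M, m, V) for a single branch length via matrix exponentials."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    SSt = np.asarray(SSt, dtype=float)
    d = A.shape[0]
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    if t == 0:
        return np.eye(d), np.zeros(d), np.zeros((d, d))
    M = expm(A * t)
    m = np.linalg.solve(A, (M - np.eye(d)) @ b)
    ksum = np.kron(A, np.eye(d)) + np.kron(np.eye(d), A)
    vecV = np.linalg.solve(ksum, (expm(ksum * t) - np.eye(d * d)) @ SSt.reshape(-1))
    V = vecV.reshape(d, d)
    return M, m, 0.5 * (V + V.T)


def ou_moments_batch(A, b, SSt, ts):
    """(M, m, V) for many branch lengths at once via eigendecomposition.

    Returns arrays of shape (n, d, d), (n, d), (n, d, d).  Falls back to the
    expm reference when A is close to defective (ill-conditioned eigenbasis).
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    SSt = np.asarray(SSt, dtype=float)
    ts = np.asarray(ts, dtype=float)
    d = A.shape[0]
    lam, P = np.linalg.eig(A.astype(complex))
    if np.linalg.cond(P) > 1e8:
        out_M = np.empty((ts.size, d, d))
        out_m = np.empty((ts.size, d))
        out_V = np.empty((ts.size, d, d))
        for i, t in enumerate(ts.ravel()):
            out_M[i], out_m[i], out_V[i] = ou_moments(A, b, SSt, float(t))
        return out_M, out_m, out_V
    Pinv = np.linalg.inv(P)
    e = np.exp(lam[None, :] * ts[:, None])  # (n, d)
    M = np.einsum("ij,nj,jk->nik", P, e, Pinv).real
    # m = A^{-1} (M - I) b, computed in the eigenbasis
    beta = Pinv @ b.astype(complex)
    m = np.einsum("ij,nj->ni", P, (e - 1.0) / lam[None, :] * beta[None, :]).real
    # V: G = Pinv SS' Pinv^T ; H_ij = G_ij (e^{(li+lj)t} - 1)/(li+lj); V = P H P^T
    G = Pinv @ SSt.astype(complex) @ Pinv.T
    lsum = lam[:, None] + lam[None, :]
    H = G[None, :, :] * (np.exp(lsum[None, :, :] * ts[:, None, None]) - 1.0) / lsum[None, :, :]
    V = np.einsum("ij,njk,lk->nil", P, H, P).real
    V = 0.5 * (V + np.swapaxes(V, 1, 2))
    zero = ts == 0
    if np.any(zero):
        M[zero] = np.eye(d)
        m[zero] = 0.0
        V[zero] = 0.0
    return M, m, V


def ou_stationary(A, b, SSt):
    """Stationary mean ``-A^{-1} b`` and covariance solving the Lyapunov
    equation ``A V + V A' + S S' = 0``."""
    A = np.asarray(A, dtype=float)
    check_stable(A)
    theta = -np.linalg.solve(A, np.asarray(b, dtype=float))
    V = solve_lyapunov(A, -np.asarray(SSt, dtype=float))
    return theta, 0.5 * (V + V.T)
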