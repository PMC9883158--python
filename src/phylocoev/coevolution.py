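"""Dynamic coevolutionary model for two ordinal traits on a phylogeny.

Political and religious authority are modelled as latent continuous traits
``eta = (eta_pol, eta_rel)`` evolving along the tree as a bivariate
Ornstein-Uhlenbeck process ``d eta = (A eta + b) dt + dW``: the diagonal of
the selection matrix A is the autoregressive pull toward equilibrium, the
off-diagonals are cross-trait selection, and the diffusion is fixed to the
identity to anchor the latent scale.  At the tips each latent receives an
additive spatially autocorrelated Gaussian-process term (squared-exponential
kernel on great-circle distance, controlling for diffusion between
neighbouring societies) and is observed as a 4-level ordinal category
through per-trait cutpoints with unit probit noise; the middle cutpoint is
fixed at 0 to remove the location redundancy.

The headline derived quantity is the change in equilibrium trait value per
robust-unit increase of the other trait,

    delta_theta[d <- e] = -(A[d,e] / A[d,d]) * MAD_e,

where MAD_e is the (raw) median absolute deviation of the posterior-mean tip
liabilities of the conditioning trait.

Inference is MCMC: truncated-normal data augmentation for the tip
liabilities, a joint Gaussian draw of all node latents and the whitened
spatial field, Gibbs updates for cutpoints and GP amplitude, and adaptive
random-walk Metropolis for (A, b) and the GP lengthscale.  Priors follow the
weakly regularising scheme: N(0,1) on off-diagonal A, -exp(N(0,1)) on the
diagonal of A, N(0,1) on b, ordered N(0,2) on free cutpoints, half-N(0,1)
on GP amplitude and log-N(log 1000, 1) on the lengthscale in km.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import ndtr, ndtri
from scipy.stats import multivariate_normal

from numba import njit

from ._ou import check_stable, ou_moments, ou_moments_batch, ou_stationary
from .inference import (
    ess,
    hpdi,
    mad,
    pp_positive,
    rhat,
    savage_dickey_logbf,
    slice_sample_1d,
)


def _slice_phi(target, x0, j, rng):
    return slice_sample_1d(lambda v: target(v, j), x0, rng, w=0.5, lo=-6.0, hi=4.0)


def _chol2(V):
    l11 = np.sqrt(V[0, 0])
    l21 = V[1, 0] / l11
    return l11, l21, np.sqrt(max(V[1, 1] - l21**2, 1e-300))
from .trees import Phylogeny, TreeSample, great_circle_distances

TRAITS = ("political_authority", "religious_authority")
_SQRT2PI = np.sqrt(2 * np.pi)

__all__ = [
    "OUParams",
    "CoevConfig",
    "CoevPosterior",
    "PhasePlane",
    "ou_transition",
    "stationary_moments",
    "coev_loglik",
    "fit_coevolution",
    "delta_theta",
    "phase_plane",
    "ancestral_states",
    "recovery_experiment",
    "mrca_node",
]


@dataclass
class OUParams:
    """Parameters of the latent coevolutionary process (D = 2 traits)."""

    A: np.ndarray
    b: np.ndarray
    cutpoints: np.ndarray  # (2, 3), middle cutpoint 0
    S: np.ndarray | None = None  # diagonal diffusion scale; default identity
    gp_amplitude: np.ndarray = field(default_factory=lambda: np.zeros(2))
    gp_lengthscale: np.ndarray = field(default_factory=lambda: np.full(2, 1000.0))

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        d = self.A.shape[0]
        if self.A.shape != (d, d) or self.b.shape != (d,):
            raise ValueError("A must be DxD and b length D")
        check_stable(self.A)
        if self.S is None:
            self.S = np.eye(d)
        self.S = np.asarray(self.S, dtype=float)
        if self.cutpoints.shape != (d, 3):
            raise ValueError("cutpoints must be (D, 3)")
        if np.any(np.diff(self.cutpoints, axis=1) <= 0):
            raise ValueError("cutpoints must be strictly increasing")
        if np.any(np.abs(self.cutpoints[:, 1]) > 1e-9):
            raise ValueError("middle cutpoint must be fixed at 0")
        self.gp_amplitude = np.asarray(self.gp_amplitude, dtype=float)
        self.gp_lengthscale = np.asarray(self.gp_lengthscale, dtype=float)
        if np.any(self.gp_amplitude < 0) or np.any(self.gp_lengthscale < 0):
            raise ValueError("GP parameters must be nonnegative")

    @property
    def D(self) -> int:
        return self.A.shape[0]

    @property
    def SSt(self) -> np.ndarray:
        return self.S @ self.S.T


def ou_transition(params: OUParams, t: float):
    """Exact Gaussian transition (M, m, V) over a branch of length t:
    child | parent ~ N(M parent + m, V)."""
    return ou_moments(params.A, params.b, params.SSt, t)


def stationary_moments(params: OUParams):
    """Equilibrium mean ``-A^{-1} b`` and stationary covariance (Lyapunov)."""
    return ou_stationary(params.A, params.b, params.SSt)


# ---------------------------------------------------------------------------
# Reference likelihood (tests and diagnostics; the sampler uses augmentation)
# ---------------------------------------------------------------------------


def _joint_tip_moments(tree: Phylogeny, params: OUParams):
    """Marginal mean and covariance of the tip latents under the tree OU.

    Propagates moments root-to-tips; cross-covariances follow from the
    linear Gaussian recursion eta_c = M eta_p + m + noise.
    """
    d = params.D
    nn = tree.n_nodes
    Ms, ms, Vs = ou_moments_batch(params.A, params.b, params.SSt, tree.edge_length)
    theta, Vinf = stationary_moments(params)
    mean = np.zeros((nn, d))
    cov = np.zeros((nn, nn, d, d))
    mean[0] = theta
    cov[0, 0] = Vinf
    for c in range(1, nn):
        p = tree.parent[c]
        mean[c] = Ms[c] @ mean[p] + ms[c]
        for u in range(c):
            cov[c, u] = Ms[c] @ cov[p, u]
            cov[u, c] = cov[c, u].T
        cov[c, c] = Ms[c] @ cov[p, p] @ Ms[c].T + Vs[c]
    tips = tree.tip_indices
    n = tips.size
    mu = mean[tips].reshape(n * d)
    Sig = np.empty((n * d, n * d))
    for a in range(n):
        for bb in range(n):
            Sig[a * d : (a + 1) * d, bb * d : (bb + 1) * d] = cov[tips[a], tips[bb]]
    return mu, 0.5 * (Sig + Sig.T)


def _ordinal_logprob(y: np.ndarray, liab: np.ndarray, cutpoints: np.ndarray) -> float:
    """Sum of log P(y | liability) with P(k) = Phi(c_{k+1}-l) - Phi(c_k-l)."""
    total = 0.0
    for t in range(y.shape[1]):
        c = np.concatenate([[-np.inf], cutpoints[t], [np.inf]])
        hi = ndtr(c[y[:, t] + 1] - liab[:, t])
        lo = ndtr(c[y[:, t]] - liab[:, t])
        p = np.clip(hi - lo, 1e-300, None)
        total += float(np.log(p).sum())
    return total


def coev_loglik(
    tree: Phylogeny,
    table: pd.DataFrame,
    coords: np.ndarray | None,
    params: OUParams,
    tip_latents: np.ndarray,
    geo_effects: np.ndarray | None = None,
) -> float:
    """Joint log density of tree-level tip latents, spatial effects and data.

    Internal nodes are marginalised analytically (the tip latents are
    jointly Gaussian under the OU model); the spatial effect per trait has
    a Gaussian-process density; the ordinal observation term evaluates the
    probit category probabilities at liability = tip latent + spatial
    effect.
    """
    from .simulate import gp_covariance

    y = table_traits(table, tree)
    n = tree.n_tips
    tip_latents = np.asarray(tip_latents, dtype=float).reshape(n, params.D)
    if geo_effects is None:
        geo_effects = np.zeros_like(tip_latents)
    geo_effects = np.asarray(geo_effects, dtype=float).reshape(n, params.D)
    mu, Sig = _joint_tip_moments(tree, params)
    # explicit Cholesky with a trace-scaled jitter: posterior trees can carry
    # near-zero branches that make the tip covariance borderline singular
    Sig = Sig + 1e-8 * np.trace(Sig) / Sig.shape[0] * np.eye(Sig.shape[0])
    L = np.linalg.cholesky(Sig)
    r = solve_triangular(L, tip_latents.reshape(-1) - mu, lower=True)
    total = float(
        -0.5 * r @ r - np.log(np.diag(L)).sum() - 0.5 * Sig.shape[0] * np.log(2 * np.pi)
    )
    for t in range(params.D):
        amp, ls = params.gp_amplitude[t], params.gp_lengthscale[t]
        if amp > 0:
            K = gp_covariance(coords, amp, ls) + 1e-8 * amp**2 * np.eye(n)
            total += float(
                multivariate_normal.logpdf(geo_effects[:, t], cov=K, allow_singular=True)
            )
        elif np.any(geo_effects[:, t] != 0):
            raise ValueError("nonzero spatial effects with zero GP amplitude")
    total += _ordinal_logprob(y, tip_latents + geo_effects, params.cutpoints)
    return total


def table_traits(table: pd.DataFrame, tree: Phylogeny) -> np.ndarray:
    """(n_tips, 2) integer trait matrix aligned to the tree's tip order."""
    idx = table.set_index("taxon")
    missing = [l for l in tree.tip_labels if l not in idx.index]
    if missing:
        raise KeyError(f"taxa missing from table: {missing}")
    y = np.column_stack([idx.loc[tree.tip_labels, c].to_numpy() for c in TRAITS]).astype(int)
    if y.min() < 0 or y.max() > 3:
        raise ValueError("ordinal traits must lie in 0..3")
    return y


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


@dataclass
class CoevConfig:
    """Sampler settings.  Desk-scale defaults; ``paper_scale()`` gives the
    full production run sizes."""

    n_iter: int = 1600
    burn: int = 600
    n_chains: int = 2
    tree_draws: int = 10
    gp: bool = True
    seed: int = 0
    fixed_root: bool = False  # root at stationary distribution by default

    @classmethod
    def paper_scale(cls, **kw) -> "CoevConfig":
        return cls(n_iter=4000, burn=1000, tree_draws=100, **kw)


class _AdaptiveBlock:
    """Random-walk proposal with Robbins-Monro scale + covariance adaptation
    during burn-in, frozen afterwards."""

    def __init__(self, dim: int, scale: float = 0.15, target: float = 0.234):
        self.dim = dim
        self.logscale = np.log(scale)
        self.target = target if dim > 1 else 0.44
        self.mean = np.zeros(dim)
        self.cov = np.eye(dim)
        self.chol = np.eye(dim)
        self.count = 0

    def propose(self, x: np.ndarray, rng) -> np.ndarray:
        return x + np.exp(self.logscale) * self.chol @ rng.standard_normal(self.dim)

    def adapt(self, x: np.ndarray, accepted: bool) -> None:
        self.count += 1
        w = 1.0 / (self.count + 10)
        self.logscale += w * ((1.0 if accepted else 0.0) - self.target)
        delta = x - self.mean
        self.mean = self.mean + w * delta
        self.cov = (1 - w) * self.cov + w * np.outer(delta, delta)
        if self.count % 100 == 0:
            try:
                self.chol = np.linalg.cholesky(self.cov + 1e-8 * np.eye(self.dim))
            except np.linalg.LinAlgError:
                pass


def _trunc_normal(rng, mean, sd, lo, hi):
    """Vectorised truncated-normal draws by inverse CDF."""
    a = ndtr((lo - mean) / sd)
    bb = ndtr((hi - mean) / sd)
    u = a + (bb - a) * rng.random(np.shape(mean))
    u = np.clip(u, 1e-15, 1 - 1e-15)
    return mean + sd * ndtri(u)


def _phi_to_A(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    A = np.array([[-np.exp(phi[0]), phi[2]], [phi[3], -np.exp(phi[1])]])
    return A, phi[4:6].copy()


@njit(cache=True)
def _branch_terms_core(a11, a12, a21, a22, b1, b2, ts):  # pragma: no cover
    """All per-branch OU quantities for the sampler, in one jitted pass.

    Returns (ok, Ms, ms, Vs, Vinv, logdet, theta, Vinf, Vinf_inv); mirrors
    the pure-numpy `_fast_moments2` (cross-checked in tests).
    """
    n = ts.shape[0]
    Ms = np.empty((n, 2, 2))
    ms = np.empty((n, 2))
    Vs = np.empty((n, 2, 2))
    Vinv = np.empty((n, 2, 2))
    logdet = np.empty(n)
    theta = np.empty(2)
    Vinf = np.empty((2, 2))
    Vinf_inv = np.empty((2, 2))
    tr = a11 + a22
    det = a11 * a22 - a12 * a21
    if tr >= 0 or det <= 0:
        return False, Ms, ms, Vs, Vinv, logdet, theta, Vinf, Vinf_inv
    disc = np.sqrt(complex(tr * tr - 4 * det))
    l1 = (tr + disc) / 2
    l2 = (tr - disc) / 2
    if abs(l1 - l2) < 1e-8:
        return False, Ms, ms, Vs, Vinv, logdet, theta, Vinf, Vinf_inv
    if abs(a12) > 1e-14:
        p00, p01 = complex(a12), complex(a12)
        p10, p11c = l1 - a11, l2 - a11
    elif abs(a21) > 1e-14:
        p00, p01 = l1 - a22, l2 - a22
        p10, p11c = complex(a21), complex(a21)
    else:
        p00, p01 = complex(1.0), complex(0.0)
        p10, p11c = complex(0.0), complex(1.0)
    dp = p00 * p11c - p01 * p10
    if abs(dp) < 1e-12:
        return False, Ms, ms, Vs, Vinv, logdet, theta, Vinf, Vinf_inv
    i00, i01 = p11c / dp, -p01 / dp
    i10, i11 = -p10 / dp, p00 / dp
    beta0 = i00 * b1 + i01 * b2
    beta1 = i10 * b1 + i11 * b2
    g00 = i00 * i00 + i01 * i01
    g01 = i00 * i10 + i01 * i11
    g11 = i10 * i10 + i11 * i11
    s11, s12, s22 = 2 * l1, l1 + l2, 2 * l2
    for k in range(n):
        t = ts[k]
        if t <= 0:
            Ms[k, 0, 0] = Ms[k, 1, 1] = 1.0
            Ms[k, 0, 1] = Ms[k, 1, 0] = 0.0
            ms[k, 0] = ms[k, 1] = 0.0
            for a in range(2):
                for c in range(2):
                    Vs[k, a, c] = 0.0
            return False, Ms, ms, Vs, Vinv, logdet, theta, Vinf, Vinf_inv
        e1 = np.exp(l1 * t)
        e2 = np.exp(l2 * t)
        Ms[k, 0, 0] = (p00 * i00 * e1 + p01 * i10 * e2).real
        Ms[k, 0, 1] = (p00 * i01 * e1 + p01 * i11 * e2).real
        Ms[k, 1, 0] = (p10 * i00 * e1 + p11c * i10 * e2).real
        Ms[k, 1, 1] = (p10 * i01 * e1 + p11c * i11 * e2).real
        w1 = (e1 - 1.0) / l1 * beta0
        w2 = (e2 - 1.0) / l2 * beta1
        ms[k, 0] = (p00 * w1 + p01 * w2).real
        ms[k, 1] = (p10 * w1 + p11c * w2).real
        h11 = g00 * (e1 * e1 - 1.0) / s11
        h12 = g01 * (e1 * e2 - 1.0) / s12
        h22 = g11 * (e2 * e2 - 1.0) / s22
        v00 = (p00 * p00 * h11 + 2 * p00 * p01 * h12 + p01 * p01 * h22).real
        v01 = (p00 * p10 * h11 + (p00 * p11c + p01 * p10) * h12 + p01 * p11c * h22).real
        v11 = (p10 * p10 * h11 + 2 * p10 * p11c * h12 + p11c * p11c * h22).real
        Vs[k, 0, 0], Vs[k, 0, 1], Vs[k, 1, 0], Vs[k, 1, 1] = v00, v01, v01, v11
        dv = v00 * v11 - v01 * v01
        if dv <= 0 or not np.isfinite(dv):
            return False, Ms, ms, Vs, Vinv, logdet, theta, Vinf, Vinf_inv
        Vinv[k, 0, 0] = v11 / dv
        Vinv[k, 1, 1] = v00 / dv
        Vinv[k, 0, 1] = Vinv[k, 1, 0] = -v01 / dv
        logdet[k] = np.log(dv)
    theta[0] = -(a22 * b1 - a12 * b2) / det
    theta[1] = -(-a21 * b1 + a11 * b2) / det
    q11, q12, q22 = -g00 / s11, -g01 / s12, -g11 / s22
    Vinf[0, 0] = (p00 * p00 * q11 + 2 * p00 * p01 * q12 + p01 * p01 * q22).real
    Vinf[0, 1] = (p00 * p10 * q11 + (p00 * p11c + p01 * p10) * q12 + p01 * p11c * q22).real
    Vinf[1, 0] = Vinf[0, 1]
    Vinf[1, 1] = (p10 * p10 * q11 + 2 * p10 * p11c * q12 + p11c * p11c * q22).real
    di = Vinf[0, 0] * Vinf[1, 1] - Vinf[0, 1] * Vinf[0, 1]
    if di <= 0 or not np.isfinite(di):
        return False, Ms, ms, Vs, Vinv, logdet, theta, Vinf, Vinf_inv
    Vinf_inv[0, 0] = Vinf[1, 1] / di
    Vinf_inv[1, 1] = Vinf[0, 0] / di
    Vinf_inv[0, 1] = Vinf_inv[1, 0] = -Vinf[0, 1] / di
    return True, Ms, ms, Vs, Vinv, logdet, theta, Vinf, Vinf_inv


@njit(cache=True)
def _color_core(parents, Ms, ms, e1, e2, eta0):  # pragma: no cover
    nn = parents.shape[0] + 1
    eta = np.empty((nn, 2))
    eta[0, 0] = eta0[0]
    eta[0, 1] = eta0[1]
    for k in range(nn - 1):
        p = parents[k]
        eta[k + 1, 0] = Ms[k, 0, 0] * eta[p, 0] + Ms[k, 0, 1] * eta[p, 1] + ms[k, 0] + e1[k]
        eta[k + 1, 1] = Ms[k, 1, 0] * eta[p, 0] + Ms[k, 1, 1] * eta[p, 1] + ms[k, 1] + e2[k]
    return eta


def _fast_moments2(A, b, ts):
    """Closed-form OU branch moments for D=2 (no LAPACK calls).

    Returns (M, m, V, theta, Vinf) arrays, or None when A is unstable or
    numerically defective (caller treats the proposal as invalid).  Agrees
    with the generic eigendecomposition route; kept separate because the
    sampler calls it thousands of times per chain.
    """
    a11, a12, a21, a22 = A[0, 0], A[0, 1], A[1, 0], A[1, 1]
    tr, det = a11 + a22, a11 * a22 - a12 * a21
    if tr >= 0 or det <= 0:
        return None
    disc = complex(tr * tr - 4 * det) ** 0.5
    l1, l2 = (tr + disc) / 2, (tr - disc) / 2
    if abs(l1 - l2) < 1e-8:
        return None  # near-defective; measure-zero under continuous proposals
    # eigenvectors as columns of P (care with triangular / diagonal A)
    if abs(a12) > 1e-14:
        P = np.array([[a12, a12], [l1 - a11, l2 - a11]], dtype=complex)
    elif abs(a21) > 1e-14:
        P = np.array([[l1 - a22, l2 - a22], [a21, a21]], dtype=complex)
    else:
        P = np.eye(2, dtype=complex)
    dp = P[0, 0] * P[1, 1] - P[0, 1] * P[1, 0]
    if abs(dp) < 1e-12:
        return None
    Pi = np.array([[P[1, 1], -P[0, 1]], [-P[1, 0], P[0, 0]]], dtype=complex) / dp
    e1 = np.exp(l1 * ts)
    e2 = np.exp(l2 * ts)
    n = ts.shape[0]
    # M = P diag(e) Pinv, expanded
    M = np.empty((n, 2, 2))
    for i in range(2):
        for k in range(2):
            M[:, i, k] = (P[i, 0] * Pi[0, k] * e1 + P[i, 1] * Pi[1, k] * e2).real
    # m = P diag((e-1)/lam) Pinv b
    beta0 = Pi[0, 0] * b[0] + Pi[0, 1] * b[1]
    beta1 = Pi[1, 0] * b[0] + Pi[1, 1] * b[1]
    w1 = (e1 - 1.0) / l1 * beta0
    w2 = (e2 - 1.0) / l2 * beta1
    m = np.empty((n, 2))
    m[:, 0] = (P[0, 0] * w1 + P[0, 1] * w2).real
    m[:, 1] = (P[1, 0] * w1 + P[1, 1] * w2).real
    # V = P H P^T with H_ij = G_ij (e^{(li+lj)t}-1)/(li+lj), G = Pinv Pinv^T
    G = Pi @ Pi.T
    s11, s12, s22 = 2 * l1, l1 + l2, 2 * l2
    h11 = G[0, 0] * (e1 * e1 - 1.0) / s11
    h12 = G[0, 1] * (e1 * e2 - 1.0) / s12
    h22 = G[1, 1] * (e2 * e2 - 1.0) / s22
    V = np.empty((n, 2, 2))
    for a in range(2):
        for c in range(a, 2):
            V[:, a, c] = (
                P[a, 0] * P[c, 0] * h11
                + (P[a, 0] * P[c, 1] + P[a, 1] * P[c, 0]) * h12
                + P[a, 1] * P[c, 1] * h22
            ).real
    V[:, 1, 0] = V[:, 0, 1]
    zero = ts <= 0
    if np.any(zero):
        M[zero] = np.eye(2)
        m[zero] = 0.0
        V[zero] = 0.0
    theta = -np.array([a22 * b[0] - a12 * b[1], -a21 * b[0] + a11 * b[1]]) / det
    # stationary covariance: t -> inf limit of the same expansion
    g11, g12, g22 = -G[0, 0] / s11, -G[0, 1] / s12, -G[1, 1] / s22
    Vinf = np.empty((2, 2))
    Vinf[0, 0] = (P[0, 0] * P[0, 0] * g11 + 2 * P[0, 0] * P[0, 1] * g12 + P[0, 1] * P[0, 1] * g22).real
    Vinf[0, 1] = (
        P[0, 0] * P[1, 0] * g11 + (P[0, 0] * P[1, 1] + P[0, 1] * P[1, 0]) * g12 + P[0, 1] * P[1, 1] * g22
    ).real
    Vinf[1, 0] = Vinf[0, 1]
    Vinf[1, 1] = (P[1, 0] * P[1, 0] * g11 + 2 * P[1, 0] * P[1, 1] * g12 + P[1, 1] * P[1, 1] * g22).real
    return M, m, V, theta, Vinf


class _TreeOUSampler:
    """One-tree MCMC for the coevolutionary model (internal)."""

    def __init__(self, tree: Phylogeny, y: np.ndarray, coords, config: CoevConfig):
        self.tree = tree
        self.y = y
        self.cfg = config
        self.nn = tree.n_nodes
        self.n = tree.n_tips
        self.tips = tree.tip_indices
        self.elen = np.maximum(tree.edge_length, 1e-8)
        self.elen[0] = 0.0
        self.parents = tree.parent[1:]
        self.children = np.arange(1, self.nn)
        self.gp = bool(config.gp)
        self.dim = 2 * self.nn + (2 * self.n if self.gp else 0)
        if self.gp:
            if coords is None:
                raise ValueError("coords required for the spatial GP")
            self.dist_km = great_circle_distances(coords).values
        # index grids for 2x2 block scatter-adds
        pat_r = np.array([[0, 0], [1, 1]])
        pat_c = np.array([[0, 1], [0, 1]])
        c2, p2 = 2 * self.children, 2 * self.parents
        self.idx = {}
        for key, (ra, ca) in {
            "cc": (c2, c2), "pp": (p2, p2), "cp": (c2, p2), "pc": (p2, c2)
        }.items():
            self.idx[key] = (ra[:, None, None] + pat_r, ca[:, None, None] + pat_c)
        self.hc = c2[:, None] + np.array([0, 1])
        self.hp = p2[:, None] + np.array([0, 1])
        self.eta_tip_idx = (2 * self.tips[:, None] + np.array([0, 1]))  # (n,2)

    # --- OU branch quantities, cached on (A, b) ---------------------------
    def _branch_terms(self, A, b):
        ok, Ms, ms, Vs, Vinv, logdet, theta, Vinf, Vinf_inv = _branch_terms_core(
            A[0, 0], A[0, 1], A[1, 0], A[1, 1], b[0], b[1], self.elen[1:]
        )
        if not ok:
            return None
        return {
            "Ms": Ms, "ms": ms, "Vs": Vs, "Vinv": Vinv, "logdet": logdet,
            "theta": theta, "Vinf": Vinf, "Vinf_inv": Vinf_inv,
        }

    @staticmethod
    def _chol2_batch(V):
        """Cholesky factors of a batch of 2x2 SPD matrices, closed form."""
        l11 = np.sqrt(V[:, 0, 0])
        l21 = V[:, 1, 0] / l11
        l22 = np.sqrt(np.maximum(V[:, 1, 1] - l21**2, 1e-300))
        return l11, l21, l22

    def _whiten(self, eta, bt):
        """Per-branch standard-normal innovations u and root innovation u0."""
        r = eta[self.children] - np.einsum("nij,nj->ni", bt["Ms"], eta[self.parents]) - bt["ms"]
        l11, l21, l22 = self._chol2_batch(bt["Vs"])
        u1 = r[:, 0] / l11
        u2 = (r[:, 1] - l21 * u1) / l22
        c11, c21, c22 = _chol2(bt["Vinf"])
        r0 = eta[0] - bt["theta"]
        u0 = np.array([r0[0] / c11, (r0[1] - c21 * r0[0] / c11) / c22])
        return np.column_stack([u1, u2]), u0

    def _color(self, u, u0, bt):
        """Reconstruct node latents from innovations under new parameters."""
        c11, c21, c22 = _chol2(bt["Vinf"])
        eta0 = bt["theta"] + np.array([c11 * u0[0], c21 * u0[0] + c22 * u0[1]])
        l11, l21, l22 = self._chol2_batch(bt["Vs"])
        e1 = l11 * u[:, 0]
        e2 = l21 * u[:, 0] + l22 * u[:, 1]
        return _color_core(self.parents, bt["Ms"], bt["ms"], e1, e2, eta0)

    def _tree_logpdf(self, eta, bt) -> float:
        r = eta[self.children] - np.einsum("nij,nj->ni", bt["Ms"], eta[self.parents]) - bt["ms"]
        quad = np.einsum("ni,nij,nj->n", r, bt["Vinv"], r)
        ll = -0.5 * float(np.sum(quad + bt["logdet"])) - (self.nn - 1) * np.log(2 * np.pi)
        r0 = eta[0] - bt["theta"]
        s, ld = np.linalg.slogdet(bt["Vinf"])
        ll += -0.5 * (float(r0 @ bt["Vinf_inv"] @ r0) + ld) - np.log(2 * np.pi)
        return ll

    # --- main loop --------------------------------------------------------
    def run(self, n_iter: int, burn: int, seed: int):
        rng = np.random.default_rng(seed)
        y = self.y
        n, nn = self.n, self.nn
        # initial state
        phi = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        phi[:2] += 0.1 * rng.standard_normal(2)
        A, b = _phi_to_A(phi)
        bt = self._branch_terms(A, b)
        cuts = np.array([[-0.7, 0.0, 0.7], [-0.7, 0.0, 0.7]])
        log_ls = np.log([1000.0, 1000.0]) + (0.2 * rng.standard_normal(2) if self.gp else 0.0)
        amp = np.array([0.3, 0.3]) if self.gp else np.zeros(2)
        eta = np.zeros((nn, 2))
        gamma = np.zeros((2, n))
        z = np.where(y == 0, -1.2, np.where(y == 1, -0.35, np.where(y == 2, 0.35, 1.2))).astype(float)
        blocks = {"ab": _AdaptiveBlock(6, scale=0.12), "ab2": _AdaptiveBlock(6, scale=0.12)}
        if self.gp:
            blocks["ls"] = _AdaptiveBlock(2, scale=0.3)
            Rinv, Rchol_logdet = self._gp_prec(log_ls)
        n_keep = n_iter - burn
        out = {
            "phi": np.empty((n_keep, 6)),
            "cuts": np.empty((n_keep, 2, 3)),
            "amp": np.empty((n_keep, 2)),
            "ls": np.empty((n_keep, 2)),
            "eta": np.empty((n_keep, nn, 2), dtype=np.float32),
            "liab_sum": np.zeros((n, 2)),
        }
        n_acc = 0
        kept = 0
        cmat = np.concatenate([np.full((2, 1), -np.inf), cuts, np.full((2, 1), np.inf)], axis=1)
        for it in range(n_iter):
            mu_liab = eta[self.tips] + (amp * gamma.T if self.gp else 0.0)
            # 1. cutpoints with z collapsed out: ordinal likelihood given the
            # liability means + truncated N(0,2) prior (c2 = 0); slice moves
            # (the classic z-conditioned Gibbs step mixes cutpoints slowly)
            for t in range(2):
                yt = y[:, t]
                mu_t = mu_liab[:, t]

                def cut_target(c, j, t=t, yt=yt, mu_t=mu_t):
                    trial = cuts[t].copy()
                    trial[j] = c
                    edges = np.concatenate([[-np.inf], trial, [np.inf]])
                    p = ndtr(edges[yt + 1] - mu_t) - ndtr(edges[yt] - mu_t)
                    if np.any(p <= 0):
                        return -np.inf
                    return float(np.log(p).sum()) - c * c / 8.0

                cuts[t, 0] = slice_sample_1d(
                    lambda c: cut_target(c, 0), cuts[t, 0], rng, w=0.3, lo=-8.0, hi=0.0
                )
                cuts[t, 2] = slice_sample_1d(
                    lambda c: cut_target(c, 2), cuts[t, 2], rng, w=0.3, lo=0.0, hi=8.0
                )
                cmat[t, 1:4] = cuts[t]
            # 2. liabilities z | eta, gamma, cutpoints, y (truncated normal)
            for t in range(2):
                lo = cmat[t, y[:, t]]
                hi = cmat[t, y[:, t] + 1]
                z[:, t] = _trunc_normal(rng, mu_liab[:, t], 1.0, lo, hi)
            # 3. (eta, gamma) | z, A, b, amp, lengthscale  (joint Gaussian)
            Lam = np.zeros((self.dim, self.dim))
            h = np.zeros(self.dim)
            ViM = np.einsum("nij,njk->nik", bt["Vinv"], bt["Ms"])
            MtViM = np.einsum("nji,njk->nik", bt["Ms"], ViM)
            Vim = np.einsum("nij,nj->ni", bt["Vinv"], bt["ms"])
            MtVim = np.einsum("nji,nj->ni", bt["Ms"], Vim)
            np.add.at(Lam, self.idx["cc"], bt["Vinv"])
            np.add.at(Lam, self.idx["pp"], MtViM)
            np.add.at(Lam, self.idx["cp"], -ViM)
            np.add.at(Lam, self.idx["pc"], -np.swapaxes(ViM, 1, 2))
            np.add.at(h, self.hc, Vim)
            np.add.at(h, self.hp, -MtVim)
            Lam[0:2, 0:2] += bt["Vinf_inv"]
            h[0:2] += bt["Vinf_inv"] @ bt["theta"]
            ei = self.eta_tip_idx
            np.add.at(Lam, (ei.ravel(), ei.ravel()), 1.0)
            np.add.at(h, ei.ravel(), z.ravel())
            if self.gp:
                for t in range(2):
                    g0 = 2 * nn + t * n
                    gsl = slice(g0, g0 + n)
                    Lam[gsl, gsl] += Rinv[t]
                    Lam[(np.arange(g0, g0 + n), np.arange(g0, g0 + n))] += amp[t] ** 2
                    Lam[(ei[:, t], np.arange(g0, g0 + n))] += amp[t]
                    Lam[(np.arange(g0, g0 + n), ei[:, t])] += amp[t]
                    h[gsl] += amp[t] * z[:, t]
            L = np.linalg.cholesky(Lam)
            w = solve_triangular(L, h, lower=True)
            x = solve_triangular(L.T, w + rng.standard_normal(self.dim), lower=False)
            eta = x[: 2 * nn].reshape(nn, 2)
            if self.gp:
                gamma = x[2 * nn :].reshape(2, n)
            # 4. (A, b) | eta: centred adaptive MH sweeps ...
            cur = self._tree_logpdf(eta, bt) - 0.5 * float(phi @ phi)
            for _ in range(3):
                prop = blocks["ab"].propose(phi, rng)
                Ap, bp = _phi_to_A(prop)
                accepted = False
                if Ap[0, 0] * Ap[1, 1] - Ap[0, 1] * Ap[1, 0] > 1e-12:
                    btp = self._branch_terms(Ap, bp)
                    if btp is not None:
                        new = self._tree_logpdf(eta, btp) - 0.5 * float(prop @ prop)
                        if np.log(rng.random()) < new - cur:
                            phi, A, b, bt, cur = prop, Ap, bp, btp, new
                            accepted = True
                if it < burn:
                    blocks["ab"].adapt(phi, accepted)
                n_acc += accepted
            # ... then interweaved non-centred sweeps: hold the whitened
            # branch innovations fixed, reconstruct eta under the proposal,
            # and accept on the observation likelihood (breaks the A-eta
            # coupling that makes the centred step a slow random walk).
            u, u0 = self._whiten(eta, bt)
            mu_obs = eta[self.tips] + (amp * gamma.T if self.gp else 0.0)
            cur_obs = -0.5 * float(np.sum((z - mu_obs) ** 2)) - 0.5 * float(phi @ phi)
            for _ in range(3):
                prop = blocks["ab2"].propose(phi, rng)
                Ap, bp = _phi_to_A(prop)
                accepted = False
                if Ap[0, 0] * Ap[1, 1] - Ap[0, 1] * Ap[1, 0] > 1e-12:
                    btp = self._branch_terms(Ap, bp)
                    if btp is not None:
                        eta_p = self._color(u, u0, btp)
                        mu_p = eta_p[self.tips] + (amp * gamma.T if self.gp else 0.0)
                        new_obs = -0.5 * float(np.sum((z - mu_p) ** 2)) - 0.5 * float(prop @ prop)
                        if np.log(rng.random()) < new_obs - cur_obs:
                            phi, A, b, bt, eta, cur_obs = prop, Ap, bp, btp, eta_p, new_obs
                            accepted = True
                if it < burn:
                    blocks["ab2"].adapt(phi, accepted)
            # slice-sample the two autoregressive (diagonal) components in
            # the non-centred space: their conditionals are heavy-tailed and
            # random-walk proposals mix them slowly
            state = {"bt": bt, "eta": eta}

            def nc_target(v, j):
                ph = phi.copy()
                ph[j] = v
                Ap, bp = _phi_to_A(ph)
                btp = self._branch_terms(Ap, bp)
                if btp is None:
                    return -np.inf
                eta_p = self._color(u, u0, btp)
                mu_p = eta_p[self.tips] + (amp * gamma.T if self.gp else 0.0)
                state["bt"], state["eta"] = btp, eta_p
                return -0.5 * float(np.sum((z - mu_p) ** 2)) - 0.5 * float(ph @ ph)

            for j in (0, 1):
                newv = _slice_phi(nc_target, phi[j], j, rng)
                if newv != phi[j]:
                    phi[j] = newv
                    nc_target(phi[j], j)  # refresh state at the accepted point
                    bt, eta = state["bt"], state["eta"]
                    A, b = _phi_to_A(phi)
            # 5. GP amplitude (Gibbs, half-normal prior) and lengthscale (MH)
            if self.gp:
                resid = z - eta[self.tips]
                for t in range(2):
                    prec = float(gamma[t] @ gamma[t]) + 1.0
                    mean_t = float(gamma[t] @ resid[:, t]) / prec
                    amp[t] = _trunc_normal(rng, mean_t, 1.0 / np.sqrt(prec), 0.0, np.inf)
                # rescale move: hold the spatial field amp*gamma fixed while
                # moving amp (prior + Jacobian decide), then unwhiten gamma;
                # breaks the amp-gamma coupling that slows the Gibbs pair
                for t in range(2):
                    if amp[t] < 1e-8:
                        continue
                    field = amp[t] * gamma[t]
                    q = float(field @ Rinv[t] @ field)
                    n_t = self.n

                    def amp_target(la, q=q, n_t=n_t):
                        a2 = np.exp(2 * la)
                        return -0.5 * a2 + la - 0.5 * q / a2 - n_t * la

                    la_new = slice_sample_1d(
                        amp_target, float(np.log(amp[t])), rng, w=0.4, lo=-6.0, hi=3.0
                    )
                    amp[t] = float(np.exp(la_new))
                    gamma[t] = field / amp[t]
                prop_ls = blocks["ls"].propose(log_ls, rng)
                cur_l = self._gp_marg(gamma, Rinv, Rchol_logdet) + self._ls_prior(log_ls)
                Rinv_p, ld_p = self._gp_prec(prop_ls)
                new_l = self._gp_marg(gamma, Rinv_p, ld_p) + self._ls_prior(prop_ls)
                acc_l = np.log(rng.random()) < new_l - cur_l
                if acc_l:
                    log_ls, Rinv, Rchol_logdet = prop_ls, Rinv_p, ld_p
                if it < burn:
                    blocks["ls"].adapt(log_ls, acc_l)
            if it >= burn:
                out["phi"][kept] = phi
                out["cuts"][kept] = cuts
                out["amp"][kept] = amp
                out["ls"][kept] = np.exp(log_ls)
                out["eta"][kept] = eta
                out["liab_sum"] += eta[self.tips] + (amp * gamma.T if self.gp else 0.0)
                kept += 1
        out["accept_ab"] = n_acc / n_iter
        out["liab_mean"] = out["liab_sum"] / max(kept, 1)
        del out["liab_sum"]
        return out

    def _gp_prec(self, log_ls):
        Rinv = np.empty((2, self.n, self.n))
        logdets = np.empty(2)
        for t in range(2):
            ls = np.exp(np.clip(log_ls[t], 0.0, 18.0))
            R = np.exp(-0.5 * (self.dist_km / ls) ** 2)
            jitter = 1e-6
            while True:
                try:
                    L = np.linalg.cholesky(R + jitter * np.eye(self.n))
                    break
                except np.linalg.LinAlgError:
                    jitter *= 100
                    if jitter > 1e2:
                        raise
            Li = solve_triangular(L, np.eye(self.n), lower=True)
            Rinv[t] = Li.T @ Li
            logdets[t] = 2.0 * float(np.log(np.diag(L)).sum())
        return Rinv, logdets

    def _gp_marg(self, gamma, Rinv, logdets) -> float:
        tot = 0.0
        for t in range(2):
            tot += -0.5 * (float(gamma[t] @ Rinv[t] @ gamma[t]) + logdets[t])
        return tot

    @staticmethod
    def _ls_prior(log_ls) -> float:
        return -0.5 * float(np.sum((log_ls - np.log(1000.0)) ** 2))


@dataclass
class CoevPosterior:
    """Pooled posterior of the coevolutionary model.

    ``draws`` maps parameter names to (n_runs, n_keep) arrays where each
    run is one chain on one tree; ``node_latents`` is a per-run list of
    (n_keep, n_nodes, 2) arrays (node indexing follows that run's tree);
    the delta-theta draws are stored under ``dtheta_pol_from_rel`` /
    ``dtheta_rel_from_pol``.
    """

    draws: dict
    node_latents: list[np.ndarray]
    run_tree_ids: list[int]
    tree_ids: list[int]
    trees: dict[int, Phylogeny]
    mad_per_trait: np.ndarray
    diagnostics: pd.DataFrame
    converged: bool
    config: CoevConfig

    PARAM_NAMES = (
        "A11", "A22", "A12", "A21", "b1", "b2",
        "cut_pol_1", "cut_pol_3", "cut_rel_1", "cut_rel_3",
        "gp_amp_pol", "gp_amp_rel", "gp_ls_pol", "gp_ls_rel",
        "dtheta_pol_from_rel", "dtheta_rel_from_pol",
    )

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].ravel()

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            lo, hi = hpdi(arr.ravel())
            rows.append(
                {
                    "parameter": name,
                    "median": float(np.median(arr)),
                    "hpdi_low": lo,
                    "hpdi_high": hi,
                    "pp_positive": pp_positive(arr),
                    "rhat": float(self.diagnostics.set_index("parameter")["rhat"].get(name, np.nan)),
                }
            )
        return pd.DataFrame(rows)


def fit_coevolution(
    table: pd.DataFrame,
    trees: TreeSample | Phylogeny,
    coords: np.ndarray | None = None,
    config: CoevConfig | None = None,
) -> CoevPosterior:
    """Fit the dynamic coevolutionary model by MCMC, pooling over trees.

    ``config.tree_draws`` trees are drawn at random from the sample (all of
    them if fewer are available); ``config.n_chains`` chains are run per
    tree and pooled.  Convergence requires split R-hat <= 1.01 on every
    reported parameter within every tree.
    """
    config = config or CoevConfig()
    if isinstance(trees, Phylogeny):
        trees = TreeSample([trees])
    if config.gp and coords is None:
        raise ValueError("coords required when the spatial GP is enabled")
    rng = np.random.default_rng(config.seed)
    k = min(config.tree_draws, len(trees))
    tree_ids = sorted(rng.choice(len(trees), size=k, replace=False).tolist())
    runs = []
    run_tree = []
    for ti in tree_ids:
        tree = trees[ti]
        y = table_traits(table, tree)
        if np.unique(y[:, 0]).size < 2 or np.unique(y[:, 1]).size < 2:
            raise ValueError("both traits must show >= 2 observed categories")
        sampler = _TreeOUSampler(tree, y, coords, config)
        for c in range(config.n_chains):
            seed = int((config.seed + 1) * 100003 + 997 * ti + c) % (2**31)
            runs.append(sampler.run(config.n_iter, config.burn, seed))
            run_tree.append(ti)
    draws = {}
    phi = np.stack([r["phi"] for r in runs])  # (runs, keep, 6)
    draws["A11"] = -np.exp(phi[:, :, 0])
    draws["A22"] = -np.exp(phi[:, :, 1])
    draws["A12"] = phi[:, :, 2]
    draws["A21"] = phi[:, :, 3]
    draws["b1"] = phi[:, :, 4]
    draws["b2"] = phi[:, :, 5]
    cuts = np.stack([r["cuts"] for r in runs])
    draws["cut_pol_1"] = cuts[:, :, 0, 0]
    draws["cut_pol_3"] = cuts[:, :, 0, 2]
    draws["cut_rel_1"] = cuts[:, :, 1, 0]
    draws["cut_rel_3"] = cuts[:, :, 1, 2]
    amp = np.stack([r["amp"] for r in runs])
    ls = np.stack([r["ls"] for r in runs])
    draws["gp_amp_pol"], draws["gp_amp_rel"] = amp[:, :, 0], amp[:, :, 1]
    draws["gp_ls_pol"], draws["gp_ls_rel"] = ls[:, :, 0], ls[:, :, 1]
    liab_mean = np.mean([r["liab_mean"] for r in runs], axis=0)
    mads = np.array([mad(liab_mean[:, 0]), mad(liab_mean[:, 1])])
    mads = np.maximum(mads, 1e-12)
    draws["dtheta_pol_from_rel"] = -(draws["A12"] / draws["A11"]) * mads[1]
    draws["dtheta_rel_from_pol"] = -(draws["A21"] / draws["A22"]) * mads[0]
    node_latents = [r["eta"] for r in runs]
    # diagnostics: per tree, chains within that tree
    reported = [n for n in draws if not n.startswith("gp_")] + (
        ["gp_amp_pol", "gp_amp_rel"] if config.gp else []
    )
    rows = []
    run_tree = np.array(run_tree)
    for name in reported:
        worst_r, min_e = 1.0, np.inf
        for ti in tree_ids:
            sel = draws[name][run_tree == ti]
            if sel.shape[0] >= 2 and np.ptp(sel) > 0:
                worst_r = max(worst_r, rhat(sel))
                min_e = min(min_e, ess(sel))
        rows.append({"parameter": name, "rhat": worst_r, "ess": min_e})
    diag = pd.DataFrame(rows)
    converged = bool(np.all(diag["rhat"] <= 1.01))
    if not converged:
        warnings.warn("coevolution model not converged (R-hat > 1.01)", RuntimeWarning)
    return CoevPosterior(
        draws=draws,
        node_latents=node_latents,
        run_tree_ids=list(run_tree),
        tree_ids=tree_ids,
        trees={t: trees[t] for t in tree_ids},
        mad_per_trait=mads,
        diagnostics=diag,
        converged=converged,
        config=config,
    )


def delta_theta(obj, mad_per_trait=None) -> dict:
    """Standardised directional coevolution effects.

    For an :class:`OUParams`, returns the two point values
    ``-(A[d,e]/A[d,d]) * mad_e``.  For a :class:`CoevPosterior`, returns per
    direction the posterior median, 95% HPDI, posterior probability of being
    positive and the Savage-Dickey 2 ln BF against zero, plus the posterior
    difference between directions.
    """
    if isinstance(obj, OUParams):
        if mad_per_trait is None:
            mad_per_trait = np.ones(2)
        mad_per_trait = np.asarray(mad_per_trait, dtype=float)
        if np.any(mad_per_trait <= 0):
            raise ValueError("MAD must be positive")
        A = obj.A
        return {
            "pol_from_rel": -(A[0, 1] / A[0, 0]) * mad_per_trait[1],
            "rel_from_pol": -(A[1, 0] / A[1, 1]) * mad_per_trait[0],
        }
    post: CoevPosterior = obj
    mads = post.mad_per_trait if mad_per_trait is None else np.asarray(mad_per_trait)
    if np.any(mads <= 0):
        raise ValueError("MAD must be positive")
    out = {}
    for key, mad_e in [("dtheta_pol_from_rel", mads[1]), ("dtheta_rel_from_pol", mads[0])]:
        d = post.pooled(key)
        lo, hi = hpdi(d)
        # prior density of dtheta at 0: dtheta = -A_de/A_dd * mad_e with
        # A_de ~ N(0,1), A_dd = -exp(N(0,1)) independent =>
        # f(0) = phi(0) * E[exp(u)] / mad = phi(0) * e^{1/2} / mad
        prior0 = np.exp(0.5) / (_SQRT2PI * mad_e)
        out[key] = {
            "median": float(np.median(d)),
            "hpdi": (lo, hi),
            "pp": pp_positive(d),
            "logbf": savage_dickey_logbf(d, prior0),
        }
    diff = post.pooled("dtheta_pol_from_rel") - post.pooled("dtheta_rel_from_pol")
    lo, hi = hpdi(diff)
    out["difference"] = {"median": float(np.median(diff)), "hpdi": (lo, hi), "pp": pp_positive(diff)}
    return out


@dataclass
class PhasePlane:
    """Deterministic drift field b + A eta over a latent grid."""

    grid_pol: np.ndarray
    grid_rel: np.ndarray
    field: np.ndarray  # (n, n, 2): d eta / dt at each grid point
    cutpoints: np.ndarray
    stationary_point: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        g1, g2 = np.meshgrid(self.grid_pol, self.grid_rel, indexing="ij")
        return pd.DataFrame(
            {
                "political": g1.ravel(),
                "religious": g2.ravel(),
                "d_political_dt": self.field[:, :, 0].ravel(),
                "d_religious_dt": self.field[:, :, 1].ravel(),
            }
        )


def phase_plane(params: OUParams, grid_bounds=(-3.0, 3.0), grid_n: int = 21) -> PhasePlane:
    """Expected instantaneous change of the latent traits on a grid."""
    lo, hi = grid_bounds
    g = np.linspace(lo, hi, grid_n)
    theta, _ = stationary_moments(params)
    field = np.empty((grid_n, grid_n, 2))
    for i, x in enumerate(g):
        for j, yv in enumerate(g):
            field[i, j] = params.b + params.A @ np.array([x, yv])
    return PhasePlane(g, g, field, params.cutpoints.copy(), theta)


def mrca_node(tree: Phylogeny, labels) -> int:
    """Index of the most recent common ancestor of a set of tip labels."""
    want = set(labels)
    pos = {tree.labels[i]: i for i in tree.tip_indices}
    missing = sorted(want - pos.keys())
    if missing:
        raise KeyError(f"labels not in tree: {missing}")
    paths = []
    for lab in want:
        node = pos[lab]
        path = []
        while node >= 0:
            path.append(node)
            node = tree.parent[node] if node > 0 else -1
        paths.append(set(path))
    common = set.intersection(*paths)
    return max(common)  # deepest (preorder index increases with depth)


def ancestral_states(posterior: CoevPosterior, clades: dict | None = None) -> pd.DataFrame:
    """Median posterior latent values and ordinal-level probabilities for
    ancestral nodes.

    ``clades`` maps clade names to lists of tip labels; within each posterior
    tree the clade's node is the MRCA of those tips (node labels are absent
    from Newick, so clades are addressed by their tip sets).  Default: the
    root.  Per draw the four level probabilities are probit rectangles of the
    node latent against that draw's cutpoints (they sum to 1 within each
    draw; the reported medians across draws need not).
    """
    any_tree = next(iter(posterior.trees.values()))
    clades = clades or {"root": any_tree.tip_labels}
    cut_names = {0: ("cut_pol_1", "cut_pol_3"), 1: ("cut_rel_1", "cut_rel_3")}
    trait_names = ("political", "religious")
    rows = []
    for name, labs in clades.items():
        nodes = {ti: mrca_node(t, labs) for ti, t in posterior.trees.items()}
        for t, tname in enumerate(trait_names):
            e_parts, lo_parts, hi_parts = [], [], []
            for r, (eta_run, ti) in enumerate(zip(posterior.node_latents, posterior.run_tree_ids)):
                e_parts.append(eta_run[:, nodes[ti], t].astype(float))
                lo_parts.append(posterior.draws[cut_names[t][0]][r])
                hi_parts.append(posterior.draws[cut_names[t][1]][r])
            e = np.concatenate(e_parts)
            c1 = np.concatenate(lo_parts)
            c3 = np.concatenate(hi_parts)
            edges = np.column_stack(
                [np.full_like(e, -np.inf), c1, np.zeros_like(e), c3, np.full_like(e, np.inf)]
            )
            probs = ndtr(edges[:, 1:] - e[:, None]) - ndtr(edges[:, :4] - e[:, None])
            med = np.median(probs, axis=0)
            rows.append(
                {
                    "clade": name,
                    "trait": tname,
                    "median_latent": float(np.median(e)),
                    **{f"p_level_{k}": float(med[k]) for k in range(4)},
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RecoveryConfig:
    """Parameter-recovery study settings (desk scale: 20 x 60 tips)."""

    n_replicates: int = 20
    n_tips: int = 60
    seed: int = 0
    true_params: OUParams | None = None
    fit: CoevConfig | None = None

    def resolved_truth(self) -> OUParams:
        if self.true_params is not None:
            return self.true_params
        return OUParams(
            A=np.array([[-1.0, 0.8], [0.0, -1.0]]),
            b=np.zeros(2),
            cutpoints=np.array([[-0.85, 0.0, 0.85], [-0.85, 0.0, 0.85]]),
            gp_amplitude=np.zeros(2),
        )


def recovery_experiment(config: RecoveryConfig | None = None) -> pd.DataFrame:
    """Simulate-and-refit study: per parameter, the fraction of replicates
    whose 95% credible interval covers the generating value."""
    from .simulate import simulate_coevolution, simulate_tree

    config = config or RecoveryConfig()
    truth = config.resolved_truth()
    fit_cfg = config.fit or CoevConfig(
        n_iter=1200, burn=400, gp=bool(np.any(truth.gp_amplitude > 0)), tree_draws=1
    )
    true_vals = {
        "A11": truth.A[0, 0], "A22": truth.A[1, 1],
        "A12": truth.A[0, 1], "A21": truth.A[1, 0],
        "b1": truth.b[0], "b2": truth.b[1],
    }
    cover = {k: [] for k in true_vals}
    for rep in range(config.n_replicates):
        seed = int(config.seed + 1000 * rep)
        tree = simulate_tree(config.n_tips, seed=seed)
        coords = None
        if np.any(truth.gp_amplitude > 0):
            from .simulate import simulate_coords

            coords = simulate_coords(config.n_tips, (-45, 25, 95, 180), seed + 1)
        liab, y = simulate_coevolution(tree, truth, coords, seed + 2)
        table = pd.DataFrame(
            {
                "taxon": tree.tip_labels,
                "political_authority": y[:, 0],
                "religious_authority": y[:, 1],
            }
        )
        cfg = CoevConfig(**{**fit_cfg.__dict__, "seed": seed + 3})
        post = fit_coevolution(table, tree, coords, cfg)
        for k, tv in true_vals.items():
            lo, hi = hpdi(post.pooled(k), 0.95)
            cover[k].append(lo <= tv <= hi)
    return pd.DataFrame(
        [
            {
                "parameter": k,
                "true_value": true_vals[k],
                "coverage": float(np.mean(v)),
                "n_replicates": config.n_replicates,
            }
            for k, v in cover.items()
        ]
    )
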