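"""Bivariate phylogenetic ordinal mixed model: signal and correlation.

Each trait's 4-level ordinal observation arises from a latent liability

    z = g + e,

where the phylogenetic effects g of the two traits are jointly matrix-normal
with between-trait covariance Sigma (standard deviations sigma_1, sigma_2,
correlation rho_phylo) and row covariance C, the tree's Brownian covariance
normalised to unit height; the residuals e are bivariate normal with unit
variances and correlation rho_resid (the probit noise).  Liabilities are cut
into categories by per-trait ordered cutpoints.  The phylogenetic signal is
the liability-scale variance partition

    lambda_t = sigma_t^2 / (sigma_t^2 + 1),

so lambda is invariant to rescaling all branch lengths jointly.

Priors: half-normal(0,1) on the phylogenetic SDs, LKJ(2) on both
correlations, ordered normal(0,2) on cutpoints.  Posterior sampling uses
truncated-normal data augmentation of the liabilities with an
eigendecomposition of C to draw the phylogenetic effects in O(n) blocks, and
Metropolis steps for the covariance parameters.  The model is iterated over
randomly drawn posterior trees and the draws pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import multivariate_normal

from .inference import ess, hpdi, rhat
from .trees import Phylogeny, TreeSample, phylo_vcv

TRAITS = ("political_authority", "religious_authority")

__all__ = [
    "SignalModelParams",
    "SignalConfig",
    "SignalPosterior",
    "lambda_from_variance",
    "signal_loglik",
    "fit_signal_model",
]


@dataclass
class SignalModelParams:
    """Parameters of the bivariate ordinal signal model."""

    sigma2_phylo: np.ndarray  # (2,) per-trait phylogenetic variance
    rho_phylo: float
    rho_resid: float
    cutpoints: np.ndarray  # (2, 3) strictly increasing per trait

    def __post_init__(self) -> None:
        self.sigma2_phylo = np.asarray(self.sigma2_phylo, dtype=float)
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        if np.any(self.sigma2_phylo < 0):
            raise ValueError("phylogenetic variances must be >= 0")
        if not (-1 <= self.rho_phylo <= 1 and -1 <= self.rho_resid <= 1):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.cutpoints.shape != (2, 3) or np.any(np.diff(self.cutpoints, axis=1) <= 0):
            raise ValueError("cutpoints must be strictly increasing triples")

    @property
    def lam(self) -> np.ndarray:
        return lambda_from_variance(self.sigma2_phylo)

    @property
    def Sigma(self) -> np.ndarray:
        s = np.sqrt(self.sigma2_phylo)
        return np.array(
            [
                [s[0] ** 2, self.rho_phylo * s[0] * s[1]],
                [self.rho_phylo * s[0] * s[1], s[1] ** 2],
            ]
        )

    @property
    def R(self) -> np.ndarray:
        return np.array([[1.0, self.rho_resid], [self.rho_resid, 1.0]])


def lambda_from_variance(sigma2) -> np.ndarray | float:
    """Phylogenetic signal sigma^2 / (sigma^2 + 1) (residual variance 1)."""
    s = np.asarray(sigma2, dtype=float)
    if np.any(s < 0):
        raise ValueError("sigma2 must be >= 0")
    out = s / (s + 1.0)
    return float(out) if out.ndim == 0 else out


def tree_correlation(tree: Phylogeny, jitter: float = 1e-10) -> np.ndarray:
    """Brownian tree covariance normalised by its maximum diagonal entry."""
    V = phylo_vcv(tree).values
    C = V / V.diagonal().max()
    return C + jitter * np.eye(C.shape[0])


def _rectangle_logprob(y: np.ndarray, g: np.ndarray, params: SignalModelParams) -> float:
    """Sum over tips of log P(y_i1, y_i2 | g_i): bivariate probit rectangle
    probabilities with residual correlation rho_resid."""
    R = params.R
    cm = np.concatenate(
        [np.full((2, 1), -np.inf), params.cutpoints, np.full((2, 1), np.inf)], axis=1
    )
    total = 0.0
    rho = params.rho_resid
    mvn = multivariate_normal(mean=np.zeros(2), cov=R)
    for i in range(y.shape[0]):
        lo = np.array([cm[0, y[i, 0]], cm[1, y[i, 1]]]) - g[i]
        hi = np.array([cm[0, y[i, 0] + 1], cm[1, y[i, 1] + 1]]) - g[i]
        if rho == 0:
            p = (ndtr(hi[0]) - ndtr(lo[0])) * (ndtr(hi[1]) - ndtr(lo[1]))
        else:
            p = float(mvn.cdf(hi, lower_limit=lo))
        total += np.log(max(p, 1e-300))
    return float(total)


def signal_loglik(
    table: pd.DataFrame,
    tree: Phylogeny,
    params: SignalModelParams,
    phylo_effects: np.ndarray,
) -> float:
    """Log p(data | effects, cutpoints) + log p(effects | tree, Sigma).

    The phylogenetic effects (n_tips, 2) have the Kronecker prior
    ``N(0, Sigma (x) C)``; the data term marginalises the correlated
    residual liabilities into bivariate probit rectangle probabilities.
    """
    y = _table_traits(table, tree)
    n = tree.n_tips
    g = np.asarray(phylo_effects, dtype=float).reshape(n, 2)
    C = tree_correlation(tree)
    total = _rectangle_logprob(y, g, params)
    if np.all(params.sigma2_phylo == 0):
        if np.any(g != 0):
            raise ValueError("nonzero effects with zero phylogenetic variance")
        return total
    Sigma = params.Sigma + 1e-12 * np.eye(2)
    K = np.kron(Sigma, C)  # trait-major stacking (g1..gn of trait 1, then trait 2)
    total += float(
        multivariate_normal.logpdf(g.T.reshape(-1), mean=np.zeros(2 * n), cov=K, allow_singular=True)
    )
    return total


def _table_traits(table: pd.DataFrame, tree: Phylogeny) -> np.ndarray:
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
class SignalConfig:
    n_iter: int = 2500
    burn: int = 800
    n_chains: int = 2
    tree_draws: int = 10
    seed: int = 0

    @classmethod
    def paper_scale(cls, **kw) -> "SignalConfig":
        return cls(n_iter=4000, burn=1000, tree_draws=100, **kw)


def _trunc_normal(rng, mean, sd, lo, hi):
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = a + (b - a) * rng.random(np.shape(mean))
    u = np.clip(u, 1e-15, 1 - 1e-15)
    return mean + sd * ndtri(u)


from .inference import slice_sample_1d as _slice_1d  # noqa: E402


def _chain(y, Q, lamC, n_iter, burn, seed):
    """One Gibbs/Metropolis chain on one tree.

    Q, lamC: eigenvectors / eigenvalues of the tree correlation matrix.
    State: liabilities z (n,2), rotated effects gt (n,2) with prior
    (gt_k1, gt_k2) ~ N(0, lam_k * Sigma), and (log s1, log s2, atanh
    rho_phylo, atanh rho_resid), cutpoints (2,3).
    """
    rng = np.random.default_rng(seed)
    n = y.shape[0]
    cuts = np.array([[-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0]], dtype=float)
    theta = np.array([0.0, 0.0, 0.0, 0.0])  # log s1, log s2, z(rho_p), z(rho_r)
    gt = np.zeros((n, 2))
    z = np.where(y == 0, -1.5, np.where(y == 1, -0.5, np.where(y == 2, 0.5, 1.5))).astype(float)
    n_keep = n_iter - burn
    out = np.empty((n_keep, 4 + 6))  # sigma2_1, sigma2_2, rho_p, rho_r, cutpoints
    kept = 0
    lamC = np.maximum(lamC, 1e-10)
    for it in range(n_iter):
        s = np.exp(theta[:2])
        rho_p = np.tanh(theta[2])
        rho_r = np.tanh(theta[3])
        Sigma = np.array([[s[0] ** 2, rho_p * s[0] * s[1]], [rho_p * s[0] * s[1], s[1] ** 2]])
        g = Q @ gt
        # 1. liabilities, trait by trait given the other (bivariate normal)
        for t in range(2):
            o = 1 - t
            mu = g[:, t] + rho_r * (z[:, o] - g[:, o])
            sd = np.sqrt(max(1.0 - rho_r**2, 1e-12))
            edges = np.concatenate([[-np.inf], cuts[t], [np.inf]])
            z[:, t] = _trunc_normal(rng, mu, sd, edges[y[:, t]], edges[y[:, t] + 1])
        # 2. cutpoints (Gibbs; truncated N(0,2) prior, ordering enforced)
        for t in range(2):
            for j in range(3):
                zlo = z[y[:, t] == j, t]
                zhi = z[y[:, t] == j + 1, t]
                lo = zlo.max() if zlo.size else (cuts[t, j - 1] if j > 0 else -8.0)
                hi = zhi.min() if zhi.size else (cuts[t, j + 1] if j < 2 else 8.0)
                lo = max(lo, cuts[t, j - 1] if j > 0 else -8.0)
                hi = min(hi, cuts[t, j + 1] if j < 2 else 8.0)
                if lo < hi:
                    cuts[t, j] = _trunc_normal(rng, 0.0, 2.0, lo, hi)
        # 3. phylogenetic effects in the eigenbasis: 2x2 block solves
        zt = Q.T @ z
        detS = Sigma[0, 0] * Sigma[1, 1] - Sigma[0, 1] ** 2
        detS = max(detS, 1e-12)
        iS = np.array([[Sigma[1, 1], -Sigma[0, 1]], [-Sigma[0, 1], Sigma[0, 0]]]) / detS
        detR = max(1.0 - rho_r**2, 1e-12)
        iR = np.array([[1.0, -rho_r], [-rho_r, 1.0]]) / detR
        # posterior precision per eigencomponent: iS/lam_k + iR
        p11 = iS[0, 0] / lamC + iR[0, 0]
        p12 = iS[0, 1] / lamC + iR[0, 1]
        p22 = iS[1, 1] / lamC + iR[1, 1]
        h1 = iR[0, 0] * zt[:, 0] + iR[0, 1] * zt[:, 1]
        h2 = iR[1, 0] * zt[:, 0] + iR[1, 1] * zt[:, 1]
        det = p11 * p22 - p12**2
        m1 = (p22 * h1 - p12 * h2) / det
        m2 = (p11 * h2 - p12 * h1) / det
        # sample via 2x2 Cholesky of the precision
        l11 = np.sqrt(p11)
        l21 = p12 / l11
        l22 = np.sqrt(np.maximum(p22 - l21**2, 1e-12))
        e1 = rng.standard_normal(n)
        e2 = rng.standard_normal(n)
        # solve L^T u = e  (upper-triangular back-substitution)
        u2 = e2 / l22
        u1 = (e1 - l21 * u2) / l11
        gt = np.column_stack([m1 + u1, m2 + u2])
        g = Q @ gt
        # 4. Sigma parameters: component-wise slice sampling, centred target
        def sig_logpost(th):
            s_ = np.exp(th[:2])
            rp = np.tanh(th[2])
            quad_det = _matrix_normal_loglik(gt, lamC, s_, rp)
            if not np.isfinite(quad_det):
                return -np.inf
            # half-normal(0,1) on s (+ log-jacobian), LKJ(2) + atanh jacobian
            prior = float(-0.5 * (s_ @ s_) + th[0] + th[1])
            prior += np.log1p(-rp**2) + np.log1p(-rp**2)
            return quad_det + prior

        for j in range(3):
            def f(v, j=j):
                th = theta.copy()
                th[j] = v
                return sig_logpost(th)

            theta[j] = _slice_1d(f, theta[j], rng, w=0.6, lo=-8, hi=4 if j < 2 else 8)
        # 4b. interweaved (non-centred) update: hold the whitened effects
        # u_k = L^{-1} gt_k / sqrt(lam_k) fixed while moving Sigma, so the
        # likelihood through z drives the move (breaks the g-Sigma coupling
        # that makes the centred step a slow random walk).
        def chol2(th):
            s_ = np.exp(th[:2])
            rp = np.tanh(th[2])
            return s_[0], rp * s_[1], s_[1] * np.sqrt(max(1 - rp**2, 1e-12))

        l11, l21, l22 = chol2(theta)
        sq = np.sqrt(lamC)
        u1 = gt[:, 0] / (l11 * sq)
        u2 = (gt[:, 1] / sq - l21 * u1) / l22
        Qu1, Qu2 = Q @ (sq * u1), Q @ (sq * u2)
        rr_cur = np.tanh(theta[3])
        d_cur = max(1.0 - rr_cur**2, 1e-12)

        def nc_logpost(th):
            m11, m21, m22 = chol2(th)
            r1 = z[:, 0] - m11 * Qu1
            r2 = z[:, 1] - (m21 * Qu1 + m22 * Qu2)
            q = (r1**2 - 2 * rr_cur * r1 * r2 + r2**2) / d_cur
            s_ = np.exp(th[:2])
            rp = np.tanh(th[2])
            prior = float(-0.5 * (s_ @ s_) + th[0] + th[1]) + 2 * np.log1p(-(rp**2))
            return -0.5 * float(q.sum()) + prior

        for j in range(3):
            def fnc(v, j=j):
                th = theta.copy()
                th[j] = v
                return nc_logpost(th)

            theta[j] = _slice_1d(fnc, theta[j], rng, w=0.6, lo=-8, hi=4 if j < 2 else 8)
        m11, m21, m22 = chol2(theta)
        gt = np.column_stack([sq * m11 * u1, sq * (m21 * u1 + m22 * u2)])
        g = Q @ gt
        # 5. residual correlation (slice on the atanh scale)
        e = z - g

        def rho_logpost(zr):
            rr = np.tanh(zr)
            d = 1.0 - rr**2
            q = (e[:, 0] ** 2 - 2 * rr * e[:, 0] * e[:, 1] + e[:, 1] ** 2) / d
            return -0.5 * float(q.sum()) - 0.5 * n * np.log(d) + 2 * np.log1p(-(rr**2))

        theta[3] = _slice_1d(rho_logpost, theta[3], rng, w=0.4, lo=-6, hi=6)
        if it >= burn:
            s = np.exp(theta[:2])
            out[kept, 0:2] = s**2
            out[kept, 2] = np.tanh(theta[2])
            out[kept, 3] = np.tanh(theta[3])
            out[kept, 4:7] = cuts[0]
            out[kept, 7:10] = cuts[1]
            kept += 1
    return out


def _matrix_normal_loglik(gt, lamC, s, rho) -> float:
    """log N(gt_k; 0, lam_k Sigma) summed over eigencomponents."""
    detS = (s[0] * s[1]) ** 2 * (1 - rho**2)
    if detS <= 0:
        return -np.inf
    iS = (
        np.array([[s[1] ** 2, -rho * s[0] * s[1]], [-rho * s[0] * s[1], s[0] ** 2]]) / detS
    )
    quad = (
        iS[0, 0] * gt[:, 0] ** 2 + 2 * iS[0, 1] * gt[:, 0] * gt[:, 1] + iS[1, 1] * gt[:, 1] ** 2
    ) / lamC
    return float(-0.5 * quad.sum() - 0.5 * (np.log(detS) + 2 * np.log(lamC)).sum())


_PARAM_NAMES = [
    "sigma2_pol", "sigma2_rel", "rho_phylo", "rho_resid",
    "cut_pol_1", "cut_pol_2", "cut_pol_3",
    "cut_rel_1", "cut_rel_2", "cut_rel_3",
]


@dataclass
class SignalPosterior:
    """Pooled posterior for the signal model (lambda draws are derived)."""

    draws: dict  # name -> (n_runs, n_keep)
    run_tree_ids: list[int]
    tree_ids: list[int]
    diagnostics: pd.DataFrame
    converged: bool
    config: SignalConfig

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].ravel()

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        rows = []
        diag = self.diagnostics.set_index("parameter")
        for name, arr in self.draws.items():
            lo, hi = hpdi(arr.ravel(), mass)
            rows.append(
                {
                    "parameter": name,
                    "median": float(np.median(arr)),
                    "hpdi_low": lo,
                    "hpdi_high": hi,
                    "rhat": float(diag["rhat"].get(name, np.nan)),
                    "ess": float(diag["ess"].get(name, np.nan)),
                }
            )
        return pd.DataFrame(rows)


def fit_signal_model(
    table: pd.DataFrame,
    trees: TreeSample | Phylogeny,
    config: SignalConfig | None = None,
) -> SignalPosterior:
    """Posterior for signal and correlation, pooled over posterior trees.

    Runs ``n_chains`` chains on each of ``tree_draws`` randomly selected
    trees.  Reports per-trait lambda, the phylogenetic and residual
    correlations and cutpoints; the convergence flag requires split R-hat
    <= 1.05 on all reported parameters within each tree.
    """
    config = config or SignalConfig()
    if isinstance(trees, Phylogeny):
        trees = TreeSample([trees])
    any_y = _table_traits(table, trees[0])
    if any_y.shape[0] < 10:
        raise ValueError("need >= 10 taxa")
    if np.unique(any_y[:, 0]).size < 2 or np.unique(any_y[:, 1]).size < 2:
        raise ValueError("each trait needs >= 2 observed categories")
    rng = np.random.default_rng(config.seed)
    k = min(config.tree_draws, len(trees))
    tree_ids = sorted(rng.choice(len(trees), size=k, replace=False).tolist())
    chains = []
    run_tree = []
    for ti in tree_ids:
        tree = trees[ti]
        y = _table_traits(table, tree)
        C = tree_correlation(tree)
        lamC, Q = np.linalg.eigh(C)
        for c in range(config.n_chains):
            seed = int((config.seed + 1) * 90007 + 991 * ti + c) % (2**31)
            out = _chain(y, Q, lamC, config.n_iter, config.burn, seed)
            chains.append(out)
            run_tree.append(ti)
    arr = np.stack(chains)  # (runs, keep, 10)
    draws = {name: arr[:, :, i] for i, name in enumerate(_PARAM_NAMES)}
    draws["lambda_pol"] = lambda_from_variance(draws["sigma2_pol"])
    draws["lambda_rel"] = lambda_from_variance(draws["sigma2_rel"])
    run_tree_arr = np.array(run_tree)
    reported = ["lambda_pol", "lambda_rel", "rho_phylo", "rho_resid"]
    rows = []
    for name in reported:
        worst_r, min_e = 1.0, np.inf
        for ti in tree_ids:
            sel = draws[name][run_tree_arr == ti]
            if sel.shape[0] >= 2 and np.ptp(sel) > 0:
                worst_r = max(worst_r, rhat(sel))
                min_e = min(min_e, ess(sel))
        rows.append({"parameter": name, "rhat": worst_r, "ess": min_e})
    diag = pd.DataFrame(rows)
    converged = bool(np.all(diag["rhat"] <= 1.05))
    if not converged:
        warnings.warn("signal model not converged (R-hat > 1.05)", RuntimeWarning)
    return SignalPosterior(
        draws=draws,
        run_tree_ids=list(run_tree),
        tree_ids=tree_ids,
        diagnostics=diag,
        converged=converged,
        config=config,
    )
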