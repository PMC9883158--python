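"""Shared Bayesian inference machinery.

Convergence diagnostics (split R-hat, effective sample size), posterior
summaries (median, highest-posterior-density intervals, posterior mass above
zero), robust scale (median absolute deviation), Savage-Dickey Bayes factors,
a reference adaptive random-walk Metropolis sampler, and a generic
stepping-stone marginal-likelihood estimator.

Conventions used throughout the package:

* chains are arrays of shape ``(n_chains, n_iterations)`` per scalar
  parameter, or ``(n_chains, n_iterations, n_params)`` for vectors;
* the MAD is the raw median absolute deviation, *without* the 1.4826
  normal-consistency factor;
* log Bayes factors follow the "twice the natural log" convention
  (Kass-Raftery scale: 0-2 bare mention, 2-6 positive, 6-10 strong,
  >=10 very strong).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "ChainSet",
    "Summary",
    "rhat",
    "ess",
    "hpdi",
    "mad",
    "pp_positive",
    "savage_dickey_logbf",
    "summarize",
    "adaptive_metropolis",
    "stepping_stone",
]


@dataclass
class ChainSet:
    """Posterior draws from a set of MCMC chains.

    Attributes
    ----------
    draws : ndarray, shape (n_chains, n_iter, n_params)
        Post-burn-in parameter draws.
    names : list of str
        Parameter names, length ``n_params``.
    seeds : list of int
        Seed used for each chain.
    accept_rate : ndarray, shape (n_chains,)
        Mean Metropolis acceptance rate per chain.
    """

    draws: np.ndarray
    names: list[str]
    seeds: list[int] = field(default_factory=list)
    accept_rate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must have shape (n_chains, n_iter, n_params)")
        if self.draws.shape[2] != len(self.names):
            raise ValueError("names length must match n_params")

    def get(self, name: str) -> np.ndarray:
        """Draws for one named parameter, shape (n_chains, n_iter)."""
        return self.draws[:, :, self.names.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        """Flattened draws for one parameter across all chains."""
        return self.get(name).ravel()


@dataclass
class Summary:
    median: float
    hpdi_low: float
    hpdi_high: float
    pp_positive: float
    rhat: float
    ess: float
    mass: float = 0.95


def rhat(chains: np.ndarray) -> float:
    """Split potential-scale-reduction factor R-hat.

    Each chain is split in half and the classic Gelman-Rubin statistic is
    computed on the resulting ``2m`` half-chains: with within-chain variance
    W and between-chain variance B,

        R-hat = sqrt( ( (n-1)/n * W + B/n ) / W ).

    Parameters
    ----------
    chains : array, shape (n_chains, n_iter)
        Requires at least 2 chains of length >= 4.

    Returns
    -------
    float -- NaN (with a warning) if all draws are identical.
    """
    c = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = c.shape
    if m < 2 or n < 4:
        raise ValueError("rhat needs >= 2 chains of length >= 4")
    half = n // 2
    splits = np.concatenate([c[:, :half], c[:, n - half :]], axis=0)
    if np.ptp(splits) == 0:
        warnings.warn("constant chains: R-hat undefined", RuntimeWarning)
        return float("nan")
    n = half
    means = splits.mean(axis=1)
    w = splits.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return float("inf")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def ess(chains: np.ndarray) -> float:
    """Effective sample size from pairwise-summed autocorrelations.

    Uses the standard initial-monotone-positive-sequence truncation of the
    chain autocorrelation function, averaged across chains (Geyer-style),
    on split chains.
    """
    c = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = c.shape
    if n < 4:
        raise ValueError("ess needs chain length >= 4")
    if np.ptp(c) == 0:
        return float("nan")
    # mean autocovariance across chains via FFT
    x = c - c.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real
    acov /= n
    w = acov.mean(axis=0)
    b = n * c.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * w[0] + b / n
    if var_plus <= 0:
        return float(m * n)
    rho = 1.0 - (w[0] - w) / var_plus
    # Geyer initial monotone positive sequence on paired sums
    tau = 0.0
    prev = np.inf
    for t in range(0, n - 1, 2):
        pair = rho[t] + rho[t + 1] if t + 1 < n else rho[t]
        if pair < 0:
            break
        pair = min(pair, prev)
        prev = pair
        tau += pair
    tau = max(2 * tau - 1.0, 1.0 / (m * n))
    return float(min(m * n / tau, m * n))


def hpdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``mass`` of the draws.

    Sorted-window method: among all windows of ``ceil(mass*n)`` consecutive
    order statistics, return the narrowest.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 2:
        return (float(x[0]), float(x[0])) if n else (np.nan, np.nan)
    k = int(np.ceil(mass * n))
    k = min(k, n)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def mad(values: np.ndarray) -> float:
    """Raw median absolute deviation, median(|x - median(x)|)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("mad of empty array")
    return float(np.median(np.abs(v - np.median(v))))


def pp_positive(draws: np.ndarray) -> float:
    """Posterior probability of being positive: fraction of draws > 0."""
    d = np.asarray(draws, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("pp_positive of empty array")
    return float(np.mean(d > 0))


def savage_dickey_logbf(
    posterior_draws: np.ndarray,
    prior_density_at_0: float,
    bandwidth: str | float = "silverman",
) -> float:
    """Savage-Dickey log Bayes factor against a point null at zero.

    Returns ``2 * ln(p_prior(0) / p_posterior(0))`` where the posterior
    density at 0 is estimated with a Gaussian KDE (Silverman bandwidth by
    default).  Positive values favour a nonzero parameter.
    """
    d = np.asarray(posterior_draws, dtype=float).ravel()
    if d.size < 500:
        raise ValueError("need >= 500 posterior draws for a stable KDE")
    if not np.isfinite(prior_density_at_0) or prior_density_at_0 <= 0:
        raise ValueError("prior density at 0 must be finite and positive")
    if np.ptp(d) == 0:
        post0 = np.inf if d[0] == 0 else 0.0
    else:
        kde = stats.gaussian_kde(d, bw_method=bandwidth)
        post0 = float(kde(0.0)[0])
    if post0 == 0:
        warnings.warn("estimated posterior density at 0 is zero", RuntimeWarning)
        return float("inf")
    return float(2.0 * (np.log(prior_density_at_0) - np.log(post0)))


def summarize(chains: np.ndarray, mass: float = 0.95) -> Summary:
    """Median / HPDI / PP>0 / R-hat / ESS summary of one parameter's chains."""
    c = np.atleast_2d(np.asarray(chains, dtype=float))
    pooled = c.ravel()
    lo, hi = hpdi(pooled, mass)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = rhat(c) if c.shape[0] >= 2 and c.shape[1] >= 4 else float("nan")
        e = ess(c) if c.shape[1] >= 4 else float("nan")
    return Summary(
        median=float(np.median(pooled)),
        hpdi_low=lo,
        hpdi_high=hi,
        pp_positive=pp_positive(pooled),
        rhat=r,
        ess=e,
        mass=mass,
    )


def slice_sample_1d(logf, x0, rng, w=0.6, max_steps=30, lo=-np.inf, hi=np.inf):
    """Univariate slice sampling with stepping-out (Neal 2003).

    Returns a new point whose stationary distribution is proportional to
    ``exp(logf)``; used for poorly scaled conditionals where random-walk
    Metropolis would need per-parameter tuning.
    """
    f0 = logf(x0)
    if not np.isfinite(f0):
        return x0
    level = f0 - rng.exponential()
    u = rng.random()
    left, right = x0 - u * w, x0 + (1 - u) * w
    for _ in range(max_steps):
        if left <= lo or logf(left) < level:
            break
        left -= w
    for _ in range(max_steps):
        if right >= hi or logf(right) < level:
            break
        right += w
    left, right = max(left, lo), min(right, hi)
    for _ in range(100):
        x1 = left + (right - left) * rng.random()
        if logf(x1) >= level:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


def adaptive_metropolis(
    logpost,
    x0: np.ndarray,
    n_iter: int = 5000,
    burn: int | None = None,
    n_chains: int = 2,
    seed: int = 0,
    init_scale: float = 0.3,
    names: list[str] | None = None,
    jitter: float = 0.1,
) -> ChainSet:
    """Reference adaptive random-walk Metropolis sampler.

    Gaussian proposals whose covariance adapts to the running empirical
    covariance of the chain during burn-in (frozen afterwards, so the
    post-burn-in chain is a valid Markov chain).  Deterministic under
    ``seed``; chain ``j`` uses seed ``seed + j``.

    Parameters
    ----------
    logpost : callable(ndarray) -> float
        Log posterior density (up to a constant).
    x0 : ndarray
        Initial parameter vector (chains are jittered around it).
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    d = x0.size
    if burn is None:
        burn = n_iter // 5
    names = names or [f"p{i}" for i in range(d)]
    all_draws = np.empty((n_chains, n_iter - burn, d))
    acc_rates = np.empty(n_chains)
    seeds = [int(seed + j) for j in range(n_chains)]
    for j in range(n_chains):
        rng = np.random.default_rng(seeds[j])
        x = x0 + jitter * rng.standard_normal(d)
        lp = logpost(x)
        while not np.isfinite(lp):
            x = x0 + jitter * rng.standard_normal(d)
            lp = logpost(x)
        scale = init_scale
        chol = np.eye(d)
        mean = x.copy()
        cov = np.eye(d)
        n_acc = 0
        kept = 0
        for it in range(n_iter):
            prop = x + scale * chol @ rng.standard_normal(d)
            lp_prop = logpost(prop)
            if np.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                n_acc += 1
            if it < burn:
                # Robbins-Monro scale targeting 0.234 + running covariance
                w = 1.0 / (it + 2)
                delta = x - mean
                mean += w * delta
                cov = (1 - w) * cov + w * np.outer(delta, delta)
                scale *= np.exp(w * ((1.0 if x is prop else 0.0) - 0.234))
                if (it + 1) % 100 == 0:
                    try:
                        chol = np.linalg.cholesky(cov + 1e-9 * np.eye(d))
                    except np.linalg.LinAlgError:
                        pass
            else:
                all_draws[j, kept] = x
                kept += 1
        acc_rates[j] = n_acc / n_iter
    return ChainSet(all_draws, names, seeds=seeds, accept_rate=acc_rates)


def stepping_stone(
    loglik,
    sample_power_posterior,
    n_stones: int = 20,
    n_iter: int = 5000,
    seed: int = 0,
    alpha: float = 0.3,
) -> float:
    """Generic stepping-stone estimate of the log marginal likelihood.

    The path of power posteriors ``p_beta(x) \\propto prior(x) * lik(x)^beta``
    is discretised at ``beta_k = (k/K)^(1/alpha)`` (quantiles of a
    Beta(alpha, 1), concentrating stones near the prior).  For each stone the
    caller-supplied ``sample_power_posterior(beta, n_iter, seed)`` must return
    draws from ``p_beta``; ``loglik`` maps a draw to its log likelihood.  Then

        log ML = sum_k log mean_j exp((beta_{k+1}-beta_k) * loglik(x_jk))

    computed with log-sum-exp throughout.
    """
    k = np.arange(n_stones + 1)
    betas = (k / n_stones) ** (1.0 / alpha)
    logml = 0.0
    for i in range(n_stones):
        draws = sample_power_posterior(betas[i], n_iter, seed + i)
        lls = np.array([loglik(x) for x in draws])
        delta = betas[i + 1] - betas[i]
        logml += logsumexp(delta * lls) - np.log(len(lls))
    return float(logml)
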