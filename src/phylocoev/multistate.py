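"""Constrained 4-state Markov models of authority-structure evolution.

The trait "structure of religious and political authority" takes four
ordered states: 0 = none, 1 = combined, 2 = partly independent,
3 = independent.  Evolution along the tree is a continuous-time Markov
chain with generator Q.  Five model structures are compared:

* ``full`` - all 12 transition rates free;
* ``strong_differentiation`` - q02 = q03 = q13 = 0 (strictly 1 -> 2 -> 3);
* ``weak_differentiation`` - q02 = q03 = 0 (1 -> 3 also allowed);
* ``strong_unification`` - q01 = q02 = q31 = 0 (strictly 3 -> 2 -> 1);
* ``weak_unification`` - q01 = q02 = 0 (3 -> 1 also allowed).

Free rates get an Exponential(mean m) prior with the mean itself uniform on
(0, 10).  Marginal likelihoods are estimated by stepping-stone sampling and
models are compared on the 2 ln BF (Kass-Raftery) scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.special import logsumexp

from .inference import ChainSet
from .trees import Phylogeny, TreeSample

N_STATES = 4
STATE_LABELS = {0: "none", 1: "combined", 2: "partly independent", 3: "independent"}

MASKS = {
    "full": frozenset(),
    "strong_differentiation": frozenset({(0, 2), (0, 3), (1, 3)}),
    "weak_differentiation": frozenset({(0, 2), (0, 3)}),
    "strong_unification": frozenset({(0, 1), (0, 2), (3, 1)}),
    "weak_unification": frozenset({(0, 1), (0, 2)}),
}

KASS_RAFTERY = [
    (2.0, "not worth more than a bare mention"),
    (6.0, "positive evidence"),
    (10.0, "strong evidence"),
    (np.inf, "very strong evidence"),
]

__all__ = [
    "RateModel",
    "ModelComparison",
    "MultistateConfig",
    "build_rate_model",
    "transition_probabilities",
    "pruning_loglik",
    "fit_multistate_mcmc",
    "stepping_stone_logml",
    "compare_models",
    "max_likelihood_fit",
    "MASKS",
    "STATE_LABELS",
]


@dataclass
class RateModel:
    """A 4-state CTMC with a named forbidden-transition mask."""

    name: str
    mask: frozenset
    rates: np.ndarray  # (4, 4) off-diagonal rates; masked entries 0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (N_STATES, N_STATES):
            raise ValueError("rates must be 4x4")
        off = ~np.eye(N_STATES, dtype=bool)
        if np.any(self.rates[off] < 0):
            raise ValueError("negative transition rate")
        for i, j in self.mask:
            if self.rates[i, j] != 0:
                raise ValueError(f"masked rate q{i}{j} must be 0")

    @property
    def free_pairs(self) -> list[tuple[int, int]]:
        """Ordered state pairs whose rate is free under the mask."""
        return [
            (i, j)
            for i in range(N_STATES)
            for j in range(N_STATES)
            if i != j and (i, j) not in self.mask
        ]

    @property
    def Q(self) -> np.ndarray:
        """Generator matrix: off-diagonal rates, rows summing to zero."""
        q = self.rates.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def with_rates(self, free_rates: np.ndarray) -> "RateModel":
        """New model with the free rates replaced (in free_pairs order)."""
        r = np.zeros((N_STATES, N_STATES))
        for v, (i, j) in zip(free_rates, self.free_pairs):
            r[i, j] = v
        return RateModel(self.name, self.mask, r)

    def stationary(self) -> np.ndarray:
        """Stationary distribution of Q (requires irreducibility)."""
        q = self.Q
        M = np.vstack([q.T, np.ones(N_STATES)])
        rhs = np.zeros(N_STATES + 1)
        rhs[-1] = 1.0
        pi, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        if np.any(pi < -1e-8):
            raise ValueError("Q not irreducible: no valid stationary distribution")
        return np.clip(pi, 0, None) / pi.sum()


def build_rate_model(name: str, rates: np.ndarray | None = None) -> RateModel:
    """Construct one of the five named models (default rate 1 on free pairs)."""
    if name not in MASKS:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(MASKS)}")
    mask = MASKS[name]
    if rates is None:
        r = np.ones((N_STATES, N_STATES))
        np.fill_diagonal(r, 0.0)
        for i, j in mask:
            r[i, j] = 0.0
    else:
        r = np.asarray(rates, dtype=float).copy()
        np.fill_diagonal(r, 0.0)
        for i, j in mask:
            r[i, j] = 0.0
    return RateModel(name, mask, r)


def transition_probabilities(q: RateModel, t: float) -> np.ndarray:
    """Transition probability matrix exp(Qt)."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    return expm(q.Q * t)


# ---------------------------------------------------------------------------
# Pruning likelihood (Felsenstein); numpy reference + numba fast path.
# ---------------------------------------------------------------------------


def _tree_arrays(tree: Phylogeny, states: dict) -> tuple:
    """Flattened arrays for the pruning recursion.

    states maps tip label -> 0..3 (or -1 / missing for an all-ones partial).
    """
    n = tree.n_nodes
    nchild = np.zeros(n, dtype=np.int64)
    for i in range(1, n):
        nchild[tree.parent[i]] += 1
    ptr = np.zeros(n + 1, dtype=np.int64)
    ptr[1:] = np.cumsum(nchild)
    cidx = np.empty(max(n - 1, 1), dtype=np.int64)
    fill = ptr[:-1].copy()
    for i in range(1, n):
        p = tree.parent[i]
        cidx[fill[p]] = i
        fill[p] += 1
    tipstate = np.full(n, -9, dtype=np.int64)
    for i in tree.tip_indices:
        lab = tree.labels[i]
        if lab not in states:
            raise KeyError(f"no state for tip {lab!r}")
        s = states[lab]
        s = -1 if s is None else int(s)
        if s != -1 and not 0 <= s < N_STATES:
            raise ValueError(f"state {s} outside 0..{N_STATES - 1} for tip {lab!r}")
        tipstate[i] = s
    return ptr, cidx, tree.edge_length.copy(), tipstate


def pruning_loglik(
    tree: Phylogeny, states: dict, q: RateModel, root_freq: np.ndarray | None = None
) -> float:
    """Log likelihood of tip states under the CTMC, by Felsenstein pruning.

    ``root_freq`` defaults to uniform over the four states.  Missing tip
    states (``-1`` or ``None``) contribute an all-ones partial.
    """
    if root_freq is None:
        root_freq = np.full(N_STATES, 0.25)
    root_freq = np.asarray(root_freq, dtype=float)
    ptr, cidx, elen, tipstate = _tree_arrays(tree, states)
    Q = q.Q
    partial = np.ones((tree.n_nodes, N_STATES))
    logscale = 0.0
    for i in tree.postorder():
        kids = cidx[ptr[i] : ptr[i + 1]]
        if kids.size == 0:
            if tipstate[i] >= 0:
                partial[i] = 0.0
                partial[i, tipstate[i]] = 1.0
            continue
        for c in kids:
            P = expm(Q * elen[c])
            partial[i] *= P @ partial[c]
        mx = partial[i].max()
        if mx <= 0:
            return -np.inf
        partial[i] /= mx
        logscale += np.log(mx)
    lik = float(root_freq @ partial[0])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logscale)


@njit(cache=True, fastmath=True)
def _loglik_core(Qc, ptr, cidx, elen, tipstate, root_freq):  # pragma: no cover
    n = ptr.shape[0] - 1
    lam, P = np.linalg.eig(Qc)
    Pinv = np.linalg.inv(P)
    real_spec = True
    for u in range(N_STATES):
        if abs(lam[u].imag) > 1e-10:
            real_spec = False
    partial = np.ones((n, N_STATES))
    logscale = 0.0
    if real_spec:
        # real arithmetic path (generic competing-rates generators):
        # rotate each eigenvector's phase so components are real
        Pr = np.empty((N_STATES, N_STATES))
        Pir = np.empty((N_STATES, N_STATES))
        lamr = np.empty(N_STATES)
        for u in range(N_STATES):
            lamr[u] = lam[u].real
            big = 0
            for r in range(1, N_STATES):
                if abs(P[r, u]) > abs(P[big, u]):
                    big = r
            ph = P[big, u] / abs(P[big, u])
            for r in range(N_STATES):
                Pr[r, u] = (P[r, u] / ph).real
                Pir[u, r] = (Pinv[u, r] * ph).real
        w = np.empty(N_STATES)
        for i in range(n - 1, -1, -1):
            lo, hi = ptr[i], ptr[i + 1]
            if hi == lo:
                if tipstate[i] >= 0:
                    for s in range(N_STATES):
                        partial[i, s] = 0.0
                    partial[i, tipstate[i]] = 1.0
                continue
            for k in range(lo, hi):
                c = cidx[k]
                for u in range(N_STATES):
                    acc = 0.0
                    for s in range(N_STATES):
                        acc += Pir[u, s] * partial[c, s]
                    w[u] = acc * np.exp(lamr[u] * elen[c])
                for r in range(N_STATES):
                    acc = 0.0
                    for u in range(N_STATES):
                        acc += Pr[r, u] * w[u]
                    if acc < 1e-300:
                        acc = 1e-300
                    partial[i, r] *= acc
            mx = 0.0
            for s in range(N_STATES):
                if partial[i, s] > mx:
                    mx = partial[i, s]
            if mx <= 0.0 or not np.isfinite(mx):
                return -np.inf
            for s in range(N_STATES):
                partial[i, s] /= mx
            logscale += np.log(mx)
    else:
        wc = np.empty(N_STATES, dtype=np.complex128)
        for i in range(n - 1, -1, -1):
            lo, hi = ptr[i], ptr[i + 1]
            if hi == lo:
                if tipstate[i] >= 0:
                    for s in range(N_STATES):
                        partial[i, s] = 0.0
                    partial[i, tipstate[i]] = 1.0
                continue
            for k in range(lo, hi):
                c = cidx[k]
                # exp(Q t) @ partial_c == P diag(e^{lam t}) Pinv partial_c
                for u in range(N_STATES):
                    acc = 0.0 + 0.0j
                    for s in range(N_STATES):
                        acc += Pinv[u, s] * partial[c, s]
                    wc[u] = acc * np.exp(lam[u] * elen[c])
                for r in range(N_STATES):
                    acc = 0.0 + 0.0j
                    for u in range(N_STATES):
                        acc += P[r, u] * wc[u]
                    p = acc.real
                    if p < 1e-300:
                        p = 1e-300
                    partial[i, r] *= p
            mx = 0.0
            for s in range(N_STATES):
                if partial[i, s] > mx:
                    mx = partial[i, s]
            if mx <= 0.0 or not np.isfinite(mx):
                return -np.inf
            for s in range(N_STATES):
                partial[i, s] /= mx
            logscale += np.log(mx)
    lik = 0.0
    for s in range(N_STATES):
        lik += root_freq[s] * partial[0, s]
    if lik <= 0.0:
        return -np.inf
    return np.log(lik) + logscale


@njit(cache=True)
def _mcmc_core(  # pragma: no cover
    ptr_all,
    cidx_all,
    elen_all,
    tip_all,
    n_trees,
    free_i,
    free_j,
    root_freq,
    beta,
    n_iter,
    burn,
    seed,
    step_rate,
    step_m,
    init_logr,
    init_m,
):
    np.random.seed(seed)
    k = free_i.shape[0]
    logr = init_logr.copy()
    m = init_m
    Qc = np.zeros((N_STATES, N_STATES), dtype=np.complex128)

    def build_Q(logr_):
        for a in range(N_STATES):
            for bb in range(N_STATES):
                Qc[a, bb] = 0.0
        for idx in range(k):
            Qc[free_i[idx], free_j[idx]] = np.exp(logr_[idx])
        for a in range(N_STATES):
            tot = 0.0 + 0.0j
            for bb in range(N_STATES):
                if bb != a:
                    tot += Qc[a, bb]
            Qc[a, a] = -tot

    def loglik(logr_, ti):
        build_Q(logr_)
        return _loglik_core(
            Qc.copy(),
            ptr_all[ti],
            cidx_all[ti],
            elen_all[ti],
            tip_all[ti],
            root_freq,
        )

    def logprior(logr_, m_):
        # rates ~ Exp(mean m), params are log rates (Jacobian sum(logr))
        s = 0.0
        for idx in range(k):
            r = np.exp(logr_[idx])
            s += -np.log(m_) - r / m_ + logr_[idx]
        return s

    n_keep = n_iter - burn
    draws = np.empty((n_keep, k + 1))
    lls = np.empty(n_keep)
    ti = np.random.randint(n_trees)
    cur_ll = loglik(logr, ti)
    cur_lp = logprior(logr, m)
    n_acc = 0
    kept = 0
    for it in range(n_iter):
        if n_trees > 1:
            ti = np.random.randint(n_trees)
            cur_ll = loglik(logr, ti)
        # joint random-walk on log rates
        prop = logr + step_rate * np.random.standard_normal(k)
        ok = True
        for idx in range(k):
            if prop[idx] < -25.0 or prop[idx] > 10.0:
                ok = False
        if ok:
            prop_ll = loglik(prop, ti)
            prop_lp = logprior(prop, m)
            if np.isfinite(prop_ll) and np.log(np.random.random()) < beta * (
                prop_ll - cur_ll
            ) + (prop_lp - cur_lp):
                logr = prop
                cur_ll = prop_ll
                cur_lp = prop_lp
                n_acc += 1
        # random-walk on the exponential mean m, reflected into (0, 10)
        mp = m + step_m * np.random.standard_normal()
        if mp < 0.0:
            mp = -mp
        if mp > 10.0:
            mp = 20.0 - mp
        if 0.0 < mp < 10.0:
            lp_mp = logprior(logr, mp)
            if np.log(np.random.random()) < lp_mp - cur_lp:
                m = mp
                cur_lp = lp_mp
        if it >= burn:
            for idx in range(k):
                draws[kept, idx] = np.exp(logr[idx])
            draws[kept, k] = m
            lls[kept] = cur_ll
            kept += 1
    return draws, lls, n_acc / n_iter


def _pack_trees(trees: TreeSample | Phylogeny, states: dict):
    if isinstance(trees, Phylogeny):
        trees = TreeSample([trees])
    packs = [_tree_arrays(t, states) for t in trees.trees]
    nmax = max(t.n_nodes for t in trees.trees)
    nt = len(packs)
    ptr_all = np.zeros((nt, nmax + 1), dtype=np.int64)
    cidx_all = np.zeros((nt, max(nmax - 1, 1)), dtype=np.int64)
    elen_all = np.zeros((nt, nmax))
    tip_all = np.full((nt, nmax), -9, dtype=np.int64)
    for i, (ptr, cidx, elen, tip) in enumerate(packs):
        n = elen.size
        ptr_all[i, : n + 1] = ptr
        ptr_all[i, n + 1 :] = ptr[-1]
        cidx_all[i, : cidx.size] = cidx
        elen_all[i, :n] = elen
        tip_all[i, :n] = tip
    return ptr_all, cidx_all, elen_all, tip_all, nt


@dataclass
class MultistateConfig:
    """MCMC / stepping-stone settings.  The defaults are desk-scale;
    ``paper_scale()`` gives full production run lengths."""

    n_iter: int = 100_000
    burn_frac: float = 0.1
    n_chains: int = 3
    n_stones: int = 20
    stone_iter: int = 3000
    stone_alpha: float = 0.3
    step_rate: float = 0.35
    step_m: float = 0.8
    root_freq: str = "uniform"  # or "stationary"
    seed: int = 0

    @classmethod
    def paper_scale(cls, **kw) -> "MultistateConfig":
        return cls(n_iter=100_000_000, burn_frac=0.1, n_stones=100, stone_iter=100_000, **kw)


def _root_freq_vec(config: MultistateConfig, model: RateModel) -> np.ndarray:
    if config.root_freq == "uniform":
        return np.full(N_STATES, 0.25)
    if config.root_freq == "stationary":
        return model.stationary()
    raise ValueError("root_freq must be 'uniform' or 'stationary'")


def fit_multistate_mcmc(
    trees: TreeSample | Phylogeny,
    states: dict,
    model: RateModel,
    config: MultistateConfig | None = None,
) -> ChainSet:
    """Posterior over free transition rates and the prior-mean hyperparameter.

    Metropolis-within-Gibbs on log rates with prior rate ~ Exp(mean m),
    m ~ Uniform(0, 10); one tree is drawn uniformly from the sample at each
    iteration.  Runs ``n_chains`` independent replicate chains.
    """
    config = config or MultistateConfig()
    if len({v for v in states.values() if v is not None and v >= 0}) < 2:
        warnings.warn(
            "fewer than 2 distinct observed states: the posterior is prior-dominated",
            RuntimeWarning,
        )
    ptr_all, cidx_all, elen_all, tip_all, nt = _pack_trees(trees, states)
    root_freq = _root_freq_vec(config, model)
    free = model.free_pairs
    fi = np.array([p[0] for p in free], dtype=np.int64)
    fj = np.array([p[1] for p in free], dtype=np.int64)
    burn = int(config.burn_frac * config.n_iter)
    chains = []
    accs = []
    seeds = []
    for c in range(config.n_chains):
        seed_c = int((config.seed + 1) * 7919 + c) % (2**31)
        rng = np.random.default_rng(seed_c)
        init_logr = rng.normal(-0.5, 0.5, len(free))
        init_m = float(rng.uniform(0.5, 3.0))
        draws, _, acc = _mcmc_core(
            ptr_all, cidx_all, elen_all, tip_all, nt, fi, fj, root_freq,
            1.0, config.n_iter, burn, seed_c, config.step_rate, config.step_m,
            init_logr, init_m,
        )
        chains.append(draws)
        accs.append(acc)
        seeds.append(seed_c)
    names = [f"q{i}{j}" for i, j in free] + ["rate_mean"]
    return ChainSet(np.stack(chains), names, seeds=seeds, accept_rate=np.array(accs))


def stepping_stone_logml(
    trees: TreeSample | Phylogeny,
    states: dict,
    model: RateModel,
    config: MultistateConfig | None = None,
) -> float:
    """Stepping-stone estimate of the log marginal likelihood.

    Powers follow beta_k = (k/K)^(1/alpha) (Beta(alpha, 1) quantiles,
    alpha = 0.3); one chain is run per stone at power beta_k and the
    contribution log mean L^(beta_{k+1}-beta_k) is accumulated in the log
    domain.
    """
    config = config or MultistateConfig()
    ptr_all, cidx_all, elen_all, tip_all, nt = _pack_trees(trees, states)
    root_freq = _root_freq_vec(config, model)
    free = model.free_pairs
    fi = np.array([p[0] for p in free], dtype=np.int64)
    fj = np.array([p[1] for p in free], dtype=np.int64)
    K = config.n_stones
    betas = (np.arange(K + 1) / K) ** (1.0 / config.stone_alpha)
    burn = max(config.stone_iter // 5, 1)
    rng = np.random.default_rng((config.seed + 1) * 104729 % (2**31))
    logr = rng.normal(-0.5, 0.5, len(free))
    m = float(rng.uniform(0.5, 3.0))
    logml = 0.0
    for k in range(K):
        seed_k = int((config.seed + 1) * 15485863 + k) % (2**31)
        draws, lls, _ = _mcmc_core(
            ptr_all, cidx_all, elen_all, tip_all, nt, fi, fj, root_freq,
            betas[k], config.stone_iter + burn, burn, seed_k,
            config.step_rate, config.step_m, logr, m,
        )
        # warm-start the next stone from this stone's last draw
        logr = np.log(np.maximum(draws[-1, :-1], 1e-12))
        m = float(draws[-1, -1])
        delta = betas[k + 1] - betas[k]
        logml += float(logsumexp(delta * lls) - np.log(lls.size))
    return float(logml)


@dataclass
class ModelComparison:
    """Pairwise 2 ln BF comparison of models from their log marginal
    likelihoods, with Kass-Raftery qualitative labels."""

    names: list[str]
    logml: np.ndarray
    bf2ln: np.ndarray = field(init=False)
    labels: list[list[str]] = field(init=False)

    def __post_init__(self) -> None:
        self.logml = np.asarray(self.logml, dtype=float)
        self.bf2ln = 2.0 * (self.logml[:, None] - self.logml[None, :])
        self.labels = [[_kass_raftery_label(v) for v in row] for row in self.bf2ln]

    def best(self) -> str:
        return self.names[int(np.argmax(self.logml))]


def _kass_raftery_label(bf2ln: float) -> str:
    a = abs(bf2ln)
    for cut, lab in KASS_RAFTERY:
        if a < cut or cut == np.inf:
            return lab
    return KASS_RAFTERY[-1][1]


def compare_models(logml: dict) -> ModelComparison:
    """Compare models given a {name: log marginal likelihood} mapping."""
    if len(logml) < 2:
        raise ValueError("need >= 2 models to compare")
    names = list(logml)
    return ModelComparison(names, np.array([logml[n] for n in names]))


def max_likelihood_fit(
    tree: Phylogeny,
    states: dict,
    model: RateModel,
    attempts: int = 100,
    seed: int = 0,
    root_freq: np.ndarray | None = None,
) -> tuple[RateModel, float]:
    """Multistart maximum-likelihood estimate of the free rates.

    Runs ``attempts`` bounded L-BFGS-B optimisations from log-normal random
    starts and returns the best fit.  Used to sanity-check prior ranges.
    """
    if attempts < 1:
        raise ValueError("attempts must be >= 1")
    free = model.free_pairs
    rng = np.random.default_rng(seed)

    def neg(logr):
        return -pruning_loglik(tree, states, model.with_rates(np.exp(logr)), root_freq)

    best = None
    for _ in range(attempts):
        x0 = rng.normal(-0.5, 1.0, len(free))
        res = minimize(neg, x0, method="L-BFGS-B", bounds=[(-12, 5)] * len(free))
        if res.success or np.isfinite(res.fun):
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError(f"all {attempts} optimisation attempts failed")
    fitted = model.with_rates(np.exp(best.x))
    return fitted, float(-best.fun)


def replicate_logml(
    trees: TreeSample | Phylogeny,
    states: dict,
    model: RateModel,
    config: MultistateConfig | None = None,
    n_replicates: int = 3,
) -> np.ndarray:
    """Independent stepping-stone replicates, for checking that repeated
    marginal-likelihood estimates agree."""
    config = config or MultistateConfig()
    out = np.empty(n_replicates)
    for r in range(n_replicates):
        cfg = MultistateConfig(**{**config.__dict__, "seed": config.seed + 1000 * r})
        out[r] = stepping_stone_logml(trees, states, model, cfg)
    return out
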