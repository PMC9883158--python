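"""Synthetic data with the statistical structure the analyses assume.

Generates ultrametric birth-death trees, spatially scattered society
coordinates, two 4-level ordinal traits obtained by thresholding correlated
latent Ornstein-Uhlenbeck trajectories (with an optional spatially
autocorrelated Gaussian-process component), and a 4-state authority-structure
trait evolved by a continuous-time Markov chain.  Every generator is
bit-reproducible under a fixed seed.

The society table mirrors the empirical layout: columns ``society, taxon,
lat, lon, political_authority, religious_authority, authority_structure``
with ordinal values in {0, 1, 2, 3}.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from ._ou import ou_moments_batch, ou_stationary
from .coevolution import OUParams
from .multistate import N_STATES, RateModel, build_rate_model
from .trees import Phylogeny, great_circle_distances

TABLE_COLUMNS = [
    "society",
    "taxon",
    "lat",
    "lon",
    "political_authority",
    "religious_authority",
    "authority_structure",
]

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_coords",
    "simulate_coevolution",
    "simulate_multistate",
    "simulate_signal_liabilities",
    "ordinalize",
    "make_dataset",
    "write_dataset",
    "TABLE_COLUMNS",
]


def default_ou_params() -> OUParams:
    """Mutual positive cross-trait selection at a strength where both the
    coupling and the phylogenetic signal are visible at desk sample sizes."""
    return OUParams(
        A=np.array([[-1.0, 0.5], [0.4, -1.0]]),
        b=np.zeros(2),
        cutpoints=np.array([[-0.85, 0.0, 0.85], [-0.85, 0.0, 0.85]]),
        gp_amplitude=np.array([0.3, 0.3]),
        gp_lengthscale=np.array([1500.0, 1500.0]),
    )


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_tips: int = 60
    birth_rate: float = 1.0
    death_rate: float = 0.3
    seed: int = 0
    ou: OUParams = field(default_factory=default_ou_params)
    q: RateModel = field(default_factory=lambda: build_rate_model("full", 0.7 * np.ones((4, 4))))
    geo_box: tuple = (-45.0, 25.0, 95.0, 180.0)  # Pacific-like lat/lon box

    def __post_init__(self) -> None:
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        if not self.birth_rate > self.death_rate >= 0:
            raise ValueError("need birth_rate > death_rate >= 0")


@dataclass
class SyntheticDataset:
    tree: Phylogeny
    society_table: pd.DataFrame
    latents: np.ndarray  # (n_tips, 2) latent liabilities incl. spatial term
    truth: SyntheticConfig


def simulate_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.3,
    seed: int = 0,
    rescale_depth: float | None = 1.0,
) -> Phylogeny:
    """Ultrametric birth-death tree conditioned on ``n_tips`` surviving tips.

    Uses dendropy's birth-death simulator, relabels the tips ``t1..tn``,
    and (by default) rescales branch lengths so the root-to-tip depth is
    exactly 1, making rate parameters comparable across replicates.
    """
    if n_tips < 4:
        raise ValueError("n_tips must be >= 4")
    if not birth_rate > death_rate >= 0:
        raise ValueError("need birth_rate > death_rate >= 0")
    rng = random.Random(int(seed))
    dtree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_tips,
        rng=rng,
        repeat_until_success=True,
    )
    for k, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{k}"
    tree = Phylogeny.from_dendropy(dtree)
    if tree.n_tips != n_tips:
        raise RuntimeError(f"birth-death simulation produced {tree.n_tips} tips")
    if rescale_depth is not None:
        depths = tree.node_depths()
        scale = rescale_depth / depths[tree.tip_indices].max()
        elen = tree.edge_length * scale
        # snap pendant edges so every tip depth is exactly rescale_depth
        depths = depths * scale
        parent_depth = depths - elen
        for i in tree.tip_indices:
            elen[i] = rescale_depth - parent_depth[i]
        tree = Phylogeny(tree.parent, elen, tree.labels)
    return tree


def simulate_coords(n: int, geo_box: tuple, seed: int = 0) -> np.ndarray:
    """Uniform (lat, lon) draws inside a bounding box; shape (n, 2)."""
    lat_min, lat_max, lon_min, lon_max = map(float, geo_box)
    if lat_min > lat_max or lon_min > lon_max:
        raise ValueError("degenerate geo_box: min exceeds max")
    if not (-90 <= lat_min <= lat_max <= 90 and -180 <= lon_min <= lon_max <= 180):
        raise ValueError("geo_box out of range")
    rng = np.random.default_rng(seed)
    lat = rng.uniform(lat_min, lat_max, n)
    lon = rng.uniform(lon_min, lon_max, n)
    return np.column_stack([lat, lon])


def ordinalize(latent, cutpoints, noise: str = "none", rng=None):
    """Map latent values to ordinal categories 0..3 via cutpoints.

    ``noise="none"`` thresholds directly (category k when
    ``c_k < latent <= c_{k+1}``, with c_0 = -inf, c_4 = +inf);
    ``noise="probit"`` adds a unit-normal draw first, so
    ``P(k) = Phi(c_{k+1} - latent) - Phi(c_k - latent)``.
    """
    c = np.asarray(cutpoints, dtype=float)
    if c.ndim != 1 or c.size != 3 or np.any(np.diff(c) <= 0):
        raise ValueError("cutpoints must be a strictly increasing triple")
    x = np.asarray(latent, dtype=float)
    if noise == "probit":
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        x = x + rng.standard_normal(x.shape if x.shape else None)
    elif noise != "none":
        raise ValueError("noise must be 'none' or 'probit'")
    return np.searchsorted(c, x, side="left").astype(int)


def gp_covariance(coords: np.ndarray, amplitude: float, lengthscale: float) -> np.ndarray:
    """Squared-exponential kernel on great-circle distance (km)."""
    d = great_circle_distances(coords).values
    return amplitude**2 * np.exp(-0.5 * (d / lengthscale) ** 2)


def simulate_coevolution(
    tree: Phylogeny,
    ou: OUParams,
    coords: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Evolve latent traits along the tree and threshold them.

    The root latent is drawn from the OU stationary distribution; each
    child from the exact Gaussian transition along its branch.  Tip latents
    get an additive Gaussian-process draw per trait (spatial
    autocorrelation) and are thresholded through the cutpoints with unit
    probit noise.

    Returns ``(liabilities, ordinal)``: the (n_tips, 2) latent liabilities
    (tree latent + spatial term) and the (n_tips, 2) integer traits.
    """
    rng = np.random.default_rng(seed)
    A, b, SSt = ou.A, ou.b, ou.SSt
    theta, Vinf = ou_stationary(A, b, SSt)
    nn = tree.n_nodes
    Ms, ms, Vs = ou_moments_batch(A, b, SSt, tree.edge_length)
    eta = np.zeros((nn, 2))
    eta[0] = theta + np.linalg.cholesky(Vinf) @ rng.standard_normal(2)
    for i in range(1, nn):
        mean = Ms[i] @ eta[tree.parent[i]] + ms[i]
        V = Vs[i]
        if tree.edge_length[i] > 0:
            eta[i] = mean + np.linalg.cholesky(V + 1e-14 * np.eye(2)) @ rng.standard_normal(2)
        else:
            eta[i] = mean
    tips = tree.tip_indices
    liab = eta[tips].copy()
    n = tips.size
    for t in range(2):
        amp, ls = ou.gp_amplitude[t], ou.gp_lengthscale[t]
        if amp > 0:
            if coords is None:
                raise ValueError("coords required when gp_amplitude > 0")
            K = gp_covariance(coords, amp, ls) + 1e-10 * np.eye(n)
            liab[:, t] += np.linalg.cholesky(K) @ rng.standard_normal(n)
    y = np.empty((n, 2), dtype=int)
    for t in range(2):
        y[:, t] = ordinalize(liab[:, t], ou.cutpoints[t], noise="probit", rng=rng)
    return liab, y


def simulate_multistate(
    tree: Phylogeny,
    q: RateModel,
    root_freq: np.ndarray | None = None,
    seed: int = 0,
) -> dict:
    """Exact (Gillespie) CTMC simulation of the structure trait.

    Returns a {tip label: state} mapping.  A root frequency putting mass on
    states that are unreachable under the model's mask is allowed.
    """
    if root_freq is None:
        root_freq = np.full(N_STATES, 1.0 / N_STATES)
    root_freq = np.asarray(root_freq, dtype=float)
    rng = np.random.default_rng(seed)
    Q = q.Q
    exit_rate = -np.diag(Q)
    state = np.empty(tree.n_nodes, dtype=int)
    state[0] = rng.choice(N_STATES, p=root_freq / root_freq.sum())
    for i in range(1, tree.n_nodes):
        s = state[tree.parent[i]]
        t_left = tree.edge_length[i]
        while True:
            if exit_rate[s] <= 0:
                break
            wait = rng.exponential(1.0 / exit_rate[s])
            if wait > t_left:
                break
            t_left -= wait
            probs = Q[s].copy()
            probs[s] = 0.0
            probs = probs / probs.sum()
            s = rng.choice(N_STATES, p=probs)
        state[i] = s
    return {tree.labels[i]: int(state[i]) for i in tree.tip_indices}


def simulate_signal_liabilities(
    tree: Phylogeny,
    sigma2: tuple = (1.5, 1.5),
    rho_phylo: float = 0.8,
    rho_resid: float = 0.2,
    cutpoints: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate ordinal data under the static signal model.

    Liability = phylogenetic effect (matrix-normal over the tree correlation
    with a 2x2 between-trait covariance) + unit-variance residual with
    correlation ``rho_resid``; thresholded without extra noise (the residual
    is the probit noise).  Returns ``(liabilities, ordinal)``.
    """
    from .trees import phylo_vcv

    if cutpoints is None:
        cutpoints = np.array([[-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0]])
    cutpoints = np.asarray(cutpoints, dtype=float)
    rng = np.random.default_rng(seed)
    V = phylo_vcv(tree).values
    C = V / V.diagonal().max()
    n = C.shape[0]
    Lc = np.linalg.cholesky(C + 1e-10 * np.eye(n))
    s = np.sqrt(np.asarray(sigma2, dtype=float))
    Sigma = np.array(
        [[s[0] ** 2, rho_phylo * s[0] * s[1]], [rho_phylo * s[0] * s[1], s[1] ** 2]]
    )
    Ls = np.linalg.cholesky(Sigma + 1e-12 * np.eye(2))
    g = Lc @ rng.standard_normal((n, 2)) @ Ls.T
    R = np.array([[1.0, rho_resid], [rho_resid, 1.0]])
    e = rng.standard_normal((n, 2)) @ np.linalg.cholesky(R).T
    z = g + e
    y = np.empty((n, 2), dtype=int)
    for t in range(2):
        y[:, t] = ordinalize(z[:, t], cutpoints[t], noise="none")
    return z, y


def make_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Tree + society table + latent truth under one seeded configuration."""
    config = config or SyntheticConfig()
    tree = simulate_tree(config.n_tips, config.birth_rate, config.death_rate, config.seed)
    coords = simulate_coords(config.n_tips, config.geo_box, config.seed + 1)
    liab, y = simulate_coevolution(tree, config.ou, coords, config.seed + 2)
    struct = simulate_multistate(tree, config.q, seed=config.seed + 3)
    labels = tree.tip_labels
    table = pd.DataFrame(
        {
            "society": [f"society_{l}" for l in labels],
            "taxon": labels,
            "lat": coords[:, 0],
            "lon": coords[:, 1],
            "political_authority": y[:, 0],
            "religious_authority": y[:, 1],
            "authority_structure": [struct[l] for l in labels],
        }
    )
    return SyntheticDataset(tree=tree, society_table=table, latents=liab, truth=config)


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write tree (Newick), society table (CSV) and a manifest (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree_path = outdir / "tree.nwk"
    tree_path.write_text(ds.tree.newick() + "\n")
    table_path = outdir / "society_table.csv"
    ds.society_table[TABLE_COLUMNS].to_csv(table_path, index=False)
    cfg = ds.truth
    manifest = {
        "seed": cfg.seed,
        "n_tips": cfg.n_tips,
        "birth_rate": cfg.birth_rate,
        "death_rate": cfg.death_rate,
        "geo_box": list(cfg.geo_box),
        "ou": {
            "A": cfg.ou.A.tolist(),
            "b": cfg.ou.b.tolist(),
            "cutpoints": cfg.ou.cutpoints.tolist(),
            "gp_amplitude": cfg.ou.gp_amplitude.tolist(),
            "gp_lengthscale": cfg.ou.gp_lengthscale.tolist(),
        },
        "ctmc": {"name": cfg.q.name, "rates": cfg.q.rates.tolist()},
        "files": {"tree": tree_path.name, "society_table": table_path.name},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
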