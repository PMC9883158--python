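"""Dynamic coevolution of political and religious authority.

Fits the latent Ornstein-Uhlenbeck coevolution model (with the spatial
Gaussian-process control) to a synthetic dataset whose generating selection
matrix couples the traits in both directions, then prints the standardized
directional effects (delta-theta), the phase-plane stationary point and
ancestral-state probabilities at the root.
"""

import numpy as np

from phylocoev.coevolution import (
    CoevConfig,
    OUParams,
    ancestral_states,
    delta_theta,
    fit_coevolution,
    phase_plane,
)
from phylocoev.simulate import SyntheticConfig, make_dataset

ds = make_dataset(SyntheticConfig(n_tips=60, seed=11))
coords = ds.society_table[["lat", "lon"]].to_numpy()
post = fit_coevolution(
    ds.society_table,
    ds.tree,
    coords,
    CoevConfig(n_iter=5000, burn=1500, n_chains=2, tree_draws=1, gp=True, seed=2),
)
print(f"converged (all split R-hat <= 1.01): {post.converged}")
print(post.diagnostics.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

dt = delta_theta(post)
for k in ("dtheta_pol_from_rel", "dtheta_rel_from_pol"):
    d = dt[k]
    print(
        f"{k}: median {d['median']:.2f}, 95% HPDI ({d['hpdi'][0]:.2f}, {d['hpdi'][1]:.2f}), "
        f"PP {d['pp']:.2f}, 2lnBF {d['logbf']:.2f}"
    )
diff = dt["difference"]
print(f"difference: median {diff['median']:.2f}, PP {diff['pp']:.2f}")

med_A = np.array(
    [
        [np.median(post.pooled("A11")), np.median(post.pooled("A12"))],
        [np.median(post.pooled("A21")), np.median(post.pooled("A22"))],
    ]
)
pp = phase_plane(
    OUParams(
        A=med_A,
        b=np.array([np.median(post.pooled("b1")), np.median(post.pooled("b2"))]),
        cutpoints=np.array(
            [
                [np.median(post.pooled("cut_pol_1")), 0, np.median(post.pooled("cut_pol_3"))],
                [np.median(post.pooled("cut_rel_1")), 0, np.median(post.pooled("cut_rel_3"))],
            ]
        ),
    )
)
print(f"\nposterior-median selection matrix:\n{np.round(med_A, 2)}")
print(f"phase-plane stationary point (latent scale): {np.round(pp.stationary_point, 2)}")
print("\nroot ancestral-state probabilities (median across draws):")
print(ancestral_states(post).to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    "\ndelta-theta is the equilibrium shift of one trait per MAD-unit"
    "\nincrease of the other: the generator couples the traits positively"
    "\nin both directions (A12 = 0.5, A21 = 0.4), so both PPs should lean"
    "\nabove 0.5."
)
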