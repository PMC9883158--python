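"""Phylogenetic signal and correlation of the two authority traits.

Fits the bivariate ordinal mixed model to a synthetic dataset generated
with known signal (lambda = 0.6 per trait) and strong phylogenetic
correlation (0.8), and prints posterior summaries.
"""

import pandas as pd

from phylocoev.signal import SignalConfig, fit_signal_model
from phylocoev.simulate import simulate_signal_liabilities, simulate_tree

tree = simulate_tree(120, seed=21)
_, y = simulate_signal_liabilities(
    tree, sigma2=(1.5, 1.5), rho_phylo=0.8, rho_resid=0.2, seed=22
)
table = pd.DataFrame(
    {"taxon": tree.tip_labels, "political_authority": y[:, 0], "religious_authority": y[:, 1]}
)
post = fit_signal_model(
    table, tree, SignalConfig(n_iter=3000, burn=1000, n_chains=2, tree_draws=1, seed=0)
)
print(post.summary().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\nconverged (all split R-hat <= 1.05): {post.converged}")
print(
    "\nlambda_* is the liability-scale variance share sigma^2/(sigma^2+1):"
    "\nthe generating value is 0.6 for both traits, with phylogenetic"
    "\ncorrelation 0.8 -- the posterior medians should sit near these and"
    "\nthe 95% HPDIs should cover them."
)
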