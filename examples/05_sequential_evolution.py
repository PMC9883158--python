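"""Differentiation vs unification of authority structures.

Simulates the 4-state structure trait under the strong differentiation
model (transitions strictly 1 -> 2 -> 3), estimates stepping-stone log
marginal likelihoods for all five constrained models, and prints the
2 ln BF comparison on the Kass-Raftery scale.
"""

import numpy as np
import pandas as pd

from phylocoev.multistate import (
    MASKS,
    MultistateConfig,
    build_rate_model,
    compare_models,
    stepping_stone_logml,
)
from phylocoev.simulate import simulate_multistate, simulate_tree

tree = simulate_tree(200, seed=31)
truth = build_rate_model("strong_differentiation", 1.5 * np.ones((4, 4)))
states = simulate_multistate(tree, truth, root_freq=np.array([0.1, 0.6, 0.2, 0.1]), seed=32)
print("observed state counts:", np.bincount(list(states.values()), minlength=4))

logml = {}
for name in MASKS:
    logml[name] = stepping_stone_logml(tree, states, build_rate_model(name), MultistateConfig(seed=1))
    print(f"log ML [{name}]: {logml[name]:.2f}")

comp = compare_models(logml)
print("\n2 ln BF matrix (row vs column):")
print(pd.DataFrame(np.round(comp.bf2ln, 1), index=comp.names, columns=comp.names).to_string())
print(f"\nbest model: {comp.best()}")
i, j = comp.names.index("strong_differentiation"), comp.names.index("strong_unification")
print(
    f"strong differentiation vs strong unification: 2lnBF = {comp.bf2ln[i, j]:.1f} "
    f"({comp.labels[i][j]})"
)
print(
    "\nData were simulated under strong differentiation, so the"
    "\ndifferentiation models should dominate both unification models"
    "\n(2 ln BF >= 2: 'positive evidence' or better)."
)
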