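"""Constrained 4-state CTMC models: masks, likelihood, MCMC, marginal
likelihoods and Bayes-factor comparison."""

import itertools

import numpy as np
import pytest

from phylocoev.multistate import (
    MASKS,
    MultistateConfig,
    build_rate_model,
    compare_models,
    fit_multistate_mcmc,
    max_likelihood_fit,
    pruning_loglik,
    stepping_stone_logml,
    transition_probabilities,
)
from phylocoev.simulate import simulate_multistate, simulate_tree
from phylocoev.trees import parse_trees


def brute_force_loglik(tree, states, q, root_freq=None):
    """Exhaustive summation over all internal-state assignments."""
    from scipy.linalg import expm

    if root_freq is None:
        root_freq = np.full(4, 0.25)
    P = {i: expm(q.Q * tree.edge_length[i]) for i in range(1, tree.n_nodes)}
    tips = set(tree.tip_indices.tolist())
    internals = [i for i in range(tree.n_nodes) if i not in tips]
    fixed = {i: states[tree.labels[i]] for i in tips}
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internals)):
        s = dict(zip(internals, assign))
        s.update(fixed)
        p = root_freq[s[0]]
        for c in range(1, tree.n_nodes):
            p *= P[c][s[tree.parent[c]], s[c]]
        total += p
    return np.log(total)


class TestRateModel:
    @pytest.mark.parametrize(
        "name,mask",
        [
            ("full", set()),
            ("strong_differentiation", {(0, 2), (0, 3), (1, 3)}),
            ("weak_differentiation", {(0, 2), (0, 3)}),
            ("strong_unification", {(0, 1), (0, 2), (3, 1)}),
            ("weak_unification", {(0, 1), (0, 2)}),
        ],
    )
    def test_masks(self, name, mask):
        m = build_rate_model(name)
        assert m.mask == frozenset(mask)
        for i, j in mask:
            assert m.Q[i, j] == 0.0

    def test_full_has_twelve_free_rates(self):
        assert len(build_rate_model("full").free_pairs) == 12

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown model"):
            build_rate_model("sideways")

    def test_rows_sum_to_zero(self):
        for name in MASKS:
            Q = build_rate_model(name).Q
            assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)


class TestTransitionProbabilities:
    def test_identity_at_zero(self):
        assert np.allclose(transition_probabilities(build_rate_model("full"), 0.0), np.eye(4))

    def test_stochastic_rows(self):
        m = build_rate_model("weak_unification", 1.3 * np.ones((4, 4)))
        for t in (0.01, 0.5, 4.0):
            P = transition_probabilities(m, t)
            assert np.allclose(P.sum(axis=1), 1, atol=1e-12)
            assert P.min() >= 0

    def test_two_state_closed_form(self):
        q01, q10 = 0.7, 0.4
        rates = np.zeros((4, 4))
        rates[0, 1], rates[1, 0] = q01, q10
        m = build_rate_model("full", rates)
        for t in (0.3, 1.5):
            P = transition_probabilities(m, t)
            expect = (q01 / (q01 + q10)) * (1 - np.exp(-(q01 + q10) * t))
            assert P[0, 1] == pytest.approx(expect, rel=1e-10)


class TestPruning:
    def test_single_tip(self):
        t = parse_trees("(a:1,b:1);").trees[0]
        # two-tip tree against direct summation
        q = build_rate_model("full", 0.6 * np.ones((4, 4)))
        from scipy.linalg import expm

        P = expm(q.Q * 1.0)
        states = {"a": 1, "b": 3}
        direct = np.log(sum(0.25 * P[r, 1] * P[r, 3] for r in range(4)))
        assert pruning_loglik(t, states, q) == pytest.approx(direct, abs=1e-12)

    def test_brute_force_small_trees(self):
        rng = np.random.default_rng(0)
        for rep in range(10):
            n = int(rng.integers(3, 7))
            t = simulate_tree(max(n, 4), seed=200 + rep)
            q = build_rate_model("full", rng.exponential(1.0, (4, 4)))
            states = {l: int(rng.integers(0, 4)) for l in t.tip_labels}
            bf = brute_force_loglik(t, states, q)
            assert pruning_loglik(t, states, q) == pytest.approx(bf, abs=1e-10)

    def test_missing_state_allowed(self, bd_tree_20):
        q = build_rate_model("full")
        states = {l: (i % 4) for i, l in enumerate(bd_tree_20.tip_labels)}
        full = pruning_loglik(bd_tree_20, states, q)
        states[bd_tree_20.tip_labels[0]] = -1
        assert pruning_loglik(bd_tree_20, states, q) > full

    def test_state_out_of_range(self, bd_tree_20):
        states = {l: 0 for l in bd_tree_20.tip_labels}
        states[bd_tree_20.tip_labels[0]] = 7
        with pytest.raises(ValueError, match="outside"):
            pruning_loglik(bd_tree_20, states, build_rate_model("full"))

    def test_masked_rate_value_is_irrelevant(self):
        # the masked entries are structurally zero: likelihood must not
        # depend on what value the caller tried to supply
        t = simulate_tree(8, seed=3)
        states = {l: (i % 4) for i, l in enumerate(t.tip_labels)}
        base = build_rate_model("strong_unification", 1.1 * np.ones((4, 4)))
        tampered = build_rate_model("strong_unification", np.where(np.ones((4, 4)) > 0, 1.1, 0))
        assert pruning_loglik(t, states, base) == pruning_loglik(t, states, tampered)


class TestMLE:
    def test_optimum_beats_truth(self):
        t = simulate_tree(40, seed=10)
        truth = build_rate_model("full", 1.0 * np.ones((4, 4)))
        states = simulate_multistate(t, truth, seed=11)
        fitted, logl = max_likelihood_fit(t, states, build_rate_model("full"), attempts=5, seed=0)
        assert logl >= pruning_loglik(t, states, truth) - 1e-9

    def test_constant_two_tips_rates_at_bound(self):
        t = parse_trees("(a:1,b:1);").trees[0]
        states = {"a": 2, "b": 2}
        fitted, _ = max_likelihood_fit(t, states, build_rate_model("full"), attempts=3, seed=1)
        # no transitions observed: exit rates from state 2 driven to the bound
        assert fitted.rates[2].max() < 1e-3

    def test_seed_determinism(self):
        t = simulate_tree(10, seed=12)
        states = {l: (i % 4) for i, l in enumerate(t.tip_labels)}
        a = max_likelihood_fit(t, states, build_rate_model("full"), attempts=3, seed=5)
        b = max_likelihood_fit(t, states, build_rate_model("full"), attempts=3, seed=5)
        assert a[1] == b[1]
        assert np.array_equal(a[0].rates, b[0].rates)


class TestMCMC:
    def test_posterior_calibrated_smoke(self):
        t = simulate_tree(100, seed=20)
        truth = build_rate_model("strong_differentiation", 1.2 * np.ones((4, 4)))
        states = simulate_multistate(t, truth, root_freq=np.array([0.2, 0.6, 0.1, 0.1]), seed=21)
        cfg = MultistateConfig(n_iter=20_000, n_chains=2, seed=0)
        cs = fit_multistate_mcmc(t, states, truth, cfg)
        assert cs.draws.shape[0] == 2
        assert set(cs.names) == {f"q{i}{j}" for i, j in truth.free_pairs} | {"rate_mean"}
        meds = np.median(cs.draws.reshape(-1, len(cs.names)), axis=0)
        assert np.all(meds[:-1] > 0)
        assert 0 < meds[-1] < 10

    def test_prior_dominance_constant_data(self):
        t = simulate_tree(30, seed=22)
        states = {l: 1 for l in t.tip_labels}
        with pytest.warns(RuntimeWarning, match="prior-dominated"):
            cs = fit_multistate_mcmc(
                t, states, build_rate_model("full"), MultistateConfig(n_iter=8000, n_chains=2, seed=1)
            )
        # exit rates from the observed state collapse toward zero
        q1 = [cs.pooled(f"q1{j}") for j in (0, 2, 3)]
        assert max(np.median(v) for v in q1) < 0.5

    def test_tree_sample_mixture_runs(self):
        from phylocoev.trees import TreeSample

        trees = TreeSample([simulate_tree(12, seed=s) for s in (1, 2, 3)])
        truth = build_rate_model("full", 0.8 * np.ones((4, 4)))
        states = simulate_multistate(trees[0], truth, seed=5)
        cs = fit_multistate_mcmc(trees, states, truth, MultistateConfig(n_iter=4000, n_chains=2))
        assert np.isfinite(cs.draws).all()


class TestModelComparison:
    def test_equal_logml_zero_bf(self):
        c = compare_models({"a": -10.0, "b": -10.0})
        assert c.bf2ln[0, 1] == 0.0
        assert c.labels[0][1] == "not worth more than a bare mention"

    def test_difference_four_strong(self):
        c = compare_models({"a": -6.0, "b": -10.0})
        assert c.bf2ln[0, 1] == pytest.approx(8.0)
        assert c.labels[0][1] == "strong evidence"

    def test_antisymmetry(self):
        c = compare_models({"a": -3.0, "b": -5.5, "c": -1.2})
        assert np.allclose(c.bf2ln, -c.bf2ln.T)
        assert c.best() == "c"

    def test_needs_two_models(self):
        with pytest.raises(ValueError):
            compare_models({"a": -1.0})


class TestSteppingStone:
    def test_empty_data_logml_zero(self):
        t = simulate_tree(10, seed=30)
        states = {l: -1 for l in t.tip_labels}  # all missing: likelihood = 1
        cfg = MultistateConfig(n_stones=5, stone_iter=400, seed=0)
        lm = stepping_stone_logml(t, states, build_rate_model("full"), cfg)
        assert lm == pytest.approx(0.0, abs=0.05)

    def test_replicates_agree(self):
        from phylocoev.multistate import replicate_logml

        t = simulate_tree(40, seed=31)
        truth = build_rate_model("full", 1.0 * np.ones((4, 4)))
        states = simulate_multistate(t, truth, seed=32)
        cfg = MultistateConfig(n_stones=10, stone_iter=1500, seed=0)
        reps = replicate_logml(t, states, truth, cfg, n_replicates=3)
        assert reps.std() < 1.0
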