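"""Synthetic-data generators: trees, coordinates, latent coevolution,
multistate CTMC simulation and ordinalization."""

import numpy as np
import pytest
from scipy.linalg import expm, solve_lyapunov
from scipy.stats import norm

from conftest import star_tree
from phylocoev.coevolution import OUParams
from phylocoev.multistate import build_rate_model
from phylocoev.simulate import (
    SyntheticConfig,
    ordinalize,
    simulate_coevolution,
    simulate_coords,
    simulate_multistate,
    simulate_signal_liabilities,
    simulate_tree,
    write_dataset,
)

CUTS = np.array([[-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0]])


class TestTreeSim:
    def test_tip_count_and_ultrametric(self):
        t = simulate_tree(10, seed=0)
        assert t.n_tips == 10
        depths = t.node_depths()[t.tip_indices]
        assert np.allclose(depths, 1.0, atol=1e-9)

    def test_seed_determinism(self):
        assert simulate_tree(15, seed=5).newick() == simulate_tree(15, seed=5).newick()
        assert simulate_tree(15, seed=5).newick() != simulate_tree(15, seed=6).newick()

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            simulate_tree(10, birth_rate=0.5, death_rate=0.8)


class TestCoords:
    def test_zero_area_box(self):
        c = simulate_coords(5, (10, 10, 50, 50), seed=0)
        assert np.allclose(c, [10, 50])

    def test_inside_box(self):
        c = simulate_coords(97, (-45, 25, 95, 180), seed=1)
        assert c[:, 0].min() >= -45 and c[:, 0].max() <= 25
        assert c[:, 1].min() >= 95 and c[:, 1].max() <= 180

    def test_deterministic(self):
        assert np.array_equal(
            simulate_coords(10, (-10, 10, 0, 20), 3), simulate_coords(10, (-10, 10, 0, 20), 3)
        )

    def test_degenerate_box(self):
        with pytest.raises(ValueError):
            simulate_coords(5, (10, -10, 0, 20))


class TestOrdinalize:
    def test_thresholding(self):
        assert ordinalize(-5.0, (-1, 0, 1)) == 0
        assert ordinalize(np.array([-0.5, 0.5, 5.0]), (-1, 0, 1)).tolist() == [1, 2, 3]

    def test_monotone(self):
        x = np.sort(np.random.default_rng(0).normal(0, 2, 100))
        y = ordinalize(x, (-1, 0, 1))
        assert np.all(np.diff(y) >= 0)

    def test_probit_category_probability(self):
        rng = np.random.default_rng(1)
        y = ordinalize(np.zeros(100_000), (-1, 0, 1), noise="probit", rng=rng)
        p1 = np.mean(y == 1)
        expect = norm.cdf(0) - norm.cdf(-1)  # 0.3413
        assert p1 == pytest.approx(expect, abs=3 * np.sqrt(expect * (1 - expect) / 100_000))

    def test_bad_cutpoints(self):
        with pytest.raises(ValueError):
            ordinalize(0.0, (1, 0, -1))


class TestCoevolutionSim:
    def test_values_in_range_and_deterministic(self, bd_tree_20, coords_20):
        p = OUParams(A=np.array([[-1.0, 0.5], [0.4, -1.0]]), b=np.zeros(2), cutpoints=CUTS,
                     gp_amplitude=np.array([0.3, 0.3]))
        l1, y1 = simulate_coevolution(bd_tree_20, p, coords_20, seed=7)
        l2, y2 = simulate_coevolution(bd_tree_20, p, coords_20, seed=7)
        assert np.array_equal(y1, y2) and np.array_equal(l1, l2)
        assert set(np.unique(y1)) <= {0, 1, 2, 3}

    def test_independent_traits_uncorrelated_on_star(self):
        t = star_tree(400, depth=8.0)
        p = OUParams(A=-np.eye(2), b=np.zeros(2), cutpoints=CUTS)
        liab, _ = simulate_coevolution(t, p, None, seed=3)
        r = np.corrcoef(liab[:, 0], liab[:, 1])[0, 1]
        assert abs(r) < 3 / np.sqrt(400)

    def test_long_branch_stationary_covariance(self):
        # terminal branches ~ 11 mean-reversion half-lives: tips are
        # independent draws from the stationary law solving AV + VA' + I = 0
        A = np.array([[-1.0, 0.5], [0.4, -1.0]])
        t = star_tree(3000, depth=8.0)
        p = OUParams(A=A, b=np.zeros(2), cutpoints=CUTS)
        liab, _ = simulate_coevolution(t, p, None, seed=4)
        Vexp = solve_lyapunov(A, -np.eye(2))
        Vemp = np.cov(liab.T)
        assert np.allclose(Vemp, Vexp, atol=4 * Vexp.max() / np.sqrt(3000) + 0.05)

    def test_degenerate_cutpoints_constant_column(self, bd_tree_20):
        cuts = np.array([[-30.0, 0.0, 1.0], [-30.0, 0.0, 1.0]])
        p = OUParams(A=-np.eye(2), b=np.array([8.0, 8.0]), cutpoints=cuts)
        _, y = simulate_coevolution(bd_tree_20, p, None, seed=5)
        assert np.all(y == 3)


class TestMultistateSim:
    def test_zero_rates_keep_root_state(self, bd_tree_20):
        q = build_rate_model("full", np.zeros((4, 4)))
        states = simulate_multistate(bd_tree_20, q, root_freq=np.array([0, 0, 1, 0]), seed=0)
        assert set(states.values()) == {2}

    def test_forbidden_transitions_never_realized(self):
        # under the strong differentiation mask, direct jumps 0->2, 0->3 and
        # 1->3 must never occur in simulated branch histories
        q = build_rate_model("strong_differentiation", 2.0 * np.ones((4, 4)))
        big_star = star_tree(2500, depth=0.8)
        realized = set()
        for seed in range(4):
            states = simulate_multistate(
                big_star, q, root_freq=np.array([0.7, 0.3, 0.0, 0.0]), seed=seed
            )
            # root -> tip over one branch: infeasible end states reveal
            # forbidden jumps only indirectly, so also track jump chains
            realized.update(states.values())
        # end states can be anything reachable; the structural check:
        Q = q.Q
        for i, j in q.mask:
            assert Q[i, j] == 0.0
        # and a state-0 root with zero alternative mass cannot reach 2 or 3
        # without passing through 1 first -- verified by jump simulation
        rng = np.random.default_rng(0)
        for rep in range(3000):
            s, t_left = 0, 0.5
            while True:
                rate = -Q[s, s]
                if rate <= 0:
                    break
                w = rng.exponential(1 / rate)
                if w > t_left:
                    break
                t_left -= w
                pr = Q[s].copy()
                pr[s] = 0
                nxt = int(rng.choice(4, p=pr / pr.sum()))
                assert (s, nxt) not in q.mask
                s = nxt

    def test_single_branch_frequencies_match_expm(self):
        q = build_rate_model("full", np.array([[0, 1.2, 0.3, 0.1],
                                               [0.5, 0, 0.9, 0.2],
                                               [0.1, 0.7, 0, 1.1],
                                               [0.2, 0.1, 0.8, 0]]))
        t = 0.6
        two_tip = star_tree(2, depth=t)
        counts = np.zeros(4)
        n = 10_000
        for rep in range(n):
            states = simulate_multistate(two_tip, q, root_freq=np.array([1, 0, 0, 0]), seed=rep)
            counts[states["t1"]] += 1
        freq = counts / n
        expect = expm(q.Q * t)[0]
        se = np.sqrt(expect * (1 - expect) / n)
        assert np.all(np.abs(freq - expect) < 3 * se + 1e-3)


class TestDataset:
    def test_table_matches_tree(self, dataset_small):
        ds = dataset_small
        assert set(ds.society_table["taxon"]) == set(ds.tree.tip_labels)
        for col in ("political_authority", "religious_authority", "authority_structure"):
            assert ds.society_table[col].between(0, 3).all()

    def test_write_dataset_roundtrip(self, dataset_small, tmp_path):
        manifest = write_dataset(dataset_small, tmp_path)
        assert (tmp_path / "tree.nwk").exists()
        assert (tmp_path / "society_table.csv").exists()
        assert manifest["n_tips"] == 40
        from phylocoev.trees import parse_trees

        t = parse_trees((tmp_path / "tree.nwk").read_text()).trees[0]
        assert set(t.tip_labels) == set(dataset_small.tree.tip_labels)

    def test_signal_liabilities_binned(self, bd_tree_20):
        z, y = simulate_signal_liabilities(bd_tree_20, seed=0)
        assert z.shape == (20, 2) and y.shape == (20, 2)
        assert set(np.unique(y)) <= {0, 1, 2, 3}

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_tips=2)
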