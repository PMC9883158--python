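"""Tree I/O, pruning, covariance structure and distance computations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylocoev.simulate import simulate_coords, simulate_tree
from phylocoev.trees import (
    EARTH_RADIUS_KM,
    DistanceMatrix,
    distance_correlation,
    great_circle_distances,
    lambda_transform,
    parse_trees,
    patristic_distances,
    phylo_vcv,
    prune_to_taxa,
)


class TestParsing:
    def test_two_tip_depths(self):
        t = parse_trees("(A:1,B:1);").trees[0]
        d = t.node_depths()
        assert np.allclose(sorted(d[t.tip_indices]), [1.0, 1.0])

    def test_three_tip_ultrametric(self, three_tip_tree):
        d = three_tip_tree.node_depths()
        assert np.allclose(d[three_tip_tree.tip_indices], 2.0)

    def test_roundtrip_preserves_patristic(self):
        t = simulate_tree(20, seed=11)
        t2 = parse_trees(t.newick()).trees[0]
        d1 = patristic_distances(t)
        d2 = patristic_distances(t2)
        order = [d2.labels.index(l) for l in d1.labels]
        assert np.allclose(d1.values, d2.values[np.ix_(order, order)], atol=1e-10)

    def test_nexus_roundtrip(self, tmp_path):
        from phylocoev.trees import TreeSample, write_trees

        sample = TreeSample([simulate_tree(8, seed=i) for i in range(3)])
        path = tmp_path / "trees.nex"
        write_trees(sample, path, format="nexus")
        back = parse_trees(path.read_text(), "nexus")
        assert len(back) == 3
        assert set(back[0].tip_labels) == set(sample[0].tip_labels)

    def test_malformed_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            parse_trees("((A:1,B:1;")

    def test_duplicate_labels_raise(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_trees("(A:1,A:1);")


class TestPrune:
    def test_identity(self, bd_tree_20):
        p = prune_to_taxa(bd_tree_20, bd_tree_20.tip_labels)
        d0 = patristic_distances(bd_tree_20)
        d1 = patristic_distances(p)
        order = [d1.labels.index(l) for l in d0.labels]
        assert np.allclose(d0.values, d1.values[np.ix_(order, order)], atol=1e-10)

    def test_three_tip_distance_preserved(self, three_tip_tree):
        p = prune_to_taxa(three_tip_tree, {"A", "C"})
        d = patristic_distances(p)
        assert d.values[d.labels.index("A"), d.labels.index("C")] == pytest.approx(4.0)

    def test_unknown_label(self, three_tip_tree):
        with pytest.raises(KeyError, match="XX"):
            prune_to_taxa(three_tip_tree, {"A", "XX"})

    def test_patristic_submatrix_random_subsets(self):
        rng = np.random.default_rng(0)
        for rep in range(20):
            t = simulate_tree(30, seed=100 + rep)
            keep = list(rng.choice(t.tip_labels, size=12, replace=False))
            p = prune_to_taxa(t, keep)
            d_full = patristic_distances(t)
            d_sub = patristic_distances(p)
            idx_f = [d_full.labels.index(l) for l in d_sub.labels]
            assert np.allclose(
                d_full.values[np.ix_(idx_f, idx_f)], d_sub.values, atol=1e-10
            )


class TestVcv:
    def test_star_tree_identity(self):
        t = parse_trees("(A:1,B:1,C:1,D:1);").trees[0]
        assert np.allclose(phylo_vcv(t).values, np.eye(4))

    def test_three_tip_values(self, three_tip_tree):
        v = phylo_vcv(three_tip_tree)
        i = {l: k for k, l in enumerate(v.labels)}
        assert v.values[i["A"], i["A"]] == pytest.approx(2.0)
        assert v.values[i["A"], i["B"]] == pytest.approx(1.0)
        assert v.values[i["A"], i["C"]] == pytest.approx(0.0)

    def test_psd_on_simulated_trees(self):
        for seed in range(8):
            t = simulate_tree(25, seed=seed)
            ev = np.linalg.eigvalsh(phylo_vcv(t).values)
            assert ev.min() >= -1e-9

    def test_lambda_transform(self):
        C = np.array([[1.0, 0.6], [0.6, 1.0]])
        assert np.allclose(lambda_transform(C, 1.0), C)
        assert np.allclose(lambda_transform(C, 0.0), np.eye(2))
        assert lambda_transform(C, 0.5)[0, 1] == pytest.approx(0.3)
        with pytest.raises(ValueError):
            lambda_transform(C, 1.2)


class TestPatristic:
    def test_two_tips(self):
        t = parse_trees("(A:1,B:1);").trees[0]
        assert patristic_distances(t).values[0, 1] == pytest.approx(2.0)

    def test_agrees_with_graph_shortest_path(self):
        import networkx as nx

        t = simulate_tree(20, seed=5)
        g = nx.Graph()
        for i in range(1, t.n_nodes):
            g.add_edge(int(t.parent[i]), i, weight=float(t.edge_length[i]))
        d = patristic_distances(t)
        tips = t.tip_indices
        for a in range(0, 20, 3):
            lengths = nx.single_source_dijkstra_path_length(g, int(tips[a]))
            for b in range(20):
                assert d.values[a, b] == pytest.approx(lengths[int(tips[b])], abs=1e-9)


class TestGreatCircle:
    def test_identical_points(self):
        d = great_circle_distances([(10.0, 20.0), (10.0, 20.0)])
        assert d.values[0, 1] == 0.0

    def test_antipodal_and_quarter(self):
        d = great_circle_distances([(0, 0), (0, 180), (0, 90)])
        assert d.values[0, 1] == pytest.approx(np.pi * EARTH_RADIUS_KM, rel=1e-9)
        assert d.values[0, 2] == pytest.approx(np.pi * EARTH_RADIUS_KM / 2, rel=1e-9)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            great_circle_distances([(95.0, 0.0), (0.0, 0.0)])

    def test_triangle_inequality_random(self):
        coords = simulate_coords(40, (-60, 60, -170, 170), seed=9)
        d = great_circle_distances(coords).values
        rng = np.random.default_rng(1)
        for _ in range(200):
            i, j, k = rng.choice(40, 3, replace=False)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-6


class TestDistanceCorrelation:
    def test_perfect_linear(self):
        t = simulate_tree(10, seed=2)
        d1 = patristic_distances(t)
        d2 = DistanceMatrix(d1.labels, 2.0 * d1.values)
        res = distance_correlation(d1, d2)
        assert res["r"] == pytest.approx(1.0)

    @pytest.mark.parametrize("n,expected_df", [(97, 4654), (10, 43), (4, 4)])
    def test_df_formula(self, n, expected_df):
        rng = np.random.default_rng(n)
        x = rng.random((n, 2))
        labels = [str(i) for i in range(n)]
        a = great_circle_distances(90 * (x - 0.5), labels)
        b = great_circle_distances(90 * (x[::-1] - 0.5), labels)
        res = distance_correlation(a, b)
        assert res["df"] == expected_df == n * (n - 1) // 2 - 2

    def test_matches_brute_force_pair_pearson(self):
        rng = np.random.default_rng(3)
        n = 5
        m1 = np.zeros((n, n))
        m2 = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        m1[iu] = rng.random(10)
        m2[iu] = rng.random(10)
        m1 += m1.T
        m2 += m2.T
        labels = list("abcde")
        res = distance_correlation(DistanceMatrix(labels, m1), DistanceMatrix(labels, m2))
        # direct Pearson over the explicit list of 10 unordered pairs
        x, y = m1[iu], m2[iu]
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert res["r"] == pytest.approx(r, abs=1e-12)

    def test_mantel_option(self):
        t = simulate_tree(12, seed=4)
        coords = simulate_coords(12, (-40, 20, 100, 170), seed=4)
        d1 = patristic_distances(t)
        d2 = great_circle_distances(coords, labels=d1.labels)
        res = distance_correlation(d1, d2, method="mantel", n_permutations=199, seed=0)
        assert 0 < res["p_mantel"] <= 1

    def test_label_mismatch(self):
        t = simulate_tree(6, seed=1)
        d1 = patristic_distances(t)
        d2 = DistanceMatrix(list(reversed(d1.labels)), d1.values)
        with pytest.raises(ValueError, match="labels"):
            distance_correlation(d1, d2)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=4, max_value=200))
def test_df_is_choose2_minus_2(n):
    idx = np.arange(n, dtype=float)
    d = np.abs(idx[:, None] - idx[None, :])
    labels = [str(i) for i in range(n)]
    res = distance_correlation(
        DistanceMatrix(labels, d), DistanceMatrix(labels, np.sqrt(d))
    )
    assert res["df"] == n * (n - 1) // 2 - 2
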