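"""Tree structure, Newick round-trips, and tree statistics."""

import numpy as np
import pytest

from errophylo.simulate import simulate_coalescent, simulate_yule
from errophylo.trees import (TreeError, gamma_statistic, parse_newick,
                             tree_height, tree_length, treeness,
                             trees_from_nexus, trees_to_nexus, write_newick)


class TestNewick:
    def test_basic_parse(self):
        t = parse_newick("((a:1,b:1):1,c:2);")
        assert t.n_tips == 3
        assert tree_height(t) == pytest.approx(2.0)
        assert tree_length(t) == pytest.approx(5.0)

    def test_round_trip_random_trees(self):
        rng = np.random.default_rng(1)
        for k in range(100):
            m = int(rng.integers(3, 12))
            t = (simulate_yule(m, 5.0, rng) if k % 2
                 else simulate_coalescent(m, 0.4, rng))
            u = parse_newick(write_newick(t))
            assert u.topology_key() == t.topology_key()

            # branch lengths preserved to 12 significant digits
            def lengths(tree):
                below = {}
                out = {}
                for node in tree.postorder():
                    if tree.is_tip(node):
                        below[node] = frozenset([tree.labels[node]])
                    else:
                        c1, c2 = tree.children[node]
                        below[node] = below[c1] | below[c2]
                    out[below[node]] = tree.branch_length(node)
                return out
            la, lb = lengths(t), lengths(u)
            for clade, val in la.items():
                assert lb[clade] == pytest.approx(val, rel=1e-10)

    def test_non_binary_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("(a:1);")
        with pytest.raises(TreeError):
            parse_newick("(a:1,b:1,c:1);")

    def test_malformed_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("((a:1,b:1:2;")

    def test_nexus_tree_log_round_trip(self, rng):
        trees = [simulate_yule(5, 4.0, rng) for _ in range(4)]
        text = trees_to_nexus(trees)
        back = trees_from_nexus(text)
        assert len(back) == 4
        for t, u in zip(trees, back):
            assert u.topology_key() == t.topology_key()
            assert tree_length(u) == pytest.approx(tree_length(t), rel=1e-9)


class TestStatistics:
    def test_length_and_height_example(self):
        t = parse_newick("((a:1,b:1):1,c:2);")
        assert tree_length(t) == 5.0
        assert tree_height(t) == 2.0

    def test_ultrametric_paths_equal(self, rng):
        t = simulate_yule(10, 6.0, rng)
        depths = t.heights[t.root] - t.heights[:10]
        assert np.allclose(depths, depths[0])
        assert tree_length(t) >= tree_height(t)

    def test_length_at_least_height_random(self, rng):
        for _ in range(20):
            t = simulate_coalescent(int(rng.integers(2, 10)), 0.5, rng)
            assert tree_length(t) >= tree_height(t)

    def test_treeness_example(self):
        assert treeness(parse_newick("((a:1,b:1):2,c:3);")) \
            == pytest.approx(2 / 7)

    def test_treeness_extremes(self):
        star = parse_newick("((a:1,b:1):0,c:1);")
        assert treeness(star) == 0.0
        pendant_free = parse_newick("((a:0,b:0):1,c:0);")
        assert treeness(pendant_free) == 1.0

    def test_treeness_two_tips_undefined(self):
        with pytest.raises(TreeError):
            treeness(parse_newick("(a:1,b:1);"))

    def test_permutation_invariance(self, rng):
        a = parse_newick("((a:1,b:1):2,(c:1.5,d:1.5):1.5);")
        b = parse_newick("((d:1.5,c:1.5):1.5,(b:1,a:1):2);")
        for stat in (tree_length, tree_height, treeness, gamma_statistic):
            assert stat(a) == pytest.approx(stat(b))


class TestGammaStatistic:
    def test_linear_lineage_accumulation_gives_zero(self):
        # choose internode intervals with k*g_k constant: cumulative
        # lineage-weighted time is exactly linear, so gamma = 0
        # n=4: g2=1/2, g3=1/3, g4=1/4 (heights 0.25, 0.25+1/3, +1/2)
        h3 = 0.25
        h2 = h3 + 1 / 3
        h1 = h2 + 1 / 2
        nwk = (f"(((a:{h3},b:{h3}):{h2 - h3},c:{h2}):{h1 - h2},d:{h1});")
        assert gamma_statistic(parse_newick(nwk)) == pytest.approx(0.0,
                                                                   abs=1e-10)

    def test_three_tip_hand_computation(self):
        # heights: root 1.0, inner 0.4 -> g2 = 0.6, g3 = 0.4, T = 2.4
        # gamma = (2*0.6 - T/2) / (T*sqrt(1/12)) = 0 exactly when
        # 2 g2 = T/2; here 1.2 = 1.2 -> 0; use asymmetric variant too
        t = parse_newick("((a:0.4,b:0.4):0.6,c:1);")
        assert gamma_statistic(t) == pytest.approx(0.0, abs=1e-12)
        # root 1.0, inner 0.8: g2=0.2, g3=0.8, T=2.8
        # gamma = (0.4 - 1.4)/(2.8*sqrt(1/12))
        t2 = parse_newick("((a:0.8,b:0.8):0.2,c:1);")
        expected = (2 * 0.2 - 2.8 / 2) / (2.8 * np.sqrt(1 / 12))
        assert gamma_statistic(t2) == pytest.approx(expected)

    def test_yule_null_distribution(self):
        rng = np.random.default_rng(3)
        gammas = [gamma_statistic(simulate_yule(20, 5.0, rng))
                  for _ in range(4000)]
        # asymptotically standard normal under constant-rate pure birth
        assert np.mean(gammas) == pytest.approx(0.0, abs=0.08)
        assert np.std(gammas) == pytest.approx(1.0, abs=0.08)

    def test_non_ultrametric_rejected(self):
        with pytest.raises(TreeError):
            gamma_statistic(parse_newick("((a:1,b:2):1,c:4);"))

    def test_requires_three_tips(self):
        with pytest.raises(TreeError):
            gamma_statistic(parse_newick("(a:1,b:1);"))
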