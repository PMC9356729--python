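"""Tree, sequence and error simulators: determinism and moment checks."""

import numpy as np
import pytest
from scipy import stats

from errophylo.alignment import strip_phasing
from errophylo.errors import (BinaryErrorParams, Gt16ErrorParams,
                              binary_error_table, gt16_error_table,
                              identity_error_table)
from errophylo.simulate import (apply_errors, simulate_alignment,
                                simulate_coalescent, simulate_yule)
from errophylo.states import BINARY, GT16
from errophylo.substitution import BinaryModelParams, build_binary_q
from errophylo.trees import parse_newick
from errophylo.alignment import AlignmentError, GenotypeAlignment


class TestTreeSimulators:
    def test_yule_two_tip_expected_height(self):
        rng = np.random.default_rng(1)
        b = 3.0
        heights = [simulate_yule(2, b, rng).tree_height()
                   for _ in range(10000)]
        # single merge: Exp(2b), mean 1/(2b)
        assert np.mean(heights) == pytest.approx(1 / (2 * b), rel=0.05)

    def test_yule_structure(self, rng):
        t = simulate_yule(30, 7.0, rng)
        assert t.n_tips == 30
        assert t.is_ultrametric()
        assert len(t.internal_postorder()) == 29

    def test_coalescent_two_tip_tmrca(self):
        rng = np.random.default_rng(2)
        theta = 0.7
        heights = [simulate_coalescent(2, theta, rng).tree_height()
                   for _ in range(10000)]
        assert np.mean(heights) == pytest.approx(theta, rel=0.05)

    def test_coalescent_16_tip_height_closed_form(self):
        rng = np.random.default_rng(3)
        theta = 0.5
        heights = [simulate_coalescent(16, theta, rng).tree_height()
                   for _ in range(4000)]
        # E[height] = theta * sum_{k=2}^{16} 2/(k(k-1)) = 2θ(1 - 1/16)
        expected = 2 * theta * (1 - 1 / 16)
        assert np.mean(heights) == pytest.approx(expected, rel=0.05)

    @pytest.mark.parametrize("sim,arg", [(simulate_yule, 5.0),
                                         (simulate_coalescent, 0.5)])
    def test_seed_determinism(self, sim, arg):
        a = sim(8, arg, np.random.default_rng(99))
        b = sim(8, arg, np.random.default_rng(99))
        assert a.topology_key() == b.topology_key()
        assert np.array_equal(a.heights, b.heights)

    @pytest.mark.parametrize("sim,bad", [(simulate_yule, 0.0),
                                         (simulate_coalescent, -1.0)])
    def test_nonpositive_rate_rejected(self, sim, bad):
        with pytest.raises(ValueError):
            sim(5, bad, np.random.default_rng(0))


class TestSequenceSimulator:
    def test_stationary_marginal_at_tip(self):
        # zero-length two-tip tree: tip states are draws from pi
        q = build_binary_q(BinaryModelParams(0.5))
        tree = parse_newick("(a:0,b:0);")
        aln = simulate_alignment(tree, q, 50_000, np.random.default_rng(4))
        freq1 = (aln.data[0] == 1).mean()
        count = np.bincount(aln.data[0], minlength=2)
        assert stats.chisquare(count, q.pi * 50_000).pvalue > 1e-4
        assert freq1 == pytest.approx(q.pi[1], abs=0.01)

    def test_pairwise_joint_matches_transition_probs(self):
        q = build_binary_q(BinaryModelParams(1.3))
        t = 0.4
        tree = parse_newick(f"(a:{t},b:{t});")
        aln = simulate_alignment(tree, q, 100_000, np.random.default_rng(5))
        P2 = q.transition_probs(2 * t)
        expected = np.array([[q.pi[x] * P2[x, y] for y in range(2)]
                             for x in range(2)])
        joint = np.zeros((2, 2))
        for x in range(2):
            for y in range(2):
                joint[x, y] = ((aln.data[0] == x) & (aln.data[1] == y)).mean()
        assert joint == pytest.approx(expected, abs=0.01)

    def test_zero_length_tree_identical_cells(self, gt16_q):
        tree = parse_newick("((a:0,b:0):0,c:0);")
        aln = simulate_alignment(tree, gt16_q, 100, np.random.default_rng(6))
        assert np.array_equal(aln.data[0], aln.data[1])
        assert np.array_equal(aln.data[0], aln.data[2])

    def test_gt16_marginal_matches_pi(self, gt16_q):
        tree = parse_newick("(a:0,b:0);")
        aln = simulate_alignment(tree, gt16_q, 50_000,
                                 np.random.default_rng(7))
        count = np.bincount(aln.data[0], minlength=16)
        assert stats.chisquare(count, gt16_q.pi * 50_000).pvalue > 1e-4


class TestApplyErrors:
    def test_identity_table_is_noop(self, rng, gt16_q, coalescent_tree):
        aln = simulate_alignment(coalescent_tree, gt16_q, 50, rng)
        assert apply_errors(aln, identity_error_table(GT16), rng) == aln

    def test_false_positive_rate_on_clean_zeros(self):
        q = build_binary_q(BinaryModelParams(0.5))
        tree = parse_newick("(a:0,b:0);")
        aln = GenotypeAlignment(
            ["a", "b"], np.zeros((2, 20000), dtype=np.int16), BINARY)
        table = binary_error_table(BinaryErrorParams(0.1, 0.2))
        obs = apply_errors(aln, table, np.random.default_rng(8))
        assert (obs.data == 1).mean() == pytest.approx(0.1, abs=0.01)

    def test_gt16_columns_reproduced_empirically(self):
        eps, delta = 0.15, 0.4
        table = gt16_error_table(Gt16ErrorParams(eps, delta))
        n = 50_000
        rng = np.random.default_rng(9)
        for true_state in (0, 1):  # AA and AC
            aln = GenotypeAlignment(
                ["a", "b"], np.full((2, n), true_state, dtype=np.int16),
                GT16)
            obs = apply_errors(aln, table, rng)
            freq = np.bincount(obs.data[0], minlength=16) / n
            assert freq == pytest.approx(table.E[:, true_state], abs=0.01)

    def test_commutes_with_site_subsetting(self, gt16_q, coalescent_tree):
        rng = np.random.default_rng(10)
        aln = simulate_alignment(coalescent_tree, gt16_q, 40, rng)
        table = gt16_error_table(Gt16ErrorParams(0.1, 0.3))
        whole = apply_errors(aln, table, np.random.default_rng(77))
        part = apply_errors(aln.subset_sites(range(40)), table,
                            np.random.default_rng(77))
        assert whole == part


class TestStripPhasing:
    def test_heterozygotes_become_ambiguities(self):
        aln = GenotypeAlignment.from_codes(
            {"a": ["AC", "AA"], "b": ["CA", "GT"]}, GT16)
        out = strip_phasing(aln)
        assert out.code_strings("a") == ["AC*", "AA"]
        assert out.code_strings("b") == ["AC*", "GT*"]
        assert not out.phased

    def test_all_homozygous_unchanged(self):
        aln = GenotypeAlignment.from_codes(
            {"a": ["AA", "CC"], "b": ["GG", "TT"]}, GT16)
        assert np.array_equal(strip_phasing(aln).data, aln.data)

    def test_idempotent(self, rng, gt16_q, coalescent_tree):
        aln = simulate_alignment(coalescent_tree, gt16_q, 30, rng)
        once = strip_phasing(aln)
        assert strip_phasing(once) == once

    def test_rejected_for_binary(self):
        aln = GenotypeAlignment.from_codes({"a": "01", "b": "10"}, BINARY)
        with pytest.raises(AlignmentError):
            strip_phasing(aln)
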