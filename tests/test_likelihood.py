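"""Pruning likelihood against exhaustive enumeration, and its invariants."""

import itertools

import dendropy
import numpy as np
import pytest

from errophylo.alignment import GenotypeAlignment
from errophylo.errors import (BinaryErrorParams, Gt16ErrorParams,
                              binary_error_table, gt16_error_table)
from errophylo.likelihood import log_likelihood, per_site_likelihoods
from errophylo.simulate import simulate_alignment, simulate_coalescent, \
    simulate_yule
from errophylo.substitution import (BinaryModelParams, Gt16ModelParams,
                                    build_binary_q, build_gt16_q)
from errophylo.trees import from_dendropy, parse_newick


def brute_force_loglik(aln, tree, q, table):
    """Independent oracle: sum over all internal-node state assignments."""
    S = q.size
    m = tree.n_tips
    internal = list(range(m, tree.n_nodes))
    out = []
    P = {node: q.transition_probs(tree.branch_length(node))
         for node in range(tree.n_nodes) if tree.parent[node] >= 0}
    for site in range(aln.n_sites):
        total = 0.0
        for assign in itertools.product(range(S), repeat=len(internal)):
            st = dict(zip(internal, assign))
            p = q.pi[st[tree.root]]
            for node in range(tree.n_nodes):
                par = tree.parent[node]
                if par < 0:
                    continue
                if node < m:
                    code = aln.codes[aln.data[
                        aln.cells.index(tree.labels[node]), site]]
                    resolved = aln.state_space.resolve(code)
                    if table is None:
                        tip = sum(P[node][st[par], y] for y in resolved)
                    else:
                        tip = sum(P[node][st[par], y] * table.E[x, y]
                                  for x in resolved for y in range(S))
                    p *= tip
                else:
                    p *= P[node][st[par], st[node]]
            total += p
        out.append(np.log(total))
    return np.array(out)


def _random_binary_case(rng, m):
    q = build_binary_q(BinaryModelParams(rng.uniform(0.2, 2.0)))
    tree = simulate_yule(m, 5.0, rng)
    aln = simulate_alignment(tree, q, 6, rng)
    return q, tree, aln


def _random_gt16_case(rng, m):
    q = build_gt16_q(Gt16ModelParams(rng.dirichlet(np.ones(6)),
                                     rng.dirichlet(np.full(16, 3.0))))
    tree = simulate_coalescent(m, 0.4, rng)
    aln = simulate_alignment(tree, q, 3, rng)
    return q, tree, aln


class TestOracleEquivalence:
    @pytest.mark.parametrize("m", [2, 3, 4, 5])
    def test_binary_all_small_trees(self, m):
        rng = np.random.default_rng(100 + m)
        q, tree, aln = _random_binary_case(rng, m)
        table = binary_error_table(
            BinaryErrorParams(rng.uniform(0, 0.3), rng.uniform(0, 0.3)))
        for tab in (None, table):
            r = log_likelihood(aln, tree, q, tab)
            assert r.per_site == pytest.approx(
                brute_force_loglik(aln, tree, q, tab), abs=1e-10)
            assert r.total == pytest.approx(r.per_site.sum())

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_gt16_small_trees_with_unphased_data(self, m):
        rng = np.random.default_rng(200 + m)
        q, tree, aln = _random_gt16_case(rng, m)
        from errophylo.alignment import strip_phasing

        table = gt16_error_table(
            Gt16ErrorParams(rng.uniform(0, 0.2), rng.uniform(0, 0.5)))
        for a in (aln, strip_phasing(aln)):
            for tab in (None, table):
                r = log_likelihood(a, tree, q, tab)
                assert r.per_site == pytest.approx(
                    brute_force_loglik(a, tree, q, tab), abs=1e-9)


class TestCollapseAndDegenerate:
    def test_zero_error_model_equals_no_error_model(self):
        rng = np.random.default_rng(7)
        q, tree, aln = _random_binary_case(rng, 6)
        zero = binary_error_table(BinaryErrorParams(0.0, 0.0))
        assert log_likelihood(aln, tree, q, zero).total == pytest.approx(
            log_likelihood(aln, tree, q, None).total, abs=1e-10)
        g, gtree, galn = _random_gt16_case(rng, 5)
        gzero = gt16_error_table(Gt16ErrorParams(0.0, 0.0))
        assert log_likelihood(galn, gtree, g, gzero).total == pytest.approx(
            log_likelihood(galn, gtree, g, None).total, abs=1e-10)

    def test_zero_length_tree_identical_states(self):
        q = build_binary_q(BinaryModelParams(0.8))
        tree = parse_newick("((a:0,b:0):0,c:0);")
        aln = GenotypeAlignment.from_codes(
            {"a": "11", "b": "11", "c": "11"}, q.state_space)
        r = log_likelihood(aln, tree, q)
        assert r.per_site == pytest.approx(np.log(q.pi[1]) * np.ones(2))

    def test_tip_name_mismatch_reported(self):
        q = build_binary_q(BinaryModelParams(0.8))
        tree = parse_newick("((a:1,b:1):1,c:2);")
        aln = GenotypeAlignment.from_codes(
            {"a": "1", "b": "1", "x": "0"}, q.state_space)
        with pytest.raises(ValueError, match="x"):
            log_likelihood(aln, tree, q)


class TestPerSite:
    def test_permuting_sites_permutes_values(self, rng):
        q, tree, aln = _random_binary_case(rng, 5)
        perm = rng.permutation(aln.n_sites)
        shuffled = aln.subset_sites(perm)
        assert per_site_likelihoods(shuffled, tree, q) == pytest.approx(
            per_site_likelihoods(aln, tree, q)[perm])

    def test_duplicated_site_duplicates_value(self, rng):
        q, tree, aln = _random_binary_case(rng, 4)
        dup = aln.subset_sites([0, 0, 1])
        v = per_site_likelihoods(dup, tree, q)
        assert v[0] == pytest.approx(v[1])

    def test_total_is_sum(self, rng):
        q, tree, aln = _random_gt16_case(rng, 5)
        r = log_likelihood(aln, tree, q)
        assert r.total == pytest.approx(r.per_site.sum(), abs=1e-9)


def _reroot_on_edge(tree, edge_child, frac, rng):
    """Re-root a TimeTree at a point on the edge above ``edge_child``."""
    d = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    # find the matching edge by its child clade
    want = None
    for nd in d.preorder_node_iter():
        leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if leaves == edge_child and nd.parent_node is not None:
            want = nd
            break
    if want is None:
        return None
    L = want.edge.length
    d.reroot_at_edge(want.edge, length1=L * frac, length2=L * (1 - frac),
                     update_bipartitions=False)
    # drop the old degenerate root if it became degree-2
    d.suppress_unifurcations()
    return from_dendropy(d)


class TestPulleyPrinciple:
    @pytest.mark.parametrize("case", ["binary", "gt16"])
    def test_rerooting_preserves_likelihood(self, case):
        # reversible model with pi at the root: likelihood must not
        # depend on root placement along any branch
        rng = np.random.default_rng(11 if case == "binary" else 12)
        if case == "binary":
            q, tree, aln = _random_binary_case(rng, 6)
            table = binary_error_table(BinaryErrorParams(0.1, 0.2))
        else:
            q, tree, aln = _random_gt16_case(rng, 5)
            table = gt16_error_table(Gt16ErrorParams(0.1, 0.3))
        base = log_likelihood(aln, tree, q, table).total
        below = {}
        for node in tree.postorder():
            if tree.is_tip(node):
                below[node] = frozenset([tree.labels[node]])
            else:
                c1, c2 = tree.children[node]
                below[node] = below[c1] | below[c2]
        tried = 0
        for node in range(tree.n_nodes):
            if tree.parent[node] < 0 or tree.parent[tree.parent[node]] < 0:
                continue
            new_tree = _reroot_on_edge(tree, below[node], 0.37, rng)
            if new_tree is None:
                continue
            assert log_likelihood(aln, new_tree, q, table).total \
                == pytest.approx(base, abs=1e-8)
            tried += 1
            if tried >= 3:
                break
        assert tried >= 1
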