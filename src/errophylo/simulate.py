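"""Generative models: trees, sequences, and tip errors.

These simulators define the study conditions of the well-calibrated
experiments.  Tree simulators are backward merge processes whose exact
densities are the tree priors in :mod:`errophylo.priors`, so simulation
and inference can share one distribution — the premise of a
well-calibrated study.  All simulators are deterministic given the
numpy Generator passed in.
"""

from __future__ import annotations

import numpy as np

from .alignment import GenotypeAlignment
from .errors import ErrorTable
from .substitution import RateMatrix
from .trees import TimeTree


def _merge_backward(m: int, interval_rate, rng: np.random.Generator,
                    labels=None) -> TimeTree:
    """Merge m lineages backward; with k lineages wait Exp(interval_rate(k))."""
    if m < 2:
        raise ValueError("need at least 2 tips")
    labels = list(labels) if labels is not None else [f"cell{i+1}" for i in range(m)]
    n_nodes = 2 * m - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children = np.full((n_nodes, 2), -1, dtype=np.int64)
    heights = np.zeros(n_nodes)
    active = list(range(m))
    t = 0.0
    nxt = m
    for k in range(m, 1, -1):
        t += rng.exponential(1.0 / interval_rate(k))
        i = rng.integers(k)
        j = rng.integers(k - 1)
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        heights[nxt] = t
        children[nxt] = (a, b)
        parent[a] = parent[b] = nxt
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return TimeTree(parent, children, heights, labels)


def simulate_yule(m: int, birthrate: float, rng: np.random.Generator,
                  labels=None) -> TimeTree:
    """Ultrametric pure-birth tree conditioned on m tips.

    With k extant lineages the internode waiting time is
    Exp(k · birthrate); a uniformly chosen pair merges at each event.
    """
    if birthrate <= 0:
        raise ValueError("birthrate must be positive")
    return _merge_backward(m, lambda k: k * birthrate, rng, labels)


def simulate_coalescent(m: int, theta: float, rng: np.random.Generator,
                        labels=None) -> TimeTree:
    """Kingman coalescent tree: waiting time Exp(k(k−1)/(2θ)) with k lineages."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    return _merge_backward(m, lambda k: k * (k - 1) / (2.0 * theta), rng, labels)


def _sample_rows(P: np.ndarray, parent_states: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Per-element categorical draw: row P[parent_states[i]] for element i."""
    cum = np.cumsum(P, axis=1)
    u = rng.random(len(parent_states))
    return (u[:, None] > cum[parent_states]).sum(axis=1)


def simulate_alignment(tree: TimeTree, rate_model: RateMatrix, n_sites: int,
                       rng: np.random.Generator) -> GenotypeAlignment:
    """Evolve n_sites characters down the tree under the substitution model.

    The root state is drawn from π per site; each child's state from the
    transition probabilities of its branch.  GT16 output is phased.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    S = rate_model.size
    states = {tree.root: rng.choice(S, size=n_sites, p=rate_model.pi)}
    for node in reversed(tree.postorder()):  # preorder
        if tree.is_tip(node):
            continue
        for c in tree.children[node]:
            c = int(c)
            P = rate_model.transition_probs(tree.branch_length(c))
            states[c] = _sample_rows(P, states[node], rng)
    m = tree.n_tips
    data = np.vstack([states[i] for i in range(m)]).astype(np.int16)
    # state indices coincide with code indices (states lead the code list)
    return GenotypeAlignment(tree.labels, data, rate_model.state_space,
                             phased=True)


def apply_errors(alignment: GenotypeAlignment, table: ErrorTable,
                 rng: np.random.Generator) -> GenotypeAlignment:
    """Corrupt each cell/site independently: observed ~ P(· | true state).

    Requires an alignment of unambiguous states (as produced by
    :func:`simulate_alignment`); missing entries would be left untouched
    but the simulator never emits them.
    """
    if table.state_space is not alignment.state_space:
        raise ValueError("error table does not match the alignment state space")
    S = table.size
    if alignment.data.max() >= S:
        raise ValueError("apply_errors requires unambiguous observed states")
    flat = alignment.data.ravel()
    observed = _sample_rows(table.E.T, flat, rng)
    data = observed.reshape(alignment.data.shape).astype(np.int16)
    return GenotypeAlignment(alignment.cells, data, alignment.state_space,
                             phased=alignment.phased)
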