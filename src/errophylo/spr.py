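"""Rooted subtree-prune-and-regraft (SPR) distance between tree topologies.

The distance is used as a topology-accuracy metric: how many SPR edits
separate an estimated tree from the truth.  Branch lengths are ignored.

Exact distances are computed through the maximum-agreement-forest (MAF)
characterisation of rooted SPR distance: augment both trees with a root
edge carrying a pseudo-leaf ρ; then d_SPR(T1, T2) equals the number of
components of a maximum agreement forest minus one.  The search runs
iterative deepening over k-subsets of edges of T1 to cut, checking each
induced leaf-label partition for agreement (identical rooted restricted
topologies and vertex-disjoint spanning subtrees in T2).  Label sets are
bitmasks, so the per-candidate check is cheap; distances up to ``d_max``
(default 6, the range reported for posterior trees) are exact.  Beyond
``d_max`` a certified bound pair is returned and flagged approximate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .trees import TimeTree, TreeError


@dataclass
class SprResult:
    """SPR distance, possibly only bracketed when above the exact cap."""

    lower: int
    upper: int
    exact: bool

    @property
    def distance(self) -> int:
        return self.lower if self.exact else self.upper


def _augmented_masks(tree: TimeTree, bit: dict) -> list[int]:
    """Leaf-set bitmasks of every node of the ρ-augmented tree."""
    m = tree.n_tips
    rho = 1 << m
    below = [0] * tree.n_nodes
    for node in tree.postorder():
        if tree.is_tip(node):
            below[node] = 1 << bit[tree.labels[node]]
        else:
            c1, c2 = tree.children[node]
            below[node] = below[c1] | below[c2]
    # augmentation: pseudo-leaf rho and a super-root above the old root
    masks = below + [rho, below[tree.root] | rho]
    return masks


def _components(cut_masks: tuple, full: int) -> list[int] | None:
    """Label sets induced by cutting the edges above the given nodes.

    Returns None when some component carries no labels (such cut sets are
    redundant: the same forest arises from fewer cuts).
    """
    comps = []
    for s in cut_masks:
        lab = s
        for d in cut_masks:
            if d is not s and (d & s) == d and d != s:
                lab &= ~d
        if lab == 0:
            return None
        comps.append(lab)
    rest = full
    for s in cut_masks:
        rest &= ~s
    if rest == 0:
        return None
    comps.append(rest)
    return comps


def _restricted_clades(masks: list[int], L: int) -> frozenset:
    out = set()
    for b in masks:
        x = b & L
        if x:
            out.add(x)
    return frozenset(out)


def _is_agreement_forest(comps: list[int], masks1: list[int],
                         masks2: list[int]) -> bool:
    # identical rooted restricted topologies
    for L in comps:
        if _restricted_clades(masks1, L) != _restricted_clades(masks2, L):
            return False
    # vertex-disjoint spanning subtrees in T2
    mrcas = []
    for L in comps:
        best = None
        for b in masks2:
            if (b & L) == L and (best is None or b & ~best == 0):
                if best is None or bin(b).count("1") < bin(best).count("1"):
                    best = b
        mrcas.append(best)
    for v in masks2:
        hits = 0
        for L, M in zip(comps, mrcas):
            if (v & L) and (v | M) == M:
                hits += 1
                if hits > 1:
                    return False
    return True


def spr_distance_bounds(tree_a: TimeTree, tree_b: TimeTree,
                        d_max: int = 6) -> SprResult:
    """Rooted SPR distance, exact up to ``d_max`` edits."""
    la, lb = set(tree_a.labels), set(tree_b.labels)
    if la != lb:
        raise TreeError("trees have different tip label sets")
    if tree_a.topology_key() == tree_b.topology_key():
        return SprResult(0, 0, True)
    m = tree_a.n_tips
    bit = {lbl: i for i, lbl in enumerate(sorted(la))}
    masks1 = _augmented_masks(tree_a, bit)
    masks2 = _augmented_masks(tree_b, bit)
    full = (1 << (m + 1)) - 1
    # cuttable edges: every node of the augmented T1 except its super-root
    cuttable = sorted(set(masks1) - {full})
    for k in range(1, d_max + 1):
        for cut in combinations(cuttable, k):
            comps = _components(cut, full)
            if comps is None:
                continue
            if _is_agreement_forest(comps, masks1, masks2):
                return SprResult(k, k, True)
    # the all-singletons partition is always an agreement forest
    return SprResult(d_max + 1, m, False)


def spr_distance(tree_a: TimeTree, tree_b: TimeTree, d_max: int = 6) -> int:
    """Exact rooted SPR distance; raises if it exceeds ``d_max``.

    Use :func:`spr_distance_bounds` to obtain bounds instead of an error
    for distant pairs.
    """
    res = spr_distance_bounds(tree_a, tree_b, d_max=d_max)
    if not res.exact:
        raise TreeError(
            f"SPR distance exceeds d_max={d_max} "
            f"(bounds [{res.lower}, {res.upper}])"
        )
    return res.distance


def apply_random_spr(tree: TimeTree, rng: np.random.Generator) -> TimeTree:
    """One uniformly chosen valid SPR edit of the topology.

    Heights of the result are synthetic (unit-rank ultrametric): the move
    is a topology operation used to construct trees a known number of
    edits away.
    """
    moves = []
    m = tree.n_tips
    for v in range(tree.n_nodes):
        p = int(tree.parent[v])
        if p < 0:
            continue
        in_sub = np.zeros(tree.n_nodes, dtype=bool)
        stack = [v]
        while stack:
            x = stack.pop()
            in_sub[x] = True
            if not tree.is_tip(x):
                stack.extend(tree.children[x])
        sib = int(tree.children[p, 0] if tree.children[p, 1] == v
                  else tree.children[p, 1])
        # regraft on the edge above u; u == old root means a new root is
        # created above it.  u == sib would reconstruct the same topology.
        for u in range(tree.n_nodes):
            if in_sub[u] or u == p or u == sib:
                continue
            moves.append((v, u))
    v, u = moves[rng.integers(len(moves))]
    kids = {i: list(tree.children[i]) for i in range(m, tree.n_nodes)}
    p = int(tree.parent[v])
    gp = int(tree.parent[p])
    sib = kids[p][0] if kids[p][1] == v else kids[p][1]
    root = tree.root
    if gp >= 0:
        kids[gp][kids[gp].index(p)] = sib
    else:
        root = sib
    if u == root:
        kids[p] = [v, u]
        root = p
    else:
        up = int(tree.parent[u])  # unchanged by pruning: u is not v or sib
        kids[up][kids[up].index(u)] = p
        kids[p] = [v, u]
    parent = np.full(tree.n_nodes, -1, dtype=np.int64)
    children = np.full((tree.n_nodes, 2), -1, dtype=np.int64)
    for i, (c1, c2) in kids.items():
        children[i] = (c1, c2)
        parent[c1] = i
        parent[c2] = i
    heights = np.zeros(tree.n_nodes)
    # synthetic ultrametric-ish heights: parent strictly above children
    order = []
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done or node < m:
            order.append(node)
        else:
            stack.append((node, True))
            stack.append((int(children[node, 0]), False))
            stack.append((int(children[node, 1]), False))
    for node in order:
        if node >= m:
            heights[node] = max(heights[children[node, 0]],
                                heights[children[node, 1]]) + 1.0
    return TimeTree(parent, children, heights, tree.labels, root=root)
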