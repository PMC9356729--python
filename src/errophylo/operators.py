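"""Metropolis–Hastings proposal kernels.

Scalar moves: multiplicative scaling (positive parameters) and reflected
uniform walks (probabilities).  Simplex moves: delta exchange preserving
the sum.  Tree moves: node-height slide, root-height scale, whole-tree
scale, narrow/wide subtree exchange, and Wilson–Balding prune–regraft.
Every kernel returns its log Hastings ratio; moves that select among
state-dependent candidate sets count candidates in both directions.
Proposals that would violate support (negative lengths, heights out of
order) return ``None`` and count as rejections.
"""

from __future__ import annotations

import math

import numpy as np

from .trees import TimeTree


class Proposal:
    """Outcome of a proposal: changed params and/or tree plus log HR."""

    __slots__ = ("params", "tree", "log_hastings", "changed")

    def __init__(self, params=None, tree=None, log_hastings=0.0, changed=()):
        self.params = params
        self.tree = tree
        self.log_hastings = log_hastings
        self.changed = changed


class Operator:
    affects_likelihood = True
    tunable = False
    weight = 1.0

    def __init__(self, name: str, weight: float = 1.0):
        self.name = name
        self.weight = weight
        self.n_proposed = 0
        self.n_accepted = 0

    def propose(self, params: dict, tree: TimeTree, rng) -> Proposal | None:
        raise NotImplementedError

    def tune(self, target: float = 0.3):
        pass

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / max(self.n_proposed, 1)


class _Tunable(Operator):
    tunable = True

    def __init__(self, name, weight=1.0, window=0.5):
        super().__init__(name, weight)
        self.window = window
        self._recent = [0, 0]  # proposed, accepted since last tune

    def record(self, accepted: bool):
        self.n_proposed += 1
        self._recent[0] += 1
        if accepted:
            self.n_accepted += 1
            self._recent[1] += 1

    def tune(self, target: float = 0.3):
        prop, acc = self._recent
        if prop < 20:
            return
        rate = acc / prop
        self.window *= math.exp(0.5 * (rate - target))
        self.window = min(max(self.window, 1e-4), 20.0)
        self._recent = [0, 0]


class ScaleOperator(_Tunable):
    """x' = x·s with log s ~ U(−w/2, w/2); Hastings ratio is s."""

    def __init__(self, param: str, weight=1.0, window=0.5,
                 affects_likelihood=True):
        super().__init__(f"scale:{param}", weight, window)
        self.param = param
        self.affects_likelihood = affects_likelihood

    def propose(self, params, tree, rng):
        s = math.exp(self.window * (rng.random() - 0.5))
        new = dict(params)
        new[self.param] = params[self.param] * s
        return Proposal(params=new, log_hastings=math.log(s),
                        changed=(self.param,))


class WalkOperator(_Tunable):
    """Uniform window walk reflected into [lo, hi]; symmetric (HR = 0)."""

    def __init__(self, param: str, weight=1.0, window=0.1, lo=0.0, hi=1.0):
        super().__init__(f"walk:{param}", weight, window)
        self.param = param
        self.lo, self.hi = lo, hi

    def propose(self, params, tree, rng):
        x = params[self.param] + self.window * (rng.random() - 0.5)
        span = self.hi - self.lo
        # reflect into the interval
        x = (x - self.lo) % (2 * span)
        x = self.lo + (x if x <= span else 2 * span - x)
        new = dict(params)
        new[self.param] = x
        return Proposal(params=new, changed=(self.param,))


class DeltaExchangeOperator(_Tunable):
    """Transfer mass between two components of a simplex parameter."""

    def __init__(self, param: str, weight=1.0, window=0.05, floor=1e-7):
        super().__init__(f"delta:{param}", weight, window)
        self.param = param
        self.floor = floor

    def propose(self, params, tree, rng):
        x = params[self.param]
        k = len(x)
        i = rng.integers(k)
        j = rng.integers(k - 1)
        if j >= i:
            j += 1
        d = rng.random() * self.window
        if x[i] - d < self.floor:
            return None
        new_x = x.copy()
        new_x[i] -= d
        new_x[j] += d
        new = dict(params)
        new[self.param] = new_x
        return Proposal(params=new, changed=(self.param,))


class NodeSlideOperator(Operator):
    """New height for a random internal non-root node, uniform between
    its highest child and its parent; symmetric."""

    def __init__(self, weight=1.0):
        super().__init__("tree:node-slide", weight)

    def propose(self, params, tree, rng):
        m = tree.n_tips
        if m < 3:
            return None
        node = int(rng.integers(m, 2 * m - 1))
        if node == tree.root:
            return None
        lo = max(tree.heights[int(c)] for c in tree.children[node])
        hi = tree.heights[tree.parent[node]]
        t = tree.copy()
        t.heights[node] = lo + rng.random() * (hi - lo)
        return Proposal(tree=t)


class RootScaleOperator(_Tunable):
    """Scale the root's offset above its higher child."""

    def __init__(self, weight=1.0, window=0.7):
        super().__init__("tree:root-scale", weight, window)

    def propose(self, params, tree, rng):
        r = tree.root
        lo = max(tree.heights[int(c)] for c in tree.children[r])
        off = tree.heights[r] - lo
        if off <= 0:
            return None
        s = math.exp(self.window * (rng.random() - 0.5))
        t = tree.copy()
        t.heights[r] = lo + off * s
        return Proposal(tree=t, log_hastings=math.log(s))


class TreeScaleOperator(_Tunable):
    """Scale all internal-node heights; HR = (#internal) log s."""

    def __init__(self, weight=1.0, window=0.3):
        super().__init__("tree:scale", weight, window)

    def propose(self, params, tree, rng):
        s = math.exp(self.window * (rng.random() - 0.5))
        m = tree.n_tips
        t = tree.copy()
        t.heights[m:] *= s
        if np.any(t.heights[t.parent[:m]] < t.heights[:m]):
            return None
        return Proposal(tree=t, log_hastings=(m - 1) * math.log(s))


def _subtree_masks(tree: TimeTree):
    masks = [0] * tree.n_nodes
    for node in tree.postorder():
        if tree.is_tip(node):
            masks[node] = 1 << node
        else:
            c1, c2 = tree.children[node]
            masks[node] = masks[c1] | masks[c2] | (1 << node)
    return masks


class ExchangeOperator(Operator):
    """Swap two subtrees (narrow: nephew↔aunt; wide: any valid pair).

    The pair is drawn uniformly from the eligible set; the Hastings ratio
    is the ratio of eligible-set sizes before and after the swap.
    """

    def __init__(self, narrow: bool = True, weight=1.0):
        super().__init__("tree:narrow-exchange" if narrow else "tree:wide-exchange",
                         weight)
        self.narrow = narrow

    def _candidates(self, tree: TimeTree):
        cands = []
        h = tree.heights
        if self.narrow:
            m = tree.n_tips
            for u in range(m, 2 * m - 1):
                p = tree.parent[u]
                if p < 0:
                    continue
                a = int(tree.children[p, 0] if tree.children[p, 1] == u
                        else tree.children[p, 1])
                if h[u] > h[a]:
                    for c in tree.children[u]:
                        cands.append((int(c), a))
        else:
            masks = _subtree_masks(tree)
            nodes = [v for v in range(tree.n_nodes) if tree.parent[v] >= 0]
            for i in nodes:
                pi = tree.parent[i]
                for j in nodes:
                    if j <= i or tree.parent[j] == pi:
                        continue
                    pj = tree.parent[j]
                    if masks[i] >> j & 1 or masks[j] >> i & 1:
                        continue
                    if h[pj] > h[i] and h[pi] > h[j]:
                        cands.append((i, j))
        return cands

    def propose(self, params, tree, rng):
        cands = self._candidates(tree)
        if not cands:
            return None
        i, j = cands[rng.integers(len(cands))]
        t = tree.copy()
        pi, pj = int(t.parent[i]), int(t.parent[j])
        t.children[pi, int(t.children[pi, 1] == i)] = j
        t.children[pj, int(t.children[pj, 1] == j)] = i
        t.parent[i], t.parent[j] = pj, pi
        t.invalidate()
        n_before = len(cands)
        n_after = len(self._candidates(t))
        if n_after == 0:
            return None
        return Proposal(tree=t,
                        log_hastings=math.log(n_before) - math.log(n_after))


class WilsonBaldingOperator(Operator):
    """Prune a subtree and regraft it onto another branch at a uniform
    height; the classic rooted prune–regraft move for time-trees.

    The pruned node i is chosen uniformly among nodes with a grandparent
    (a constant-size set); the destination branch uniformly among valid
    ones; the new attachment height uniformly in its feasible interval.
    Regrafting above the root is not proposed (root exchanges are covered
    by the exchange moves).
    """

    def __init__(self, weight=1.0):
        super().__init__("tree:wilson-balding", weight)

    @staticmethod
    def _valid_targets(tree: TimeTree, i: int, p: int, masks):
        h = tree.heights
        out = []
        for j in range(tree.n_nodes):
            if j == i or j == p or j == tree.root:
                continue
            if masks[i] >> j & 1:
                continue
            if h[tree.parent[j]] > h[i]:
                out.append(j)
        return out

    def propose(self, params, tree, rng):
        m = tree.n_tips
        cand_i = [v for v in range(tree.n_nodes)
                  if tree.parent[v] >= 0 and tree.parent[tree.parent[v]] >= 0]
        if not cand_i:
            return None
        i = cand_i[rng.integers(len(cand_i))]
        p = int(tree.parent[i])
        gp = int(tree.parent[p])
        s = int(tree.children[p, 0] if tree.children[p, 1] == i
                else tree.children[p, 1])
        masks = _subtree_masks(tree)
        targets = self._valid_targets(tree, i, p, masks)
        if not targets:
            return None
        j = targets[rng.integers(len(targets))]
        pj = int(tree.parent[j])
        h = tree.heights
        lo_f = max(h[i], h[j])
        # in the pruned tree the branch above the old sibling runs to gp
        hi_f = h[gp] if j == s else h[pj]
        if hi_f <= lo_f:
            return None
        u = lo_f + rng.random() * (hi_f - lo_f)
        # reverse move: regraft i back next to its old sibling s under gp
        lo_r = max(h[i], h[s])
        hi_r = h[gp]
        t = tree.copy()
        # detach p: gp adopts s
        t.children[gp, int(t.children[gp, 1] == p)] = s
        t.parent[s] = gp
        if j == s:
            # reattach on the same branch (now s under gp): topology kept,
            # p keeps children {i, s} and only its height changes
            t.children[gp, int(t.children[gp, 1] == s)] = p
            t.parent[s] = p
            t.parent[p] = gp
        else:
            t.children[pj, int(t.children[pj, 1] == j)] = p
            t.children[p, int(t.children[p, 1] == s)] = j
            t.parent[j] = p
            t.parent[p] = pj
        t.heights[p] = u
        t.invalidate()
        masks2 = _subtree_masks(t)
        n_rev = len(self._valid_targets(t, i, p, masks2))
        n_fwd = len(targets)
        log_hr = (math.log(n_fwd) + math.log(hi_f - lo_f)
                  - math.log(n_rev) - math.log(hi_r - lo_r))
        return Proposal(tree=t, log_hastings=log_hr)


class UpDownOperator(_Tunable):
    """Jointly scale tree heights (up) and correlated scalars (up/down).

    Classic remedy for the strong posterior correlation between tree
    height and its rate-like hyperparameter: all internal heights and the
    ``up`` parameters are multiplied by s, the ``down`` parameters divided
    by s.  HR = (#scaled up − #scaled down)·log s with heights counted
    individually.
    """

    def __init__(self, up=(), down=(), weight=1.0, window=0.2):
        super().__init__(f"updown:{'+'.join(up) or '-'}/{'+'.join(down) or '-'}",
                         weight, window)
        self.up = tuple(up)
        self.down = tuple(down)

    def propose(self, params, tree, rng):
        s = math.exp(self.window * (rng.random() - 0.5))
        m = tree.n_tips
        t = tree.copy()
        t.heights[m:] *= s
        if np.any(t.heights[t.parent[:m]] < t.heights[:m]):
            return None
        new = dict(params)
        for name in self.up:
            new[name] = params[name] * s
        for name in self.down:
            new[name] = params[name] / s
        ndim = (m - 1) + len(self.up) - len(self.down)
        return Proposal(params=new, tree=t, log_hastings=ndim * math.log(s),
                        changed=self.up + self.down)
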