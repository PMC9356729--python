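"""Rooted binary time-trees and the tree statistics reported for them.

A :class:`TimeTree` is a strictly binary rooted tree with m labelled tips
and node heights (tips at height 0 unless dated).  Branch lengths are
height differences, in units of expected substitutions per site (or years
when calibrated).  The representation is flat arrays (parent, children,
heights) so MCMC proposals can clone and mutate trees cheaply; Newick
parsing/writing round-trips through dendropy.
"""

from __future__ import annotations

import io

import numpy as np
import dendropy


class TreeError(ValueError):
    pass


class TimeTree:
    """Rooted binary tree with node heights.

    Nodes are integers ``0 .. 2m-2``: tips ``0..m-1`` carry ``labels``,
    the rest are internal.  ``children[i]`` is ``(-1, -1)`` for tips.
    """

    __slots__ = ("parent", "children", "heights", "labels", "root",
                 "_postorder", "_ipostorder")

    def __init__(self, parent, children, heights, labels, root=None,
                 validate: bool = True):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = np.asarray(children, dtype=np.int64)
        self.heights = np.asarray(heights, dtype=float)
        self.labels = list(labels)
        self.root = int(root) if root is not None else int(np.nonzero(self.parent < 0)[0][0])
        self._postorder = None
        self._ipostorder = None
        if validate:
            self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    def validate(self):
        m = self.n_tips
        if m < 2:
            raise TreeError("a tree needs at least 2 tips")
        if len(set(self.labels)) != m:
            raise TreeError("tip labels must be unique")
        if self.parent.shape != (2 * m - 1,) or self.children.shape != (2 * m - 1, 2):
            raise TreeError("inconsistent array shapes")
        if (self.parent < 0).sum() != 1:
            raise TreeError("exactly one root expected")
        for i in range(m, 2 * m - 1):
            c1, c2 = self.children[i]
            if c1 < 0 or c2 < 0:
                raise TreeError(f"internal node {i} is not binary")
            for c in (c1, c2):
                if self.parent[c] != i:
                    raise TreeError("parent/child arrays disagree")
                if self.heights[i] < self.heights[c] - 1e-12:
                    raise TreeError("parent below child")
        if len(self.postorder()) != self.n_nodes:
            raise TreeError("tree is not connected")

    def postorder(self):
        """Node ids in post-order (children before parents); cached."""
        if self._postorder is None:
            order = []
            stack = [(self.root, False)]
            while stack:
                node, done = stack.pop()
                if done or self.is_tip(node):
                    order.append(node)
                else:
                    stack.append((node, True))
                    stack.append((int(self.children[node, 0]), False))
                    stack.append((int(self.children[node, 1]), False))
            self._postorder = order
        return self._postorder

    def internal_postorder(self):
        """Internal node ids in post-order; cached."""
        if self._ipostorder is None:
            m = self.n_tips
            self._ipostorder = [n for n in self.postorder() if n >= m]
        return self._ipostorder

    def invalidate(self):
        """Drop cached traversals after a topology change."""
        self._postorder = None
        self._ipostorder = None

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        if p < 0:
            return 0.0
        return float(self.heights[p] - self.heights[node])

    def branch_lengths(self) -> np.ndarray:
        bl = self.heights[self.parent] - self.heights
        bl[self.root] = 0.0
        return bl

    def copy(self) -> "TimeTree":
        t = TimeTree.__new__(TimeTree)
        t.parent = self.parent.copy()
        t.children = self.children.copy()
        t.heights = self.heights.copy()
        t.labels = self.labels
        t.root = self.root
        # height-only moves keep the topology: share cached traversals
        t._postorder = self._postorder
        t._ipostorder = self._ipostorder
        return t

    # -- statistics --------------------------------------------------------

    def tree_length(self) -> float:
        """Sum of all branch lengths."""
        return float(self.branch_lengths().sum())

    def tree_height(self) -> float:
        """Maximum root-to-tip path length."""
        m = self.n_tips
        return float(self.heights[self.root] - self.heights[:m].min())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        m = self.n_tips
        h = self.tree_height()
        return bool(np.ptp(self.heights[:m]) <= rel_tol * max(h, 1e-300))

    def clades(self):
        """Frozensets of tip labels below each internal node (root included)."""
        below = {}
        for node in self.postorder():
            if self.is_tip(node):
                below[node] = frozenset([self.labels[node]])
            else:
                c1, c2 = self.children[node]
                below[node] = below[c1] | below[c2]
        return [below[n] for n in range(self.n_tips, self.n_nodes)]

    def topology_key(self) -> frozenset:
        """Canonical rooted-topology identifier (the set of clades)."""
        return frozenset(self.clades())

    # -- Newick ------------------------------------------------------------

    def to_newick(self, precision: int = 12) -> str:
        fmt = f"%.{precision}g"
        out = []

        def rec(node):
            if self.is_tip(node):
                out.append(self.labels[node])
            else:
                out.append("(")
                rec(int(self.children[node, 0]))
                out.append(",")
                rec(int(self.children[node, 1]))
                out.append(")")
            p = self.parent[node]
            if p >= 0:
                out.append(":" + fmt % (self.heights[p] - self.heights[node]))

        rec(self.root)
        out.append(";")
        return "".join(out)


def from_dendropy(dtree: dendropy.Tree) -> TimeTree:
    """Convert a dendropy tree (branch lengths required) to a TimeTree."""
    dnodes = list(dtree.preorder_node_iter())
    for nd in dnodes:
        nchild = len(nd.child_nodes())
        if nchild not in (0, 2):
            raise TreeError(
                f"tree is not strictly binary: node with {nchild} children"
            )
    tips = [nd for nd in dnodes if nd.is_leaf()]
    labels = [nd.taxon.label if nd.taxon else nd.label for nd in tips]
    if any(lbl is None for lbl in labels):
        raise TreeError("every tip needs a label")
    m = len(tips)
    index = {id(nd): i for i, nd in enumerate(tips)}
    nxt = m
    for nd in dnodes:
        if not nd.is_leaf():
            index[id(nd)] = nxt
            nxt += 1
    parent = np.full(2 * m - 1, -1, dtype=np.int64)
    children = np.full((2 * m - 1, 2), -1, dtype=np.int64)
    depth = np.zeros(2 * m - 1)
    for nd in dnodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            if nd.edge.length is None:
                raise TreeError("branch lengths are required")
            depth[i] = depth[p] + float(nd.edge.length)
        for k, ch in enumerate(nd.child_nodes()):
            children[i, k] = index[id(ch)]
    heights = depth.max() - depth
    heights -= heights[:m].min()
    heights[heights < 0] = 0.0
    return TimeTree(parent, children, heights, labels)


def parse_newick(text: str) -> TimeTree:
    """Parse a Newick string with branch lengths into a TimeTree."""
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from exc
    return from_dendropy(dtree)


def write_newick(tree: TimeTree) -> str:
    return tree.to_newick()


def tree_length(tree: TimeTree) -> float:
    return tree.tree_length()


def tree_height(tree: TimeTree) -> float:
    return tree.tree_height()


def treeness(tree: TimeTree) -> float:
    """Fraction of total tree length contributed by internal branches."""
    if tree.n_tips < 3:
        raise TreeError("treeness requires at least 3 tips")
    bl = tree.branch_lengths()
    total = bl.sum()
    internal = bl[tree.n_tips:].sum()
    if total == 0:
        raise TreeError("treeness undefined for a zero-length tree")
    return float(internal / total)


def gamma_statistic(tree: TimeTree, rel_tol: float = 1e-6) -> float:
    """Pybus–Harvey γ from the internode intervals of an ultrametric tree.

    γ is approximately standard normal under a constant-rate pure-birth
    process; negative values indicate internal nodes closer to the root
    than expected.
    """
    n = tree.n_tips
    if n < 3:
        raise TreeError("gamma statistic requires at least 3 tips")
    if not tree.is_ultrametric(rel_tol):
        raise TreeError("gamma statistic is defined on ultrametric trees")
    # g[k] = duration with exactly k lineages, k = 2..n
    internal = np.sort(tree.heights[n:])[::-1]  # root first
    times = np.concatenate([internal, [0.0]])
    g = times[:-1] - times[1:]  # g[0] is the 2-lineage interval
    ks = np.arange(2, n + 1)
    kg = ks * g
    T = kg.sum()
    csum = np.cumsum(kg)[:-1]  # partial sums for i = 2..n-1
    mean_part = csum.sum() / (n - 2)
    return float((mean_part - T / 2.0) / (T * np.sqrt(1.0 / (12.0 * (n - 2)))))


def trees_to_nexus(trees, names=None) -> str:
    """Write a collection of TimeTrees as a Nexus trees block."""
    trees = list(trees)
    if not trees:
        raise TreeError("no trees to write")
    labels = trees[0].labels
    buf = io.StringIO()
    buf.write("#NEXUS\nBegin trees;\n\tTranslate\n")
    for i, lbl in enumerate(labels, 1):
        sep = "," if i < len(labels) else ""
        buf.write(f"\t\t{i} {lbl}{sep}\n")
    buf.write("\t\t;\n")
    index = {lbl: str(i) for i, lbl in enumerate(labels, 1)}
    for k, t in enumerate(trees):
        nwk = t.to_newick()
        for lbl in sorted(index, key=len, reverse=True):
            nwk = nwk.replace(lbl + ":", index[lbl] + ":")
        name = names[k] if names is not None else f"STATE_{k}"
        buf.write(f"tree {name} = {nwk}\n")
    buf.write("End;\n")
    return buf.getvalue()


def trees_from_nexus(text: str):
    """Read trees from a Nexus trees block into TimeTrees."""
    tlist = dendropy.TreeList.get(data=text, schema="nexus")
    return [from_dendropy(t) for t in tlist]
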