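"""Felsenstein pruning likelihood with error-aware tip partials.

Sites evolve independently, so the alignment log-likelihood is the sum of
per-site values.  The partial likelihood of internal node g with children
e, f on branches t_e, t_f is

    L_g(x) = [Σ_y P_xy(t_e) L_e(y)] · [Σ_z P_xz(t_f) L_f(z)],

and the site likelihood is Σ_x π_x L_root(x).  Without an error model the
tip partial for observed state x is the indicator vector; with one it is
the column of conditional observation probabilities (P(x|y) over true
states y); ambiguities sum their resolutions and missing data gives the
all-ones vector.

Implementation notes: identical site patterns are collapsed and weighted
(per-site values are expanded back on demand); transition matrices for
all branches come from one batched eigendecomposition product; partials
are rescaled every few levels with accumulated log scalers, which guards
against underflow without changing the returned value.
"""

from __future__ import annotations

import numpy as np

from .alignment import GenotypeAlignment
from .errors import ErrorTable
from .substitution import RateMatrix
from .trees import TimeTree

_RESCALE_INTERVAL = 8  # internal nodes between rescaling sweeps


class LikelihoodResult:
    """Total log-likelihood with lazily expanded per-site values."""

    def __init__(self, total: float, per_pattern: np.ndarray,
                 pattern_index: np.ndarray):
        self.total = total
        self._per_pattern = per_pattern
        self._pattern_index = pattern_index

    @property
    def per_site(self) -> np.ndarray:
        return self._per_pattern[self._pattern_index]


class LikelihoodEngine:
    """Reusable pruning engine bound to one alignment and tip ordering.

    MCMC re-evaluates the likelihood with new parameters and heights many
    thousands of times; the engine owns the pattern compression, the
    code-resolution matrix and the work buffers.
    """

    def __init__(self, alignment: GenotypeAlignment, tree: TimeTree):
        if set(alignment.cells) != set(tree.labels):
            missing = set(alignment.cells) ^ set(tree.labels)
            raise ValueError(
                f"tree tips and alignment cells differ: {sorted(missing)}"
            )
        self.alignment = alignment
        space = alignment.state_space
        S = space.size
        row_of_tip = np.array([alignment.cells.index(lbl)
                               for lbl in tree.labels])
        data = alignment.data[row_of_tip]           # (m, n) in tip-node order
        # collapse identical site patterns
        patterns, index, counts = np.unique(
            data, axis=1, return_inverse=True, return_counts=True)
        self.pattern_data = np.ascontiguousarray(patterns)   # (m, n_pat)
        self.pattern_index = index.ravel()
        self.pattern_counts = counts.astype(float)
        # resolution matrix: R[code, x] = 1 iff state x is a resolution
        codes = alignment.codes
        R = np.zeros((len(codes), S))
        for k, code in enumerate(codes):
            R[k, list(space.resolve(code))] = 1.0
        self.resolution = R
        m = tree.n_tips
        self.n_nodes = 2 * m - 1
        self._buf = np.empty((self.n_nodes, self.pattern_data.shape[1], S))
        self._scaler = np.empty(self.pattern_data.shape[1])

    def total(self, tree: TimeTree, rate_model: RateMatrix,
              error_table: ErrorTable | None = None) -> float:
        return self._run(tree, rate_model, error_table)[0]

    def compute(self, tree: TimeTree, rate_model: RateMatrix,
                error_table: ErrorTable | None = None) -> LikelihoodResult:
        total, per_pattern = self._run(tree, rate_model, error_table)
        return LikelihoodResult(total, per_pattern, self.pattern_index)

    def _run(self, tree, rate_model, error_table):
        S = rate_model.size
        if error_table is None:
            W = self.resolution
        else:
            W = self.resolution @ error_table.E
        bl = tree.heights[tree.parent] - tree.heights
        bl[tree.root] = 0.0
        if bl.min() < -1e-12:
            raise ValueError("negative branch length")
        np.clip(bl, 0.0, None, out=bl)
        w, U, sqrt_pi = rate_model._eig
        expwt = np.exp(bl[:, None] * w[None, :])
        # P[b] = exp(Q t_b), reconstructed from the symmetrised eigensystem
        P = np.matmul(U[None, :, :] * expwt[:, None, :], U.T)
        P *= sqrt_pi[None, None, :] / sqrt_pi[None, :, None]
        np.clip(P, 0.0, None, out=P)
        m = tree.n_tips
        buf = self._buf
        buf[:m] = W[self.pattern_data]
        scaler = self._scaler
        scaler[:] = 0.0
        children = tree.children
        since_rescale = 0
        for node in tree.internal_postorder():
            c1, c2 = children[node]
            np.multiply(buf[c1] @ P[c1].T, buf[c2] @ P[c2].T, out=buf[node])
            since_rescale += 1
            if since_rescale >= _RESCALE_INTERVAL:
                mx = buf[node].max(axis=1)
                if mx.min() <= 0.0:
                    bad = int(np.argmax(mx <= 0.0))
                    site = int(np.argmax(self.pattern_index == bad))
                    raise FloatingPointError(
                        f"zero partial likelihood at site {site + 1}")
                buf[node] /= mx[:, None]
                scaler += np.log(mx)
                since_rescale = 0
        site_l = buf[tree.root] @ rate_model.pi
        if site_l.min() <= 0.0:
            bad = int(np.argmax(site_l <= 0.0))
            site = int(np.argmax(self.pattern_index == bad))
            raise FloatingPointError(f"zero likelihood at site {site + 1}")
        per_pattern = np.log(site_l) + scaler
        total = float(per_pattern @ self.pattern_counts)
        if not np.isfinite(total):
            raise FloatingPointError("non-finite log-likelihood")
        return total, per_pattern


def log_likelihood(alignment: GenotypeAlignment, tree: TimeTree,
                   rate_model: RateMatrix,
                   error_table: ErrorTable | None = None) -> LikelihoodResult:
    """Alignment log-likelihood given tree, substitution and error model."""
    return LikelihoodEngine(alignment, tree).compute(tree, rate_model, error_table)


def per_site_likelihoods(alignment: GenotypeAlignment, tree: TimeTree,
                         rate_model: RateMatrix,
                         error_table: ErrorTable | None = None) -> np.ndarray:
    """Vector of per-site log-likelihoods (diagnostic view of the same sum)."""
    return log_likelihood(alignment, tree, rate_model, error_table).per_site
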