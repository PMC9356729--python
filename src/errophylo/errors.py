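"""Observation error models for single-cell SNV data.

Errors act on the tips of the tree: the true genotype y is observed as x
with probability E[x, y] = P(x | y).  Two models are provided:

* **Binary** (false positives/negatives): P(1|0) = α, P(0|1) = β.
* **GT16** (allelic dropout δ and combined amplification/sequencing
  error ϵ), acting on ordered diploid genotypes.  For a true homozygote
  aa::

      P(aa|aa) = 1 − ϵ + δϵ/2
      P(ab|aa) = P(ba|aa) = (1−δ) ϵ/6          (b ≠ a)
      P(bb|aa) = δϵ/6                          (b ≠ a)

  For a true ordered heterozygote ab (a ≠ b, alleles c ∉ {a, b})::

      P(ab|ab) = (1−δ)(1−ϵ)
      P(aa|ab) = P(bb|ab) = δ/2 + ϵ/6 − δϵ/3
      P(ac|ab) = P(cb|ab) = (1−δ) ϵ/6
      P(cc|ab) = δϵ/6

  All other observations have probability zero.  This is the per-allele
  reading of the model: the first observed allele derives from a, the
  second from b, and a single error event never swaps the pair, so e.g.
  P(ba|ab) = 0 while P(ba|aa) = P(ab|aa).  Under this convention each
  column of the 16×16 table sums to exactly 1 and the table collapses to
  the identity at ϵ = δ = 0.

Unphased heterozygous observations ab* are handled as ambiguities with
P(ab*|y) = P(ab|y) + P(ba|y).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .states import BINARY, GT16, MISSING, NUCLEOTIDES, StateSpace
from .substitution import InvalidParameterError

COLUMN_SUM_TOL = 1e-10


class ErrorTableConstructionError(RuntimeError):
    """Raised when an error table fails its normalization invariant."""


def _check_prob(name, value):
    if not np.isfinite(value) or not 0.0 <= value <= 1.0:
        raise InvalidParameterError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class BinaryErrorParams:
    """False positive probability α and false negative probability β."""

    alpha: float
    beta: float

    def __post_init__(self):
        _check_prob("alpha", self.alpha)
        _check_prob("beta", self.beta)


@dataclass
class Gt16ErrorParams:
    """Amplification/sequencing error ϵ and allelic dropout δ."""

    eps: float
    delta: float

    def __post_init__(self):
        _check_prob("eps", self.eps)
        _check_prob("delta", self.delta)


class ErrorTable:
    """Conditional observation probabilities E[x, y] = P(observe x | true y).

    Columns (fixed true state y) are probability distributions over the
    observed states x.
    """

    def __init__(self, E: np.ndarray, state_space: StateSpace):
        E = np.asarray(E, dtype=float)
        if np.any(E < -COLUMN_SUM_TOL) or np.any(E > 1 + COLUMN_SUM_TOL):
            raise ErrorTableConstructionError("error table entries outside [0, 1]")
        colsums = E.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > COLUMN_SUM_TOL):
            worst = np.argmax(np.abs(colsums - 1.0))
            raise ErrorTableConstructionError(
                f"error-table column for true state "
                f"{state_space.states[worst]!r} sums to {colsums[worst]!r}, not 1"
            )
        self.E = np.clip(E, 0.0, 1.0)
        self.state_space = state_space

    @property
    def size(self) -> int:
        return self.E.shape[0]


def binary_error_table(params: BinaryErrorParams) -> ErrorTable:
    """2×2 table: P(0|0)=1−α, P(1|0)=α, P(0|1)=β, P(1|1)=1−β."""
    a, b = params.alpha, params.beta
    E = np.array([[1.0 - a, b],
                  [a, 1.0 - b]])
    return ErrorTable(E, BINARY)


def gt16_error_table(params: Gt16ErrorParams) -> ErrorTable:
    """16×16 GT16 error table over ordered genotypes (see module docstring)."""
    eps, delta = params.eps, params.delta
    idx = {s: i for i, s in enumerate(GT16.states)}
    E = np.zeros((16, 16))
    p_hom_keep = 1.0 - eps + 0.5 * delta * eps
    p_hom_to_het = (1.0 - delta) * eps / 6.0
    p_hom_to_hom = delta * eps / 6.0
    p_het_keep = (1.0 - delta) * (1.0 - eps)
    p_het_to_hom = 0.5 * delta + eps / 6.0 - delta * eps / 3.0
    p_het_one_err = (1.0 - delta) * eps / 6.0
    p_het_to_other_hom = delta * eps / 6.0
    for a in NUCLEOTIDES:
        for b in NUCLEOTIDES:
            y = idx[a + b]
            if a == b:
                E[idx[a + a], y] = p_hom_keep
                for c in NUCLEOTIDES:
                    if c == a:
                        continue
                    E[idx[a + c], y] = p_hom_to_het
                    E[idx[c + a], y] = p_hom_to_het
                    E[idx[c + c], y] = p_hom_to_hom
            else:
                E[idx[a + b], y] = p_het_keep
                E[idx[a + a], y] = p_het_to_hom
                E[idx[b + b], y] = p_het_to_hom
                for c in NUCLEOTIDES:
                    if c in (a, b):
                        continue
                    E[idx[a + c], y] = p_het_one_err  # second allele b -> c
                    E[idx[c + b], y] = p_het_one_err  # first allele a -> c
                    E[idx[c + c], y] = p_het_to_other_hom
    return ErrorTable(E, GT16)


def identity_error_table(state_space: StateSpace) -> ErrorTable:
    """Error-free observation: the identity table."""
    return ErrorTable(np.eye(state_space.size), state_space)


def tip_partials(observed: str, table: ErrorTable | None,
                 state_space: StateSpace | None = None) -> np.ndarray:
    """Per-site partial likelihood vector over true states for one tip.

    For an observed unambiguous state x the vector is (P(x|y) for all y);
    for an ambiguity (unphased heterozygote ab*) the sum of the resolved
    rows; for missing data the all-ones vector.  With ``table=None`` the
    error-free indicator convention applies (``state_space`` then required).
    """
    if table is None:
        if state_space is None:
            raise ValueError("state_space required when no error table is given")
        space = state_space
        E = np.eye(space.size)
    else:
        space = table.state_space
        E = table.E
    if observed == MISSING:
        return np.ones(space.size)
    rows = space.resolve(observed)
    return E[list(rows)].sum(axis=0)


def partials_lookup(table: ErrorTable | None, state_space: StateSpace,
                    codes: list[str]) -> np.ndarray:
    """Matrix of tip partial vectors, one row per code in ``codes``.

    Used by the likelihood engine: alignments store integer code indices
    into this lookup so tip partials for a whole alignment are a single
    fancy-indexing operation.
    """
    return np.vstack([tip_partials(c, table, state_space) for c in codes])
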