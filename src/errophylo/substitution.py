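"""Binary and GT16 substitution models.

The binary model has a single back-mutation rate λ (0→1 occurs at rate 1,
1→0 at rate λ), giving stationary frequencies π = (λ/(λ+1), 1/(λ+1)).

The GT16 model extends the general time-reversible nucleotide model to the
16 ordered diploid genotypes: only single-allele changes have nonzero rate,

    Q[aa→ab] = r_ab π_ab,  Q[aa→ba] = r_ab π_ba,
    Q[ab→aa] = r_ab π_aa,  Q[ab→bb] = r_ab π_bb,

with six exchangeabilities r = (r_AC, r_AG, r_AT, r_CG, r_CT, r_GT) and
equilibrium genotype frequencies π.  Both models are time-reversible, so
transition probabilities P(t) = exp(Qt) are computed by eigendecomposition
of the symmetrised form diag(√π) Q diag(1/√π).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .states import BINARY, GT16, NUCLEOTIDES, StateSpace

#: Unordered allele pairs indexing the 6-vector of GT16 exchangeabilities.
RATE_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))

MIN_FREQ = 1e-8  # below this, Q risks losing irreducibility


def _gt16_sparsity():
    """Index arrays for the nonzero off-diagonals of the GT16 generator:
    single-allele changes between a homozygote and a heterozygote."""
    states = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)
    idx = {s: i for i, s in enumerate(states)}
    pair_idx = {}
    for k, (a, b) in enumerate(RATE_PAIRS):
        pair_idx[a + b] = pair_idx[b + a] = k
    rows, cols, ridx = [], [], []
    for a in NUCLEOTIDES:
        for b in NUCLEOTIDES:
            if a == b:
                continue
            k = pair_idx[a + b]
            for x, y in ((a + a, a + b), (a + a, b + a),
                         (a + b, a + a), (a + b, b + b)):
                rows.append(idx[x])
                cols.append(idx[y])
                ridx.append(k)
    import numpy as _np
    return (_np.array(rows), _np.array(cols), _np.array(ridx))


class InvalidParameterError(ValueError):
    pass


@dataclass
class BinaryModelParams:
    """Back-mutation rate λ of the binary model (forward rate fixed at 1)."""

    lam: float

    def __post_init__(self):
        if not np.isfinite(self.lam) or self.lam <= 0:
            raise InvalidParameterError(f"lam must be positive, got {self.lam}")


@dataclass
class Gt16ModelParams:
    """GT16 exchangeabilities and equilibrium genotype frequencies.

    ``rates`` is the 6-vector (r_AC, r_AG, r_AT, r_CG, r_CT, r_GT);
    ``freqs`` the 16-vector π over the canonical genotype order.
    """

    rates: np.ndarray
    freqs: np.ndarray

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.rates.shape != (6,) or np.any(self.rates <= 0):
            raise InvalidParameterError("rates must be 6 positive values")
        if self.freqs.shape != (16,) or np.any(self.freqs < MIN_FREQ):
            raise InvalidParameterError(
                f"freqs must be 16 values, each >= {MIN_FREQ}"
            )
        if abs(self.freqs.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("freqs must sum to 1 within 1e-12")


class RateMatrix:
    """A reversible rate matrix Q with stationary distribution π.

    Holds an eigendecomposition of the symmetrised generator for fast,
    stable computation of P(t) = exp(Qt).
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray, state_space: StateSpace,
                 normalized: bool = False):
        self.Q = np.asarray(Q, dtype=float)
        self.pi = np.asarray(pi, dtype=float)
        self.state_space = state_space
        self.normalized = normalized
        self._decompose()

    def _decompose(self):
        pi = self.pi
        if np.all(pi > MIN_FREQ / 2):
            sqrt_pi = np.sqrt(pi)
            S = self.Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
            S = 0.5 * (S + S.T)  # symmetric up to round-off for reversible Q
            w, U = np.linalg.eigh(S)
            self._eig = (w, U, sqrt_pi)
        else:  # pragma: no cover - guarded by parameter validation
            self._eig = None

    @property
    def size(self) -> int:
        return self.Q.shape[0]

    def expected_rate(self) -> float:
        """Expected substitutions per site per unit branch length, −Σ π_x Q_xx."""
        return float(-np.dot(self.pi, np.diag(self.Q)))

    def transition_probs(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) for branch length t ≥ 0."""
        if t < 0:
            raise ValueError(f"branch length must be nonnegative, got {t}")
        if self._eig is not None:
            w, U, sqrt_pi = self._eig
            inner = (U * np.exp(w * t)) @ U.T
            P = inner * (sqrt_pi[None, :] / sqrt_pi[:, None])
        else:  # pragma: no cover
            P = scipy.linalg.expm(self.Q * t)
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


_GT16_SPARSITY = _gt16_sparsity()


def build_binary_q(params: BinaryModelParams) -> RateMatrix:
    """Binary rate matrix Q = [[−1, 1], [λ, −λ]] with π = (λ/(λ+1), 1/(λ+1)).

    Used unnormalised: the forward mutation rate is fixed at 1, so branch
    lengths are in units of expected 0→1 substitutions per site at a site
    currently in state 0.
    """
    lam = params.lam
    Q = np.array([[-1.0, 1.0], [lam, -lam]])
    pi = np.array([lam / (lam + 1.0), 1.0 / (lam + 1.0)])
    return RateMatrix(Q, pi, BINARY, normalized=False)


def build_gt16_q(params: Gt16ModelParams, normalize: bool = True) -> RateMatrix:
    """GT16 rate matrix; only single-allele changes have nonzero rate.

    With ``normalize`` (default), Q is rescaled so the expected rate
    −Σ_x π_x Q_xx equals 1 and branch lengths read as expected
    substitutions per site.
    """
    pi = params.freqs
    rows, cols, ridx = _GT16_SPARSITY
    Q = np.zeros((16, 16))
    Q[rows, cols] = params.rates[ridx] * pi[cols]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        mu = -np.dot(pi, np.diag(Q))
        Q /= mu
    return RateMatrix(Q, pi, GT16, normalized=normalize)
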