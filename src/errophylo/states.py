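"""State spaces for single-cell SNV characters.

Two spaces are supported: the binary presence/absence space {0, 1} and the
GT16 space of ordered diploid nucleotide genotypes
(AA, AC, AG, AT, CA, ..., TT).  Unphased heterozygotes are represented as
ambiguity codes ``ab*`` resolving to the two phased orders {ab, ba};
missing data is ``?`` and resolves to every state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NUCLEOTIDES = "ACGT"

#: Canonical GT16 state order: first allele major, i.e. index = 4*a + b.
GT16_STATES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)

BINARY_STATES = ("0", "1")

MISSING = "?"


@dataclass(frozen=True)
class StateSpace:
    """An ordered discrete character state space with ambiguity codes.

    Parameters
    ----------
    name : str
        ``"binary"`` or ``"gt16"``.
    states : tuple of str
        Ordered unambiguous state labels.
    ambiguity_map : dict
        Maps every recognised code (including the unambiguous states and
        the missing code) to the tuple of state indices it resolves to.
    """

    name: str
    states: tuple
    ambiguity_map: dict = field(compare=False)

    @property
    def size(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        """Index of an unambiguous state label."""
        try:
            return self.states.index(label)
        except ValueError:
            raise KeyError(f"unknown state label {label!r} for {self.name}")

    def resolve(self, code: str):
        """Tuple of state indices a code resolves to."""
        try:
            return self.ambiguity_map[code]
        except KeyError:
            raise KeyError(f"unknown code {code!r} for state space {self.name}")

    def is_ambiguous(self, code: str) -> bool:
        return len(self.resolve(code)) > 1


def _binary_space() -> StateSpace:
    amb = {"0": (0,), "1": (1,), MISSING: (0, 1)}
    return StateSpace(name="binary", states=BINARY_STATES, ambiguity_map=amb)


def unphased_code(a: str, b: str) -> str:
    """Canonical ambiguity code for an unphased heterozygote {ab, ba}."""
    if a == b:
        raise ValueError("unphased code is only defined for heterozygotes")
    lo, hi = sorted((a, b))
    return f"{lo}{hi}*"


def _gt16_space() -> StateSpace:
    amb = {s: (i,) for i, s in enumerate(GT16_STATES)}
    for i, a in enumerate(NUCLEOTIDES):
        for b in NUCLEOTIDES[i + 1:]:
            code = unphased_code(a, b)
            amb[code] = (GT16_STATES.index(a + b), GT16_STATES.index(b + a))
    amb[MISSING] = tuple(range(16))
    return StateSpace(name="gt16", states=GT16_STATES, ambiguity_map=amb)


BINARY = _binary_space()
GT16 = _gt16_space()


def get_state_space(name: str) -> StateSpace:
    if name == "binary":
        return BINARY
    if name == "gt16":
        return GT16
    raise ValueError(f"unknown state space {name!r}")
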