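"""Genotype alignments: m cells × n sites of SNV character codes."""

from __future__ import annotations

import numpy as np

from .states import GT16, MISSING, StateSpace, unphased_code


def code_list(space: StateSpace) -> list[str]:
    """Canonical ordered list of all recognised codes for a state space:
    unambiguous states, then ambiguity codes, then the missing code."""
    extras = sorted(c for c in space.ambiguity_map
                    if c not in space.states and c != MISSING)
    return list(space.states) + extras + [MISSING]


class AlignmentError(ValueError):
    pass


class GenotypeAlignment:
    """Matrix of state/ambiguity/missing codes for m cells at n sites.

    Data is stored as integer indices into :func:`code_list` for the
    alignment's state space, so tip partial vectors for the whole matrix
    are a single lookup.
    """

    def __init__(self, cells: list[str], data: np.ndarray,
                 state_space: StateSpace, phased: bool = True):
        self.cells = list(cells)
        self.data = np.asarray(data, dtype=np.int16)
        self.state_space = state_space
        self.phased = bool(phased)
        self.codes = code_list(state_space)
        m, n = self.data.shape if self.data.ndim == 2 else (0, 0)
        if m != len(self.cells) or m < 2 or n < 1:
            raise AlignmentError(
                f"alignment needs >=2 cells and >=1 site, got {m} x {n}"
            )
        if len(set(self.cells)) != m:
            raise AlignmentError("duplicate cell names")
        if self.data.min() < 0 or self.data.max() >= len(self.codes):
            raise AlignmentError("invalid state codes in alignment")

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_codes(cls, cell_to_codes: dict, state_space: StateSpace,
                   phased: bool = True) -> "GenotypeAlignment":
        """Build from a mapping cell name → sequence of code strings."""
        codes = code_list(state_space)
        index = {c: i for i, c in enumerate(codes)}
        cells = list(cell_to_codes)
        lengths = {len(v) for v in cell_to_codes.values()}
        if len(lengths) != 1:
            raise AlignmentError("ragged alignment: unequal sequence lengths")
        n = lengths.pop()
        data = np.zeros((len(cells), n), dtype=np.int16)
        for i, cell in enumerate(cells):
            for j, code in enumerate(cell_to_codes[cell]):
                try:
                    data[i, j] = index[code]
                except KeyError:
                    raise AlignmentError(
                        f"unknown code {code!r} at cell {cell!r}, site {j + 1}"
                    )
        return cls(cells, data, state_space, phased=phased)

    def code_strings(self, cell: str) -> list[str]:
        i = self.cells.index(cell)
        return [self.codes[k] for k in self.data[i]]

    def subset_sites(self, sites) -> "GenotypeAlignment":
        return GenotypeAlignment(self.cells, self.data[:, sites],
                                 self.state_space, phased=self.phased)

    def __eq__(self, other):
        return (isinstance(other, GenotypeAlignment)
                and self.cells == other.cells
                and self.state_space.name == other.state_space.name
                and self.phased == other.phased
                and np.array_equal(self.data, other.data))


def strip_phasing(alignment: GenotypeAlignment) -> GenotypeAlignment:
    """Replace every phased heterozygote ab with the ambiguity ab* = {ab, ba}.

    Homozygotes and missing entries are unchanged; the result is marked
    unphased.  Idempotent.
    """
    if alignment.state_space is not GT16 and alignment.state_space.name != "gt16":
        raise AlignmentError("strip_phasing applies to GT16 alignments only")
    codes = alignment.codes
    remap = np.arange(len(codes), dtype=np.int16)
    index = {c: i for i, c in enumerate(codes)}
    for i, c in enumerate(codes):
        if len(c) == 2 and c[0] != c[1]:
            remap[i] = index[unphased_code(c[0], c[1])]
    return GenotypeAlignment(alignment.cells, remap[alignment.data],
                             alignment.state_space, phased=False)
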