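"""Alignment, tree-log and trace I/O.

Formats
-------
FASTA (two-line records):
    binary      one character per site: ``0``, ``1``, missing ``?``.
    GT16        two characters per site (the allele pair): phased
                genotypes uppercase (``AC``), unphased heterozygote
                ambiguities lowercase (``ac`` = {AC, CA}), missing ``??``.

Nexus DATA blocks use one symbol per site: ``01`` for binary and
``0123456789ABCDEF`` for the 16 genotypes in canonical order, with
unphased heterozygotes as ambiguity sets ``{xy}`` and missing ``?``.

VCF (read-only, via pysam): diploid GT fields become GT16 codes —
``A|C`` → AC, ``A/C`` → unphased ac, ``./.`` → missing.  Non-SNV records
are skipped and counted.

MCMC traces are written as tab-separated logs (one row per sampled
state) readable by common trace viewers; tree logs as Nexus trees
blocks.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pysam

from .alignment import AlignmentError, GenotypeAlignment
from .mcmc import McmcTrace
from .states import (GT16, MISSING, StateSpace, get_state_space,
                     unphased_code)
from .trees import trees_to_nexus

log = logging.getLogger("errophylo")

GT16_SYMBOLS = "0123456789ABCDEF"


# -- FASTA ------------------------------------------------------------------

def _codes_to_fasta(codes: list[str], space: StateSpace) -> str:
    if space.name == "binary":
        return "".join(codes)
    out = []
    for c in codes:
        if c == MISSING:
            out.append("??")
        elif c.endswith("*"):
            out.append(c[:2].lower())
        else:
            out.append(c)
    return "".join(out)


def _fasta_to_codes(seq: str, space: StateSpace, name: str) -> list[str]:
    if space.name == "binary":
        return list(seq)
    if len(seq) % 2:
        raise AlignmentError(
            f"sequence {name!r}: GT16 sequences need two characters per site")
    codes = []
    for j in range(0, len(seq), 2):
        pair = seq[j:j + 2]
        if pair == "??":
            codes.append(MISSING)
        elif pair.islower():
            try:
                codes.append(unphased_code(pair[0].upper(), pair[1].upper()))
            except ValueError:
                raise AlignmentError(
                    f"sequence {name!r}, site {j // 2 + 1}: lowercase pair "
                    f"{pair!r} is not a heterozygote")
        else:
            codes.append(pair)
    return codes


def write_fasta(alignment: GenotypeAlignment, path) -> None:
    with open(path, "w") as fh:
        for cell in alignment.cells:
            fh.write(f">{cell}\n")
            fh.write(_codes_to_fasta(alignment.code_strings(cell),
                                     alignment.state_space) + "\n")


def read_fasta(path, state_space) -> GenotypeAlignment:
    if isinstance(state_space, str):
        state_space = get_state_space(state_space)
    seqs: dict[str, str] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise AlignmentError(f"duplicate sequence name {name!r}")
                seqs[name] = ""
            elif name is None:
                raise AlignmentError("sequence data before first header")
            else:
                seqs[name] += line
    if not seqs:
        raise AlignmentError(f"no sequences in {path}")
    cells = {n: _fasta_to_codes(s, state_space, n) for n, s in seqs.items()}
    phased = not any(c.endswith("*") for codes in cells.values()
                     for c in codes)
    return GenotypeAlignment.from_codes(cells, state_space, phased=phased)


# -- Nexus data blocks ------------------------------------------------------

def _nexus_symbol(code: str, space: StateSpace) -> str:
    if code == MISSING:
        return "?"
    if space.name == "binary":
        return code
    if code.endswith("*"):
        i, j = space.resolve(code)
        return "{%s%s}" % (GT16_SYMBOLS[i], GT16_SYMBOLS[j])
    return GT16_SYMBOLS[space.index(code)]


def write_nexus(alignment: GenotypeAlignment, path) -> None:
    space = alignment.state_space
    symbols = "01" if space.name == "binary" else GT16_SYMBOLS
    width = max(len(c) for c in alignment.cells) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBegin data;\n")
        fh.write(f"\tDimensions ntax={alignment.n_cells} "
                 f"nchar={alignment.n_sites};\n")
        fh.write(f'\tFormat datatype=standard symbols="{symbols}" '
                 'missing=? gap=-;\n')
        fh.write("\tMatrix\n")
        for cell in alignment.cells:
            row = "".join(_nexus_symbol(c, space)
                          for c in alignment.code_strings(cell))
            fh.write(f"\t{cell.ljust(width)}{row}\n")
        fh.write("\t;\nEnd;\n")


_NEXUS_TOKEN = re.compile(r"\{([0-9A-F]{2})\}|([0-9A-F?\-])")


def read_nexus(path, state_space) -> GenotypeAlignment:
    if isinstance(state_space, str):
        state_space = get_state_space(state_space)
    space = state_space
    text = Path(path).read_text()
    match = re.search(r"matrix(.*?);", text, re.IGNORECASE | re.DOTALL)
    if not match:
        raise AlignmentError(f"no Matrix block found in {path}")
    cells: dict[str, list[str]] = {}
    for line in match.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        name = line.split()[0]
        row = line[len(name):].strip().replace(" ", "")
        codes = []
        pos = 0
        while pos < len(row):
            m = _NEXUS_TOKEN.match(row, pos)
            if not m:
                raise AlignmentError(
                    f"taxon {name!r}: unknown symbol {row[pos]!r} "
                    f"at site {len(codes) + 1}")
            pos = m.end()
            if m.group(1):  # ambiguity set {xy}: the two phasings of ab
                a, b = (GT16_SYMBOLS.index(ch) for ch in m.group(1))
                ga, gb = space.states[a], space.states[b]
                if ga != gb[::-1] or ga[0] == ga[1]:
                    raise AlignmentError(
                        f"taxon {name!r}, site {len(codes) + 1}: ambiguity "
                        f"{{{ga},{gb}}} is not an unphased heterozygote")
                codes.append(unphased_code(ga[0], ga[1]))
            elif m.group(2) in ("?", "-"):
                codes.append(MISSING)
            elif space.name == "binary":
                codes.append(m.group(2))
            else:
                codes.append(space.states[GT16_SYMBOLS.index(m.group(2))])
        cells.setdefault(name, []).extend(codes)
    phased = not any(c.endswith("*") for v in cells.values() for c in v)
    return GenotypeAlignment.from_codes(cells, space, phased=phased)


def read_alignment(path, fmt: str, state_space) -> GenotypeAlignment:
    if fmt == "fasta":
        return read_fasta(path, state_space)
    if fmt == "nexus":
        return read_nexus(path, state_space)
    if fmt == "vcf":
        return vcf_to_gt16(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_alignment(alignment: GenotypeAlignment, path, fmt: str) -> None:
    if fmt == "fasta":
        write_fasta(alignment, path)
    elif fmt == "nexus":
        write_nexus(alignment, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# -- VCF --------------------------------------------------------------------

def vcf_to_gt16(path) -> GenotypeAlignment:
    """Convert diploid GT fields of a VCF into a GT16 alignment.

    Sites are records in file order; non-SNV records (indels, symbolic
    alleles) are skipped with a logged count.  Haploid or >2-allele GT
    calls raise, naming the record.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if not samples:
        raise AlignmentError("VCF has no sample columns")
    columns = {s: [] for s in samples}
    skipped = 0
    positions = []
    for rec in vcf:
        alleles = rec.alleles or ()
        if any(a is None or len(a) != 1 or a.upper() not in "ACGT"
               for a in alleles):
            skipped += 1
            continue
        for s in samples:
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or all(a is None for a in gt):
                columns[s].append(MISSING)
                continue
            if len(gt) != 2:
                raise AlignmentError(
                    f"record {rec.chrom}:{rec.pos}: sample {s!r} has a "
                    f"{len(gt)}-ploid genotype; diploid GT required")
            if any(a is None for a in gt):
                columns[s].append(MISSING)
                continue
            a, b = (alleles[i].upper() for i in gt)
            if call.phased or a == b:
                columns[s].append(a + b)
            else:
                columns[s].append(unphased_code(a, b))
        positions.append(f"{rec.chrom}:{rec.pos}")
    if skipped:
        log.info("vcf_to_gt16: skipped %d non-SNV records", skipped)
    if not positions:
        raise AlignmentError("no usable SNV records in VCF")
    aln = GenotypeAlignment.from_codes(columns, GT16,
                                       phased=not any(
                                           c.endswith("*")
                                           for v in columns.values()
                                           for c in v))
    aln.positions = positions
    return aln


# -- traces and tree logs ---------------------------------------------------

def write_trace(trace: McmcTrace, path) -> None:
    """Tab-separated trace log (one row per sampled state)."""
    import pandas as pd

    df = pd.DataFrame({"state": trace.states, **trace.columns})
    df.to_csv(path, sep="\t", index=False)


def write_tree_log(trace: McmcTrace, path) -> None:
    states, trees = zip(*trace.trees)
    Path(path).write_text(
        trees_to_nexus(trees, names=[f"STATE_{s}" for s in states]))
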