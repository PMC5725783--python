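"""Genetic-code tables and codon-state conventions.

The engine works on the 61 sense codons of the standard genetic code,
ordered lexicographically over the alphabet A < C < G < T.  Alignment
cells are *sets* of sense-codon indices: a singleton is an observed
codon, a larger set an IUPAC-ambiguous observation, and the full set a
gap/missing cell.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable, IUPACData

NUCLEOTIDES = "ACGT"
STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(STANDARD_TABLE.stop_codons))

#: the 61 sense codons, lexicographic in A<C<G<T
SENSE_CODONS = tuple(
    c for c in ("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in STANDARD_TABLE.stop_codons
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

#: amino acid (one-letter) encoded by each sense codon
CODON_AA = tuple(STANDARD_TABLE.forward_table[c] for c in SENSE_CODONS)

FULL_SET = frozenset(range(N_CODONS))

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a<->b is a transition."""
    return (a in _PURINES) == (b in _PURINES) and a != b


# IUPAC nucleotide ambiguity expansion, e.g. "Y" -> {"C","T"}; gaps and
# anything unknown expand to all four nucleotides.
_AMBIG = {k.upper(): set(v.upper()) for k, v in IUPACData.ambiguous_dna_values.items()}


def expand_nucleotide(symbol: str) -> set[str]:
    s = symbol.upper()
    if s in _AMBIG:
        return set(_AMBIG[s])
    return set(NUCLEOTIDES)  # gap characters, '?', etc.


@lru_cache(maxsize=16384)
def codon_cell(codon: str) -> frozenset:
    """Expand a (possibly ambiguous) codon string into a sense-codon set.

    A codon containing any gap character is treated as fully missing.
    Raises ``ValueError`` if the expansion contains no sense codon
    (i.e. the codon can only be a stop).
    """
    codon = codon.upper()
    if any(ch in "-.~" for ch in codon):
        return FULL_SET
    sets = [expand_nucleotide(ch) for ch in codon]
    states = frozenset(
        CODON_INDEX["".join(t)]
        for t in itertools.product(*sets)
        if "".join(t) in CODON_INDEX
    )
    if not states:
        raise ValueError(f"codon {codon!r} admits only stop codons")
    if len(states) == 64 - 3:
        return FULL_SET
    return states


def cell_amino_acids(cell: frozenset) -> frozenset:
    """Amino acids compatible with a codon cell (missing -> all)."""
    return frozenset(CODON_AA[i] for i in cell)


# single-nucleotide-difference structure of the 61x61 rate matrix,
# precomputed once: index pairs, transition flag, synonymous flag
def _neighbor_arrays():
    ii, jj, ts, syn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diff) != 1:
                continue
            a, b = diff[0]
            ii.append(i)
            jj.append(j)
            ts.append(is_transition(a, b))
            syn.append(CODON_AA[i] == CODON_AA[j])
    return (
        np.asarray(ii, dtype=np.intp),
        np.asarray(jj, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(syn, dtype=bool),
    )


NEIGHBOR_I, NEIGHBOR_J, NEIGHBOR_TRANSITION, NEIGHBOR_SYNONYMOUS = _neighbor_arrays()


def translate_cell_sequence(cells) -> list[frozenset]:
    """Per-codon amino-acid sets for a sequence of codon cells."""
    return [cell_amino_acids(c) for c in cells]
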