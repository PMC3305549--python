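"""Genetic-code tables for the 61-state sense-codon space.

The universal code is used throughout: the three stop codons (TAA, TAG,
TGA) are excluded from the state space of every codon model, so state
vectors and rate matrices are 61-dimensional.  Codons are indexed in
lexicographic (A<C<G<T) order of their nucleotide triplets.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCS = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)

#: the 61 sense codons, lexicographic order
CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCS, repeat=3)
    if "".join(c) not in STOP_CODONS
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
N_CODONS = len(CODONS)  # 61

#: amino acid encoded by each sense codon
AA_OF_CODON: tuple[str, ...] = tuple(standard_dna_table.forward_table[c] for c in CODONS)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _pair_tables():
    """Precompute the single-step codon pairs and their change type.

    Returns index arrays (i, j) over ordered pairs of sense codons that
    differ at exactly one nucleotide position, with boolean arrays marking
    transitions (vs transversions) and synonymous (vs nonsynonymous)
    changes.
    """
    ii, jj, ts, syn = [], [], [], []
    for i, a in enumerate(CODONS):
        for j, b in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(x, y) for x, y in zip(a, b) if x != y]
            if len(diffs) != 1:
                continue
            ii.append(i)
            jj.append(j)
            ts.append(diffs[0] in _TRANSITIONS)
            syn.append(AA_OF_CODON[i] == AA_OF_CODON[j])
    return (
        np.asarray(ii, dtype=np.intp),
        np.asarray(jj, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(syn, dtype=bool),
    )


PAIR_I, PAIR_J, PAIR_IS_TRANSITION, PAIR_IS_SYNONYMOUS = _pair_tables()


def codons_of(seq: str) -> list[str]:
    """Split a nucleotide string into codons (length must be a multiple of 3)."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[k : k + 3] for k in range(0, len(seq), 3)]


def encode_codons(seq: str) -> np.ndarray:
    """Encode a gap-free CDS as an array of sense-codon indices."""
    try:
        return np.asarray([CODON_INDEX[c] for c in codons_of(seq.upper())], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"not a sense codon: {exc.args[0]!r}") from None
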