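"""Codon alignment construction and sanitation.

Codon-model likelihoods require gap-free, frame-consistent alignments over
the 61 sense codons.  This module translates CDS records, maps a protein
multiple alignment back onto codons (one amino-acid column = one codon
column), removes every codon column containing a gap or ambiguity in any
row (complete deletion, the cleandata convention), and provides the
pairwise-deletion site selection used by protein distance estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

_GAP_CODON = "---"
_AMBIG = set("NXnx")


@dataclass
class CodonAlignment:
    """Aligned coding sequences stored as strings of codon columns."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        lens = {len(r) for r in self.rows}
        if len(lens) > 1:
            raise ValueError("rows differ in length")
        if lens and next(iter(lens)) % 3:
            raise ValueError("row length not a multiple of 3")

    @property
    def length(self) -> int:
        """Number of codon columns."""
        return len(self.rows[0]) // 3 if self.rows else 0

    def codon_column(self, k: int) -> list[str]:
        return [r[3 * k : 3 * k + 3] for r in self.rows]

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def has_gaps(self) -> bool:
        return any("-" in r or set(r) & _AMBIG for r in self.rows)

    # -- FASTA IO --------------------------------------------------------

    @classmethod
    def read_fasta(cls, path: str | Path) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in records], [str(r.seq).upper() for r in records])

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.names, self.rows):
                fh.write(f">{name}\n{row}\n")


def translate(cds: str) -> str:
    """Translate a CDS with the universal code.

    A terminal stop codon is dropped; an internal stop, a length not
    divisible by 3, or characters outside ACGTN are errors.  Codons
    containing N translate to X.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    if set(cds) - set("ACGTN"):
        raise ValueError(f"invalid characters in CDS: {sorted(set(cds) - set('ACGTN'))}")
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError(f"internal stop codon at codon {protein.index('*') + 1}")
    return protein


def backmap(
    protein_alignment: list[tuple[str, str]] | dict[str, str],
    cds_records: dict[str, str],
) -> CodonAlignment:
    """Map an aligned protein MSA onto codons using the paired CDS.

    Each aligned protein row, gaps removed, must translate-match its CDS
    (terminal stops ignored); every amino-acid column then expands to one
    codon column, with protein gaps becoming ``---``.
    """
    items = list(protein_alignment.items()) if isinstance(protein_alignment, dict) else list(protein_alignment)
    names, rows = [], []
    for name, prot_row in items:
        try:
            cds = cds_records[name]
        except KeyError:
            raise KeyError(f"no CDS record for {name!r}") from None
        cds = cds.upper()
        expect = translate(cds)
        ungapped = prot_row.replace("-", "")
        if ungapped != expect:
            raise ValueError(
                f"protein row for {name!r} does not match translated CDS "
                f"({ungapped[:10]}... vs {expect[:10]}...)"
            )
        out = []
        k = 0
        for aa in prot_row:
            if aa == "-":
                out.append(_GAP_CODON)
            else:
                out.append(cds[3 * k : 3 * k + 3])
                k += 1
        names.append(name)
        rows.append("".join(out))
    return CodonAlignment(names, rows)


def strip_gap_columns(aln: CodonAlignment) -> tuple[CodonAlignment, list[int]]:
    """Delete every codon column with a gap or ambiguity in any row.

    Returns the cleaned alignment and the column map new→old (0-based
    original codon column indices), preserving order, so downstream site
    reports can be expressed in original alignment coordinates.
    """
    keep: list[int] = []
    for k in range(aln.length):
        col = aln.codon_column(k)
        if all("-" not in c and not (set(c) & _AMBIG) for c in col):
            keep.append(k)
    rows = ["".join(r[3 * k : 3 * k + 3] for k in keep) for r in aln.rows]
    return CodonAlignment(list(aln.names), rows), keep


def pairwise_shared_sites(
    row_a: str, row_b: str, ambiguous: set[str] | None = None
) -> list[int]:
    """Indices where both rows are ungapped and unambiguous.

    Operates on per-character sites; rows must have equal length.  The
    default ambiguity set is {N, X} (nucleotide N, generic X); protein
    callers should pass ``ambiguous={'X'}`` since N is asparagine there.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    bad = (set(_AMBIG) if ambiguous is None else
           {c for a in ambiguous for c in (a.upper(), a.lower())}) | {"-"}
    return [i for i, (x, y) in enumerate(zip(row_a, row_b)) if x not in bad and y not in bad]


def write_column_map(column_map: list[int], path: str | Path) -> None:
    """Write the new→old codon-column map as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("new_column\told_column\n")
        for new, old in enumerate(column_map):
            fh.write(f"{new}\t{old}\n")
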