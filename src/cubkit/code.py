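"""Genetic-code tables and degeneracy bookkeeping.

All sequences are handled in the DNA alphabet (ACGT); RNA input is converted
on the way in.  The default code is NCBI translation table 11 (bacterial,
archaeal and plant plastid), whose sense-codon assignments coincide with the
standard code: 61 sense codons, 3 stops, and the familiar degeneracy census
(Met and Trp single-codon, nine 2-fold families, Ile 3-fold, five 4-fold,
and Leu/Ser/Arg 6-fold).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

from Bio.Data import CodonTable

BASES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def dna(seq: str) -> str:
    """Normalize a nucleotide string to upper-case DNA."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return dna(seq).translate(_COMPLEMENT)[::-1]


def is_transition(a: str, b: str) -> bool:
    """True when a->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    return a != b and ((a in PURINES) == (b in PURINES))


class GeneticCode:
    """A codon table restricted to unambiguous DNA triplets.

    Parameters
    ----------
    table_id:
        NCBI translation-table identifier (for provenance only).
    codon_to_aa:
        Mapping of the sense codons to one-letter amino acids.
    stop_codons:
        The stop triplets, never counted as sense codons.
    """

    def __init__(self, table_id: int, codon_to_aa: Mapping[str, str],
                 stop_codons: Iterable[str]):
        self.table_id = int(table_id)
        self.codon_to_aa = {dna(c): aa for c, aa in codon_to_aa.items()}
        self.stop_codons = tuple(sorted(dna(c) for c in stop_codons))
        self.sense_codons = tuple(sorted(self.codon_to_aa))
        fams: dict[str, list[str]] = defaultdict(list)
        for codon, aa in self.codon_to_aa.items():
            fams[aa].append(codon)
        self.aa_to_codons = {aa: tuple(sorted(cods)) for aa, cods in fams.items()}
        self.amino_acids = tuple(sorted(self.aa_to_codons))

    @classmethod
    def from_table(cls, table_id: int = 11) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(table_id, table.forward_table, table.stop_codons)

    # -- lookups ---------------------------------------------------------
    def aa_of(self, codon: str) -> str:
        return self.codon_to_aa[dna(codon)]

    def family(self, aa: str) -> tuple[str, ...]:
        """Synonymous codons of an amino acid, alphabetically ordered."""
        return self.aa_to_codons[aa]

    def degeneracy_class(self, aa: str) -> int:
        """Family size: 1, 2, 3, 4 or 6 under the standard bacterial code."""
        return len(self.aa_to_codons[aa])

    def degeneracy_census(self) -> dict[int, int]:
        """Number of amino acids per degeneracy class."""
        census: dict[int, int] = defaultdict(int)
        for aa in self.amino_acids:
            census[self.degeneracy_class(aa)] += 1
        return dict(census)

    def is_stop(self, codon: str) -> bool:
        return dna(codon) in self.stop_codons

    def translate(self, seq: str) -> str:
        """Translate an in-frame CDS; '*' for stops, 'X' for ambiguous codons."""
        s = dna(seq)
        if len(s) % 3:
            raise ValueError("sequence length is not a multiple of 3")
        out = []
        for i in range(0, len(s), 3):
            codon = s[i:i + 3]
            if codon in self.codon_to_aa:
                out.append(self.codon_to_aa[codon])
            elif codon in self.stop_codons:
                out.append("*")
            else:
                out.append("X")
        return "".join(out)


_DEFAULT: GeneticCode | None = None


def default_code() -> GeneticCode:
    """The shared table-11 instance used when no code is passed explicitly."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = GeneticCode.from_table(11)
    return _DEFAULT
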