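"""HEP/LEP selection and conserved/variable codon domains of ortholog families.

Genes encoding highly (HEP) and lowly (LEP) expressed proteins are picked by
abundance quantiles within a core gene set.  For each gene's ortholog family,
codons are back-threaded onto the amino-acid alignment; alignment columns are
classified as conserved (one amino acid in every row, no gaps), variable (no
amino acid above proportion 0.5 among non-gap residues) or intermediate, and
the reference member's codons at conserved/variable columns are concatenated
into the cr/vr domain sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .code import GeneticCode, default_code, dna
from .core import CodingSequence

GAP = "-"
CONSERVED, VARIABLE, INTERMEDIATE = "conserved", "variable", "intermediate"


@dataclass
class AbundanceTable:
    """Protein abundances on a ppm-like scale; strictly positive."""

    abundance: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.abundance, dtype=float)
        if (s <= 0).any():
            bad = list(s.index[s <= 0])[:5]
            raise ValueError(f"non-positive abundances, e.g. {bad}")
        self.abundance = s


def select_hep_lep(abund: AbundanceTable,
                   core_genes: Sequence[str],
                   hep_q: float = 0.9,
                   lep_q: float = 0.1) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """HEP/LEP gene subsets by abundance quantiles within a core gene set.

    HEP are the genes at or above quantile ``hep_q`` of the abundances of the
    core genes with data; LEP at or below ``lep_q``.  Genes without abundance
    are excluded (counted via a warning).
    """
    if not (0.0 < lep_q < hep_q < 1.0):
        raise ValueError("need 0 < lep_q < hep_q < 1")
    with_data = [g for g in core_genes if g in abund.abundance.index]
    missing = len(list(core_genes)) - len(with_data)
    if missing:
        warnings.warn(f"{missing} core genes lack abundance data; excluded")
    if len(with_data) < 20:
        raise ValueError("abundances available for fewer than 20 core genes")
    values = abund.abundance.loc[with_data]
    if float(values.max()) == float(values.min()):
        raise ValueError("degenerate abundance distribution: all values equal")
    hi = float(values.quantile(hep_q))
    lo = float(values.quantile(lep_q))
    hep = tuple(g for g in with_data if values[g] >= hi)
    lep = tuple(g for g in with_data if values[g] <= lo)
    if set(hep) & set(lep):
        raise ValueError("HEP and LEP quantiles overlap")
    return hep, lep


@dataclass
class CodonAlignment:
    """An ortholog family with codons threaded onto its aa alignment.

    ``codon_rows[member][col]`` is a codon or '---' where the member has a
    gap; ``column_classes`` is filled by :func:`classify_columns`.
    """

    family_id: str
    aa_rows: dict[str, str]
    codon_rows: dict[str, list[str]]
    reference: str
    column_classes: list[str] | None = None

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(self.aa_rows)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.aa_rows.values())))


def backthread(aa_alignment: Mapping[str, str],
               cds: Mapping[str, str],
               family_id: str = "family",
               reference: str | None = None,
               code: GeneticCode | None = None) -> CodonAlignment:
    """Thread each member's codons onto its aligned amino-acid row.

    Per member, the translated CDS (minus a trailing stop, if present) must
    equal the ungapped aligned row; mismatches raise with the member and the
    first offending position.
    """
    code = code or default_code()
    if not aa_alignment:
        raise ValueError("empty alignment")
    lengths = {len(row) for row in aa_alignment.values()}
    if len(lengths) != 1:
        raise ValueError("aligned rows have unequal lengths")
    aa_rows = {m: row.upper() for m, row in aa_alignment.items()}
    codon_rows: dict[str, list[str]] = {}
    for member, row in aa_rows.items():
        if member not in cds:
            raise ValueError(f"no CDS for member {member!r}")
        seq = dna(cds[member])
        if len(seq) % 3:
            raise ValueError(f"member {member!r}: CDS length not a multiple of 3")
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        if codons and code.is_stop(codons[-1]):
            codons = codons[:-1]
        protein = "".join(code.codon_to_aa.get(c, "X") for c in codons)
        ungapped = row.replace(GAP, "")
        if len(protein) != len(ungapped):
            raise ValueError(
                f"member {member!r}: CDS encodes {len(protein)} residues but "
                f"the aligned row has {len(ungapped)}")
        for i, (a, b) in enumerate(zip(protein, ungapped)):
            if a != b:
                raise ValueError(
                    f"member {member!r}: translation mismatch at residue "
                    f"{i + 1} ({a!r} vs aligned {b!r})")
        threaded: list[str] = []
        k = 0
        for aa in row:
            if aa == GAP:
                threaded.append(GAP * 3)
            else:
                threaded.append(codons[k])
                k += 1
        codon_rows[member] = threaded
    ref = reference or next(iter(aa_rows))
    if ref not in aa_rows:
        raise ValueError(f"reference member {ref!r} not in alignment")
    return CodonAlignment(family_id=family_id, aa_rows=aa_rows,
                          codon_rows=codon_rows, reference=ref)


def classify_columns(aln: CodonAlignment,
                     variable_max_prop: float = 0.5) -> list[str]:
    """Classify every column as conserved, variable or intermediate.

    Conserved: a single amino acid in all rows and no gap (a gapped column is
    never fully conserved).  Variable: among non-gap residues, no amino acid
    has proportion above ``variable_max_prop``.  Everything else is
    intermediate.
    """
    if len(aln.members) < 2:
        raise ValueError("column classification needs at least 2 members")
    classes: list[str] = []
    rows = list(aln.aa_rows.values())
    for col in range(aln.n_columns):
        residues = [row[col] for row in rows]
        non_gap = [r for r in residues if r != GAP]
        if not non_gap:
            classes.append(INTERMEDIATE)
            continue
        counts = pd.Series(non_gap).value_counts()
        if GAP not in residues and len(counts) == 1:
            classes.append(CONSERVED)
        elif counts.iloc[0] / len(non_gap) <= variable_max_prop:
            classes.append(VARIABLE)
        else:
            classes.append(INTERMEDIATE)
    aln.column_classes = classes
    return classes


def extract_domains(aln: CodonAlignment, which: str) -> CodingSequence:
    """Concatenate the reference member's codons at cr or vr columns.

    Columns where the reference has a gap are skipped.  Zero qualifying
    columns yield an empty sequence with a warning (expected for sparse
    LEP_cr collections).
    """
    if aln.column_classes is None:
        classify_columns(aln)
    which = {"cr": CONSERVED, "vr": VARIABLE}.get(which, which)
    if which not in (CONSERVED, VARIABLE):
        raise ValueError(f"unknown domain class {which!r}")
    ref_codons = aln.codon_rows[aln.reference]
    assert aln.column_classes is not None
    picked = [codon for codon, cls_name in zip(ref_codons, aln.column_classes)
              if cls_name == which and GAP not in codon]
    if not picked:
        warnings.warn(f"family {aln.family_id!r}: no {which} codons for "
                      f"reference {aln.reference!r}")
    suffix = "cr" if which == CONSERVED else "vr"
    return CodingSequence(id=f"{aln.family_id}|{suffix}", seq="".join(picked))


def conservation_percent(aln: CodonAlignment,
                         method: str = "conserved_columns") -> float:
    """Amino-acid sequence conservation of a family, in percent.

    Default: 100 x (#conserved columns) / (#columns where the reference has a
    residue).  ``method="pairwise_identity"`` returns the mean pairwise
    identity over non-gap column pairs instead.
    """
    if aln.column_classes is None:
        classify_columns(aln)
    if method == "conserved_columns":
        ref_row = aln.aa_rows[aln.reference]
        denom = sum(1 for aa in ref_row if aa != GAP)
        if denom == 0:
            raise ValueError("reference row is all gaps")
        assert aln.column_classes is not None
        conserved = sum(1 for cls_name in aln.column_classes
                        if cls_name == CONSERVED)
        return 100.0 * conserved / denom
    if method == "pairwise_identity":
        rows = list(aln.aa_rows.values())
        same = comparable = 0
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                for a, b in zip(rows[i], rows[j]):
                    if a != GAP and b != GAP:
                        comparable += 1
                        same += a == b
        if comparable == 0:
            raise ValueError("no comparable residue pairs")
        return 100.0 * same / comparable
    raise ValueError(f"unknown conservation method {method!r}")
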