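"""Per-gene and per-set codon usage statistics.

The raw material is a table of raw codon counts (RCC): one row per gene,
one column per sense codon.  From an aggregated row this module derives

* CUF  -- codon usage frequency, a codon's share within its synonymous family;
* RSCU -- relative synonymous codon usage, CUF scaled by family size;
* GC3  -- fraction of G/C at the third codon position;
* Nc   -- Wright's effective number of codons (20 = maximal bias, 61 = none).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .code import GeneticCode, default_code, dna


class FrameError(ValueError):
    """A coding sequence whose length is not a multiple of three."""


@dataclass
class CodingSequence:
    """A nucleotide coding sequence with optional gene-set labels."""

    id: str
    seq: str
    set_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.seq = dna(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3


@dataclass
class GeneSetPartition:
    """Assignment of genes to named, ancestry-ordered gene sets.

    ``sets`` preserves insertion order; for the singletons/C1..Cn/PHE layout
    the insertion order is the ancestry order used throughout the package.
    """

    sets: dict[str, tuple[str, ...]]

    @property
    def set_names(self) -> tuple[str, ...]:
        return tuple(self.sets)

    def genes(self) -> tuple[str, ...]:
        out: list[str] = []
        for members in self.sets.values():
            out.extend(members)
        return tuple(out)

    def labels_of(self, gene: str) -> tuple[str, ...]:
        return tuple(name for name, members in self.sets.items() if gene in members)

    @classmethod
    def from_items(cls, items: Iterable[tuple[str, str]]) -> "GeneSetPartition":
        """Build from (gene_id, set_label) pairs, keeping first-seen label order."""
        sets: dict[str, list[str]] = {}
        for gene, label in items:
            sets.setdefault(label, []).append(gene)
        return cls({k: tuple(v) for k, v in sets.items()})


@dataclass
class CodonCountTable:
    """Genes x sense-codons integer count matrix plus per-gene skip tallies.

    ``counts`` columns are the 61 sense codons in fixed alphabetical order;
    ``skipped`` counts codons dropped because they contained a non-ACGT base.
    """

    counts: pd.DataFrame
    skipped: pd.Series
    code_id: int = 11

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def row(self, gene: str) -> pd.Series:
        return self.counts.loc[gene]

    def aggregate(self, genes: Sequence[str] | None = None) -> pd.Series:
        """Element-wise sum of member rows (all rows when ``genes`` is None)."""
        if genes is None:
            return self.counts.sum(axis=0)
        return self.counts.loc[list(genes)].sum(axis=0)

    def subset(self, genes: Sequence[str]) -> "CodonCountTable":
        genes = list(genes)
        return CodonCountTable(self.counts.loc[genes].copy(),
                               self.skipped.loc[genes].copy(), self.code_id)

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        counts = self.counts.add(other.counts, fill_value=0).astype(int)
        skipped = self.skipped.add(other.skipped, fill_value=0).astype(int)
        return CodonCountTable(counts, skipped, self.code_id)


def count_codons(seqs: Iterable[CodingSequence],
                 code: GeneticCode | None = None,
                 frame: str = "strict") -> CodonCountTable:
    """Count sense codons per gene.

    Stop codons are never counted; codons containing a non-ACGT character are
    skipped and tallied per gene.  Under ``frame="strict"`` an out-of-frame
    sequence raises :class:`FrameError`; ``frame="trim"`` drops the trailing
    partial codon with a warning.
    """
    code = code or default_code()
    if frame not in ("strict", "trim"):
        raise ValueError(f"unknown frame policy {frame!r}")
    sense = list(code.sense_codons)
    col_index = {codon: j for j, codon in enumerate(sense)}
    stops = set(code.stop_codons)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    skips: list[int] = []
    for rec in seqs:
        s = rec.seq
        if len(s) % 3:
            if frame == "strict":
                raise FrameError(
                    f"gene {rec.id!r}: length {len(s)} is not a multiple of 3")
            warnings.warn(f"gene {rec.id!r}: trailing partial codon dropped")
            s = s[:len(s) - len(s) % 3]
        vec = np.zeros(len(sense), dtype=int)
        skipped = 0
        for i in range(0, len(s), 3):
            codon = s[i:i + 3]
            j = col_index.get(codon)
            if j is not None:
                vec[j] += 1
            elif codon not in stops:
                skipped += 1
        ids.append(rec.id)
        rows.append(vec)
        skips.append(skipped)
    counts = pd.DataFrame(np.vstack(rows) if rows else
                          np.empty((0, len(sense)), dtype=int),
                          index=pd.Index(ids, name="gene"), columns=sense)
    skipped_s = pd.Series(skips, index=counts.index, name="skipped", dtype=int)
    return CodonCountTable(counts, skipped_s, code.table_id)


@dataclass
class UsageProfile:
    """Codon usage of a gene or pooled gene set.

    ``cuf`` holds within-family frequencies (NaN for families with zero
    counts -- undefined, never zero-filled); ``aa_freq`` sums to 1 over the
    amino acids; ``rscu`` and ``nc`` are populated on demand.
    """

    cuf: pd.Series
    aa_freq: pd.Series
    gc3: float
    rscu: pd.Series | None = None
    nc: float | None = None
    code_id: int = 11
    label: str | None = None

    def defined_aa(self, code: GeneticCode | None = None) -> tuple[str, ...]:
        """Amino acids whose family CUF is defined (non-NaN)."""
        code = code or default_code()
        return tuple(aa for aa in code.amino_acids
                     if not any(math.isnan(self.cuf[c]) for c in code.family(aa)))


def _as_counts(counts: Mapping[str, float] | pd.Series,
               code: GeneticCode) -> pd.Series:
    s = pd.Series(counts, dtype=float)
    unknown = set(s.index) - set(code.sense_codons)
    if unknown:
        s = s.drop(labels=sorted(unknown))
    return s.reindex(code.sense_codons).fillna(0.0)


def gc3_of_counts(counts: Mapping[str, float] | pd.Series,
                  code: GeneticCode | None = None) -> float:
    """Fraction of counted sense codons with G or C at the third position."""
    code = code or default_code()
    n = _as_counts(counts, code)
    total = float(n.sum())
    if total == 0:
        raise ValueError("no sense codons")
    gc = sum(v for codon, v in n.items() if codon[2] in "GC")
    return gc / total


def cuf_profile(counts: Mapping[str, float] | pd.Series,
                code: GeneticCode | None = None,
                label: str | None = None) -> UsageProfile:
    """CUF, amino-acid frequencies and GC3 of an aggregated count row."""
    code = code or default_code()
    n = _as_counts(counts, code)
    total = float(n.sum())
    if total == 0:
        raise ValueError("no sense codons")
    cuf = pd.Series(np.nan, index=n.index)
    aa_freq = pd.Series(0.0, index=pd.Index(code.amino_acids, name="aa"))
    for aa in code.amino_acids:
        fam = list(code.family(aa))
        fam_total = float(n[fam].sum())
        aa_freq[aa] = fam_total / total
        if fam_total > 0:
            cuf[fam] = n[fam] / fam_total
    gc3 = gc3_of_counts(n, code)
    return UsageProfile(cuf=cuf, aa_freq=aa_freq, gc3=gc3,
                        code_id=code.table_id, label=label)


def rscu_profile(counts: Mapping[str, float] | pd.Series,
                 code: GeneticCode | None = None,
                 label: str | None = None) -> UsageProfile:
    """As :func:`cuf_profile`, with RSCU = family_size * CUF populated."""
    code = code or default_code()
    profile = cuf_profile(counts, code, label=label)
    k = pd.Series({c: code.degeneracy_class(code.aa_of(c))
                   for c in code.sense_codons}, dtype=float)
    profile.rscu = profile.cuf * k
    return profile


def profile_from_cuf(cuf: Mapping[str, float],
                     aa_freq: Mapping[str, float],
                     code: GeneticCode | None = None,
                     label: str | None = None) -> UsageProfile:
    """Assemble a profile from explicit CUF and amino-acid frequencies.

    CUFs are renormalized within each family; amino-acid frequencies over the
    amino acids; GC3 is the expectation of a G/C third base under the joint
    codon distribution aa_freq * cuf.
    """
    code = code or default_code()
    cuf_s = pd.Series(np.nan, index=pd.Index(code.sense_codons))
    aa_s = pd.Series(aa_freq, dtype=float).reindex(code.amino_acids).fillna(0.0)
    if aa_s.sum() <= 0:
        raise ValueError("amino-acid frequencies sum to zero")
    aa_s = aa_s / aa_s.sum()
    given = pd.Series(cuf, dtype=float)
    for aa in code.amino_acids:
        fam = list(code.family(aa))
        vals = given.reindex(fam)
        if vals.notna().any():
            v = vals.fillna(0.0)
            if v.sum() <= 0:
                raise ValueError(f"family of {aa} has zero total CUF")
            cuf_s[fam] = v / v.sum()
        elif aa_s[aa] > 0:
            raise ValueError(f"amino acid {aa} has positive frequency "
                             "but no CUF given")
    joint = pd.Series({c: (aa_s[code.aa_of(c)] * cuf_s[c]
                           if not math.isnan(cuf_s[c]) else 0.0)
                       for c in code.sense_codons})
    gc3 = float(sum(v for c, v in joint.items() if c[2] in "GC") / joint.sum())
    k = pd.Series({c: code.degeneracy_class(code.aa_of(c))
                   for c in code.sense_codons}, dtype=float)
    return UsageProfile(cuf=cuf_s, aa_freq=aa_s, gc3=gc3, rscu=cuf_s * k,
                        code_id=code.table_id, label=label)


_NC_WEIGHTS = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}


def effective_number_of_codons(counts: Mapping[str, float] | pd.Series,
                               code: GeneticCode | None = None,
                               small_sample_correction: bool = False) -> float:
    """Wright's effective number of codons of an aggregated count row.

    Per-amino-acid homozygosity is the plug-in F = sum(p_i^2) by default, so
    that exactly uniform synonymous usage yields Nc = 61 and one-codon-per-aa
    usage yields Nc = 20 at any count depth.  ``small_sample_correction``
    switches to Wright's estimator F = (n*sum(p^2) - 1)/(n - 1).

    A missing 3-fold class mean is imputed from the 2- and 4-fold means
    (Wright's rule); any other missing class falls back to the mean of the
    available class means, with a warning.  Values above 61 are possible for
    tiny inputs and are reported as-is with a warning.
    """
    code = code or default_code()
    n = _as_counts(counts, code)
    by_class: dict[int, list[float]] = {}
    for aa in code.amino_acids:
        fam = list(code.family(aa))
        k = len(fam)
        if k == 1:
            continue
        n_aa = float(n[fam].sum())
        if n_aa < 2:
            continue
        p = (n[fam] / n_aa).to_numpy()
        f = float((p ** 2).sum())
        if small_sample_correction:
            f = (n_aa * f - 1.0) / (n_aa - 1.0)
        if f <= 0:
            continue
        by_class.setdefault(k, []).append(f)
    fbar = {k: float(np.mean(v)) for k, v in by_class.items()}
    if not fbar:
        warnings.warn("no degenerate family with computable homozygosity; "
                      "Nc undefined")
        return math.nan
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = 1.0 / ((1.0 / fbar[2] + 1.0 / fbar[4]) / 2.0)
    missing = [k for k in _NC_WEIGHTS if k not in fbar]
    if missing:
        fill = float(np.mean(list(fbar.values())))
        warnings.warn(f"no computable homozygosity for class(es) {missing}; "
                      "imputed with the mean of the available class means")
        for k in missing:
            fbar[k] = fill
    nc = 2.0 + sum(w / fbar[k] for k, w in _NC_WEIGHTS.items())
    if nc > 61.0 + 1e-9:
        warnings.warn(f"Nc = {nc:.3f} exceeds 61 (small-sample artifact); "
                      "reported as-is")
    return nc


def rscu_ca_matrix(table: CodonCountTable,
                   code: GeneticCode | None = None) -> pd.DataFrame:
    """Genes x codons RSCU matrix with absent families set to 0.

    This is the correspondence-analysis input convention; inside
    :class:`UsageProfile` absent families stay undefined instead.
    """
    code = code or default_code()
    out = np.zeros(table.counts.shape, dtype=float)
    cols = list(table.counts.columns)
    values = table.counts.to_numpy(dtype=float)
    for aa in code.amino_acids:
        fam = [cols.index(c) for c in code.family(aa)]
        k = len(fam)
        tot = values[:, fam].sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            block = np.where(tot > 0, k * values[:, fam] / tot, 0.0)
        out[:, fam] = block
    return pd.DataFrame(out, index=table.counts.index, columns=cols)
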