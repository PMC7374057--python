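"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA goes through Biopython; tables are TSV via pandas.  All writers are
deterministic (fixed column order, fixed float formatting) so reruns with the
same seed produce byte-identical artifacts.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .code import GeneticCode, default_code
from .core import CodingSequence, CodonCountTable, GeneSetPartition, UsageProfile
from .disttree import DistanceMatrix
from .domains import AbundanceTable
from .tai import AdaptivenessTable, TRNAPool


# -- FASTA ------------------------------------------------------------------

def read_cds_fasta(path: str | Path) -> list[CodingSequence]:
    return [CodingSequence(id=rec.id, seq=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[CodingSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Aligned amino-acid FASTA as an ordered id -> row mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- count tables and profiles -----------------------------------------------

def write_count_table(table: CodonCountTable, path: str | Path) -> None:
    out = table.counts.copy()
    out["skipped"] = table.skipped
    out.to_csv(path, sep="\t")


def read_count_table(path: str | Path,
                     code: GeneticCode | None = None) -> CodonCountTable:
    code = code or default_code()
    df = pd.read_csv(path, sep="\t", index_col=0)
    skipped = (df.pop("skipped").astype(int) if "skipped" in df.columns
               else pd.Series(0, index=df.index))
    counts = df.reindex(columns=list(code.sense_codons)).fillna(0).astype(int)
    return CodonCountTable(counts, skipped, code.table_id)


def write_profile_tsv(profile: UsageProfile, path: str | Path,
                      code: GeneticCode | None = None) -> None:
    code = code or default_code()
    rows = []
    for codon in code.sense_codons:
        aa = code.aa_of(codon)
        rows.append({
            "codon": codon,
            "aa": aa,
            "cuf": float(profile.cuf[codon]),
            "rscu": (float(profile.rscu[codon])
                     if profile.rscu is not None else math.nan),
            "aa_freq": float(profile.aa_freq[aa]),
        })
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# gc3={profile.gc3:.10g}")
        if profile.nc is not None:
            fh.write(f"\tnc={profile.nc:.10g}")
        if profile.label:
            fh.write(f"\tlabel={profile.label}")
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_profile_tsv(path: str | Path,
                     code: GeneticCode | None = None) -> UsageProfile:
    code = code or default_code()
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for item in first[1:].strip().split("\t"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    meta[k] = v
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    df = df.set_index("codon").reindex(list(code.sense_codons))
    cuf = df["cuf"].astype(float)
    rscu = df["rscu"].astype(float) if "rscu" in df.columns else None
    aa_freq = pd.Series({aa: 0.0 for aa in code.amino_acids})
    if "aa_freq" in df.columns:
        for codon in df.index:
            aa_freq[code.aa_of(codon)] = float(df.loc[codon, "aa_freq"])
    gc3 = float(meta.get("gc3", "nan"))
    nc = float(meta["nc"]) if "nc" in meta else None
    return UsageProfile(cuf=cuf, aa_freq=aa_freq, gc3=gc3, rscu=rscu, nc=nc,
                        code_id=code.table_id, label=meta.get("label"))


# -- partitions, tRNA pools, abundances ---------------------------------------

def write_partition_tsv(partition: GeneSetPartition, path: str | Path) -> None:
    rows = [(gene, name) for name, members in partition.sets.items()
            for gene in members]
    pd.DataFrame(rows, columns=["gene", "set"]).to_csv(path, sep="\t",
                                                       index=False)


def read_partition_tsv(path: str | Path) -> GeneSetPartition:
    df = pd.read_csv(path, sep="\t")
    return GeneSetPartition.from_items(
        (str(row.gene), str(row.set)) for row in df.itertuples())


def write_trna_tsv(pool: TRNAPool, path: str | Path) -> None:
    rows = sorted(pool.tgcn.items())
    pd.DataFrame(rows, columns=["anticodon", "copy_number"]).to_csv(
        path, sep="\t", index=False)


def read_trna_tsv(path: str | Path) -> TRNAPool:
    df = pd.read_csv(path, sep="\t")
    return TRNAPool({str(r.anticodon): int(r.copy_number)
                     for r in df.itertuples()})


def write_abundance_tsv(abund: AbundanceTable, path: str | Path) -> None:
    df = abund.abundance.rename("abundance").rename_axis("protein")
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_abundance_tsv(path: str | Path) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AbundanceTable(df.iloc[:, 0].astype(float))


def write_adaptiveness_tsv(adapt: AdaptivenessTable, path: str | Path) -> None:
    df = pd.DataFrame({
        "codon": list(adapt.W.index),
        "W": adapt.W.to_numpy(),
        "w": adapt.w.to_numpy(),
        "substituted": [int(c in adapt.substituted) for c in adapt.W.index],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# -- distance matrices and trees ----------------------------------------------

def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(tuple(df.index), df.to_numpy(dtype=float))


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick + ("\n" if not newick.endswith("\n") else ""))
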