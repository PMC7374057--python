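"""Codon-usage differences between gene sets: delta-CUF, C/U biases, groups.

The C bias is an enrichment of C-ending codons in the pyrimidine-ending
2-fold families (Asp, Phe, His, Asn, Tyr) and the 3-fold Ile box; the Cys
codon TGC is excluded because it shows no ancestry-dependent C bias.  The U
bias is an enrichment of U-ending codons in the 4-fold families (Val, Thr,
Pro, Ala, Gly) and the 4-fold boxes of the 6-fold amino acids (Ser, Leu,
Arg).  Both are tested with a one-sample, one-sided t test across the
eligible codons' CUF differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .code import GeneticCode, default_code
from .core import UsageProfile

#: C-ending codons of the pyrimidine-ending 2-/3-fold families, minus TGC (Cys).
C_BIAS_CODONS = ("AAC", "ATC", "CAC", "GAC", "TAC", "TTC")

#: U-ending codons of the 4-fold families and of the 4-fold boxes of Ser/Leu/Arg.
U_BIAS_CODONS = ("ACT", "CCT", "CGT", "CTT", "GCT", "GGT", "GTT", "TCT")


@dataclass
class BiasProfile:
    """Per-codon CUF differences between two profiles (set1 - set2)."""

    delta: pd.Series
    excluded_families: tuple[str, ...] = ()
    label1: str | None = None
    label2: str | None = None


@dataclass
class BiasTest:
    codons: tuple[str, ...]
    deltas: pd.Series
    mean_delta: float
    statistic: float
    p_value: float
    zero_variance: bool = False


def delta_cuf(profile1: UsageProfile, profile2: UsageProfile,
              code: GeneticCode | None = None) -> BiasProfile:
    """CUF(set1) - CUF(set2) per codon over the families defined in both.

    Families undefined in either profile are excluded and listed; the deltas
    of each shared family sum to zero by construction.
    """
    code = code or default_code()
    delta = pd.Series(np.nan, index=pd.Index(code.sense_codons, name="codon"))
    excluded: list[str] = []
    any_shared = False
    for aa in code.amino_acids:
        fam = list(code.family(aa))
        if profile1.cuf[fam].isna().any() or profile2.cuf[fam].isna().any():
            excluded.append(aa)
            continue
        any_shared = True
        delta[fam] = profile1.cuf[fam] - profile2.cuf[fam]
    if not any_shared:
        raise ValueError("profiles share no defined family")
    return BiasProfile(delta=delta, excluded_families=tuple(excluded),
                       label1=profile1.label, label2=profile2.label)


def _one_sided_t(deltas: pd.Series) -> BiasTest:
    d = deltas.dropna()
    if len(d) < 3:
        raise ValueError("fewer than 3 eligible codons with defined delta")
    values = d.to_numpy(dtype=float)
    mean = float(values.mean())
    if float(values.std(ddof=1)) <= 1e-12 * max(1.0, abs(mean)):
        # degenerate: identical deltas; report the limiting test outcome
        if mean > 0:
            t, p = math.inf, 0.0
        elif mean < 0:
            t, p = -math.inf, 1.0
        else:
            t, p = 0.0, 0.5
        return BiasTest(tuple(d.index), d, mean, t, p, zero_variance=True)
    res = stats.ttest_1samp(values, 0.0, alternative="greater")
    return BiasTest(tuple(d.index), d, mean,
                    float(res.statistic), float(res.pvalue))


def c_bias_test(bias: BiasProfile) -> BiasTest:
    """One-sided t test of the C-bias deltas against zero (delta > 0)."""
    return _one_sided_t(bias.delta.reindex(list(C_BIAS_CODONS)))


def u_bias_test(bias: BiasProfile) -> BiasTest:
    """One-sided t test of the U-bias deltas against zero (delta > 0)."""
    return _one_sided_t(bias.delta.reindex(list(U_BIAS_CODONS)))


def bias_test_across_species(biases: Sequence[BiasProfile],
                             which: str = "c") -> BiasTest:
    """Second testing mode: one-sided t test on per-species mean deltas.

    Each species contributes the mean delta over its eligible codons, and the
    test is run across species -- the aggregation used when several genomes
    are compared at once.
    """
    codons = C_BIAS_CODONS if which.lower().startswith("c") else U_BIAS_CODONS
    means = pd.Series(
        {i: float(b.delta.reindex(list(codons)).dropna().mean())
         for i, b in enumerate(biases)})
    return _one_sided_t(means)


@dataclass
class GroupCall:
    """A genome's codon-usage diversity group (A-D) with its evidence."""

    group: str
    evidence: dict[str, float]


def classify_group(gc_total: float,
                   gc3_by_set: Mapping[str, float],
                   margin: float = 0.03,
                   low_gc: float = 0.36,
                   high_gc: float = 0.60) -> GroupCall:
    """Classify a genome into codon-usage diversity groups A-D.

    ``gc3_by_set`` must provide GC3 for 'singletons', 'core' (the pooled most
    ancestral core by default) and 'phe'.  Rules, checked in order:

    * A -- very low global GC (< ``low_gc``) with
      GC3(singletons) > GC3(core) > GC3(PHE);
    * B -- low/intermediate GC (< ``high_gc``) where GC3(core) exceeds both
      GC3(PHE) and GC3(singletons) by at least ``margin`` (the biphasic
      pattern);
    * C -- GC3(PHE) > GC3(core) > GC3(singletons);
    * D -- very high global GC (>= ``high_gc``) with
      GC3(core) >= GC3(PHE) > GC3(singletons).

    Anything else is an explicit 'none' call, evidence retained.
    """
    keys = {k.lower(): v for k, v in gc3_by_set.items()}
    try:
        s, c, p = keys["singletons"], keys["core"], keys["phe"]
    except KeyError as exc:
        raise ValueError(f"missing GC3 for set {exc}") from exc
    evidence = {"gc_total": float(gc_total), "gc3_singletons": float(s),
                "gc3_core": float(c), "gc3_phe": float(p), "margin": margin}
    if gc_total < low_gc and s > c > p:
        return GroupCall("A", evidence)
    if gc_total < high_gc and c - max(p, s) >= margin:
        return GroupCall("B", evidence)
    if p > c > s:
        return GroupCall("C", evidence)
    if gc_total >= high_gc and c >= p > s:
        return GroupCall("D", evidence)
    return GroupCall("none", evidence)
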