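"""tRNA adaptation: absolute adaptiveness (Wi), tAI, m-tAI, DCBS, Sij training.

A codon's absolute adaptiveness W_i sums, over the anticodons allowed to
decode it, the tRNA gene copy number weighted by a pairing-efficiency factor
(1 - s) where s is the wobble penalty of the codon:anticodon pairing class.
Relative adaptiveness w_i = W_i / max W; the tAI of a gene is the geometric
mean of w over its codons.  The wobble penalties can be trained per genome by
maximizing the Spearman correlation between the directional codon bias score
(DCBS) and the tAI across genes, with Nelder-Mead from random restarts.

Allowed pairings (anticodons written 5'->3'; position 34 is the first base):

===========  ====================  ======================
codon 3' nt  Watson-Crick (s = 0)  wobble (trainable s)
===========  ====================  ======================
U            A34  (class "A:U")*   G34  (class "G:U")
C            G34                   A34-as-inosine ("I:C")
A            U34                   A34-as-inosine ("I:A")
G            C34                   U34  (class "U:G")
===========  ====================  ======================

(*) the A:U slot is itself trainable: bacterial A34 is normally deaminated to
inosine, so its efficiency on U-ending codons is genome dependent.  The
nonstandard U3:U34 pairing is deliberately excluded from the index.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import spearmanr

from .code import GeneticCode, default_code, dna, revcomp
from .core import CodonCountTable, UsageProfile

WOBBLE_CLASSES = ("A:U", "G:U", "I:C", "I:A", "U:G")

#: dos Reis-style starting penalties (bacterial defaults).
DOS_REIS_SIJ = {"A:U": 0.0, "G:U": 0.41, "I:C": 0.28, "I:A": 0.9999, "U:G": 0.68}


@dataclass
class TRNAPool:
    """Anticodon gene copy numbers, anticodons as 5'->3' DNA triplets."""

    tgcn: dict[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for anticodon, n in self.tgcn.items():
            a = dna(anticodon)
            if len(a) != 3 or any(b not in "ACGT" for b in a):
                raise ValueError(f"invalid anticodon {anticodon!r}")
            if n < 0:
                raise ValueError(f"negative copy number for {anticodon!r}")
            clean[a] = clean.get(a, 0) + int(n)
        if not any(v > 0 for v in clean.values()):
            raise ValueError("tRNA pool has no anticodon with positive copy number")
        self.tgcn = clean

    def copies(self, anticodon: str) -> int:
        return self.tgcn.get(dna(anticodon), 0)


@dataclass
class SijWeights:
    """Pairing-efficiency penalties per wobble class, each in [0, 1]."""

    s: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.s) - set(WOBBLE_CLASSES)
        if unknown:
            raise ValueError(f"unknown pairing class(es): {sorted(unknown)}")
        for cls_name, v in self.s.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"s[{cls_name}] = {v} outside [0, 1]")
        self.s = {k: float(self.s.get(k, DOS_REIS_SIJ[k])) for k in WOBBLE_CLASSES}

    def as_array(self) -> np.ndarray:
        return np.array([self.s[k] for k in WOBBLE_CLASSES])

    def to_json(self, **extra) -> str:
        return json.dumps({"s": self.s, **extra}, indent=2, sort_keys=True)


@dataclass
class AdaptivenessTable:
    """Absolute (W) and relative (w) adaptiveness per sense codon."""

    W: pd.Series
    w: pd.Series
    substituted: tuple[str, ...] = ()


def pairing_partners(code: GeneticCode | None = None
                     ) -> dict[str, tuple[tuple[str, str | None], ...]]:
    """Allowed (anticodon, pairing-class) pairs per sense codon.

    Class ``None`` marks a fixed Watson-Crick pairing (s = 0); named classes
    are the trainable entries of :data:`WOBBLE_CLASSES`.
    """
    code = code or default_code()
    table: dict[str, tuple[tuple[str, str | None], ...]] = {}
    for codon in code.sense_codons:
        wc = revcomp(codon)             # anticodon 5'->3'; wc[0] is position 34
        tail = wc[1:]
        third = codon[2]
        if third == "T":
            pairs = ((wc, "A:U"), ("G" + tail, "G:U"))
        elif third == "C":
            pairs = ((wc, None), ("A" + tail, "I:C"))
        elif third == "A":
            pairs = ((wc, None), ("A" + tail, "I:A"))
        else:
            pairs = ((wc, None), ("T" + tail, "U:G"))
        table[codon] = pairs
    return table


def absolute_adaptiveness(pool: TRNAPool,
                          s: SijWeights | Mapping[str, float] | None = None,
                          code: GeneticCode | None = None) -> AdaptivenessTable:
    """W_i = sum over allowed pairings of (1 - s_class) * tGCN[anticodon].

    Codons with W = 0 receive the geometric mean of the nonzero relative
    adaptiveness values (dos Reis convention) and are flagged as substituted.
    """
    code = code or default_code()
    if s is None:
        s = SijWeights(dict(DOS_REIS_SIJ))
    elif not isinstance(s, SijWeights):
        s = SijWeights(dict(s))
    partners = pairing_partners(code)
    W = pd.Series(0.0, index=pd.Index(code.sense_codons, name="codon"))
    for codon, pairs in partners.items():
        total = 0.0
        for anticodon, cls_name in pairs:
            penalty = 0.0 if cls_name is None else s.s[cls_name]
            total += (1.0 - penalty) * pool.copies(anticodon)
        W[codon] = total
    w_max = W.max()
    if w_max <= 0:
        raise ValueError("pool decodes nothing: all W are zero")
    w = W / w_max
    zero = w.index[w <= 0]
    substituted: tuple[str, ...] = ()
    if len(zero):
        nonzero = w[w > 0]
        gm = float(np.exp(np.log(nonzero).mean()))
        w = w.copy()
        w[zero] = gm
        substituted = tuple(zero)
    return AdaptivenessTable(W=W, w=w, substituted=substituted)


def gene_tai(counts: Mapping[str, float] | pd.Series,
             adapt: AdaptivenessTable) -> float:
    """Geometric mean of w over a gene's codons, with multiplicity."""
    n = pd.Series(counts, dtype=float).reindex(adapt.w.index).fillna(0.0)
    total = float(n.sum())
    if total == 0:
        raise ValueError("gene has no sense codons")
    return float(np.exp((n * np.log(adapt.w)).sum() / total))


def genome_tai(table: CodonCountTable, adapt: AdaptivenessTable) -> pd.Series:
    """Vectorized per-gene tAI over a count table."""
    counts = table.counts[list(adapt.w.index)].to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("table contains genes without sense codons")
    tai = np.exp(counts @ np.log(adapt.w.to_numpy()) / totals)
    return pd.Series(tai, index=table.genes, name="tai")


def modal_tai(profile: UsageProfile, adapt: AdaptivenessTable,
              code: GeneticCode | None = None) -> float:
    """m-tAI: geometric mean of w under the joint usage aa_freq * cuf.

    Equals the tAI of the profile's modal sequence up to rounding in the
    sequence's integer codon counts.
    """
    code = code or default_code()
    log_sum = 0.0
    weight = 0.0
    for aa in code.amino_acids:
        f_aa = float(profile.aa_freq.get(aa, 0.0))
        if f_aa <= 0:
            continue
        fam = list(code.family(aa))
        if profile.cuf[fam].isna().any():
            raise ValueError(f"amino acid {aa} has positive frequency but "
                             "undefined family CUF")
        for codon in fam:
            q = f_aa * float(profile.cuf[codon])
            if q > 0:
                log_sum += q * math.log(float(adapt.w[codon]))
                weight += q
    if weight <= 0:
        raise ValueError("profile carries no usage mass")
    return float(math.exp(log_sum / weight))


def gene_dcbs(counts: Mapping[str, float] | pd.Series) -> float:
    """Directional codon bias score of one gene.

    With f(xyz) the gene's sense-codon frequencies and f1, f2, f3 its
    positional nucleotide frequencies (from the same codons),
    d(xyz) = max(f/(f1 f2 f3), f1 f2 f3/f) and DCBS is the mean of d over the
    gene's codons with multiplicity.  DCBS >= 1, with equality when codon
    frequencies factorize into the positional frequencies.
    """
    n = pd.Series(counts, dtype=float)
    n = n[n > 0]
    total = float(n.sum())
    if total == 0:
        raise ValueError("gene has no sense codons")
    f = n / total
    pos = [{b: 0.0 for b in "ACGT"} for _ in range(3)]
    for codon, freq in f.items():
        for k in range(3):
            pos[k][codon[k]] += freq
    d_sum = 0.0
    for codon, freq in f.items():
        expect = pos[0][codon[0]] * pos[1][codon[1]] * pos[2][codon[2]]
        if expect <= 0:  # impossible when codon observed; guard anyway
            raise ValueError(f"zero positional frequency for observed {codon}")
        ratio = freq / expect
        d_sum += freq * max(ratio, 1.0 / ratio)
    return float(d_sum)


def genome_dcbs(table: CodonCountTable) -> pd.Series:
    return pd.Series({g: gene_dcbs(table.row(g)) for g in table.genes},
                     name="dcbs")


@dataclass
class SijTrainingResult:
    weights: SijWeights
    rho: float
    start_rhos: tuple[float, ...]
    restart_rhos: tuple[float, ...]
    seed: int
    n_genes: int


def train_sij(table: CodonCountTable,
              pool: TRNAPool,
              restarts: int = 20,
              seed: int = 0,
              code: GeneticCode | None = None,
              max_iter: int = 500,
              ftol: float = 1e-6) -> SijTrainingResult:
    """Train the wobble penalties by maximizing Spearman(DCBS, tAI).

    Each restart draws a start uniformly in [0,1]^5 from the seeded generator
    and runs Nelder-Mead on the negative correlation; proposals outside the
    box are clipped to [0, 1].  The best restart is returned together with
    the achieved correlation; results are reproducible given the seed.
    """
    code = code or default_code()
    if len(table.genes) < 50:
        warnings.warn("fewer than 50 genes; trained weights may be unstable")
    dcbs = genome_dcbs(table).to_numpy()
    if float(np.std(dcbs)) == 0.0:
        raise ValueError("zero variance in DCBS: all genes identical")
    counts = table.counts[list(code.sense_codons)].to_numpy(dtype=float)
    totals = counts.sum(axis=1)

    def objective(x: np.ndarray) -> float:
        # cap just below 1 (dos Reis convention) so no codon's W collapses to 0
        s = SijWeights(dict(zip(WOBBLE_CLASSES, np.clip(x, 0.0, 0.9999))))
        adapt = absolute_adaptiveness(pool, s, code)
        tai = counts @ np.log(adapt.w.to_numpy()) / totals
        rho = spearmanr(dcbs, tai).statistic
        if math.isnan(rho):
            return 0.0
        return -rho

    rng = np.random.default_rng(seed)
    best_x: np.ndarray | None = None
    best_f = math.inf
    start_rhos: list[float] = []
    restart_rhos: list[float] = []
    for _ in range(max(1, restarts)):
        x0 = rng.uniform(0.0, 1.0, len(WOBBLE_CLASSES))
        start_rhos.append(-objective(x0))
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": max_iter, "fatol": ftol,
                                "xatol": 1e-4})
        restart_rhos.append(-float(res.fun))
        if res.fun < best_f:
            best_f = float(res.fun)
            best_x = np.clip(res.x, 0.0, 0.9999)
    assert best_x is not None
    weights = SijWeights(dict(zip(WOBBLE_CLASSES, best_x)))
    return SijTrainingResult(weights=weights, rho=-best_f,
                             start_rhos=tuple(start_rhos),
                             restart_rhos=tuple(restart_rhos),
                             seed=seed, n_genes=len(table.genes))
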