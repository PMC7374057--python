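"""Modal codon usage of a gene set and artificial modal sequences.

The modal usage is the codon usage of the largest internally consistent core
of a gene collection, found by iterating: score every gene against a
candidate usage with a per-amino-acid multinomial likelihood-ratio (G)
statistic, keep the genes whose chi-square p-value exceeds a cutoff, and
re-pool the accepted genes into the next candidate.  A contaminated
collection therefore converges to its majority component rather than to the
pooled mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2

from .code import GeneticCode, default_code
from .core import CodingSequence, CodonCountTable, UsageProfile, rscu_profile

CUF_FLOOR = 1e-6


@dataclass
class ModalResult:
    profile: UsageProfile
    accepted_genes: tuple[str, ...]
    iterations: int
    converged: bool
    p_values: pd.Series


def _candidate_cuf(pooled: pd.Series, code: GeneticCode) -> pd.Series:
    """Pooled CUF floored at CUF_FLOOR and renormalized within each family.

    A family absent from the pool becomes uniform, so genes using it are
    scored against an uninformative candidate instead of crashing the log.
    """
    q = pd.Series(0.0, index=pooled.index)
    for aa in code.amino_acids:
        fam = list(code.family(aa))
        v = pooled[fam].astype(float).clip(lower=0.0) + 0.0
        tot = v.sum()
        p = v / tot if tot > 0 else pd.Series(1.0 / len(fam), index=fam)
        p = p.clip(lower=CUF_FLOOR)
        q[fam] = p / p.sum()
    return q


def modal_usage(table: CodonCountTable,
                code: GeneticCode | None = None,
                p_cutoff: float = 0.1,
                max_iter: int = 50) -> ModalResult:
    """Iteratively estimate the modal codon usage of a gene collection.

    Per gene the statistic is G = 2 * sum_c n_c ln(n_c / (N_aa q_c)) with q
    the candidate CUF, referred to chi-square with sum(k_aa - 1) degrees of
    freedom over the families observed in that gene.  Genes with p > cutoff
    are accepted; convergence is an accepted set identical to the one that
    produced the candidate.
    """
    code = code or default_code()
    if not (0.0 < p_cutoff < 1.0):
        raise ValueError("p_cutoff must lie in (0, 1)")
    if len(table.genes) < 2:
        raise ValueError("modal usage needs at least 2 genes")
    counts = table.counts.to_numpy(dtype=float)
    genes = table.genes
    cols = list(table.counts.columns)
    # amino-acid aggregation matrix: codons x amino acids
    aa_list = list(code.amino_acids)
    agg = np.zeros((len(cols), len(aa_list)))
    fam_size = np.zeros(len(aa_list))
    for j, aa in enumerate(aa_list):
        for codon in code.family(aa):
            agg[cols.index(codon), j] = 1.0
        fam_size[j] = code.degeneracy_class(aa)

    n_ln_n = xlogy(counts, counts).sum(axis=1)
    n_aa = counts @ agg                                   # genes x aa
    n_ln_naa = xlogy(n_aa, n_aa).sum(axis=1)
    df = ((n_aa > 0) * (fam_size - 1.0)).sum(axis=1)

    accepted = np.ones(len(genes), dtype=bool)
    converged = False
    iterations = 0
    p = np.ones(len(genes))
    for iterations in range(1, max_iter + 1):
        pooled = pd.Series(counts[accepted].sum(axis=0), index=cols)
        q = _candidate_cuf(pooled, code).to_numpy()
        g = 2.0 * (n_ln_n - n_ln_naa - counts @ np.log(q))
        g = np.maximum(g, 0.0)                            # guard tiny negatives
        p = np.where(df > 0, chi2.sf(g, np.maximum(df, 1e-12)), 1.0)
        new_accepted = p > p_cutoff
        if not new_accepted.any():
            raise ValueError("accepted set became empty; "
                             "consider a larger p_cutoff")
        if (new_accepted == accepted).all():
            converged = True
            break
        accepted = new_accepted
    accepted_ids = tuple(genes[accepted])
    pooled = pd.Series(counts[accepted].sum(axis=0), index=cols)
    profile = rscu_profile(pooled, code, label="modal")
    return ModalResult(profile=profile, accepted_genes=accepted_ids,
                       iterations=iterations, converged=converged,
                       p_values=pd.Series(p, index=genes))


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Largest-remainder rounding; remainder ties go to the lowest index so the
    allocation is deterministic.
    """
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights sum to zero")
    quota = w / w.sum() * total
    base = np.floor(quota).astype(int)
    short = total - int(base.sum())
    if short > 0:
        remainder = quota - base
        # stable sort descending by remainder, ascending by index
        order = np.lexsort((np.arange(len(w)), -remainder))
        base[order[:short]] += 1
    return base


def modal_sequence(profile: UsageProfile,
                   aa_freq: pd.Series | None = None,
                   min_codons: int = 10020,
                   code: GeneticCode | None = None,
                   seq_id: str | None = None) -> CodingSequence:
    """Emit an artificial CDS realizing a profile's CUF and aa composition.

    Codon counts follow largest-remainder rounding of aa_freq * min_codons,
    then of cuf within each family; codons are laid out grouped by amino acid
    (alphabetical) with synonymous codons in alphabetical order, so the output
    is deterministic.  The default length (10,020 codons) keeps even the
    rarest families well represented.
    """
    code = code or default_code()
    if min_codons < 1:
        raise ValueError("min_codons must be positive")
    aa_freq = profile.aa_freq if aa_freq is None else aa_freq
    aa_freq = pd.Series(aa_freq, dtype=float).reindex(code.amino_acids).fillna(0.0)
    aas = [aa for aa in code.amino_acids if aa_freq[aa] > 0]
    if not aas:
        raise ValueError("no amino acid with positive frequency")
    for aa in aas:
        fam = list(code.family(aa))
        if profile.cuf[fam].isna().any():
            raise ValueError(f"amino acid {aa} has positive frequency but "
                             "undefined family CUF")
    per_aa = largest_remainder(aa_freq[aas].to_numpy(), min_codons)
    parts: list[str] = []
    for aa, n_aa in zip(aas, per_aa):
        if n_aa == 0:
            continue
        fam = list(code.family(aa))
        per_codon = largest_remainder(profile.cuf[fam].to_numpy(), int(n_aa))
        for codon, k in zip(fam, per_codon):
            parts.append(codon * int(k))
    seq = "".join(parts)
    label = profile.label or "profile"
    return CodingSequence(id=seq_id or f"modal|{label}|n={len(seq) // 3}",
                          seq=seq)
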