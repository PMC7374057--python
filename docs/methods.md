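# Methods

This note records the models, conventions and design choices behind
`cubkit`, in the spirit of a statistical-software methods appendix.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Genetic code and counting

All statistics are defined over the 61 sense codons of NCBI translation
table 11 (configurable); the three stop codons are never counted.  The
degeneracy census of this code — 2 single-codon amino acids, nine 2-fold,
one 3-fold (Ile), five 4-fold and three 6-fold families — is the backbone of
every family-wise statistic.  Start codons are counted as their table-11
sense meaning (no initiator special-casing).  The frame policy is strict by
default: an out-of-frame CDS raises an error naming the gene; a `trim` mode
drops the trailing partial codon with a warning.  Codons containing any
non-ACGT character are skipped and tallied per gene.

## Usage statistics

- **CUF** is a codon's frequency within its synonymous family.  A family
  with zero counts is *undefined* (NaN), never zero-filled — except when a
  genes × codons RSCU matrix is exported as correspondence-analysis input,
  where absent families contribute 0, the common CA convention.
- **GC3** is the fraction of counted sense codons with G or C at the third
  position.
- **Nc** follows Wright's weighting 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆.  The
  per-amino-acid homozygosity is the plug-in F = Σp² by default, so that
  exactly uniform usage gives Nc = 61 and one-codon-per-amino-acid usage
  gives Nc = 20 at any finite count depth; Wright's small-sample estimator
  F = (nΣp² − 1)/(n − 1) is available via `small_sample_correction=True` and
  converges to the plug-in value as counts grow.  A missing 3-fold class
  mean is imputed from the 2- and 4-fold means (Wright's rule); any other
  missing class falls back to the mean of the available class means, with a
  warning — Wright does not define this case, and the fallback keeps tiny
  inputs scorable rather than undefined.  Values above 61 can occur for very
  small genes and are reported as-is with a warning.

## Modal codon usage

The modal usage of a gene collection is estimated by a fixed-point
iteration: the candidate usage starts at the pooled CUF; each gene is scored
against the candidate with a per-amino-acid multinomial likelihood-ratio
statistic G = 2 Σ_aa Σ_c n_c ln(n_c/(N_aa q_c)) referred to a chi-square
with Σ_aa (k_aa − 1) degrees of freedom over the families observed in that
gene; genes with p > 0.1 (default) are accepted and re-pooled into the next
candidate; convergence is an accepted set identical to the one that produced
the candidate (maximum 50 iterations).  The candidate CUF is floored at
10⁻⁶ and renormalized per family before taking logs, so genes using a
family absent from the pool are scored against an uninformative candidate
instead of crashing.  The chi-square approximation to the per-gene p-value
is a deliberate choice over simulation — it is deterministic, fast, and only
the *ranking* induced by the cutoff matters for the fixed point.

Artificial modal sequences realize a profile deterministically: amino-acid
counts by largest-remainder rounding of aa_freq × length, within-family codon
counts by largest-remainder rounding of CUF, codons laid out grouped by
amino acid with synonymous codons in alphabetical order.  The default length
is 10,020 codons (≥ 10,000 and divisible by the common family sizes), which
keeps each codon's realized share within ~1/n_aa of its target — small
enough that the m-tAI of a profile and the tAI of its realized sequence
agree to about 10⁻⁵.

## Correspondence analysis

Standard CA: with P the correspondence matrix and r, c its margins, the SVD
of D_r^{-1/2}(P − rcᵀ)D_c^{-1/2} yields principal coordinates (total inertia
= χ²/n).  CA signs are arbitrary, so each dimension is flipped to make the
column with the largest absolute standard coordinate positive — a
deterministic convention needed for testing, not a scientific claim.
Supplementary rows are projected as row-profile × column standard
coordinates, which reproduces an active row's coordinates exactly.  A table
whose rows are all proportional has zero inertia and is returned as a
single all-zero dimension rather than an error.  Gene-set centroids are
plain arithmetic means of member-gene coordinates (first two dimensions by
default).

## Translational adaptation

Absolute adaptiveness of codon i is Wᵢ = Σⱼ (1 − s_class(i,j)) · tGCNⱼ over
the allowed codon–anticodon pairings; wᵢ = Wᵢ/max W.  The pairing table
(anticodons 5'→3', position 34 first):

| codon 3' base | Watson–Crick slot | wobble slot |
|---|---|---|
| U | A34 (class `A:U`, trainable) | G34 (`G:U`) |
| C | G34 (s = 0) | A34 as inosine (`I:C`) |
| A | U34 (s = 0) | A34 as inosine (`I:A`) |
| G | C34 (s = 0) | U34 (`U:G`) |

The `A:U` slot is itself trainable because bacterial A34 is normally
deaminated to inosine.  The nonstandard U3:U34 pairing is deliberately
excluded, which is why a 4-fold U bias is invisible to the index (a property
the test suite asserts).  Codons with W = 0 receive the geometric mean of
the nonzero w values and are flagged.

Per-gene tAI is the geometric mean of w over the gene's codons; the m-tAI
of a gene set applies the same geometric mean under the joint usage
aa_freq × CUF of the set's modal profile.  DCBS is computed per gene from
its own sense-codon counts: with f the codon frequencies and f₁f₂f₃ the
product of the gene's positional nucleotide frequencies,
d = max(f/(f₁f₂f₃), f₁f₂f₃/f) and DCBS is the count-weighted mean of d
(≥ 1, = 1 when codon usage factorizes into positional composition).

Wobble-penalty training maximizes Spearman's ρ between DCBS and tAI across
genes with Nelder–Mead (default 20 restarts, 500 iterations, objective
tolerance 10⁻⁶), starts drawn uniformly from [0,1]⁵ with a seeded
generator, and proposals clipped to [0, 0.9999] — the cap just below 1
keeps every codon's W positive, so wobble-only codons retain their
copy-number-driven ranking instead of collapsing into the geometric-mean
substitute.  Since tAI depends on the penalties only through the fixed count
matrix, the objective is cheap and the 5-dimensional search converges in
seconds on hundreds of genes.

## Bias profiles and diversity groups

ΔCUF between two gene sets is computed over families defined in both (per
family the deltas sum to zero).  The **C bias** test takes the C-ending
codons of the pyrimidine-ending 2-fold families (Asp GAC, Phe UUC, His CAC,
Asn AAC, Tyr UAC) plus 3-fold Ile AUC — Cys UGC is excluded because it shows
no ancestry-dependent C bias — and applies a one-sample, one-sided t test of
Δ > 0.  The **U bias** test does the same over the U-ending codons of the
4-fold families (Val, Thr, Pro, Ala, Gly) and the 4-fold boxes of the
6-fold amino acids (Ser UCU, Leu CUU, Arg CGU).  A second mode tests
per-species mean deltas across several genomes.  An (essentially) constant
delta vector is reported as the limiting test outcome (t = ±∞, p ∈ {0, 1},
or t = 0, p = 0.5 at zero), flagged `zero_variance`, rather than NaN.

Genomes are classified into codon-usage diversity groups from global GC and
the GC3 of singletons, most-ancestral core (pooled Cn by default) and PHE:
A — global GC < 0.36 with GC3 decreasing singletons → core → PHE;
B — global GC < 0.60 with GC3(core) exceeding both others by ≥ 0.03 (the
biphasic pattern; the margin is the smallest gap that reads as biphasic and
is configurable); C — GC3 strictly increasing; D — global GC ≥ 0.60 with
GC3(core) ≥ GC3(PHE) > GC3(singletons).  Anything else is an explicit
`none` call with the evidence retained.

## Conserved and variable codon domains

HEP/LEP gene subsets are the ≥ 0.9 / ≤ 0.1 abundance quantiles (defaults,
configurable) among core genes with abundance data.  Codons are
back-threaded onto amino-acid alignments after verifying that each member's
translated CDS equals its ungapped row.  Column rules: *conserved* = one
amino acid in every row and no gap (a gapped column can never be fully
conserved); *variable* = no amino acid above proportion 0.5 among non-gap
residues; everything else *intermediate*.  cr/vr domains concatenate the
reference member's codons at qualifying columns, skipping reference gaps;
an empty domain is a warning, not an error (sparse LEP_cr collections are
expected).  Sequence conservation defaults to percent fully conserved
columns over columns where the reference has a residue; mean pairwise
identity is available as an alternative metric.

## Usage distances and trees

The distance between two usage profiles is D = Σ_aa m_aa · ½ Σ_c |Δcuf(c)|
with m_aa the mean of the two amino-acid frequencies — a per-family L1
difference that down-weights rare amino acids.  It is symmetric, satisfies
the triangle inequality, and is invariant to relabeling codons within a
family.  Trees are built with Saitou–Nei neighbor joining: deterministic
tie-breaking (the minimal-Q pair with the lowest index order joins first),
and negative branch lengths clamped to zero with the deficit moved to the
sibling branch (Phylip-compatible practice).  NJ is exact on additive
distances, which the tests exploit as an oracle alongside scikit-bio's
implementation.

## Synthetic data: the study conditions

The generator emulates the inputs the analysis needs, at desk scale.

**Genomes.**  Gene sets (singletons, C1…Cn, PHE) sample codons per amino
acid from a mixture (1 − m)·mutational + m·selected, with the selection
intensity m rising monotonically with ancestry (defaults 0.05 for
singletons, 0.25→0.70 across four cores, 0.92 for PHE).  The mutational
profile is GC3-driven (weight 0.42); the ancestral-selection profile is
GC-richer (0.60) and carries the planted C bias (×3 on the six C-bias
codons) and a moderate U bias (×2); the PHE set blends its selected
component 70 % toward an expression profile that keeps the full C bias but
intensifies the 4-fold U bias (×8) and shifts 2-fold purine families toward
A-ending codons over a lower GC3 baseline (0.45).  Two features of this
geometry matter: the linear two-profile mixture alone cannot produce the
biphasic (group B) GC3 pattern — GC3 would be monotone in m — so the
expression blend is what bends the trajectory down after the cores; and the
expression direction deliberately shares the ancestral-selection component,
since with a near-orthogonal expression direction the first CA dimension is
captured by the PHE displacement and the core gradient projects flat,
contrary to the directional shift the analysis is meant to exhibit.  Gene
lengths are log-normal (median 300 codons, σ = 0.35); amino-acid
composition is a typical bacterial average; protein abundances are
log-normal with location increasing in m, so selected sets look highly
expressed.  Everything is reproducible from the config seed.

**tRNA pools.**  Pools are sparse, as in real prokaryotes: per codon box a
G34 isoacceptor (reads NNC by Watson–Crick and NNU by G:U wobble), a U34
isoacceptor (NNA directly, NNG by wobble), and a C34 isoacceptor only where
the G-ending codon dominates its purine partner; copy numbers are
proportional to overall codon usage (aa_freq × CUF, total ≈ 140 genes).
Sparseness is essential: if every codon had a direct decoder the wobble
penalties would be unidentifiable from sequence data.

**Penalty-recovery study.**  The planted-truth experiment fixes true
penalties s* (near bacterial values), derives w* from a pool, and builds a
genome of 800 genes × 450 codons whose selected preference is CUF ∝ w*⁴,
with per-gene intensity m = U(0,1)^0.7 (top-heavy, expression-like).  These
sizes were chosen so the DCBS carries enough signal (ρ between DCBS and
intensity ≈ 0.5); with shorter genes or a flatter preference the sampling
noise of the objective itself — not the optimizer — caps how well the
planted adaptiveness can be recovered.

**M0 evolution.**  Null sequences evolve under the one-ratio Goldman–Yang
model: rates zero for multi-nucleotide changes, π_j for synonymous
transversions, κπ_j for synonymous transitions, and ω times those for
nonsynonymous changes; π is F3×4 (positional nucleotide products with stop
mass removed and renormalized), and the generator is scaled to one expected
substitution per codon per unit branch length at equilibrium.  Simulation is
exact per-site Gillespie rather than matrix exponentials — event sequences
are cheap at desk scale and the sampler doubles as a reference for the rate
matrix.  ω may be a per-site vector, which is how fast columns are planted
for the conserved/variable analyses.  No indels and no among-site rate
variation beyond the ω classes.  The built-in NG86 counter
(pathway-averaged differences, mutations to stops counted toward the
nonsynonymous share, Jukes–Cantor correction) verifies the simulator's
KA/KS; it matches Biopython's NG86 to machine precision on common inputs.
Note that NG86 counts sites assuming equal mutation rates, so at κ = 2 the
measured ratio at true ω = 1 sits slightly below 1 — the cross-checks use a
compositionally balanced root so this bias stays small.

**Ortholog families with selection.**  The natural counterpart of the M0
null keeps synonymous usage under selection: column classes (conserved /
variable / intermediate) are planted, every member's amino acids follow
them, and every member's codons are redrawn from the set's profile.  The
natural-versus-null contrast evolves the same reference CDS under M0 (slow
ω at planted-conserved columns, fast elsewhere) and runs both arms through
the identical cr/vr → modal → distance pipeline.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis consumes: family-wise
codon preferences with graded selection intensity, tRNA pools consistent
with those preferences, expression-correlated abundances, and alignable
ortholog families with and without codon selection.  It does not emulate
operon structure, codon ramps or pair biases, mRNA secondary structure,
horizontal transfer, paralogy, indels, or genome-wide mutational
heterogeneity.  Passing tests therefore show that the estimators recover
planted signals of realistic size and shape — not that any particular real
genome will show them.

## Numerical conventions

Largest-remainder roundings break remainder ties toward the lowest index;
the modal iteration guards log(0) with the 10⁻⁶ CUF floor; CA drops
singular values below 10⁻¹² of the largest; NJ ties join the lowest index
pair; bias tests detect zero variance at a relative tolerance of 10⁻¹²;
training clips penalties to [0, 0.9999].  All stochastic components take
explicit integer seeds, and all writers format floats deterministically, so
pipeline reruns are byte-identical.

## Known limitations

- The per-gene modal p-values use the chi-square approximation, which is
  anti-conservative for genes with many sparse families; only the induced
  ranking matters for the fixed point, but the accepted-set size at a given
  cutoff should not be over-interpreted.
- The tAI family of indices cannot express a 4-fold U bias (no A34 decoder,
  U:U excluded), so m-tAI understates the adaptation of strongly U-biased
  gene sets — visible in the generator's group-B PHE sets, and the reason
  the U bias is assessed by its own test rather than through m-tAI.
- NG86 is reported as defined; it is known to be biased downward under
  transition bias and strongly non-uniform codon frequencies.
- The group A–D classifier uses fixed GC windows (0.36, 0.60) and a 0.03
  GC3 margin; borderline genomes can legitimately classify as `none`.
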