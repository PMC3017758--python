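# Methods

`phytrim` selects alignment columns for phylogenetic inference with two
complementary procedures — an entropy-like variability score weighted by a
residue similarity matrix, and an iterative stationarity filter built on
Stuart's matched-pairs test of marginal symmetry — plus three recoding
schemes (RY, codon translation, degenerated codons).  This note records the
models, the parameter choices and their rationale, the numerical decisions,
and what the synthetic benchmarks do and do not demonstrate.

## Entropy-like column score

For column c let Π(c) be the diagonal matrix of relative frequencies of the
canonical states (r = 4 nucleotides or 20 amino acids) and S a symmetric
non-negative similarity matrix.  With μ = 1/trace(Π(c)S), the score is the
von-Neumann-style entropy

    h(c) = − Σ_s λ_s log_r λ_s,

where λ_s are the eigenvalues of μ·Π(c)·S; μ makes them sum to one.  With
S = I the λ_s are the state frequencies and h is the ordinary Shannon
entropy (base r): a constant column scores 0 and a uniformly variable one
scores ≈ 1.  With a substitution-informed S, exchanges that are biologically
expected (I/L/M/V) mix into a dominant eigenvalue and depress h, while
unexpected co-occurrences (C/Q/W/Y) do not — so h measures *unexpected*
variability, not variability as such.

Numerics: the non-zero spectrum of Π½ S Π½ (symmetric, hence real) equals
that of ΠS restricted to the states present, so each column costs one small
symmetric eigenproblem; whole-alignment scoring batches one r×r `eigvalsh`
per column.  Eigenvalues in [−10⁻¹², 0) from rounding are clamped to zero
and 0·log 0 := 0.  The score is invariant under positive scaling of S, so
none of the embedded matrices is renormalized.

Gap handling: Π(c) is computed over canonical residues only; gaps, missing
(`?`) and ambiguity codes are excluded from Π and all count toward the gap
proportion g(c).  An all-gap column gets h = 0 and g = 1, carries no
smoothing weight, and can never be selected.

## Similarity matrices

* **BLOSUM target frequencies.**  The score uses the Henikoff joint
  substitution probabilities q_ij (the "target frequencies" underlying the
  BLOSUM log-odds scores), not the rounded integer score matrices — the
  rounding in the published log-odds is far too coarse to reconstruct q_ij
  (attempting it shifts the I/L/M/V worked example from 0.300 to 0.256).
  The published full-precision tables for BLOSUM45, 50, 62, 80 and 90 are
  embedded under `phytrim/data/`; these five clustering levels are the ones
  for which full-precision q_ij tables are published in the public-domain
  NCBI toolkit.  BLOSUM62 is the default for amino-acid (and translated
  codon) alignments; `suggest_blosum_eta` recommends the nearest available
  level from the min–max pairwise identity rule, with the documented caveat
  that this rule underestimates the best-performing level on diverged data.
* **DNA PAM.**  PAM-1 is built from the transition/transversion ratio κ
  (default 2.0): diagonal 0.99, transitions 0.01κ/(2+κ), transversions
  0.01/(2+κ).  PAM-η (default η = 100) is the η-th matrix power of PAM-1,
  computed by repeated squaring so rows remain stochastic to machine
  precision for η up to at least 10⁴.
* **Identity**, which reduces h to Shannon entropy; useful as a reference,
  not recommended for trimming.

## Conserved-region selection

Raw scores are smoothed with a gap-weighted window of half-width w (default
1): h̃(c) = Σ (1−g)h / Σ (1−g) over max(1, c−w)..min(m, c+w); a window with
zero total weight keeps the raw score.  Columns with h̃ strictly below the
threshold (default 0.5; a tie counts as variable) form conserved (C) runs,
the rest variable (V) runs.  Each V run flanked by C runs on both sides is
merged back when the gap-weighted mean of h over the combined C∪V∪C span is
below the threshold and the span contains less than 30% gap cells; passes
repeat left-to-right until a fixpoint, which exists because each merge
removes two regions.

Two post-filters follow.  Columns with gap proportion above `max_col_gap`
(default 0.2, matching the distributed trimmers' convention) are removed:
the merge rule alone is deliberately forgiving — a variable block flanked by
long, well-conserved regions can be absorbed because the flanks dominate the
span average — and the gap filter is what keeps heavily gapped, ambiguously
aligned blocks out of the selection regardless.  Setting it to 1.0 disables
the filter (all-gap columns are still never kept).  Finally, kept runs
shorter than `min_block` (default 5) columns are dropped.  Codon alignments
are translated (universal code) and scored as amino acids; a kept amino-acid
column keeps its three nucleotide positions.

## Stationarity filter

For sequences i, j the divergence matrix F counts aligned canonical state
pairs (columns with a gap, missing or ambiguous residue in either sequence
are skipped; counts, not proportions, because the test covariance is
count-scaled).  Stuart's matched-pairs χ² test of marginal symmetry uses the
first r−1 marginal differences d_s = F_s· − F_·s and covariance
V_ss = F_s· + F_·s − 2F_ss, V_st = −(F_st + F_ts); the statistic is
dᵀV⁺d with a spectral pseudo-inverse (relative eigenvalue cutoff 10⁻¹⁰) and
df = rank(V); p is the χ² upper tail via the regularized incomplete gamma
function.  A symmetric F gives statistic 0, p = 1; rank 0 yields
(0, 0, p=1).  For nucleotide data the 3×3 full-rank case is solved in closed
form (adjugate), with the spectral path as fallback — the trimming loops
re-estimate all pairwise p-values after every single column removal, so this
is the hot path.  The χ² approximation is unreliable on short alignments; a
warning is logged when a pair contributes fewer than 1000 counted columns.

Trimming proceeds in two phases.  *Crude phase:* while any pairwise
p ≤ 0.1, remove the highest-h column (static ranking, ties by column index),
re-estimating all p-values after each removal; consecutive removal steps are
evaluated in one batched computation, which is arithmetically identical to
checking after every removal.  *Refinement:* for each removed column c,
σ(c) = Σ_pairs log(p_ij with c added to the kept set / p_ij); columns are
then re-removed from the full alignment in ascending σ order until all pairs
pass, which can only enlarge the kept set.  The refinement repeats until the
kept set stops growing, capped at `max_outer_iters` (default 50) outer
iterations.  The returned set always satisfies min pairwise p > 0.1 (the
bound is strict; equality fails), or an empty-selection error names the
worst pair.

A genuine limitation, visible in the quartet benchmark below: the test
checks *marginal* symmetry per sequence pair, so a maximal passing set can
retain biased columns whose compositional excesses cancel in the margins
while their *joint* co-occurrence pattern (two lineages independently driven
toward high GC at the same columns) persists.  Stationarity trimming
therefore reduces, but does not provably eliminate, compositional
attraction; this is a property of the matched-pairs approach itself, not of
the implementation.

## Synthetic benchmarks

All generators are pure functions of their parameters and a seed.

* **Informative/noise mixture** (entropy-trimming benchmark): ten clusters
  of 30–70 amino-acid columns, half simulated down one shared random
  bifurcating 40-taxon tree (branch lengths U(0.02, 0.15)), half on star
  trees with branches U(1.0, 2.0) — no shared history, near-saturated
  columns — additionally gapped at a per-cluster rate U(0.3, 0.6).  The
  substitution model is Poisson (equal exchangeabilities): every
  substitution is "radical" under BLOSUM weighting, so informative clusters
  are kept conserved by short branches rather than by conservative exchanges.
  The gap rate emulates what a progressive aligner does to unrelated
  segments (saturated *and* gap-riddled); with gapless noise the region
  merge would re-absorb large noise blocks between long conserved flanks,
  which is precisely the situation the gap filter exists for.  What passing
  shows: the score threshold separates conserved tree signal from saturated
  noise at realistic gap structure.  What it does not show: performance on
  real aligner output with misalignment artefacts, indels, or
  rate-heterogeneous sites.
* **GC-heterogeneous quartet** (stationarity benchmark): four F81 DNA
  sequences on ((u,v),(x,y)), 10,000 columns, uniform root composition.  A
  fraction f of columns evolves with stationary frequencies of 80% GC on the
  two long non-sister external branches (u, x) and 20% GC on the short ones
  (v, y); the rest is compositionally homogeneous.  Branch lengths (internal
  0.05, long externals 0.8, short externals 0.1) were calibrated once so the
  convergent composition genuinely misleads the distance estimator on raw
  alignments — with much shorter externals the artefact does not materialize
  at all.  The companion estimator computes F81 distances (alignment-wide
  base frequencies; saturated pairs capped at distance 10 with a warning)
  and picks the quartet pairing minimizing the sum of intra-pair distances,
  ties broken lexicographically.
* The quartet benchmark measures the contrast between raw and trimmed
  alignments at f = 0.4: every trimmed replicate passes all pairwise
  symmetry tests by construction, the raw alignments are almost always
  resolved wrongly, and trimming multiplies the recovery rate several-fold —
  but it does not restore near-perfect recovery under this fixture.  The
  residual joint bias described above survives marginal-symmetry filtering,
  and in regimes strong enough to fool the raw estimate it also degrades the
  trimmed one; we verified that a quartet maximum-likelihood estimate under
  the homogeneous model is misled by the same retained columns, so this is
  not an artefact of using distances.  Exact recovery percentages therefore
  depend strongly on the tree geometry and on the inference method, and the
  numbers the tests print should be read as the rescue's direction and
  magnitude under this fixture, not as a universal rate.

## Recoding

RY coding maps A,G→R and C,T→Y; ambiguity codes map to R/Y when their
nucleotide set lies wholly within one class, otherwise to N; gaps and `?`
become `-`.  Codon translation uses the universal genetic code; a triplet
containing a gap yields `-`, a degenerate triplet resolving to one amino
acid yields it (ATH→I), to {N,D}→B, {Q,E}→Z, anything broader→X, and stop
codons become `?` with a logged warning (pseudogene-like input degrades
gracefully instead of failing).  Degenerated-codon recoding replaces each
amino acid by the 3-letter IUPAC pattern covering its synonymous codons
(table kept verbatim even where a pattern over-covers, e.g. serine WSX,
leucine YTX: the historical coding is the contract, not biochemical
tightness); the historical `X` wildcard is emitted as IUPAC `N` unless
`keep_x` is set.

## Interfaces and formats

FASTA and NEXUS writing go through Biopython; PHYLIP sequential is read in a
relaxed dialect (whitespace-delimited names of any length) and written in
the strict 10-character dialect with a truncation warning.  `?` is recorded
as missing and treated as a gap throughout.  The HTML report lists h̃ and
gap proportion per column with bar rendering and kept/removed highlighting.
The `phytrim` command is a thin layer over the library: `trim`, `convert`,
`generate`, `report`; when both trimmings are requested the entropy stage
runs first and the stationarity stage sees only its survivors.

## Problem sizes

The test suite exercises the quartet benchmark at 10,000 columns with tens
of seeded replicates and the mixture benchmark at 40 taxa × ~500 columns
with ~10 replicates; both finish in minutes on one core thanks to the
batched Stuart evaluation.  Larger alignments scale linearly in columns and
quadratically in sequences for the stationarity phase.

## Known limitations

* Stationarity trimming enforces pairwise marginal symmetry only (see
  above); an overall multi-sequence symmetry test is not implemented.
* Bowker's complete-symmetry test is deliberately not offered as the
  driving statistic.
* The BLOSUM family is limited to the five levels with published
  full-precision target frequencies; amino-acid PAM/JTT/WAG series and
  estimation of matrices from data are out of scope.
* Only frame-0 codon reading and the universal genetic code are supported;
  interleaved PHYLIP is not read.
* Row (sequence) trimming is not performed.
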