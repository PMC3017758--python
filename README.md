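# phytrim

Block selection and recoding for multiple sequence alignments ahead of
phylogenetic tree inference.

Alignments of real gene families mix columns that carry tree signal with
columns that are saturated, ambiguously aligned, or compositionally biased;
feeding the latter to a tree program degrades or actively misleads the
inference.  `phytrim` addresses both failure modes for DNA, protein and
codon alignments:

* **Entropy-based trimming** scores each column c with a von-Neumann-style
  entropy h(c) = −Σ λ_s log_r λ_s, where λ_s are the eigenvalues of
  μ·Π(c)·S — Π(c) the diagonal matrix of residue frequencies in the column,
  S a similarity matrix (BLOSUM target frequencies for proteins, PAM-η for
  DNA), μ = 1/trace(Π(c)S).  Expected substitutions (I↔L↔M↔V under
  BLOSUM) collapse into a dominant eigenvalue and score low; unexpected
  co-occurrence scores high.  Smoothed scores below 0.5 define conserved
  regions; short variable runs are merged back; gappy columns and short
  blocks are dropped.
* **Stationarity-based trimming** removes columns responsible for
  compositional heterogeneity.  For every sequence pair the divergence
  matrix F is tested for marginal symmetry with Stuart's matched-pairs χ²
  test (statistic dᵀV⁺d on the first r−1 marginal differences); columns are
  removed — first by decreasing h, then re-optimized by a per-column score
  σ(c) = Σ log(p_ij^{(c)}/p_ij) — until every pairwise p-value exceeds 0.1.
* **Recoding**: nucleotide→RY, codon→amino acid (universal code), and amino
  acid→degenerated codon (I → ATH, A → GCN, …), for bias-reduced or
  nucleotide-level downstream analysis.

Intended users: anyone assembling single-gene or supermatrix datasets for
tree inference who would otherwise hand-curate alignment blocks.

## Worked example

```python
from phytrim import (Alignment, blosum_target, column_profile, entropy_score,
                     identity_matrix)

col = Alignment([("a", "I"), ("b", "L"), ("c", "M"), ("d", "V")], "AA")
prof = column_profile(col, 0)
print(entropy_score(prof, identity_matrix(20)))   # 0.4628  (plain Shannon)
print(entropy_score(prof, blosum_target(50)))     # 0.2998  (expected exchanges)

col2 = Alignment([("a", "C"), ("b", "Q"), ("c", "W"), ("d", "Y")], "AA")
print(entropy_score(column_profile(col2, 0), blosum_target(50)))  # 0.4534
```

Both columns have four equally frequent residues, so plain Shannon entropy
cannot tell them apart (0.4628 each).  The BLOSUM50 target frequencies
declare I/L/M/V an ordinary set of exchanges (0.2998, comfortably below the
0.5 conservation threshold) but C/Q/W/Y an unexpected one (0.4534) — that
separation is the whole point of weighting the score by a similarity matrix.

End-to-end, on a simulated quartet whose GC-biased columns attract the two
non-sister long branches (`python examples/stationarity_quartet.py`):

```
simulated quartet: 4 x 10000, true topology (('u', 'v'), ('x', 'y'))
untrimmed estimate: (('u', 'x'), ('v', 'y'))
kept 3657 columns (min pairwise Stuart p = 0.100027)
trimmed estimate:   (('u', 'v'), ('x', 'y'))
```

The raw alignment groups the two GC-rich taxa; after stationarity trimming
every sequence pair passes the symmetry test and, in this run, the true
topology is recovered.  Trimming certifies pairwise marginal symmetry, not
topology: columns whose compositional excesses cancel in the margins can
survive and keep some attraction (across seeds trimming improves recovery
several-fold without making it perfect; see `docs/methods.md`).  The other
scripts under `examples/` demonstrate entropy trimming on an
informative/noise mixture, the recoding conversions, and the BLOSUM level
suggestion.

## Command line

```bash
phytrim trim -i aln.fasta -t AA -m BLOSUM62 -o trimmed.fasta --html report.html
phytrim trim -i aln.fasta -t DNA -s -o trimmed.fasta      # entropy + stationarity
phytrim convert -i aln.fasta -t DNA --to ry -o ry.fasta
phytrim generate --kind quartet -f 0.4 --seed 1 -o q.fasta --truth q.nwk
phytrim report -i aln.fasta -t AA -o report.html
```

Flag conventions: `-t` sequence type, `-m` similarity matrix (`BLOSUM62`,
`PAM100`, `ID4`/`ID20`), `-k` transition/transversion ratio for PAM
construction, `-e` entropy threshold (0.5), `-w` smoothing half-window (1),
`-g` merge gap cutoff (0.30), `--max-col-gap` per-column gap limit (0.2),
`-b` minimum block length (5), `-s` adds stationarity trimming (`-p`
p-value threshold, 0.1).  Formats: FASTA and sequential PHYLIP in; FASTA,
PHYLIP, NEXUS and an HTML score report out.

## Layout

```
src/phytrim/     library (alignment, io, alphabets, matrices, entropy,
                 stationary, synth, cli) + embedded BLOSUM target tables
examples/        one short narrative script per capability
tests/           pytest suite
docs/methods.md  models, parameter rationale, numerics, limitations
```
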