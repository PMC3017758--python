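"""Entropy-like column scoring and conserved-region selection.

For each alignment column c the score

    h(c) = -trace[ mu * Pi(c) * S * log_r( mu * Pi(c) * S ) ]

is computed, where Pi(c) is the diagonal matrix of relative canonical-residue
frequencies, S a similarity matrix, and mu = 1/trace(Pi(c) S) normalizes the
eigenvalues of mu*Pi(c)*S to sum to one.  h(c)=0 for a constant column; h(c)
approaches 1 for columns whose variability is unexpected under S.  Columns are
then smoothed with a gap-weighted sliding window, thresholded into conserved
(C) and variable (V) runs, and V runs flanked by conserved regions are merged
back when the combined region stays below the score threshold and a gap
cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .alignment import Alignment, SeqType
from .io import TrimReport
from .matrices import SimilarityMatrix, default_matrix

__all__ = [
    "ColumnProfile",
    "RegionPartition",
    "column_profile",
    "column_profiles",
    "entropy_score",
    "entropy_scores",
    "smooth_scores",
    "partition_regions",
    "merge_regions",
    "entropy_trim",
]

logger = logging.getLogger(__name__)

_EIG_CLAMP = -1e-12


@dataclass
class ColumnProfile:
    """Canonical-residue counts of one column.

    ``g`` is the proportion of non-canonical cells (gaps, missing data and
    ambiguity codes all count as gaps); ``pi`` the relative frequencies over
    canonical residues (summing to 1 when any canonical residue is present).
    """

    counts: np.ndarray
    g: float
    states: str

    @property
    def pi(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total


def count_matrix(aln: Alignment, states: str | None = None) -> np.ndarray:
    """Canonical-state counts per column, shape (r, m)."""
    states = states or aln.seq_type.canonical
    arr = aln.to_array()
    return np.stack([(arr == s).sum(axis=0) for s in states]).astype(float)


def column_profile(aln: Alignment, c: int) -> ColumnProfile:
    """Profile of 0-based column ``c``."""
    states = aln.seq_type.canonical
    col = aln.column(c)
    counts = np.array([col.count(s) for s in states], dtype=float)
    g = 1.0 - counts.sum() / aln.n
    return ColumnProfile(counts=counts, g=g, states=states)


def column_profiles(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """All column profiles at once: (pi matrix of shape (r, m), g vector)."""
    counts = count_matrix(aln)
    totals = counts.sum(axis=0)
    g = 1.0 - totals / aln.n
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(totals > 0, counts / totals, 0.0)
    return pi, g


def _entropy_from_pi(pi: np.ndarray, S: np.ndarray, r: int) -> float:
    """Eigenvalue entropy of mu*diag(pi)*S, base r.

    Only the support of pi matters: the nonzero spectrum of diag(pi)S equals
    that of its principal submatrix on the support, and is real because
    diag(pi)S is similar to the symmetric sqrt(Pi) S sqrt(Pi)."""
    support = np.flatnonzero(pi > 0)
    if support.size == 0:
        return 0.0
    p = pi[support]
    sub = S[np.ix_(support, support)]
    root = np.sqrt(p)
    sym = sub * np.outer(root, root)
    lam = eigh(sym, eigvals_only=True)
    total = lam.sum()
    if total <= 0:
        raise FloatingPointError(
            "trace(Pi S) is not positive; similarity matrix has a zero "
            "diagonal on the column's residues"
        )
    lam = lam / total
    if (lam < _EIG_CLAMP).any():
        logger.debug("clamping negative eigenvalue %s", lam.min())
    lam = np.clip(lam, 0.0, None)
    nz = lam[lam > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(r)) + 0.0


def entropy_score(profile: ColumnProfile, S: SimilarityMatrix) -> float:
    """Entropy-like score of one column profile under similarity matrix S.

    Returns 0 for a constant or empty (all-gap) column; the score is invariant
    under positive scaling of S."""
    if len(profile.states) != S.r:
        raise ValueError(
            f"profile over {len(profile.states)} states does not match "
            f"{S.r}x{S.r} similarity matrix"
        )
    return _entropy_from_pi(profile.pi, S.S, S.r)


def entropy_scores(aln: Alignment, S: SimilarityMatrix | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (h, g) vectors for a whole alignment.

    CODON alignments must be translated by the caller first; this function
    scores the alignment in its native alphabet."""
    if S is None:
        S = default_matrix(aln.seq_type)
    pi, g = column_profiles(aln)
    # batched over columns: absent states only add zero eigenvalues, so the
    # full r x r symmetrized spectrum matches the per-column support submatrix
    root = np.sqrt(pi.T)                              # (m, r)
    sym = S.S[None] * root[:, :, None] * root[:, None, :]
    lam = np.linalg.eigvalsh(sym)
    totals = lam.sum(axis=1, keepdims=True)
    empty = totals[:, 0] <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(totals > 0, lam / totals, 0.0)
    lam = np.clip(lam, 0.0, None)
    with np.errstate(divide="ignore"):
        logs = np.where(lam > 0, np.log(lam), 0.0)
    h = -(lam * logs).sum(axis=1) / np.log(S.r) + 0.0
    h[empty] = 0.0
    return h, g


def smooth_scores(h: np.ndarray, g: np.ndarray, w: int = 1) -> np.ndarray:
    """Gap-weighted sliding-window average of h.

    Window spans max(1, c-w)..min(m, c+w) (1-based), weights 1-g(i); columns
    with no weight anywhere in their window keep their raw score."""
    h = np.asarray(h, dtype=float)
    g = np.asarray(g, dtype=float)
    if h.shape != g.shape:
        raise ValueError("h and g must have the same length")
    if w < 0:
        raise ValueError("window half-width must be non-negative")
    m = h.size
    weights = 1.0 - g
    out = np.empty(m)
    for c in range(m):
        lo, hi = max(0, c - w), min(m, c + w + 1)
        wsum = weights[lo:hi].sum()
        if wsum > 0:
            out[c] = float((weights[lo:hi] * h[lo:hi]).sum() / wsum)
        else:
            out[c] = h[c]
    return out


@dataclass
class RegionPartition:
    """Alternating conserved (C) / variable (V) runs tiling columns 1..m.

    ``runs`` holds 1-based inclusive ``(start, end, kind)`` tuples in order.
    """

    m: int
    runs: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = 1
        for start, end, kind in self.runs:
            if start != expected or end < start or kind not in ("C", "V"):
                raise ValueError(f"runs do not tile 1..{self.m}: {self.runs}")
            expected = end + 1
        if expected != self.m + 1:
            raise ValueError(f"runs do not tile 1..{self.m}: {self.runs}")

    def conserved_mask(self) -> np.ndarray:
        mask = np.zeros(self.m, dtype=bool)
        for start, end, kind in self.runs:
            if kind == "C":
                mask[start - 1:end] = True
        return mask

    @property
    def n_regions(self) -> int:
        return len(self.runs)


def partition_regions(h_smooth: np.ndarray, threshold: float = 0.5
                      ) -> RegionPartition:
    """Maximal runs of conserved (h-smooth strictly below threshold) and
    variable columns.  A column scoring exactly the threshold is variable."""
    h_smooth = np.asarray(h_smooth, dtype=float)
    conserved = h_smooth < threshold
    runs: list[tuple[int, int, str]] = []
    start = 0
    for c in range(1, h_smooth.size + 1):
        if c == h_smooth.size or conserved[c] != conserved[start]:
            runs.append((start + 1, c, "C" if conserved[start] else "V"))
            start = c
    return RegionPartition(m=h_smooth.size, runs=runs)


def _combined_stats(h, g, start, end):
    """Gap-weighted mean score and gap proportion over 1-based cols start..end."""
    sl = slice(start - 1, end)
    weights = 1.0 - g[sl]
    wsum = weights.sum()
    mean_h = float((weights * h[sl]).sum() / wsum) if wsum > 0 else np.inf
    gap_prop = float(g[sl].mean())
    return mean_h, gap_prop


def merge_regions(
    partition: RegionPartition,
    h: np.ndarray,
    g: np.ndarray,
    threshold: float = 0.5,
    gap_cutoff: float = 0.30,
) -> RegionPartition:
    """Iteratively merge variable runs back into their flanking conserved runs.

    A V run flanked by C runs on both sides is merged when the gap-weighted
    mean score over the combined C-V-C span stays below ``threshold`` and the
    span contains less than ``gap_cutoff`` gaps.  Left-to-right passes repeat
    until a fixpoint; every merge reduces the region count, so termination is
    guaranteed."""
    h = np.asarray(h, dtype=float)
    g = np.asarray(g, dtype=float)
    runs = list(partition.runs)
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(runs):
            if (
                runs[i][2] == "V"
                and 0 < i < len(runs) - 1
                and runs[i - 1][2] == "C"
                and runs[i + 1][2] == "C"
            ):
                start, end = runs[i - 1][0], runs[i + 1][1]
                mean_h, gap_prop = _combined_stats(h, g, start, end)
                if mean_h < threshold and gap_prop < gap_cutoff:
                    runs[i - 1:i + 2] = [(start, end, "C")]
                    changed = True
                    i -= 1
                    continue
            i += 1
    return RegionPartition(m=partition.m, runs=runs)


def _min_block_filter(mask: np.ndarray, min_block: int) -> np.ndarray:
    """Drop kept runs shorter than min_block columns."""
    if min_block <= 1:
        return mask
    out = mask.copy()
    m = mask.size
    c = 0
    while c < m:
        if out[c]:
            start = c
            while c < m and out[c]:
                c += 1
            if c - start < min_block:
                out[start:c] = False
        else:
            c += 1
    return out


def entropy_trim(
    aln: Alignment,
    S: SimilarityMatrix | None = None,
    threshold: float = 0.5,
    w: int = 1,
    gap_cutoff: float = 0.30,
    min_block: int = 5,
    max_col_gap: float = 0.2,
) -> tuple[np.ndarray, TrimReport]:
    """Select the phylogenetically informative columns of an alignment.

    Codon alignments are translated and scored as amino acids (so that amino
    acid similarity matrices apply); a kept amino-acid column keeps all three
    of its nucleotide positions.  After region merging, two post-filters are
    applied: columns whose gap proportion exceeds ``max_col_gap`` are removed
    (0.2 by default — heavily gapped columns are kept out of the selection
    even when region merging absorbed them; set to 1.0 to disable), then kept
    runs shorter than ``min_block`` columns are dropped.

    Returns a boolean keep-mask over the input columns and a
    :class:`~phytrim.io.TrimReport`.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    scored = aln
    if aln.seq_type is SeqType.CODON:
        from .alphabets import translate_codons

        scored = translate_codons(aln)
    if S is None:
        S = default_matrix(scored.seq_type)
    h, g = entropy_scores(scored, S)
    h_smooth = smooth_scores(h, g, w)
    partition = partition_regions(h_smooth, threshold)
    partition = merge_regions(partition, h, g, threshold, gap_cutoff)
    mask = partition.conserved_mask()
    mask &= (g <= max_col_gap) & (g < 1.0)
    mask = _min_block_filter(mask, min_block)

    expand = 3 if aln.seq_type is SeqType.CODON else 1
    full_mask = np.repeat(mask, expand)
    report = TrimReport.from_mask(
        full_mask,
        h_smooth=np.repeat(h_smooth, expand),
        g=np.repeat(g, expand),
        regions=[
            ((s - 1) * expand + 1, e * expand, k) for s, e, k in partition.runs
        ],
        params={
            "matrix": S.kind,
            "threshold": threshold,
            "w": w,
            "gap_cutoff": gap_cutoff,
            "min_block": min_block,
            "max_col_gap": max_col_gap,
        },
    )
    logger.info(
        "entropy trimming kept %d of %d columns", int(full_mask.sum()), aln.m
    )
    if logger.isEnabledFor(logging.DEBUG):
        for c in np.flatnonzero(~mask):
            logger.debug(
                "removed column %d (h-smooth %.4g, gap %.4g)",
                c + 1, h_smooth[c], g[c],
            )
    return full_mask, report
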