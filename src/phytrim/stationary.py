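"""Stationarity-based column trimming.

Tree inference assumes the substitution process is stationary: character-state
frequencies stay constant across lineages.  For every pair of sequences a
divergence matrix F counts the aligned state pairs; under stationarity its row
and column marginals agree (marginal symmetry), which Stuart's chi-squared
matched-pairs test assesses.  Trimming proceeds in two phases:

1. **crude removal** — while any pairwise p-value is at or below the
   threshold, drop the column with the highest entropy-like score;
2. **add-and-remove refinement** — for every removed column c, the score
   sigma(c) = sum over pairs of log(p_ij with c added / p_ij) measures whether
   re-adding c helps; columns are re-removed from the full alignment in
   increasing sigma order until all pairs pass, enlarging the kept set.  The
   refinement repeats until the kept set stops growing.

The chi-squared approximation behind Stuart's test is unreliable on short
alignments; a warning is logged when a pair contributes fewer than 1000
counted columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special

from .alignment import Alignment, SeqType
from .io import TrimReport
from .matrices import BLOSUM_LEVELS, SimilarityMatrix

__all__ = [
    "PairCounts",
    "StuartResult",
    "SigmaScore",
    "EmptySelectionError",
    "pair_divergence_counts",
    "stuart_test",
    "chi2_sf",
    "crude_removal",
    "sigma_scores",
    "stationary_trim",
    "suggest_blosum_eta",
]

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-10
_SMALL_SAMPLE = 1000


class EmptySelectionError(RuntimeError):
    """No column subset satisfies the pairwise homogeneity requirement."""


@dataclass
class PairCounts:
    """r x r divergence counts for one ordered sequence pair.

    ``F[s, t]`` counts columns where sequence i shows canonical state s and
    sequence j shows state t; columns with a gap, missing or ambiguous residue
    in either sequence are not counted."""

    F: np.ndarray
    n_pair: int


@dataclass
class StuartResult:
    """Outcome of the matched-pairs test of marginal symmetry."""

    statistic: float
    df: int
    p: float
    log_p: float


@dataclass
class SigmaScore:
    """Effect of adding one column to the homogeneous set on all p-values."""

    column: int
    sigma: float


def chi2_sf(x: float, df: float) -> float:
    """Upper tail of the chi-squared distribution, Q(df/2, x/2)."""
    if np.any(np.asarray(x) < 0):
        raise ValueError("chi-squared statistic must be non-negative")
    if np.any(np.asarray(df) <= 0):
        raise ValueError("degrees of freedom must be positive")
    return float(special.gammaincc(df / 2.0, x / 2.0))


def _state_codes(aln: Alignment) -> np.ndarray:
    """(n, m) int array of canonical state indices, -1 for anything else."""
    states = aln.seq_type.canonical
    arr = aln.to_array()
    codes = np.full(arr.shape, -1, dtype=np.int16)
    for k, s in enumerate(states):
        codes[arr == s] = k
    return codes


def _pair_F(ci: np.ndarray, cj: np.ndarray, r: int) -> np.ndarray:
    both = (ci >= 0) & (cj >= 0)
    return np.bincount(
        ci[both] * r + cj[both], minlength=r * r
    ).reshape(r, r).astype(float)


def pair_divergence_counts(
    aln: Alignment, i: int, j: int, mask: np.ndarray | None = None
) -> PairCounts:
    """Divergence counts for sequences ``i`` and ``j`` (0-based) over the
    columns selected by ``mask`` (all columns when omitted)."""
    if i == j:
        raise ValueError("divergence counts need two distinct sequences")
    codes = _state_codes(aln)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        codes = codes[:, mask]
    F = _pair_F(codes[i], codes[j], aln.r)
    n_pair = int(F.sum())
    if n_pair == 0:
        raise EmptySelectionError(
            f"sequences {i} and {j} share no column with canonical residues"
        )
    return PairCounts(F=F, n_pair=n_pair)


def _stuart_batch(Fs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stuart statistic, df and log p for a (k, r, r) stack of count matrices.

    d holds the first r-1 marginal differences; V is the matched-pairs
    covariance (V_ss = row_s + col_s - 2 F_ss, V_st = -(F_st + F_ts)).  The
    statistic is d' V^+ d with a spectral pseudo-inverse (relative eigenvalue
    cutoff 1e-10); df is the number of retained eigenvalues."""
    Fs = np.asarray(Fs, dtype=float)
    rows = Fs.sum(axis=2)
    cols = Fs.sum(axis=1)
    d = (rows - cols)[:, :-1]
    M = Fs + np.swapaxes(Fs, 1, 2)
    V = -M[:, :-1, :-1]
    diag = rows[:, :-1] + cols[:, :-1] - 2 * np.diagonal(Fs, axis1=1, axis2=2)[:, :-1]
    idx = np.arange(V.shape[1])
    V[:, idx, idx] = diag
    stat = np.empty(V.shape[0])
    df = np.empty(V.shape[0], dtype=int)
    general = np.ones(V.shape[0], dtype=bool)
    if V.shape[1] == 3:
        # fast closed-form path for the (by far most common) full-rank
        # nucleotide case; singular items fall through to the spectral path
        det = (
            V[:, 0, 0] * (V[:, 1, 1] * V[:, 2, 2] - V[:, 1, 2] ** 2)
            - V[:, 0, 1] * (V[:, 0, 1] * V[:, 2, 2] - V[:, 1, 2] * V[:, 0, 2])
            + V[:, 0, 2] * (V[:, 0, 1] * V[:, 1, 2] - V[:, 1, 1] * V[:, 0, 2])
        )
        scale = np.einsum("kii->k", V)
        ok = det > (np.maximum(scale, 1.0) ** 3) * 1e-9
        if ok.any():
            Vk, dk = V[ok], d[ok]
            c00 = Vk[:, 1, 1] * Vk[:, 2, 2] - Vk[:, 1, 2] ** 2
            c01 = Vk[:, 1, 2] * Vk[:, 0, 2] - Vk[:, 0, 1] * Vk[:, 2, 2]
            c02 = Vk[:, 0, 1] * Vk[:, 1, 2] - Vk[:, 1, 1] * Vk[:, 0, 2]
            c11 = Vk[:, 0, 0] * Vk[:, 2, 2] - Vk[:, 0, 2] ** 2
            c12 = Vk[:, 0, 1] * Vk[:, 0, 2] - Vk[:, 0, 0] * Vk[:, 1, 2]
            c22 = Vk[:, 0, 0] * Vk[:, 1, 1] - Vk[:, 0, 1] ** 2
            quad = (
                dk[:, 0] ** 2 * c00 + dk[:, 1] ** 2 * c11 + dk[:, 2] ** 2 * c22
                + 2 * dk[:, 0] * dk[:, 1] * c01
                + 2 * dk[:, 0] * dk[:, 2] * c02
                + 2 * dk[:, 1] * dk[:, 2] * c12
            )
            stat[ok] = quad / det[ok]
            df[ok] = 3
            general = ~ok
    if general.any():
        lam, U = np.linalg.eigh(V[general])
        lmax = lam[:, -1:]
        keep = lam > np.maximum(lmax, 1.0) * _RANK_TOL
        proj = np.einsum("kij,ki->kj", U, d[general])
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(keep, proj**2 / np.where(keep, lam, 1.0), 0.0)
        stat[general] = terms.sum(axis=1)
        df[general] = keep.sum(axis=1)
    log_p = np.zeros_like(stat)
    pos = df > 0
    with np.errstate(divide="ignore"):
        # chdtrc is the plain ufunc behind the chi-squared survival function;
        # calling it directly keeps the per-removal re-estimation loops cheap.
        log_p[pos] = np.log(special.chdtrc(df[pos], stat[pos]))
    stat[~pos] = 0.0
    return stat, df, log_p


def stuart_test(counts: PairCounts | np.ndarray) -> StuartResult:
    """Stuart's chi-squared matched-pairs test of marginal symmetry on F.

    A symmetric F (equal marginals) gives statistic 0 and p = 1.  When the
    covariance is singular a generalized inverse is used and the degrees of
    freedom equal its rank; a fully degenerate case (rank 0) yields
    statistic 0, df 0, p 1."""
    F = counts.F if isinstance(counts, PairCounts) else np.asarray(counts, float)
    if F.sum() < _SMALL_SAMPLE:
        logger.debug(
            "Stuart's test on %d counted columns; the chi-squared "
            "approximation is unreliable below ~1000", int(F.sum())
        )
    stat, df, log_p = _stuart_batch(F[None])
    return StuartResult(
        statistic=float(stat[0]),
        df=int(df[0]),
        p=float(np.exp(log_p[0])),
        log_p=float(log_p[0]),
    )


# ---------------------------------------------------------------------------
# Trimming machinery
# ---------------------------------------------------------------------------

def _pairs(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


class _PairState:
    """Per-pair divergence counts under a common column mask, with cheap
    column addition/removal.

    ``contrib[c, k]`` caches, for column c and pair k, the flattened F cell
    the column contributes to (-1 when either sequence is non-canonical)."""

    def __init__(self, codes: np.ndarray, r: int, mask: np.ndarray):
        self.codes = codes
        self.r = r
        self.pairs = _pairs(codes.shape[0])
        self.mask = mask.copy()
        m = codes.shape[1]
        self.contrib = np.full((m, len(self.pairs)), -1, dtype=np.int32)
        for k, (i, j) in enumerate(self.pairs):
            both = (codes[i] >= 0) & (codes[j] >= 0)
            self.contrib[both, k] = codes[i, both] * r + codes[j, both]
        self.F = np.stack(
            [_pair_F(codes[i, mask], codes[j, mask], r) for i, j in self.pairs]
        )

    def remove_column(self, c: int) -> None:
        assert self.mask[c]
        self.mask[c] = False
        self._update(c, -1.0)

    def add_column(self, c: int) -> None:
        assert not self.mask[c]
        self.mask[c] = True
        self._update(c, +1.0)

    def _update(self, c: int, delta: float) -> None:
        idx = self.contrib[c]
        valid = idx >= 0
        flat = self.F.reshape(len(self.pairs), self.r * self.r)
        flat[np.flatnonzero(valid), idx[valid]] += delta

    def log_ps(self) -> np.ndarray:
        _, _, log_p = _stuart_batch(self.F)
        return log_p

    def min_p(self) -> tuple[float, tuple[int, int]]:
        log_p = self.log_ps()
        k = int(np.argmin(log_p))
        return float(np.exp(log_p[k])), self.pairs[k]


def _remove_until_pass(
    state: _PairState,
    order: list[int],
    p_threshold: float,
    chunk: int = 128,
) -> int | None:
    """Remove columns in ``order`` until every pairwise p exceeds the
    threshold, re-estimating all p-values after each single removal.

    Returns the number of columns removed, or None if even removing all of
    ``order`` does not reach the threshold.  The p-value checks for a chunk
    of consecutive removal steps are evaluated in one batched call, which is
    arithmetically identical to checking after every removal."""
    log_thresh = np.log(p_threshold)
    minp, _ = state.min_p()
    if minp > p_threshold:
        return 0
    n_pairs = len(state.pairs)
    r2 = state.r * state.r
    # keep the (chunk, n_pairs, r, r) snapshot stack around ~50 MB
    chunk = max(1, min(chunk, 50_000_000 // (n_pairs * r2 * 8)))
    order = np.asarray(order, dtype=int)
    pos = 0
    while pos < len(order):
        steps = min(chunk, len(order) - pos)
        cols = order[pos:pos + steps]
        sub = state.contrib[cols]                      # (steps, n_pairs)
        valid = sub >= 0
        deltas = np.zeros((steps, n_pairs, r2))
        s_idx, p_idx = np.nonzero(valid)
        deltas[s_idx, p_idx, sub[valid]] = 1.0
        snaps = state.F.reshape(1, n_pairs, r2) - np.cumsum(deltas, axis=0)
        _, _, log_p = _stuart_batch(
            snaps.reshape(steps * n_pairs, state.r, state.r)
        )
        per_step = log_p.reshape(steps, n_pairs).min(axis=1)
        passing = np.flatnonzero(per_step > log_thresh)
        t = int(passing[0]) if passing.size else steps - 1
        state.F = snaps[t].reshape(n_pairs, state.r, state.r).copy()
        state.mask[cols[:t + 1]] = False
        if logger.isEnabledFor(logging.DEBUG):
            for k in range(t + 1):
                logger.debug(
                    "removed column %d (min pairwise p %.4g)",
                    cols[k] + 1, float(np.exp(log_p.reshape(steps, n_pairs)
                                              .min(axis=1)[k])),
                )
        if passing.size:
            return pos + t + 1
        pos += steps
    return None


def crude_removal(
    aln: Alignment,
    h: np.ndarray,
    p_threshold: float = 0.1,
    start_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Remove columns in decreasing entropy-like score order until every
    pairwise Stuart p-value exceeds ``p_threshold``.

    Ties in h break by ascending column index.  Raises
    :class:`EmptySelectionError`, naming the worst pair, if the alignment
    cannot be homogenized before running out of columns."""
    h = np.asarray(h, dtype=float)
    codes = _state_codes(aln)
    mask = (
        np.ones(aln.m, dtype=bool) if start_mask is None
        else np.asarray(start_mask, dtype=bool).copy()
    )
    if h.shape != (aln.m,):
        raise ValueError("h must provide one score per column")
    state = _PairState(codes, aln.r, mask)
    order = np.lexsort((np.arange(aln.m), -h))
    order = [c for c in order if mask[c]]
    removed = _remove_until_pass(state, order, p_threshold)
    if removed is None or not state.mask.any():
        minp, worst = state.min_p()
        raise EmptySelectionError(
            "homogenizing the alignment requires removing every column; "
            f"worst pair {worst} (p = {minp:.4g} before emptiness)"
        )
    return state.mask.copy()


def sigma_scores(
    aln: Alignment, C: np.ndarray, codes: np.ndarray | None = None
) -> list[SigmaScore]:
    """sigma(c) = sum over pairs of log(p_ij^(c) / p_ij) for every column c
    outside the kept set ``C``.

    p_ij^(c) is the Stuart p-value after adding column c to C; positive sigma
    means re-adding c raises most p-values.  Computed exactly, by forming
    C + {c} for each candidate (one-column count updates, vectorized across
    candidates).  A candidate driving some p to zero gets sigma = -inf."""
    mask = np.asarray(C, dtype=bool)
    if codes is None:
        codes = _state_codes(aln)
    state = _PairState(codes, aln.r, mask)
    base_log_p = state.log_ps()
    candidates = np.flatnonzero(~mask)
    sigma = np.zeros(candidates.size)
    r = aln.r
    for k, (i, j) in enumerate(state.pairs):
        si = codes[i, candidates]
        sj = codes[j, candidates]
        both = (si >= 0) & (sj >= 0)
        if not both.any():
            continue
        stack = np.repeat(state.F[k][None], both.sum(), axis=0)
        flat = stack.reshape(both.sum(), r * r)
        flat[np.arange(both.sum()), si[both] * r + sj[both]] += 1.0
        _, _, log_p = _stuart_batch(stack)
        sigma[both] += log_p - base_log_p[k]
    return [
        SigmaScore(column=int(c), sigma=float(s))
        for c, s in zip(candidates, sigma)
    ]


def stationary_trim(
    aln: Alignment,
    p_threshold: float = 0.1,
    max_outer_iters: int = 50,
    S: SimilarityMatrix | None = None,
    h: np.ndarray | None = None,
) -> tuple[np.ndarray, TrimReport]:
    """Select a maximal compositionally homogeneous column subset.

    Runs the crude entropy-ranked removal, then the sigma-guided add-and-
    remove refinement until the kept set stops growing (or
    ``max_outer_iters`` outer iterations).  On return every pairwise Stuart
    p-value on the kept columns exceeds ``p_threshold``.
    """
    if aln.seq_type is SeqType.CODON:
        raise ValueError(
            "stationarity trimming operates on DNA or AA alignments; "
            "translate codon alignments first"
        )
    if h is None:
        from .entropy import entropy_scores

        h, _ = entropy_scores(aln, S)
    codes = _state_codes(aln)
    m = aln.m
    full = np.ones(m, dtype=bool)
    state = _PairState(codes, aln.r, full)
    if state.F.sum(axis=(1, 2)).min() < _SMALL_SAMPLE:
        logger.warning(
            "some sequence pair contributes fewer than %d counted columns; "
            "Stuart's chi-squared approximation may be unreliable",
            _SMALL_SAMPLE,
        )
    minp, _ = state.min_p()
    if minp > p_threshold:
        mask = full
    else:
        mask = crude_removal(aln, h, p_threshold)
        for it in range(max_outer_iters):
            scores = sigma_scores(aln, mask, codes)
            if not scores:
                break
            order = sorted(scores, key=lambda s: (s.sigma, s.column))
            trial = _PairState(codes, aln.r, full)
            removed = _remove_until_pass(
                trial, [s.column for s in order], p_threshold
            )
            if removed is None:
                # removing every candidate reproduces the current set
                break
            new_mask = trial.mask.copy()
            assert new_mask[mask].all(), "kept set must never shrink"
            if new_mask.sum() == mask.sum():
                mask = new_mask
                break
            logger.info(
                "refinement iteration %d: kept %d -> %d columns",
                it + 1, int(mask.sum()), int(new_mask.sum()),
            )
            mask = new_mask

    final = _PairState(codes, aln.r, mask)
    minp, worst = final.min_p()
    if minp <= p_threshold:
        raise EmptySelectionError(
            f"final column set violates homogeneity: pair {worst} "
            f"has p = {minp:.4g}"
        )
    report = TrimReport.from_mask(
        mask,
        params={
            "procedure": "stationary",
            "p_threshold": p_threshold,
            "min_pairwise_p": round(minp, 6),
            "worst_pair": worst,
        },
    )
    logger.info(
        "stationarity trimming kept %d of %d columns (min pairwise p %.4g)",
        int(mask.sum()), m, minp,
    )
    return mask, report


def suggest_blosum_eta(aln: Alignment) -> tuple[int, int]:
    """Suggest a BLOSUM clustering level from pairwise percent identity.

    eta = min over sequences i of (max over j != i of % identity between i
    and j), with identity computed over columns where both sequences carry
    canonical residues.  Returns ``(eta, recommended_level)`` where the
    recommendation is the nearest available BLOSUM table, clamped to the
    supported range.  Advisory only: on diverged data this rule is known to
    underestimate the level that trims best."""
    if aln.seq_type is not SeqType.AA:
        raise ValueError("BLOSUM level suggestion requires an AA alignment")
    codes = _state_codes(aln)
    n = aln.n
    row_max = np.full(n, -np.inf)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            both = (codes[i] >= 0) & (codes[j] >= 0)
            total = int(both.sum())
            if total == 0:
                logger.warning(
                    "sequences %d and %d share no comparable columns; "
                    "pair excluded from identity scan", i, j,
                )
                continue
            pct = 100.0 * (codes[i][both] == codes[j][both]).sum() / total
            row_max[i] = max(row_max[i], pct)
    valid = row_max[np.isfinite(row_max)]
    if valid.size == 0:
        raise EmptySelectionError("no sequence pair has comparable columns")
    eta = int(round(valid.min()))
    recommended = min(BLOSUM_LEVELS, key=lambda lv: (abs(lv - eta), lv))
    return eta, recommended
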