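"""Similarity matrices used by the entropy-like column score.

Three families are provided:

* **BLOSUM target frequencies** — the Henikoff joint substitution
  probabilities q_ij (NOT the integer log-odds scores).  The published
  full-precision tables for BLOSUM45, 50, 62, 80 and 90 are embedded as
  package data; BLOSUM62 is the default for amino-acid alignments.
* **DNA PAM** — PAM-1 built from a transition/transversion ratio kappa
  (diagonal 0.99, transition 0.01*kappa/(2+kappa), transversion
  0.01/(2+kappa)), raised to the eta-th matrix power; PAM-100 with kappa=2
  is the default for nucleotide alignments.
* **Identity** — reduces the score to the ordinary Shannon entropy.

The column score is invariant under scaling of the matrix, so no
renormalization is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .alignment import AA_CANONICAL, DNA_CANONICAL

__all__ = [
    "SimilarityMatrix",
    "BLOSUM_LEVELS",
    "blosum_target",
    "pam_dna",
    "identity_matrix",
    "default_matrix",
]

#: BLOSUM clustering levels with published full-precision target frequencies.
BLOSUM_LEVELS = (45, 50, 62, 80, 90)


@dataclass(frozen=True)
class SimilarityMatrix:
    """A symmetric non-negative r x r similarity matrix with its state order."""

    S: np.ndarray
    kind: str
    states: str
    eta: int | None = None
    kappa: float | None = None

    @property
    def r(self) -> int:
        return self.S.shape[0]

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("similarity matrix must be square")
        if S.shape[0] != len(self.states):
            raise ValueError("state order does not match matrix dimension")
        if (S < 0).any():
            raise ValueError("similarity matrix entries must be non-negative")
        object.__setattr__(self, "S", S)


def blosum_target(eta: int = 62) -> SimilarityMatrix:
    """The BLOSUM-eta target-frequency (joint probability) matrix.

    Entries are the Henikoff q_ij; the matrix is symmetric and sums to ~1.
    Raises a ``ValueError`` listing the supported clustering levels for any
    other ``eta``.
    """
    if eta not in BLOSUM_LEVELS:
        raise ValueError(
            f"unsupported BLOSUM level {eta}; available levels with published "
            f"target-frequency tables: {', '.join(map(str, BLOSUM_LEVELS))}"
        )
    text = (
        resources.files("phytrim.data").joinpath(f"blosum{eta}.qij").read_text()
    )
    rows = [
        [float(tok) for tok in line.split()]
        for line in text.splitlines()
        if line and not line.startswith("#")
    ]
    S = np.array(rows)
    return SimilarityMatrix(S, kind=f"blosum{eta}", states=AA_CANONICAL, eta=eta)


def pam_dna(kappa: float = 2.0, eta: int = 100) -> SimilarityMatrix:
    """DNA PAM-eta matrix built from the transition/transversion ratio kappa.

    PAM-1 has diagonal 0.99, transition entries 0.01*kappa/(2+kappa) and
    transversion entries 0.01/(2+kappa) (rows sum to 1); PAM-eta is the
    eta-th matrix power of PAM-1, computed by repeated squaring so rows stay
    stochastic to machine precision.  State order A, C, G, T; transitions are
    A<->G and C<->T.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if not isinstance(eta, (int, np.integer)) or eta < 1:
        raise ValueError(f"eta must be a positive integer, got {eta!r}")
    ts = 0.01 * kappa / (2.0 + kappa)
    tv = 0.01 / (2.0 + kappa)
    # order ACGT: transitions A-G (0,2) and C-T (1,3)
    P1 = np.full((4, 4), tv)
    P1[0, 2] = P1[2, 0] = P1[1, 3] = P1[3, 1] = ts
    np.fill_diagonal(P1, 0.99)
    S = np.linalg.matrix_power(P1, int(eta))
    return SimilarityMatrix(
        S, kind=f"pam{eta}", states=DNA_CANONICAL, eta=int(eta), kappa=kappa
    )


def identity_matrix(r: int) -> SimilarityMatrix:
    """The r x r identity; the column score then equals Shannon entropy."""
    if r == 4:
        states = DNA_CANONICAL
    elif r == 20:
        states = AA_CANONICAL
    else:
        raise ValueError(f"identity matrix supports r in {{4, 20}}, got {r}")
    return SimilarityMatrix(np.eye(r), kind="identity", states=states)


def default_matrix(seq_type) -> SimilarityMatrix:
    """BLOSUM62 for amino acids (and codon alignments scored as amino acids),
    PAM-100 with kappa=2 for DNA."""
    from .alignment import SeqType

    st = SeqType(seq_type)
    if st is SeqType.DNA:
        return pam_dna(2.0, 100)
    return blosum_target(62)


def parse_matrix_spec(spec: str, kappa: float = 2.0) -> SimilarityMatrix:
    """Parse a user-facing matrix name: ``BLOSUM62``, ``PAM100``, or ``ID4``/
    ``ID20`` (also plain ``ID`` meaning identity chosen by alphabet later is
    not supported here; pass the cardinality)."""
    s = spec.strip().upper()
    if s.startswith("BLOSUM"):
        return blosum_target(int(s[6:]))
    if s.startswith("PAM"):
        return pam_dna(kappa, int(s[3:]))
    if s.startswith("ID"):
        return identity_matrix(int(s[2:]))
    raise ValueError(f"unrecognized similarity matrix spec {spec!r}")
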