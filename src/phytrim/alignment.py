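"""Core multiple-sequence-alignment container and alphabet definitions.

An :class:`Alignment` is an ordered set of equally long sequences over a
declared alphabet (DNA, amino acid, or DNA read as in-frame codons).  All
trimming, recoding and testing machinery in this package consumes and emits
this one type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "SeqType",
    "Alignment",
    "AlignmentShapeError",
    "AlphabetError",
    "GAP",
    "MISSING",
    "DNA_CANONICAL",
    "AA_CANONICAL",
    "DNA_AMBIGUITY",
    "AA_AMBIGUITY",
]

GAP = "-"
MISSING = "?"

DNA_CANONICAL = "ACGT"
AA_CANONICAL = "ARNDCQEGHILKMFPSTWYV"

#: IUPAC degenerate nucleotide codes -> set of canonical nucleotides.
DNA_AMBIGUITY: dict[str, frozenset[str]] = {
    "M": frozenset("AC"),
    "R": frozenset("AG"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "X": frozenset("ACGT"),
}

#: Amino-acid ambiguity codes -> set of canonical residues.
AA_AMBIGUITY: dict[str, frozenset[str]] = {
    "B": frozenset("ND"),
    "Z": frozenset("QE"),
    "X": frozenset(AA_CANONICAL),
}


class SeqType(str, Enum):
    """Declared alphabet of an alignment."""

    DNA = "DNA"
    AA = "AA"
    CODON = "CODON"

    @property
    def canonical(self) -> str:
        return AA_CANONICAL if self is SeqType.AA else DNA_CANONICAL

    @property
    def ambiguity(self) -> dict[str, frozenset[str]]:
        return AA_AMBIGUITY if self is SeqType.AA else DNA_AMBIGUITY

    @property
    def r(self) -> int:
        """Alphabet cardinality used in scoring (4 for nucleotides, 20 for AA)."""
        return 20 if self is SeqType.AA else 4


class AlignmentShapeError(ValueError):
    """Sequences have unequal lengths, or the alignment is otherwise malformed."""


class AlphabetError(ValueError):
    """A residue is not legal for the declared alphabet."""


def _validate_residues(identifier: str, seq: str, seq_type: SeqType) -> None:
    legal = set(seq_type.canonical) | set(seq_type.ambiguity) | {GAP, MISSING}
    for pos, ch in enumerate(seq):
        if ch not in legal:
            raise AlphabetError(
                f"illegal residue {ch!r} at position {pos + 1} of sequence "
                f"{identifier!r} for declared alphabet {seq_type.value}"
            )


@dataclass
class Alignment:
    """n aligned sequences of m columns over a declared alphabet.

    Residues are stored uppercased; the gap symbols ``.`` and ``-`` are both
    stored as ``-`` and ``?`` marks missing data (treated as a gap by every
    downstream computation).
    """

    records: list[tuple[str, str]]
    seq_type: SeqType
    _array: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.seq_type = SeqType(self.seq_type)
        if len(self.records) < 2:
            raise AlignmentShapeError("an alignment needs at least two sequences")
        normalized = []
        lengths = set()
        ids = set()
        for ident, seq in self.records:
            if ident in ids:
                raise AlignmentShapeError(f"duplicate sequence identifier {ident!r}")
            ids.add(ident)
            seq = seq.upper().replace(".", GAP)
            _validate_residues(ident, seq, self.seq_type)
            normalized.append((ident, seq))
            lengths.add(len(seq))
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        (m,) = lengths
        if m == 0:
            raise AlignmentShapeError("alignment has zero columns")
        if self.seq_type is SeqType.CODON and m % 3 != 0:
            raise AlignmentShapeError(
                f"codon alignment length {m} is not divisible by 3"
            )
        self.records = normalized

    # -- basic geometry ----------------------------------------------------
    @property
    def n(self) -> int:
        """Number of sequences."""
        return len(self.records)

    @property
    def m(self) -> int:
        """Number of columns."""
        return len(self.records[0][1])

    @property
    def r(self) -> int:
        return self.seq_type.r

    @property
    def identifiers(self) -> list[str]:
        return [ident for ident, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    def to_array(self) -> np.ndarray:
        """Character matrix of shape (n, m), dtype '<U1'.  Cached."""
        if self._array is None or self._array.shape != (self.n, self.m):
            self._array = np.array(
                [list(seq) for seq in self.sequences], dtype="<U1"
            )
        return self._array

    def column(self, c: int) -> str:
        """Residues of 0-based column ``c`` as a string."""
        return "".join(seq[c] for seq in self.sequences)

    def take_columns(self, mask: np.ndarray) -> "Alignment":
        """Sub-alignment keeping the columns where boolean ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.m,):
            raise AlignmentShapeError(
                f"mask length {mask.shape} does not match column count {self.m}"
            )
        if not mask.any():
            raise AlignmentShapeError("cannot build an alignment with zero columns")
        arr = self.to_array()[:, mask]
        records = [
            (ident, "".join(row)) for ident, row in zip(self.identifiers, arr)
        ]
        return Alignment(records, self.seq_type)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.records == other.records and self.seq_type == other.seq_type
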