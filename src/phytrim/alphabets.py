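"""Character-state coding tables and alignment recoding.

Three conversions are provided, all column-local:

* nucleotide -> RY coding (purine/pyrimidine two-state collapse, which
  suppresses GC-content signal),
* in-frame codons -> amino acids (universal genetic code),
* amino acids -> degenerated codons (each residue becomes the 3-letter IUPAC
  pattern covering all of its synonymous codons, so a protein alignment can be
  analysed as nucleotides).
"""

from __future__ import annotations

import logging
from itertools import product

from Bio.Data import CodonTable

from .alignment import (
    DNA_AMBIGUITY,
    GAP,
    MISSING,
    Alignment,
    SeqType,
)

__all__ = [
    "UNIVERSAL_CODE",
    "DEGENERATE_CODON",
    "PURINES",
    "PYRIMIDINES",
    "expand_degenerate_codon",
    "dna_to_ry",
    "translate_codons",
    "aa_to_degenerate_codons",
]

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: Universal genetic code, codon -> one-letter amino acid ('*' for stops).
_table = CodonTable.unambiguous_dna_by_id[1]
UNIVERSAL_CODE: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    UNIVERSAL_CODE[_stop] = "*"

#: Degenerated codon per amino acid: for each codon position the IUPAC letter
#: covering the nucleotides seen across all synonymous codons.  ``X`` is kept
#: as the literal "any nucleotide" wildcard here; emitters may normalize it to
#: the IUPAC-standard ``N``.
DEGENERATE_CODON: dict[str, str] = {
    "A": "GCX",
    "R": "MGX",
    "N": "AAY",
    "D": "GAY",
    "C": "TGY",
    "Q": "CAR",
    "E": "GAR",
    "G": "GGX",
    "H": "CAY",
    "I": "ATH",
    "L": "YTX",
    "K": "AAR",
    "M": "ATG",
    "F": "TTY",
    "P": "CCX",
    "S": "WSX",
    "T": "ACX",
    "W": "TGG",
    "Y": "TAY",
    "V": "GTX",
    # ambiguous residues
    "B": "RAY",
    "Z": "SAR",
    "X": "XXX",
}


def _nt_set(symbol: str) -> frozenset[str]:
    if symbol in "ACGT":
        return frozenset(symbol)
    return DNA_AMBIGUITY[symbol]


def expand_degenerate_codon(codon: str) -> set[str]:
    """All unambiguous codons matched by a 3-letter IUPAC pattern."""
    return {
        "".join(c) for c in product(*(_nt_set(sym) for sym in codon.upper()))
    }


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------

def _ry_symbol(ch: str) -> str:
    if ch in (GAP, MISSING):
        return ch if ch == GAP else GAP
    nts = _nt_set(ch)
    if nts <= PURINES:
        return "R"
    if nts <= PYRIMIDINES:
        return "Y"
    return "N"


def dna_to_ry(aln: Alignment) -> Alignment:
    """Collapse a nucleotide alignment to purine (R) / pyrimidine (Y) states.

    Ambiguity codes whose nucleotide set lies wholly within one class map to
    that class (e.g. S={C,G} spans both, so S -> N; K={G,T} spans both -> N;
    but R, Y map to themselves); gaps and missing data become ``-``.
    """
    if aln.seq_type is SeqType.AA:
        raise ValueError("RY-coding applies to nucleotide alignments only")
    records = [
        (ident, "".join(_ry_symbol(ch) for ch in seq))
        for ident, seq in aln.records
    ]
    return Alignment(records, SeqType.DNA)


def _translate_triplet(triplet: str, where: str = "") -> str:
    if GAP in triplet or MISSING in triplet:
        return GAP
    expansions = expand_degenerate_codon(triplet)
    aas = {UNIVERSAL_CODE[c] for c in expansions}
    if aas == {"*"}:
        logger.warning("stop codon %s%s translated as missing ('?')",
                       triplet, where)
        return MISSING
    aas.discard("*")
    if len(aas) == 1:
        return next(iter(aas))
    if aas == {"N", "D"}:
        return "B"
    if aas == {"Q", "E"}:
        return "Z"
    return "X"


def translate_codons(aln: Alignment) -> Alignment:
    """Translate an in-frame codon alignment into amino acids.

    A triplet containing a gap or missing symbol yields ``-``; a degenerate
    triplet whose expansion encodes a single amino acid resolves to it (e.g.
    ATH -> I), otherwise to an ambiguity code; a stop codon becomes ``?``.
    """
    if aln.seq_type is not SeqType.CODON:
        raise ValueError("translation requires a CODON alignment")
    records = []
    for ident, seq in aln.records:
        out = []
        for k in range(0, len(seq), 3):
            out.append(
                _translate_triplet(
                    seq[k:k + 3], f" (sequence {ident!r}, codon {k // 3 + 1})"
                )
            )
        records.append((ident, "".join(out)))
    return Alignment(records, SeqType.AA)


def aa_to_degenerate_codons(aln: Alignment, keep_x: bool = False) -> Alignment:
    """Back-translate an amino-acid alignment into degenerated codons.

    Each residue is replaced by the 3-letter IUPAC pattern covering all of its
    synonymous codons (I -> ATH, A -> GCN, ...); ``-`` becomes ``---`` and
    ``?`` becomes ``???``.  With ``keep_x`` the historical ``X`` wildcard is
    emitted instead of the IUPAC-standard ``N``.
    """
    if aln.seq_type is not SeqType.AA:
        raise ValueError("degenerate-codon conversion requires an AA alignment")
    records = []
    for ident, seq in aln.records:
        out = []
        for ch in seq:
            if ch == GAP:
                out.append(GAP * 3)
            elif ch == MISSING:
                out.append(MISSING * 3)
            else:
                codon = DEGENERATE_CODON[ch]
                out.append(codon if keep_x else codon.replace("X", "N"))
        records.append((ident, "".join(out)))
    return Alignment(records, SeqType.DNA)
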