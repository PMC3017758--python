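"""Character-state recoding: RY, codon translation, degenerated codons.

RY coding collapses nucleotides to purines/pyrimidines, discarding the
within-class (A<->G, C<->T) signal that carries most GC-content bias.
Degenerated codons turn a protein alignment back into nucleotide patterns
covering every synonymous codon, so nucleotide tools can run on it.
"""

from phytrim import (
    Alignment,
    aa_to_degenerate_codons,
    dna_to_ry,
    translate_codons,
    write_alignment,
)

dna = Alignment([("a", "ATGATCGGC"), ("b", "ATGATTGGA")], "DNA")
print("RY coding:")
print(write_alignment(dna_to_ry(dna), "fasta"))

codons = Alignment(dna.records, "CODON")
protein = translate_codons(codons)
print("translated (universal code):")
print(write_alignment(protein, "fasta"))

print("degenerated codons (I -> ATH, G -> GGN, ...):")
print(write_alignment(aa_to_degenerate_codons(protein), "fasta"))
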