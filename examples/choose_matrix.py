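"""Pick a BLOSUM stringency level from pairwise identity.

The rule eta = min over sequences of the maximum pairwise percent identity
mirrors how the BLOSUM clustering levels were built; it tends to
underestimate the level that trims best on diverged data, so treat the
output as a starting point, not an answer.
"""

from phytrim import make_informative_noise_mix, suggest_blosum_eta

aln, _ = make_informative_noise_mix(n_taxa=12, seed=3)
eta, recommended = suggest_blosum_eta(aln)
print(f"{aln.n} sequences x {aln.m} columns")
print(f"min-max pairwise identity eta = {eta}%")
print(f"nearest available target-frequency table: BLOSUM{recommended}")
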