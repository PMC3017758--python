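"""Stationarity-based trimming rescues a quartet from GC attraction.

Simulates four DNA sequences on ((u,v),(x,y)) where 40% of the columns evolve
with 80% GC on the non-sister branches u and x (and 20% GC on v, y).  The
compositional convergence attracts u and x, so a distance-based topology
estimate on the raw alignment is usually wrong; after removing the
compositionally heterogeneous columns the true topology is recovered here.

Trimming guarantees that every sequence pair passes the marginal-symmetry
test on the kept columns; it does not guarantee topology recovery, because
biased columns whose compositional excesses cancel in the margins can
survive (see docs/methods.md).  Across seeds the trimmed recovery rate is
several-fold higher than the untrimmed one, not perfect.
"""

from phytrim import (
    GC_QUARTET_TOPOLOGY,
    make_gc_quartet,
    quartet_topology,
    stationary_trim,
)

aln, truth = make_gc_quartet(0.4, length=10000, seed=7)
print(f"simulated quartet: {aln.n} x {aln.m}, true topology {truth}")
print("untrimmed estimate:", quartet_topology(aln))

mask, report = stationary_trim(aln)
trimmed = aln.take_columns(mask)
print(f"kept {int(mask.sum())} columns "
      f"(min pairwise Stuart p = {report.params['min_pairwise_p']})")
print("trimmed estimate:  ", quartet_topology(trimmed))
# The min pairwise p above 0.1 certifies that no sequence pair rejects
# marginal symmetry on the kept columns.
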