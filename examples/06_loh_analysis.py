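"""Loss-of-heterozygosity: genotype markers, segment, classify, and test
breakpoint overlap against a feature set by permutation.
"""

import numpy as np
import pandas as pd

from mafoot.genome import GenomeDef, Interval, MarkerTable
from mafoot.loh import breakpoint_intervals, detect_loh, permutation_overlap_test

genome = GenomeDef(chromosomes=(("chr1", 500_000),))

# Markers every 5 kb; an interstitial LOH tract for parent 1 spans
# markers 20..29 (positions 100..145 kb).
pos = np.arange(5_000, 500_000, 5_000)
d1 = np.full(len(pos), 30)
d2 = np.full(len(pos), 30)
d1[20:30], d2[20:30] = 60, 0
markers = MarkerTable(pd.DataFrame({
    "chrom": "chr1", "pos": pos, "allele_p1": "A", "allele_p2": "G",
    "depth_p1": d1, "depth_p2": d2,
}))

[seg] = detect_loh(markers, "SA/NA-HU-1", genome, {"chr1": 2})
print(f"{seg.loh_class} LOH for {seg.parent}: {seg.start}-{seg.end} "
      f"({seg.n_markers} markers)")
print("breakpoint regions:", seg.breakpoint_up, seg.breakpoint_down)

# The tract/marker breakpoint formula on explicit coordinates:
up, down = breakpoint_intervals(start=100_000, end=150_000,
                                first=105_000, last=145_000)
print("formula intervals:", up, down)

# Do the two breakpoints overlap a fragile-site catalog more than chance?
features = [Interval("chr1", s, s + 1_999) for s in range(95_000, 160_000, 10_000)]
queries = [Interval("chr1", *seg.breakpoint_up), Interval("chr1", *seg.breakpoint_down)]
p, z, obs = permutation_overlap_test(queries, features, genome,
                                     ntimes=1000, seed=5)
print(f"observed overlaps {obs}/2, permutation p = {p:.4f}, z = {z:.1f}")
# Both breakpoint regions hit the dense local feature cluster; the
# permutation p-value says how unusual that is under random placement.
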