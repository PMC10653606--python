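"""Coverage-based karyotype, rDNA copy number and mtDNA heteroplasmy.

Simulates depth for a line with a trisomy, contracted rDNA and a
partial mitochondrial deletion, then calls all three back.
"""

import numpy as np

from mafoot.cnv import call_chromosome_cn, mtdna_estimate, rdna_copy_number
from mafoot.genome import Interval
from mafoot.simulate import SimulationConfig, demo_genome, simulate_depth, study_design

genome = demo_genome()
cfg = SimulationConfig(
    genome=genome,
    design=study_design(callable_sites=1_500_000, lines_per_condition={"RM": 1}),
    seed=2, depth_noise_sd=0.05,
)
karyotype = {c: 2 for c in genome.nuclear_chromosomes()}
karyotype["chr1"] = 3  # trisomy

rng = np.random.default_rng(3)
sample = simulate_depth(karyotype, cfg, ploidy=2, rng=rng,
                        rdna_repeats=110.0,            # contracted from 150
                        mtdna_copy=18.0, mtdna_presence=(1, 12_000))
ancestor = simulate_depth({c: 2 for c in karyotype}, cfg, ploidy=2,
                          rng=np.random.default_rng(4), rdna_repeats=150.0)

kar = call_chromosome_cn(sample, genome, ploidy=2)
print("karyotype:", {c: kar.cn(c) for c in genome.nuclear_chromosomes()},
      "events:", kar.events)

rdna = rdna_copy_number(sample, ancestor, genome,
                        chrXII_cn=kar.cn(genome.rdna_locus.chrom), ploidy=2)
print(f"rDNA vs ancestor: per sample {rdna.per_sample:.2f}, "
      f"per chromosome {rdna.per_chrXII:.2f}")

L = genome.length_of(genome.mito_name)
genes = {n: Interval(genome.mito_name, int(f * L), int(f * L) + 999)
         for n, f in (("ATP6", 0.10), ("COX2", 0.40), ("COX3", 0.70))}
mt = mtdna_estimate(sample, genome, genes)
print(f"mtDNA: status {mt.status}, presence {mt.presence_fraction:.2f}, "
      f"retained {[(a, b) for a, b in mt.retained_segments]}")
# The trisomy is called exactly under 5% log-normal noise; rDNA reads
# ~110/150 = 0.73 per sample; the 12 kb retained mtDNA segment makes
# the genome heteroplasmic with ~16% of windows present.
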