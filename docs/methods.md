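# Methods

This note documents the models, defaults and numerical choices behind
`mafoot`, what the synthetic-data generator does and does not emulate,
and the limitations a user should know before trusting results on real
data.

## Experimental model

A mutation-accumulation (MA) line is a lineage restreaked from one
random colony at fixed intervals. Between bottlenecks a colony grows
from a single cell without appreciable death, so the generations per
bottleneck are `G = log2(N)` for colony size `N`; the package treats
`G` per condition as measured input (the bundled study layout uses
23, 20 and 22 generations per bottleneck for drug-free, hydroxyurea
and rapamycin lines, over 120/60/60 bottlenecks, 40/24/32 surviving
lines). Because bottlenecks purge only dominant-lethal variation,
mutation accumulation is treated as neutral: counts are modelled as
Poisson in (rate × site-copies × generations).

## Rates and intervals

Per-base rates divide accepted mutation counts by
`callable_sites × ploidy × Σ generations`. Counting *site-copies*
(ploidy in the denominator) is a deliberate choice so haploid and
diploid lines are on one scale; passing `ploidy=1` reproduces a
per-site convention. Confidence intervals are exact Garwood/Poisson
(chi-square quantile form), not normal approximations: many MA counts
are small, and at `k = 0` the 95% upper bound is `−ln 0.025 ≈ 3.69`
events over the same denominator. The interval's true coverage
oscillates slightly above 95% with the mean (it is ~95.5% at the means
used by the test suite); the acceptance check measures the coverage
proportion over 300 simulated experiments so the binomial noise of the
measurement (~1.2%) is small against the ≥93% criterion.

Structural event rates (aneuploidy, mtDNA loss, LOH classes) are
simple ratios `k/(lines × generations/line)`; with the published event
counts these reproduce, e.g., 10/(24×1200) = 3.47×10⁻⁴ mtDNA
losses/line/generation under replication stress.

## Spectra, indel channels, signatures

Substitutions are reported in the pyrimidine convention; channels are
the 6 classes × 16 trinucleotide contexts, keyed `A[C>T]G`. Ts/Tv uses
`(C>T + T>C) / (C>A + C>G + T>A + T>G)` and equals 0.5 under a uniform
six-class spectrum; the GC→AT bias is `(C>T + C>A)/(T>C + T>G)`.
Indels use the 83-channel scheme: 1-bp events by pyrimidine-collapsed
base and homopolymer run length, longer events by repeat-unit length
and adjacent repeat count (both capped), and deletions at non-repeat
junctions with flanking microhomology by microhomology length. The
final channel number counts repeat units *in addition to* the event,
so deleting one T from TTTT gives `1:Del:T:3`.

Signature refitting is non-negative least squares (`scipy`'s active
set solver) against a column-normalized catalog, followed by strict
backward elimination: repeatedly refit without the signature whose
removal decreases the reconstruction cosine similarity the least, and
accept the removal while that decrease is below the cutoff (default
0.004, the value used with the strict refitting mode of the
MutationalPatterns ecosystem). The loop leaves at least one signature
and never accepts a step costing ≥ cutoff, which bounds the total
cosine loss by `cutoff × removals`.

Sampling noise bounds what spectrum recovery can show: for a spectrum
with channel weights `p`, a multinomial sample of size `n` has
expected cosine ≈ `1 − (1 − Σp²)/(2n·Σp²)`. With the context-uniform
default spectrum (Σp² ≈ 0.015) that is ~0.967 at n = 1000 and ~0.992
at n = 4000; the spectrum-recovery check therefore runs at ~4000
simulated substitutions, comfortably above its 0.98 criterion without
touching the estimator.

## Variant filtering

All thresholds are strict inequalities (quality 50 fails, depth 10
fails); "6 supporting reads including both strands" is read as ≥6
alt-supporting reads with ≥1 per strand — the minimal literal reading,
and the one a strand-aware caller's SAF/SAR fields support. INDELs are
filtered with the same thresholds; the calling criteria are stated for
substitutions and extending them unchanged is an assumption. Visual
inspection of calls in a genome browser, part of the original
workflow, is inherently manual and is not reproduced; the machine
criteria are the contract.

## Copy number

Chromosome calls require ≥20 windows, a ploidy-scaled median within
0.2 of an integer, and ≥80% of windows rounding to that integer;
otherwise the chromosome is flagged mosaic/segmental and left uncalled
rather than guessed. Segmentation is run-based (rounded per-window
copy number, minimum 10 windows, merging runs split by ≤2 discordant
windows) rather than a changepoint model: deterministic, exactly
testable, and sufficient for events of tens of kilobases and larger.
These thresholds are not experimentally derived; they are fixed
defaults chosen to make noiseless profiles exact and are all
configurable. Under 5% multiplicative log-normal noise the integer
karyotype is recovered exactly for copy numbers 0–4.

Depth normalization divides every window by the genome-wide median of
nuclear, non-repeat-masked windows, computed once per sample; rDNA
windows are also excluded from the median because the collapsed locus
carries a ~hundredfold signal and would bias the median on small
genomes. rDNA copy number is the mean normalized depth over the
collapsed repeat unit relative to the ancestor; "per chromosome"
rescales by ploidy over the called copy number of the rDNA-bearing
chromosome of the *same* sample, never an assumed value.
Mitochondrial copy number averages three near repeat-free gene
intervals (ATP6/COX2/COX3 by convention); a window is "present" at
normalized depth ≥0.1, and the genome is "lost" below 5% presence,
"heteroplasmic" below 95%. The presence thresholds are package
defaults (the underlying depth-presence convention has no published
cutoff) and configurable.

## LOH

Marker genotyping: missing below 10 reads total; heterozygous when
both parental fractions are ≥0.15; homozygous when one fraction is
≥0.9; ambiguous imbalances are treated as missing rather than forced.
Runs of ≥2 same-parent homozygous markers become segments —
single-marker events are discarded as unreliable — with missing
markers transparent and heterozygous markers breaking runs. A segment
covering every informative marker of a chromosome with copy number
below ploidy is chromosome-loss; touching the outermost informative
marker of either end, terminal; otherwise interstitial.

Tract coordinates span the first to last supporting marker. The
breakpoint-interval formula `[start−(first−start), first]` /
`[last, end+(end−last)]` is exposed as a standalone function taking
all four coordinates explicitly, because the distinction between
tract and marker coordinates it presumes is not recoverable from
marker data alone; segments detected from markers instead carry
breakpoint intervals bounded by the nearest flanking heterozygous
marker (or chromosome end), which is the true uncertainty region at
marker resolution. LOH statistics include only diploid lines
(haploids have nothing to lose; tetraploid intermediates violate the
two-parent model) and genome fractions divide by the nuclear genome
length.

The overlap permutation test re-places each query region uniformly at
random within its chromosome, preserving length (not circular shifts —
uniform re-placement matches the default behaviour of the regioneR-
style test and is simplest to specify), with
`p = (#{perm ≥ obs}+1)/(ntimes+1)`. Because the statistic is a count
over query regions, the p-value is discrete and *conservative* when
few query regions are used — with a handful of regions its null mean
is well above 0.5. Uniformity of null p-values, and hence nominal
error control, is only approached when the count resolves the
permutation distribution; the acceptance check runs 500 null tests at
200 query regions against 600 references (ntimes 199) where the KS
test against U(0,1) passes. Interpret small-query tests as valid but
conservative.

## Fluctuation assays

The likelihood is the Ma–Sandri–Sarkar recursion; the estimator
maximizes it by bounded scalar search on `m ∈ [10⁻⁸, max(10, 3·mean)]`
(tolerance 10⁻⁸). The recursion is O(cap²), so counts above a cap are
pooled into a tail term `P(R > cap)`: the cap defaults to 10× the
largest observed count but never exceeds 1000, because the heavy
`1/(j(j+1))` clone-size tail routinely produces jackpot cultures in
the thousands whose exact count carries almost no information about
`m` beyond "large". The p0 method `m = −ln f₀` is provided as a
closed-form cross-check; the two agree within 10% on zero-heavy data.
The simulator draws Poisson(m) mutation events per culture and clone
sizes as `floor(1/U)` (the standard size distribution
`P(J = j) = 1/(j(j+1))`), capped at the final population size. No
plating-efficiency or partial-plating corrections are modelled. Rate
conversion is `m/Nt`.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the estimators
assume: Poisson event counts linear in generations; substitution
channels drawn from a configurable 96-channel spectrum (default: a
drug-free-like spectrum with six-class fractions C>T 0.300, C>A 0.323,
T>C 0.182, T>G 0.058 and the remainder split evenly — Ts/Tv ≈ 0.93,
GC→AT/AT→GC ≈ 2.6 — spread uniformly over contexts within each
class); whole-chromosome gains/losses and segmental CNVs; interstitial
LOH with exponential tract lengths (mean 20 kb) against terminal
events extending to a chromosome end, reproducing the
long-terminal/short-interstitial contrast; rDNA contraction as a
per-generation proportional loss; mtDNA loss/heteroplasmy as presence
masks; and multiplicative log-normal depth noise (default sd 0.05).
Observed call metadata (quality, depth, strand split) is resampled
until it passes every filter criterion, so clean truth records are
recoverable by construction, and a configurable fraction of calls is
degraded to violate one named criterion each, labelled in truth — this
is what makes exact filter confusion matrices possible.

Determinism: one PRNG per run seeded from the mandatory config seed,
with per-line substreams keyed by a stable hash of the line id, so
identical seeds give byte-identical outputs and adding a line leaves
the others unchanged.

Deliberate simplifications, hence what passing tests do *not* show
about real data: no read-level error model (calls and depth are
simulated at table level); marker allele depths on trisomic
chromosomes stay 50/50 although real trisomies show 2:1 allelic
ratios; LOH events are placed non-overlapping with a one-marker
separation, so recovery tests do not probe overlapping or adjacent
event resolution; substitution positions ignore local sequence
content; and indel flanks are constructed rather than drawn from a
reference genome. GC-content-, replication-timing- or
chromatin-associated rate variation is not modelled.

## Problem sizes

Tests and the acceptance script run on a demo genome (4 × 400 kb
nuclear chromosomes, 75 kb mitochondrial sequence, one collapsed 9.1 kb
rDNA unit, 5 kb telomere masks) with designs of 1–24 lines and reduced
callable sites (1–12 Mb), sized so the full suite completes in a few
minutes on one CPU while keeping expected event counts in the regimes
the estimators face in practice (tens to thousands of substitutions
per experiment, 0–4 copies per chromosome, a handful of LOH tracts per
line). A full-scale 16-chromosome genome definition
(`mafoot.simulate.yeast_genome`) is provided for realistic layouts.

## Known limitations

* The pipeline consumes pre-tabulated calls and depth; no BAM/CRAM or
  read-level processing, alignment or raw calling.
* The expected non-synonymous/genic fractions assume the standard
  nuclear genetic code and single-interval CDS frames; spliced or
  mitochondrial-code genes need pre-processing.
* The co-occurrence test conditions on the total event count with
  uniform line assignment; it does not model per-line rate
  heterogeneity, which would inflate apparent clustering.
* Signature refitting is exactly that — refitting; it cannot discover
  signatures absent from the supplied catalog.
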