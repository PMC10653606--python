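"""Loss-of-heterozygosity detection and statistics on parental markers.

A hybrid diploid carries heterozygous markers distinguishing its two
parental subgenomes; LOH converts a run of them to homozygosity for
one parent.  Detection works at marker resolution: each marker is
genotyped from its two parental allele depths, runs of >= 2 consecutive
same-parent homozygous markers become segments (single-marker runs are
discarded as unreliable), and segments are classified as interstitial,
terminal (reaching the outermost informative marker of a chromosome
end) or whole-chromosome loss (all markers homozygous with reduced
copy number).  Breakpoints live between the outermost homozygous
marker and the nearest flanking heterozygous marker.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomeDef, Interval, MALDesign, MarkerTable, ValidationError

__all__ = [
    "LOHSegment",
    "LOHStatistics",
    "call_marker_state",
    "call_marker_states",
    "segment_loh",
    "classify_loh",
    "breakpoint_intervals",
    "detect_loh",
    "loh_statistics",
    "permutation_overlap_test",
]

LOH_CLASSES = ("interstitial", "terminal", "chromosome_loss")


@dataclass(frozen=True)
class LOHSegment:
    """A run of homozygous markers assigned to one parent.

    ``first``/``last`` are the outermost homozygous marker positions;
    the tract [start, end] spans those same positions.  Breakpoint
    intervals extend from the tract edge to the nearest flanking
    heterozygous marker (or the chromosome end when none exists).
    """

    line_id: str
    chrom: str
    parent: str  # "P1" | "P2"
    start: int
    end: int
    n_markers: int
    loh_class: str = "interstitial"
    breakpoint_up: tuple[int, int] | None = None
    breakpoint_down: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_markers < 2:
            raise ValidationError("LOH segment needs >= 2 supporting markers")
        if self.start > self.end:
            raise ValidationError("segment start > end")
        if self.parent not in ("P1", "P2"):
            raise ValidationError(f"bad parent {self.parent!r}")
        if self.loh_class not in LOH_CLASSES:
            raise ValidationError(f"bad LOH class {self.loh_class!r}")

    @property
    def first(self) -> int:
        return self.start

    @property
    def last(self) -> int:
        return self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def call_marker_state(
    depth_p1: int,
    depth_p2: int,
    min_depth: int = 10,
    het_minor_frac: float = 0.15,
    hom_major_frac: float = 0.9,
) -> str:
    """Genotype one marker from parental allele depths.

    Returns ``het``, ``homP1``, ``homP2`` or ``missing``.  Markers
    with total depth below ``min_depth`` are missing; heterozygous
    requires both parental fractions >= ``het_minor_frac``; homozygous
    requires one parent's fraction >= ``hom_major_frac``; anything in
    between is treated as missing (ambiguous allelic imbalance).
    """
    if depth_p1 < 0 or depth_p2 < 0:
        raise ValidationError("negative marker depth")
    total = depth_p1 + depth_p2
    if total < min_depth:
        return "missing"
    f1 = depth_p1 / total
    f2 = depth_p2 / total
    if f1 >= het_minor_frac and f2 >= het_minor_frac:
        return "het"
    if f1 >= hom_major_frac:
        return "homP1"
    if f2 >= hom_major_frac:
        return "homP2"
    return "missing"


def call_marker_states(
    markers: MarkerTable,
    min_depth: int = 10,
    het_minor_frac: float = 0.15,
    hom_major_frac: float = 0.9,
) -> list[str]:
    """Vector of marker states in table order."""
    return [
        call_marker_state(int(d1), int(d2), min_depth, het_minor_frac, hom_major_frac)
        for d1, d2 in zip(markers.markers["depth_p1"], markers.markers["depth_p2"])
    ]


def segment_loh(
    states: Sequence[str],
    positions: Sequence[int],
    chrom: str = "",
    line_id: str = "",
) -> list[LOHSegment]:
    """Collapse marker states of one chromosome into LOH segments.

    Missing markers are transparent (they neither support nor break a
    run); heterozygous markers break runs.  Only runs of >= 2 markers
    homozygous for the same parent become segments; the tract spans the
    first to last supporting marker.
    """
    if len(states) != len(positions):
        raise ValidationError("states and positions length mismatch")
    if any(positions[i] >= positions[i + 1] for i in range(len(positions) - 1)):
        raise ValidationError("marker positions must be strictly increasing")
    segments: list[LOHSegment] = []
    run_parent: str | None = None
    run_pos: list[int] = []

    def flush() -> None:
        nonlocal run_parent, run_pos
        if run_parent is not None and len(run_pos) >= 2:
            segments.append(
                LOHSegment(
                    line_id=line_id,
                    chrom=chrom,
                    parent=run_parent,
                    start=run_pos[0],
                    end=run_pos[-1],
                    n_markers=len(run_pos),
                )
            )
        run_parent, run_pos = None, []

    for st, pos in zip(states, positions):
        if st == "missing":
            continue
        if st == "het":
            flush()
        elif st in ("homP1", "homP2"):
            parent = st[3:]
            if parent != run_parent:
                flush()
                run_parent = parent
            run_pos.append(pos)
        else:
            raise ValidationError(f"unknown marker state {st!r}")
    flush()
    return segments


def classify_loh(
    segment: LOHSegment,
    informative_positions: Sequence[int],
    chromosome_cn: int | None,
    ploidy: int = 2,
) -> str:
    """Classify a segment as interstitial, terminal or chromosome loss.

    ``informative_positions`` are the positions of all non-missing
    markers on the chromosome.  Chromosome loss requires the segment to
    cover every informative marker and the chromosome copy number to be
    below ploidy; terminal segments reach the outermost informative
    marker on either end.
    """
    if not informative_positions:
        raise ValidationError("no informative markers on chromosome")
    lo, hi = min(informative_positions), max(informative_positions)
    covers_all = segment.start <= lo and segment.end >= hi
    if covers_all and chromosome_cn is not None and chromosome_cn < ploidy:
        return "chromosome_loss"
    if segment.start <= lo or segment.end >= hi:
        return "terminal"
    return "interstitial"


def breakpoint_intervals(
    start: int, end: int, first: int, last: int, chrom_length: int | None = None
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Breakpoint uncertainty intervals from tract/marker coordinates.

    Upstream interval is [start - (first - start), first]; downstream
    is [last, end + (end - last)]; both clipped to [1, chrom_length].
    Requires start <= first <= last <= end.  When start == first the
    upstream interval degenerates to a point (and symmetrically
    downstream).
    """
    if not (start <= first <= last <= end):
        raise ValidationError(
            f"breakpoint ordering violated: start={start} first={first} "
            f"last={last} end={end}"
        )
    up_lo = start - (first - start)
    down_hi = end + (end - last)
    up_lo = max(1, up_lo)
    if chrom_length is not None:
        down_hi = min(chrom_length, down_hi)
    return (up_lo, first), (last, down_hi)


def detect_loh(
    markers: MarkerTable,
    line_id: str,
    genome: GenomeDef,
    chromosome_cn: dict[str, int | None] | None = None,
    ploidy: int = 2,
    min_depth: int = 10,
    het_minor_frac: float = 0.15,
    hom_major_frac: float = 0.9,
) -> list[LOHSegment]:
    """Full per-line LOH calling: genotype, segment, classify, annotate.

    ``chromosome_cn`` (e.g. from :func:`mafoot.cnv.call_chromosome_cn`)
    enables the chromosome-loss class; without it whole-chromosome
    homozygosity is classified terminal.
    """
    states = call_marker_states(markers, min_depth, het_minor_frac, hom_major_frac)
    out: list[LOHSegment] = []
    df = markers.markers.assign(state=states)
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].tolist()
        sts = grp["state"].tolist()
        informative = [p for p, s in zip(pos, sts) if s != "missing"]
        het_pos = [p for p, s in zip(pos, sts) if s == "het"]
        cn = (chromosome_cn or {}).get(chrom)
        for seg in segment_loh(sts, pos, chrom=chrom, line_id=line_id):
            cls = classify_loh(seg, informative, cn, ploidy)
            # breakpoints bounded by nearest flanking het marker
            prev_het = max((p for p in het_pos if p < seg.start), default=1)
            next_het = min(
                (p for p in het_pos if p > seg.end),
                default=genome.length_of(chrom),
            )
            out.append(
                LOHSegment(
                    line_id=line_id,
                    chrom=chrom,
                    parent=seg.parent,
                    start=seg.start,
                    end=seg.end,
                    n_markers=seg.n_markers,
                    loh_class=cls,
                    breakpoint_up=(prev_het, seg.start),
                    breakpoint_down=(seg.end, next_het),
                )
            )
    return out


@dataclass
class LOHStatistics:
    """Per-class rates, per-line genome fractions and tract lengths."""

    rates: dict[str, float]  # class -> events/line/generation
    overall_rate: float
    genome_fraction: dict[str, float]  # line_id -> fraction of genome in LOH
    lengths: dict[str, list[int]] = field(default_factory=dict)
    n_lines: int = 0


def loh_statistics(
    segments: Iterable[LOHSegment],
    design: MALDesign,
    genome: GenomeDef,
    condition: str | None = None,
) -> LOHStatistics:
    """Summarize LOH segments against the experimental design.

    Only diploid lines enter the statistics (haploids have no
    heterozygosity to lose; tetraploid intermediates violate the
    two-parent model).  Rates divide event counts by the summed
    generations of the eligible lines; genome fractions divide summed
    tract lengths by the nuclear genome length.
    """
    lines = [
        ln
        for ln in design
        if ln.ploidy == 2 and (condition is None or ln.condition == condition)
    ]
    if not lines:
        raise ValidationError("no eligible diploid lines in design")
    eligible = {ln.line_id for ln in lines}
    total_gens = sum(ln.total_generations for ln in lines)
    counts = {c: 0 for c in LOH_CLASSES}
    lengths: dict[str, list[int]] = {c: [] for c in LOH_CLASSES}
    frac: dict[str, float] = {ln.line_id: 0.0 for ln in lines}
    glen = genome.nuclear_length
    n_total = 0
    for seg in segments:
        if seg.line_id not in eligible:
            continue
        genome.validate_position(seg.chrom, seg.start)
        genome.validate_position(seg.chrom, seg.end)
        counts[seg.loh_class] += 1
        lengths[seg.loh_class].append(seg.length)
        frac[seg.line_id] += seg.length / glen
        n_total += 1
    rates = {c: counts[c] / total_gens for c in LOH_CLASSES}
    return LOHStatistics(
        rates=rates,
        overall_rate=n_total / total_gens,
        genome_fraction=frac,
        lengths=lengths,
        n_lines=len(lines),
    )


# ---------------------------------------------------------------------------
# Region-overlap permutation test


def _merge_sorted(regions: Sequence[Interval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[Interval]] = defaultdict(list)
    for iv in regions:
        by_chrom[iv.chrom].append(iv)
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        for iv in ivs:
            if starts and iv.start <= ends[-1] + 1:
                ends[-1] = max(ends[-1], iv.end)
            else:
                starts.append(iv.start)
                ends.append(iv.end)
        out[chrom] = (np.array(starts), np.array(ends))
    return out


def _hits(
    q_starts: np.ndarray, q_ends: np.ndarray,
    ref_starts: np.ndarray, ref_ends: np.ndarray,
) -> np.ndarray:
    """Boolean overlap flags of query intervals against merged sorted
    reference intervals (any shape; vectorized)."""
    i = np.searchsorted(ref_ends, q_starts, side="left")
    ok = i < len(ref_starts)
    hit = np.zeros(q_starts.shape, dtype=bool)
    hit[ok] = ref_starts[np.minimum(i[ok], len(ref_starts) - 1)] <= q_ends[ok]
    return hit


def permutation_overlap_test(
    query: Sequence[Interval],
    reference: Sequence[Interval],
    genome: GenomeDef,
    ntimes: int = 1000,
    alternative: str = "greater",
    seed: int | None = None,
) -> tuple[float, float, int]:
    """Test whether query regions overlap reference regions more than chance.

    Each permutation re-places every query region uniformly at random
    within its own chromosome, preserving its length; the statistic is
    the number of query regions overlapping at least one reference
    region.  Returns ``(p, z, observed)`` with the add-one empirical
    p-value and the z-score against the permutation distribution.
    """
    if ntimes < 1:
        raise ValidationError("ntimes must be >= 1")
    if alternative not in ("greater", "less"):
        raise ValidationError(f"bad alternative {alternative!r}")
    if not query:
        raise ValidationError("empty query region set")
    for iv in query:
        if len(iv) > genome.length_of(iv.chrom):
            raise ValidationError(f"region longer than its chromosome: {iv}")
    ref = _merge_sorted(reference)
    rng = np.random.default_rng(seed)
    observed = 0
    perm_stats = np.zeros(ntimes, dtype=int)
    by_chrom: dict[str, list[Interval]] = defaultdict(list)
    for q in query:
        by_chrom[q.chrom].append(q)
    for chrom, qs in by_chrom.items():
        if chrom not in ref:
            continue
        rs, re = ref[chrom]
        q_starts = np.array([q.start for q in qs])
        lens = np.array([len(q) for q in qs])
        observed += int(_hits(q_starts, q_starts + lens - 1, rs, re).sum())
        L = genome.length_of(chrom)
        # uniform re-placement within the chromosome, lengths preserved
        starts = rng.integers(1, L - lens + 2, size=(ntimes, len(qs)))
        perm_stats += _hits(starts, starts + lens - 1, rs, re).sum(axis=1)
    if alternative == "greater":
        p = (int((perm_stats >= observed).sum()) + 1) / (ntimes + 1)
    else:
        p = (int((perm_stats <= observed).sum()) + 1) / (ntimes + 1)
    sd = float(perm_stats.std(ddof=0))
    z = float((observed - perm_stats.mean()) / sd) if sd > 0 else float("nan")
    return p, z, observed
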