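"""Synthetic mutation-accumulation datasets with known ground truth.

The generator emulates the statistical structure the analysis stages
assume: per-line mutation counts are Poisson in (rate x site-copies x
generations), substitution channels follow a configurable 96-channel
spectrum, karyotypes acquire whole-chromosome and segmental
copy-number events, hybrid lines acquire interstitial/terminal LOH
tracts with class-specific length distributions, and depth profiles
carry multiplicative log-normal noise with rDNA and mitochondrial
scaling.  Observed tables (variant calls with quality/depth/strand
metadata, windowed depth, marker allele depths) are emitted alongside
truth tables so every estimator can be scored against a known answer.

A configurable fraction of true calls is deliberately degraded to
violate each variant-filter criterion; degraded records are labelled
in the truth table, so filter tests can assert exact confusion
matrices.

Determinism: all randomness derives from the mandatory config seed;
per-line sub-streams are keyed by a stable hash of the line id, so
adding a line leaves the others' data unchanged.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .filters import FILTER_REASONS
from .genome import (
    DepthProfile,
    GenomeDef,
    Interval,
    MALDesign,
    MALine,
    MarkerTable,
    ValidationError,
    VariantCall,
)
from .spectra import SBS96_CHANNELS

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "LineData",
    "yeast_genome",
    "demo_genome",
    "study_design",
    "ypd_spectrum96",
    "uniform_spectrum96",
    "simulate_mal",
    "simulate_depth",
    "simulate_fluctuation",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# S. cerevisiae chromosome lengths (bp, SGD R64), used for full-scale runs.
_YEAST_CHROMS = (
    ("chrI", 230_218), ("chrII", 813_184), ("chrIII", 316_620),
    ("chrIV", 1_531_933), ("chrV", 576_874), ("chrVI", 270_161),
    ("chrVII", 1_090_940), ("chrVIII", 562_643), ("chrIX", 439_888),
    ("chrX", 745_751), ("chrXI", 666_816), ("chrXII", 1_078_177),
    ("chrXIII", 924_431), ("chrXIV", 784_333), ("chrXV", 1_091_291),
    ("chrXVI", 948_066),
)


def yeast_genome() -> GenomeDef:
    """Full-scale S. cerevisiae-like genome: 16 nuclear chromosomes,
    ~86 kb mitochondrial sequence, rDNA collapsed to one 9.1 kb repeat
    unit on chromosome XII, 10 kb telomeric repeat masks."""
    mask = []
    for name, ln in _YEAST_CHROMS:
        mask.append(Interval(name, 1, 10_000))
        mask.append(Interval(name, ln - 9_999, ln))
    return GenomeDef(
        chromosomes=_YEAST_CHROMS + (("chrM", 85_779),),
        centromeres={name: ln // 2 for name, ln in _YEAST_CHROMS},
        rdna_locus=Interval("chrXII", 451_000, 460_100),
        mito_name="chrM",
        repeat_mask=tuple(mask),
    )


def demo_genome(n_chroms: int = 4, chrom_length: int = 400_000) -> GenomeDef:
    """Small synthetic genome for fast tests and examples: ``n_chroms``
    equal nuclear chromosomes, a 75 kb mitochondrial sequence, an rDNA
    unit on the last nuclear chromosome, 5 kb telomere masks."""
    chroms = tuple((f"chr{i + 1}", chrom_length) for i in range(n_chroms))
    mask = []
    for name, ln in chroms:
        mask.append(Interval(name, 1, 5_000))
        mask.append(Interval(name, ln - 4_999, ln))
    rdna_chrom = chroms[-1][0]
    return GenomeDef(
        chromosomes=chroms + (("chrM", 75_000),),
        centromeres={name: ln // 2 for name, ln in chroms},
        rdna_locus=Interval(rdna_chrom, chrom_length // 2, chrom_length // 2 + 9_099),
        mito_name="chrM",
        repeat_mask=tuple(mask),
    )


_BACKGROUNDS_HOM = ("WA/WA", "WE/WE", "NA/NA", "SA/SA")
_BACKGROUNDS_HYB = ("WA/WE", "NA/WE", "NA/WA", "SA/WE", "SA/WA", "SA/NA")


def study_design(
    callable_sites: int = 12_000_000,
    lines_per_condition: dict[str, int] | None = None,
) -> MALDesign:
    """The MA experiment layout: three conditions with their bottleneck
    counts and generations per bottleneck (YPD: 120 x 23; HU: 60 x 20;
    RM: 60 x 22) and the surviving line counts (40/24/32).

    ``lines_per_condition`` can shrink the design for fast runs while
    keeping the per-line generation structure.
    """
    survivors = {
        "YPD": (40, 120, 23.0, _BACKGROUNDS_HYB + _BACKGROUNDS_HOM),
        "HU": (24, 60, 20.0, ("NA/NA",) + tuple(b for b in _BACKGROUNDS_HYB if b != "SA/WA")),
        "RM": (32, 60, 22.0, ("NA/NA", "SA/SA") + _BACKGROUNDS_HYB),
    }
    lines = []
    for cond, (n_lines, n_bn, gpb, bgs) in survivors.items():
        if lines_per_condition is not None:
            n_lines = lines_per_condition.get(cond, 0)
        for i in range(n_lines):
            bg = bgs[i % len(bgs)]
            rep = i // len(bgs) + 1
            lines.append(
                MALine(
                    line_id=f"{bg}-{cond}-{rep}",
                    background=bg,
                    condition=cond,
                    n_bottlenecks=n_bn,
                    gens_per_bottleneck=gpb,
                    callable_sites=callable_sites,
                    ploidy=2,
                )
            )
    return MALDesign(tuple(lines))


def uniform_spectrum96() -> dict[str, float]:
    """Flat spectrum: every 96 channel equally likely."""
    return {ch: 1.0 / 96 for ch in SBS96_CHANNELS}


def ypd_spectrum96() -> dict[str, float]:
    """Drug-free (YPD-like) substitution spectrum.

    Six-class fractions chosen to reproduce the canonical yeast
    spontaneous profile: C>T 0.300, C>A 0.323, T>C 0.182, T>G 0.058,
    C>G and T>A sharing the remainder — giving Ts/Tv ~ 0.93 and a
    GC-to-AT / AT-to-GC ratio ~ 2.6.  Within each class the 16
    trinucleotide contexts are equally weighted.
    """
    six = {
        "C>T": 0.300, "C>A": 0.323, "T>C": 0.182,
        "T>G": 0.058, "C>G": 0.0685, "T>A": 0.0685,
    }
    total = sum(six.values())
    return {
        ch: six[ch[2:5]] / total / 16.0
        for ch in SBS96_CHANNELS
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one synthetic MA experiment.

    Rates are per base per generation (``sub_rate``, ``indel_rate``)
    or per line per generation (aneuploidy, segmental CNV, LOH).
    ``spectrum96`` must sum to 1.  ``degrade_fractions`` maps a filter
    reason code to the fraction of true calls degraded to violate that
    criterion.  ``seed`` is mandatory; identical seeds give identical
    output.
    """

    genome: GenomeDef
    design: MALDesign
    seed: int
    sub_rate: float = 1.89e-10
    indel_rate: float = 1.41e-11
    spectrum96: dict[str, float] = field(default_factory=ypd_spectrum96)
    aneu_gain_rate: float = 1.2e-4  # gains dominate losses ~6:1
    aneu_loss_rate: float = 0.2e-4
    seg_cnv_rate: float = 2.0e-5
    loh_rate_interstitial: float = 1.0e-4
    loh_rate_terminal: float = 5.0e-5
    loh_interstitial_mean_kb: float = 20.0
    rdna_contraction: float = 0.0  # per-generation proportional repeat loss
    rdna_ancestor_repeats: float = 150.0
    mtdna_loss_prob: float = 0.09
    mtdna_het_prob: float = 0.0
    mtdna_copy_number: float = 20.0
    depth_noise_sd: float = 0.05
    qual_range: tuple[float, float] = (100.0, 3000.0)
    depth_mean: float = 100.0
    window_size: int = 10_000
    mito_window_size: int = 100
    marker_spacing: int = 5_000
    degrade_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "sub_rate", "indel_rate", "aneu_gain_rate", "aneu_loss_rate",
            "seg_cnv_rate", "loh_rate_interstitial", "loh_rate_terminal",
            "rdna_contraction", "mtdna_loss_prob", "mtdna_het_prob",
            "depth_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        total = sum(self.spectrum96.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"spectrum96 sums to {total}, expected 1")
        bad = set(self.spectrum96) - set(SBS96_CHANNELS)
        if bad:
            raise ValidationError(f"unknown spectrum channels: {sorted(bad)[:3]}")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for r in self.degrade_fractions:
            if r not in FILTER_REASONS:
                raise ValidationError(f"unknown degrade reason {r!r}")


@dataclass
class LineData:
    """Observed data for one line."""

    line_id: str
    variants: list[VariantCall]
    depth: DepthProfile
    markers: MarkerTable | None  # None for non-hybrid lines


@dataclass
class SimulationResult:
    """Truth tables plus observed per-line data and ancestor profiles."""

    config: SimulationConfig
    truth: dict[str, pd.DataFrame]
    lines: dict[str, LineData]
    ancestor_depth: DepthProfile


def _line_rng(seed: int, line_id: str, stream: str = "") -> np.random.Generator:
    key = zlib.crc32(f"{line_id}|{stream}".encode())
    return np.random.default_rng([seed % (2**31), key])


def _is_hybrid(background: str) -> bool:
    parts = background.split("/")
    return len(parts) == 2 and parts[0] != parts[1]


def _sample_channel_bases(rng, channels, probs):
    """Sample a 96 channel, return (channel, ref, alt, context) on a
    random strand (the pyrimidine convention is a reporting convention;
    the genome sees both strands)."""
    ch = channels[rng.choice(len(channels), p=probs)]
    five, ref, alt, three = ch[0], ch[2], ch[4], ch[6]
    ctx = five + ref + three
    if rng.random() < 0.5:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        ctx = "".join(_COMPLEMENT[b] for b in reversed(ctx))
    return ch, ref, alt, ctx


def _sample_positions(rng, genome: GenomeDef, n: int) -> list[tuple[str, int]]:
    """Uniform positions over unmasked nuclear genome (2 bp margin so a
    trinucleotide context always exists)."""
    chroms = genome.nuclear_chromosomes()
    lens = np.array([genome.length_of(c) for c in chroms], dtype=float)
    probs = lens / lens.sum()
    out: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    while len(out) < n:
        c = chroms[rng.choice(len(chroms), p=probs)]
        pos = int(rng.integers(2, genome.length_of(c)))
        if genome.in_repeat_mask(c, pos):
            continue
        if (c, pos) in seen:
            continue
        seen.add((c, pos))
        out.append((c, pos))
    return out


def _observe_call(rng, cfg: SimulationConfig) -> tuple[float, int, int, int]:
    """Sample (qual, depth, alt_fwd, alt_rev) for a clean call; resampled
    until it passes every per-record filter criterion, so clean truth
    records are recoverable by construction."""
    while True:
        qual = float(rng.uniform(*cfg.qual_range))
        depth = int(rng.poisson(cfg.depth_mean))
        if depth <= 10:
            continue
        alt = int(rng.binomial(depth, 0.5))
        fwd = int(rng.binomial(alt, 0.5))
        rev = alt - fwd
        if qual > 50 and alt >= 6 and fwd >= 1 and rev >= 1:
            return qual, depth, fwd, rev


def _degrade(rng, cfg, call: VariantCall, reason: str) -> VariantCall:
    """Return a copy of the call violating exactly the given criterion."""
    if reason == "single_caller":
        return replace(call, callers=frozenset({"A"}))
    if reason == "low_qual":
        return replace(call, qual=float(rng.uniform(1.0, 50.0)))
    if reason == "low_depth":
        d = int(rng.integers(1, 11))
        alt = min(call.alt_support, d)
        fwd = max(1, min(call.alt_fwd, alt - 1)) if alt >= 2 else alt
        return replace(call, depth=d, alt_fwd=fwd, alt_rev=alt - fwd)
    if reason == "low_support":
        alt = int(rng.integers(2, 6))
        fwd = int(rng.integers(1, alt))
        return replace(call, alt_fwd=fwd, alt_rev=alt - fwd)
    if reason == "one_strand":
        return replace(call, alt_fwd=call.alt_support, alt_rev=0)
    if reason == "ancestral":
        return replace(call, in_ancestor=True)
    if reason == "repeat_region":
        if not cfg.genome.repeat_mask:
            raise ValidationError("cannot degrade into an empty repeat mask")
        iv = cfg.genome.repeat_mask[int(rng.integers(len(cfg.genome.repeat_mask)))]
        pos = int(rng.integers(iv.start, iv.end + 1))
        return replace(call, chrom=iv.chrom, pos=pos)
    raise ValidationError(f"cannot degrade for reason {reason!r}")


def _choose_degradations(rng, n: int, fractions: dict[str, float]) -> list[str | None]:
    tags: list[str | None] = [None] * n
    idx = rng.permutation(n)
    cursor = 0
    for reason, frac in sorted(fractions.items()):
        k = int(round(frac * n))
        for i in idx[cursor : cursor + k]:
            tags[i] = reason
        cursor += k
    return tags


# ---------------------------------------------------------------------------
# Karyotype / depth simulation


def _simulate_karyotype(rng, cfg: SimulationConfig, line: MALine):
    gens = line.total_generations
    chroms = cfg.genome.nuclear_chromosomes()
    cn = {c: line.ploidy for c in chroms}
    events = []
    n_gain = rng.poisson(cfg.aneu_gain_rate * gens)
    n_loss = rng.poisson(cfg.aneu_loss_rate * gens)
    for _ in range(n_gain):
        c = chroms[rng.integers(len(chroms))]
        cn[c] += 1
        events.append((c, "gain", 1))
    for _ in range(n_loss):
        c = chroms[rng.integers(len(chroms))]
        if cn[c] > 0:
            cn[c] -= 1
            events.append((c, "loss", 1))
    return cn, events


def _simulate_seg_cnvs(rng, cfg: SimulationConfig, line: MALine, karyotype):
    gens = line.total_generations
    chroms = cfg.genome.nuclear_chromosomes()
    n = rng.poisson(cfg.seg_cnv_rate * gens)
    segs = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        clen = cfg.genome.length_of(c)
        if clen < 150_000:
            continue
        seg_len = int(rng.uniform(50_000, min(200_000, clen // 2)))
        start = int(rng.integers(cfg.window_size, clen - seg_len))
        delta = 1 if rng.random() < 0.7 else -1
        if karyotype[c] + delta < 0:
            delta = 1
        segs.append((c, start, start + seg_len - 1, karyotype[c] + delta))
    return segs


def simulate_depth(
    karyotype: dict[str, int],
    config: SimulationConfig,
    ploidy: int = 2,
    rng: np.random.Generator | None = None,
    seg_cnvs=(),
    rdna_repeats: float | None = None,
    mtdna_copy: float | None = None,
    mtdna_presence: tuple[int, int] | None = None,
) -> DepthProfile:
    """Windowed normalized depth for a given integer karyotype.

    Each nuclear window has norm_depth = (cn / ploidy) x LogNormal(0,
    depth_noise_sd); rDNA windows are additionally scaled by the repeat
    count, mitochondrial windows (100 bp) by the mtDNA copy number and,
    for heteroplasmic genomes, a presence interval outside which depth
    is zero.
    """
    if any(v < 0 for v in karyotype.values()):
        raise ValidationError("negative copy number")
    g = config.genome
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    sd = config.depth_noise_sd

    def noise(n):
        if sd == 0:
            return np.ones(n)
        return rng.lognormal(0.0, sd, size=n)

    seg_by_chrom: dict[str, list] = {}
    for c, s, e, cnv_cn in seg_cnvs:
        seg_by_chrom.setdefault(c, []).append((s, e, cnv_cn))
    for chrom in g.nuclear_chromosomes():
        clen = g.length_of(chrom)
        starts = np.arange(1, clen + 1, config.window_size)
        ends = np.minimum(starts + config.window_size - 1, clen)
        mids = (starts + ends) // 2
        base = np.full(len(starts), karyotype.get(chrom, ploidy) / ploidy)
        for s, e, cnv_cn in seg_by_chrom.get(chrom, ()):
            sel = (mids >= s) & (mids <= e)
            base[sel] = cnv_cn / ploidy
        if g.rdna_locus is not None and g.rdna_locus.chrom == chrom:
            sel = (mids >= g.rdna_locus.start) & (mids <= g.rdna_locus.end)
            reps = rdna_repeats if rdna_repeats is not None else config.rdna_ancestor_repeats
            base[sel] = base[sel] * reps
        nd = base * noise(len(base))
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "raw_depth": nd * config.depth_mean, "norm_depth": nd,
        }))
    if g.mito_name is not None:
        clen = g.length_of(g.mito_name)
        starts = np.arange(1, clen + 1, config.mito_window_size)
        ends = np.minimum(starts + config.mito_window_size - 1, clen)
        mids = (starts + ends) // 2
        copy = mtdna_copy if mtdna_copy is not None else config.mtdna_copy_number
        base = np.full(len(starts), float(copy))
        if mtdna_presence is not None:
            sel = (mids >= mtdna_presence[0]) & (mids <= mtdna_presence[1])
            base[~sel] = 0.0
        nd = base * noise(len(base))
        rows.append(pd.DataFrame({
            "chrom": g.mito_name, "start": starts, "end": ends,
            "raw_depth": nd * config.depth_mean, "norm_depth": nd,
        }))
    return DepthProfile(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# LOH simulation


def _marker_positions(cfg: SimulationConfig, chrom: str) -> np.ndarray:
    clen = cfg.genome.length_of(chrom)
    return np.arange(cfg.marker_spacing, clen, cfg.marker_spacing)


def _simulate_loh_events(rng, cfg: SimulationConfig, line: MALine, karyotype):
    """Place non-overlapping LOH tracts, snapped to marker positions so
    noiseless recovery is exact at marker resolution."""
    gens = line.total_generations
    chroms = cfg.genome.nuclear_chromosomes()
    events = []  # (chrom, first_marker_idx, last_marker_idx, parent, class)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def free(chrom, i0, i1):
        # one-marker gap between events keeps runs separable
        return all(i1 < a - 1 or i0 > b + 1 for a, b in occupied[chrom])

    # whole-chromosome loss from aneuploidy (diploid -> 1 copy)
    for chrom in chroms:
        if karyotype[chrom] < line.ploidy:
            n_mark = len(_marker_positions(cfg, chrom))
            if n_mark >= 2 and free(chrom, 0, n_mark - 1):
                parent = "P1" if rng.random() < 0.5 else "P2"
                events.append((chrom, 0, n_mark - 1, parent, "chromosome_loss"))
                occupied[chrom].append((0, n_mark - 1))

    n_term = rng.poisson(cfg.loh_rate_terminal * gens)
    for _ in range(n_term):
        chrom = chroms[rng.integers(len(chroms))]
        marks = _marker_positions(cfg, chrom)
        if len(marks) < 4:
            continue
        right = rng.random() < 0.5
        # start uniform along the chromosome, extending to the end
        i = int(rng.integers(1, len(marks) - 1))
        i0, i1 = (i, len(marks) - 1) if right else (0, i)
        if i1 - i0 < 1 or not free(chrom, i0, i1):
            continue
        parent = "P1" if rng.random() < 0.5 else "P2"
        events.append((chrom, i0, i1, parent, "terminal"))
        occupied[chrom].append((i0, i1))

    n_int = rng.poisson(cfg.loh_rate_interstitial * gens)
    for _ in range(n_int):
        chrom = chroms[rng.integers(len(chroms))]
        marks = _marker_positions(cfg, chrom)
        if len(marks) < 6:
            continue
        length = rng.exponential(cfg.loh_interstitial_mean_kb * 1_000)
        n_span = max(1, int(length // cfg.marker_spacing))
        i0 = int(rng.integers(1, max(2, len(marks) - n_span - 1)))
        i1 = min(i0 + n_span, len(marks) - 2)
        if i1 - i0 < 1 or not free(chrom, i0, i1):
            continue
        parent = "P1" if rng.random() < 0.5 else "P2"
        events.append((chrom, i0, i1, parent, "interstitial"))
        occupied[chrom].append((i0, i1))
    return events


def _simulate_markers(rng, cfg: SimulationConfig, loh_events) -> MarkerTable:
    loh_by_chrom: dict[str, list] = {}
    for chrom, i0, i1, parent, _cls in loh_events:
        loh_by_chrom.setdefault(chrom, []).append((i0, i1, parent))
    frames = []
    for chrom in cfg.genome.nuclear_chromosomes():
        marks = _marker_positions(cfg, chrom)
        n = len(marks)
        half = cfg.depth_mean / 2.0
        d1 = rng.poisson(half, size=n).astype(int)
        d2 = rng.poisson(half, size=n).astype(int)
        # clip allele depths so genotyping is exact: clipped fractions
        # always satisfy the het thresholds at heterozygous markers
        lo, hi = max(1, int(0.7 * half)), max(2, int(1.3 * half))
        d1 = np.clip(d1, lo, hi)
        d2 = np.clip(d2, lo, hi)
        for i0, i1, parent in loh_by_chrom.get(chrom, ()):
            sel = slice(i0, i1 + 1)
            tot = d1[sel] + d2[sel]
            if parent == "P1":
                d1[sel], d2[sel] = tot, 0
            else:
                d1[sel], d2[sel] = 0, tot
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": marks,
            "allele_p1": "A", "allele_p2": "G",
            "depth_p1": d1, "depth_p2": d2,
        }))
    return MarkerTable(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Indel sequence construction


def _simulate_indel_seqs(rng, n: int):
    """Random indel events with constructed flanks: returns tuples of
    (seq, var_type, flank5, flank3)."""
    bases = "ACGT"
    out = []
    for _ in range(n):
        var_type = "deletion" if rng.random() < 0.6 else "insertion"
        ln = 1 + int(rng.geometric(0.7)) - 1  # mostly 1 bp
        ln = min(ln + 1, 5) if rng.random() < 0.2 else 1
        seq = "".join(bases[rng.integers(4)] for _ in range(ln))
        n_rep = int(rng.geometric(0.5)) - 1  # adjacent copies of the unit
        flank3 = seq * n_rep
        flank3 += "".join(bases[rng.integers(4)] for _ in range(25 - len(flank3) % 25))
        flank5 = "".join(bases[rng.integers(4)] for _ in range(25))
        # avoid accidental extra repeats at the 5' junction
        while flank5.endswith(seq):
            flank5 = flank5[: -len(seq)] + "".join(
                bases[rng.integers(4)] for _ in range(len(seq))
            )
        out.append((seq, var_type, flank5, flank3))
    return out


# ---------------------------------------------------------------------------
# Top-level simulation


def simulate_mal(config: SimulationConfig) -> SimulationResult:
    """Generate a full synthetic MA dataset with truth tables.

    Returns truth DataFrames (``substitutions``, ``indels``,
    ``aneuploidy``, ``segmental_cnv``, ``loh``, ``rdna``, ``mtdna``)
    and per-line observed data (variant calls, depth profile, marker
    table for hybrid lines).  With all event rates zero the observed
    tables contain no variants and flat depth (up to noise).
    """
    cfg = config
    truth_subs, truth_indels, truth_aneu = [], [], []
    truth_seg, truth_loh, truth_rdna, truth_mtdna = [], [], [], []
    lines: dict[str, LineData] = {}

    anc_rng = _line_rng(cfg.seed, "__ancestor__", "depth")
    ancestor_depth = simulate_depth(
        {c: 2 for c in cfg.genome.nuclear_chromosomes()},
        cfg, ploidy=2, rng=anc_rng,
        rdna_repeats=cfg.rdna_ancestor_repeats,
        mtdna_copy=cfg.mtdna_copy_number,
    )

    for line in cfg.design:
        if line.callable_sites <= 0:
            raise ValidationError(f"{line.line_id}: zero callable sites")
        gens = line.total_generations
        site_gens = line.callable_sites * line.ploidy * gens

        # --- substitutions ------------------------------------------
        rng = _line_rng(cfg.seed, line.line_id, "subs")
        n_subs = int(rng.poisson(cfg.sub_rate * site_gens))
        channels = list(cfg.spectrum96.keys())
        probs = np.array([cfg.spectrum96[c] for c in channels])
        probs = probs / probs.sum()
        positions = _sample_positions(rng, cfg.genome, n_subs)
        tags = _choose_degradations(rng, n_subs, cfg.degrade_fractions)
        calls: list[VariantCall] = []
        for (chrom, pos), tag in zip(positions, tags):
            ch, ref, alt, ctx = _sample_channel_bases(rng, channels, probs)
            qual, depth, fwd, rev = _observe_call(rng, cfg)
            call = VariantCall(
                line_id=line.line_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
                var_type="substitution", qual=qual, depth=depth,
                alt_fwd=fwd, alt_rev=rev, callers=frozenset({"A", "B"}),
            )
            if tag is not None:
                call = _degrade(rng, cfg, call, tag)
            calls.append(call)
            truth_subs.append({
                "line_id": line.line_id, "chrom": call.chrom, "pos": call.pos,
                "ref": ref, "alt": alt, "context": ctx, "channel": ch,
                "degraded_reason": tag or "",
            })

        # --- indels --------------------------------------------------
        rng = _line_rng(cfg.seed, line.line_id, "indels")
        n_ind = int(rng.poisson(cfg.indel_rate * site_gens))
        ind_pos = _sample_positions(rng, cfg.genome, n_ind)
        ind_tags = _choose_degradations(rng, n_ind, cfg.degrade_fractions)
        for (chrom, pos), (seq, var_type, f5, f3), tag in zip(
            ind_pos, _simulate_indel_seqs(rng, n_ind), ind_tags
        ):
            qual, depth, fwd, rev = _observe_call(rng, cfg)
            anchor = "A"
            ref, alt = (
                (anchor + seq, anchor) if var_type == "deletion" else (anchor, anchor + seq)
            )
            call = VariantCall(
                line_id=line.line_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
                var_type=var_type, qual=qual, depth=depth,
                alt_fwd=fwd, alt_rev=rev, callers=frozenset({"A", "B"}),
            )
            if tag is not None:
                call = _degrade(rng, cfg, call, tag)
            calls.append(call)
            truth_indels.append({
                "line_id": line.line_id, "chrom": call.chrom, "pos": call.pos,
                "seq": seq, "var_type": var_type,
                "flank_5p": f5, "flank_3p": f3,
                "degraded_reason": tag or "",
            })

        # --- karyotype, segmental CNV, depth ------------------------
        rng = _line_rng(cfg.seed, line.line_id, "cnv")
        karyotype, aneu_events = _simulate_karyotype(rng, cfg, line)
        for c, kind, delta in aneu_events:
            truth_aneu.append({
                "line_id": line.line_id, "chrom": c, "event": kind, "delta": delta,
            })
        seg_cnvs = _simulate_seg_cnvs(rng, cfg, line, karyotype)
        for c, s, e, cn in seg_cnvs:
            truth_seg.append({
                "line_id": line.line_id, "chrom": c, "start": s, "end": e,
                "copy_number": cn,
            })

        rdna_factor = (1.0 - cfg.rdna_contraction) ** gens
        rdna_repeats = cfg.rdna_ancestor_repeats * rdna_factor
        truth_rdna.append({
            "line_id": line.line_id, "repeats": rdna_repeats,
            "relative_to_ancestor": rdna_factor,
        })

        rng_mt = _line_rng(cfg.seed, line.line_id, "mtdna")
        u = rng_mt.random()
        mito_len = (
            cfg.genome.length_of(cfg.genome.mito_name)
            if cfg.genome.mito_name
            else 0
        )
        mt_copy: float = cfg.mtdna_copy_number
        mt_presence: tuple[int, int] | None = None
        if u < cfg.mtdna_loss_prob:
            mt_status = "lost"
            mt_copy = 0.0
        elif u < cfg.mtdna_loss_prob + cfg.mtdna_het_prob and mito_len:
            mt_status = "heteroplasmic"
            seg_len = int(rng_mt.uniform(0.05, 0.4) * mito_len)
            start = int(rng_mt.integers(1, mito_len - seg_len))
            mt_presence = (start, start + seg_len - 1)
        else:
            mt_status = "intact"
        truth_mtdna.append({
            "line_id": line.line_id, "status": mt_status,
            "copy_number": 0.0 if mt_status == "lost" else mt_copy,
            "presence_start": mt_presence[0] if mt_presence else 0,
            "presence_end": mt_presence[1] if mt_presence else 0,
        })

        rng_depth = _line_rng(cfg.seed, line.line_id, "depth")
        depth_profile = simulate_depth(
            karyotype, cfg, ploidy=line.ploidy, rng=rng_depth,
            seg_cnvs=seg_cnvs, rdna_repeats=rdna_repeats,
            mtdna_copy=mt_copy, mtdna_presence=mt_presence,
        )

        # --- LOH + markers (hybrids only) ----------------------------
        markers = None
        if _is_hybrid(line.background) and line.ploidy == 2:
            rng_loh = _line_rng(cfg.seed, line.line_id, "loh")
            loh_events = _simulate_loh_events(rng_loh, cfg, line, karyotype)
            for chrom, i0, i1, parent, cls in loh_events:
                marks = _marker_positions(cfg, chrom)
                truth_loh.append({
                    "line_id": line.line_id, "chrom": chrom,
                    "start": int(marks[i0]), "end": int(marks[i1]),
                    "n_markers": i1 - i0 + 1, "parent": parent, "class": cls,
                })
            markers = _simulate_markers(rng_loh, cfg, loh_events)

        lines[line.line_id] = LineData(
            line_id=line.line_id, variants=calls,
            depth=depth_profile, markers=markers,
        )

    def frame(rows, cols):
        return pd.DataFrame(rows, columns=cols)

    truth = {
        "substitutions": frame(truth_subs, [
            "line_id", "chrom", "pos", "ref", "alt", "context", "channel",
            "degraded_reason",
        ]),
        "indels": frame(truth_indels, [
            "line_id", "chrom", "pos", "seq", "var_type", "flank_5p",
            "flank_3p", "degraded_reason",
        ]),
        "aneuploidy": frame(truth_aneu, ["line_id", "chrom", "event", "delta"]),
        "segmental_cnv": frame(truth_seg, [
            "line_id", "chrom", "start", "end", "copy_number",
        ]),
        "loh": frame(truth_loh, [
            "line_id", "chrom", "start", "end", "n_markers", "parent", "class",
        ]),
        "rdna": frame(truth_rdna, ["line_id", "repeats", "relative_to_ancestor"]),
        "mtdna": frame(truth_mtdna, [
            "line_id", "status", "copy_number", "presence_start", "presence_end",
        ]),
    }
    return SimulationResult(
        config=cfg, truth=truth, lines=lines, ancestor_depth=ancestor_depth
    )


# ---------------------------------------------------------------------------
# On-disk layout


def write_simulation(result: SimulationResult, outdir) -> None:
    """Write a simulated dataset as the canonical TSV layout.

    ``design.tsv``, ``genome.yaml``, ``variants.tsv`` (all observed
    calls), ``ancestor_depth.tsv``, per-line ``depth/<line>.tsv`` and
    ``markers/<line>.tsv`` (hybrids), and ``truth_<table>.tsv``.
    """
    from pathlib import Path

    from .genome import (
        write_depth_profile,
        write_design,
        write_markers,
        write_variants,
    )

    out = Path(outdir)
    (out / "depth").mkdir(parents=True, exist_ok=True)
    (out / "markers").mkdir(exist_ok=True)
    write_design(result.config.design, out / "design.tsv")
    result.config.genome.to_yaml(out / "genome.yaml")
    all_calls = [c for ld in result.lines.values() for c in ld.variants]
    write_variants(all_calls, out / "variants.tsv")
    write_depth_profile(result.ancestor_depth, out / "ancestor_depth.tsv")
    for line_id, ld in result.lines.items():
        safe = line_id.replace("/", "_")
        write_depth_profile(ld.depth, out / "depth" / f"{safe}.tsv")
        if ld.markers is not None:
            write_markers(ld.markers, out / "markers" / f"{safe}.tsv")
    for name, df in result.truth.items():
        df.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Fluctuation cultures


def simulate_fluctuation(
    m: float, n_cultures: int, Nt: float, seed: int
) -> np.ndarray:
    """Mutant counts for parallel cultures under the Luria-Delbrück model.

    Mutation events per culture are Poisson(m); each event founds a
    clone whose final size follows the standard size distribution
    P(size = j) = 1 / (j (j + 1)) (sampled as floor(1/U)), capped at
    the final population size.
    """
    if m < 0:
        raise ValidationError("m must be >= 0")
    if n_cultures < 1:
        raise ValidationError("need at least one culture")
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_cultures, dtype=np.int64)
    n_events = rng.poisson(m, size=n_cultures)
    for i, k in enumerate(n_events):
        if k == 0:
            continue
        u = rng.random(k)
        sizes = np.minimum(np.floor(1.0 / u), Nt)
        counts[i] = int(sizes.sum())
    return counts
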