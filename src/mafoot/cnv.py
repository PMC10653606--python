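"""Coverage-based copy-number analysis.

Whole-chromosome copy number is the ploidy-scaled median of normalized
window depth, accepted only when the chromosome is internally
consistent (median close to an integer and most windows agreeing);
otherwise it is flagged mosaic/segmental.  Segmental CNVs are maximal
runs of windows rounding to a non-modal copy number.  rDNA copy number
is read from depth over the reference's collapsed single-repeat rDNA
locus, normalized to the ancestor; mitochondrial copy number from
three near repeat-free genes, with heteroplasmy scored as partial
window presence along the mitochondrial genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import DepthProfile, GenomeDef, Interval, ValidationError

__all__ = [
    "KaryotypeCall",
    "CnvSegment",
    "RdnaEstimate",
    "MtdnaEstimate",
    "call_chromosome_cn",
    "segment_cnv",
    "rdna_copy_number",
    "mtdna_estimate",
]


@dataclass(frozen=True)
class KaryotypeCall:
    """Integer copy number per chromosome plus gain/loss events."""

    copy_number: dict[str, int | None]  # None = mosaic/segmental, no call
    confidence: dict[str, float]  # fraction of windows rounding to the call
    events: tuple[tuple[str, str, int], ...]  # (chrom, gain|loss, delta)
    ploidy: int

    def cn(self, chrom: str) -> int | None:
        return self.copy_number.get(chrom)


@dataclass(frozen=True)
class CnvSegment:
    """A run of windows at a copy number different from the chromosome mode."""

    chrom: str
    start: int
    end: int
    copy_number: int
    n_windows: int
    breakpoint_up: tuple[int, int]  # interval between flanking windows
    breakpoint_down: tuple[int, int]


@dataclass(frozen=True)
class RdnaEstimate:
    """rDNA repeat copies relative to the ancestor."""

    per_sample: float
    per_chrXII: float


@dataclass(frozen=True)
class MtdnaEstimate:
    """Mitochondrial copy number and heteroplasmy summary."""

    copy_number: float
    presence_fraction: float
    retained_segments: tuple[tuple[int, int], ...]  # (start, end) bp
    status: str  # intact | heteroplasmic | lost


def _chrom_windows(
    profile: DepthProfile, genome: GenomeDef, chrom: str, drop_masked: bool = True
) -> np.ndarray:
    df = profile.on(chrom)
    if "norm_depth" not in df.columns:
        raise ValidationError("profile not normalized; run normalize_depth first")
    if drop_masked and (genome.repeat_mask or genome.rdna_locus is not None):
        mid = (df["start"] + df["end"]) // 2
        keep = [
            not genome.in_repeat_mask(chrom, int(p))
            and not (
                genome.rdna_locus is not None
                and genome.rdna_locus.contains(chrom, int(p))
            )
            for p in mid
        ]
        df = df[keep]
    return df["norm_depth"].to_numpy(dtype=float)


def call_chromosome_cn(
    profile: DepthProfile,
    genome: GenomeDef,
    ploidy: int = 2,
    min_windows: int = 20,
    round_margin: float = 0.2,
    consistency: float = 0.8,
) -> KaryotypeCall:
    """Call integer copy number per nuclear chromosome from window depth.

    A chromosome is called at cn = round(ploidy x median(norm_depth))
    only if the scaled median is within ``round_margin`` of that integer
    and at least ``consistency`` of windows round to it; otherwise its
    call is ``None`` (mosaic/segmental flag).  Repeat-masked and rDNA
    windows are excluded.  Gains/losses are reported relative to
    baseline ploidy.
    """
    copy_number: dict[str, int | None] = {}
    confidence: dict[str, float] = {}
    events: list[tuple[str, str, int]] = []
    for chrom in genome.nuclear_chromosomes():
        depths = _chrom_windows(profile, genome, chrom)
        if len(depths) < min_windows:
            raise ValidationError(
                f"{chrom}: {len(depths)} windows < required {min_windows}"
            )
        scaled = ploidy * np.median(depths)
        cn = int(round(scaled))
        per_window = np.round(ploidy * depths).astype(int)
        frac = float(np.mean(per_window == cn))
        if abs(scaled - cn) <= round_margin and frac >= consistency:
            copy_number[chrom] = cn
            confidence[chrom] = frac
            if cn > ploidy:
                events.append((chrom, "gain", cn - ploidy))
            elif cn < ploidy:
                events.append((chrom, "loss", ploidy - cn))
        else:
            copy_number[chrom] = None
            confidence[chrom] = frac
    return KaryotypeCall(
        copy_number=copy_number,
        confidence=confidence,
        events=tuple(events),
        ploidy=ploidy,
    )


def segment_cnv(
    profile: DepthProfile,
    genome: GenomeDef,
    ploidy: int = 2,
    min_windows: int = 10,
    merge_gap: int = 2,
) -> list[CnvSegment]:
    """Detect segmental CNVs as runs of discordant integer window copy number.

    Each window is rounded to cn = round(ploidy x norm_depth); maximal
    runs of identical cn different from the chromosome's modal cn, of
    length >= ``min_windows``, become segments.  Runs at the same cn
    separated by <= ``merge_gap`` discordant windows are merged.
    Breakpoints are reported at window resolution: the interval from
    the last position of the flanking window to the first position of
    the segment (and symmetrically downstream).
    """
    segments: list[CnvSegment] = []
    for chrom in genome.nuclear_chromosomes():
        df = profile.on(chrom)
        if df.empty:
            continue
        if "norm_depth" not in df.columns:
            raise ValidationError("profile not normalized")
        starts = df["start"].to_numpy(dtype=int)
        ends = df["end"].to_numpy(dtype=int)
        cn = np.round(ploidy * df["norm_depth"].to_numpy(dtype=float)).astype(int)
        vals, counts = np.unique(cn, return_counts=True)
        modal = int(vals[np.argmax(counts)])
        # raw runs of non-modal cn
        runs: list[tuple[int, int, int]] = []  # (i0, i1 inclusive, cn)
        i = 0
        n = len(cn)
        while i < n:
            if cn[i] != modal:
                j = i
                while j + 1 < n and cn[j + 1] == cn[i]:
                    j += 1
                runs.append((i, j, int(cn[i])))
                i = j + 1
            else:
                i += 1
        # merge same-cn runs separated by few discordant windows
        merged: list[tuple[int, int, int]] = []
        for run in runs:
            if (
                merged
                and merged[-1][2] == run[2]
                and run[0] - merged[-1][1] - 1 <= merge_gap
            ):
                prev = merged.pop()
                merged.append((prev[0], run[1], run[2]))
            else:
                merged.append(run)
        for i0, i1, c in merged:
            nwin = i1 - i0 + 1
            if nwin < min_windows:
                continue
            up = (ends[i0 - 1] if i0 > 0 else 1, starts[i0])
            down = (ends[i1], starts[i1 + 1] if i1 + 1 < n else genome.length_of(chrom))
            segments.append(
                CnvSegment(
                    chrom=chrom,
                    start=int(starts[i0]),
                    end=int(ends[i1]),
                    copy_number=c,
                    n_windows=nwin,
                    breakpoint_up=(int(up[0]), int(up[1])),
                    breakpoint_down=(int(down[0]), int(down[1])),
                )
            )
    return segments


def _rdna_mean(profile: DepthProfile, locus: Interval) -> float:
    df = profile.on(locus.chrom)
    mid = (df["start"] + df["end"]) // 2
    sel = df[(mid >= locus.start) & (mid <= locus.end)]
    if sel.empty:
        raise ValidationError("no depth windows over the rDNA locus")
    return float(sel["norm_depth"].mean())


def rdna_copy_number(
    profile: DepthProfile,
    ancestor_profile: DepthProfile,
    genome: GenomeDef,
    chrXII_cn: int,
    ploidy: int = 2,
) -> RdnaEstimate:
    """rDNA copies relative to the ancestor, per sample and per chromosome.

    Depth over the collapsed single-repeat rDNA locus measures total
    repeat content; dividing by the ancestor's value gives the
    per-sample relative copy number, and rescaling by ploidy over the
    called chromosome XII copy number gives repeats per chromosome.
    """
    if genome.rdna_locus is None:
        raise ValidationError("genome has no rDNA locus defined")
    if chrXII_cn < 1:
        raise ValidationError("chromosome XII copy number must be >= 1")
    anc = _rdna_mean(ancestor_profile, genome.rdna_locus)
    if anc <= 0:
        raise ValidationError("ancestor rDNA depth is zero")
    per_sample = _rdna_mean(profile, genome.rdna_locus) / anc
    per_chr = per_sample * ploidy / chrXII_cn
    return RdnaEstimate(per_sample=per_sample, per_chrXII=per_chr)


def mtdna_estimate(
    profile: DepthProfile,
    genome: GenomeDef,
    gene_intervals: dict[str, Interval],
    present_threshold: float = 0.1,
    lost_threshold: float = 0.05,
) -> MtdnaEstimate:
    """Mitochondrial copy number and heteroplasmy from windowed depth.

    Copy number is the mean normalized depth over the supplied near
    repeat-free genes (ATP6/COX2/COX3 by convention).  Heteroplasmy is
    scored on the full mitochondrial profile: a window is "present" if
    its normalized depth is at least ``present_threshold``; the genome
    is ``lost`` if the present fraction is below ``lost_threshold``,
    ``heteroplasmic`` below 0.95, else ``intact``.  Retained segments
    are maximal runs of present windows, in bp.
    """
    if genome.mito_name is None:
        raise ValidationError("genome has no mitochondrial sequence")
    mito = profile.on(genome.mito_name)
    if mito.empty:
        raise ValidationError("no mitochondrial depth windows")
    if "norm_depth" not in mito.columns:
        raise ValidationError("profile not normalized")
    gene_depths = []
    mid = (mito["start"] + mito["end"]) // 2
    for name, iv in gene_intervals.items():
        if iv.chrom != genome.mito_name:
            raise ValidationError(f"gene {name} not on the mitochondrial sequence")
        sel = mito[(mid >= iv.start) & (mid <= iv.end)]
        if sel.empty:
            raise ValidationError(f"no depth windows over gene {name}")
        gene_depths.append(sel["norm_depth"].to_numpy(dtype=float))
    copy_number = float(np.mean(np.concatenate(gene_depths)))

    present = (mito["norm_depth"] >= present_threshold).to_numpy()
    presence_fraction = float(np.mean(present))
    starts = mito["start"].to_numpy(dtype=int)
    ends = mito["end"].to_numpy(dtype=int)
    segments: list[tuple[int, int]] = []
    i = 0
    while i < len(present):
        if present[i]:
            j = i
            while j + 1 < len(present) and present[j + 1]:
                j += 1
            segments.append((int(starts[i]), int(ends[j])))
            i = j + 1
        else:
            i += 1
    if presence_fraction < lost_threshold:
        status = "lost"
    elif presence_fraction < 0.95:
        status = "heteroplasmic"
    else:
        status = "intact"
    return MtdnaEstimate(
        copy_number=copy_number,
        presence_fraction=presence_fraction,
        retained_segments=tuple(segments),
        status=status,
    )
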