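"""Genome model and table input/output.

All coordinates in this package are 1-based and inclusive on both ends.
BED input (0-based, half-open) is converted at the parsing boundary.
Tab-separated tables with a header row are the canonical interchange
format; the column names used by each reader/writer are module constants
so that round-trips are exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Interval",
    "GenomeDef",
    "MALine",
    "MALDesign",
    "VariantCall",
    "DepthProfile",
    "MarkerTable",
    "FormatError",
    "ValidationError",
    "read_variants",
    "write_variants",
    "read_depth_windows",
    "write_depth_profile",
    "read_markers",
    "write_markers",
    "read_design",
    "write_design",
    "normalize_depth",
]

VARIANT_COLUMNS = [
    "line_id", "chrom", "pos", "ref", "alt", "var_type", "qual",
    "depth", "alt_fwd", "alt_rev", "callers", "in_ancestor",
]
DEPTH_COLUMNS = ["chrom", "start", "end", "raw_depth"]
MARKER_COLUMNS = ["chrom", "pos", "allele_p1", "allele_p2", "depth_p1", "depth_p2"]
DESIGN_COLUMNS = [
    "line_id", "background", "condition", "n_bottlenecks",
    "gens_per_bottleneck", "callable_sites", "ploidy",
]


class FormatError(ValueError):
    """A table or file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


@dataclass(frozen=True, order=True)
class Interval:
    """Closed genomic interval [start, end], 1-based."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"bad interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def _merge_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Sort and merge overlapping/adjacent intervals per chromosome."""
    out: list[Interval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + 1:
            prev = out.pop()
            out.append(Interval(prev.chrom, prev.start, max(prev.end, iv.end)))
        else:
            out.append(iv)
    return tuple(out)


@dataclass(frozen=True)
class GenomeDef:
    """Reference genome layout used by every downstream stage.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs; nuclear chromosomes plus,
        optionally, the mitochondrial sequence named by ``mito_name``.
    centromeres
        Centromere midpoint per nuclear chromosome (bp), optional.
    rdna_locus
        The ribosomal-DNA array collapsed to a single repeat unit, as an
        interval on one chromosome.  Depth over this interval measures
        repeat copy number.
    mito_name
        Name of the mitochondrial sequence, or ``None`` if absent.
    repeat_mask
        Intervals excluded from variant calling and depth medians
        (telomeres, Ty elements, ...).  Normalized to a sorted,
        non-overlapping tuple.
    cds_annotation
        Optional coding intervals as ``(chrom, start, end, strand)``
        with strand in {"+", "-"}.
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromeres: dict[str, int] = field(default_factory=dict)
    rdna_locus: Interval | None = None
    mito_name: str | None = None
    repeat_mask: tuple[Interval, ...] = ()
    cds_annotation: tuple[tuple[str, int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValidationError("genome needs at least one chromosome")
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ValidationError("duplicate chromosome names")
        for name, ln in self.chromosomes:
            if ln <= 0:
                raise ValidationError(f"chromosome {name} has length {ln}")
        for chrom, pos in self.centromeres.items():
            if not 1 <= pos <= lengths.get(chrom, 0):
                raise ValidationError(f"centromere outside {chrom}")
        for iv in self.repeat_mask:
            if iv.chrom not in lengths or iv.end > lengths[iv.chrom]:
                raise ValidationError(f"mask interval outside genome: {iv}")
        if self.rdna_locus is not None:
            iv = self.rdna_locus
            if iv.chrom not in lengths or iv.end > lengths[iv.chrom]:
                raise ValidationError("rDNA locus outside genome")
        if self.mito_name is not None and self.mito_name not in lengths:
            raise ValidationError(f"mito sequence {self.mito_name!r} not in genome")
        object.__setattr__(self, "repeat_mask", _merge_intervals(self.repeat_mask))

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def nuclear_chromosomes(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes if n != self.mito_name)

    @property
    def nuclear_length(self) -> int:
        return sum(ln for n, ln in self.chromosomes if n != self.mito_name)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def in_repeat_mask(self, chrom: str, pos: int) -> bool:
        return any(iv.contains(chrom, pos) for iv in self.repeat_mask)

    def validate_position(self, chrom: str, pos: int) -> None:
        if not 1 <= pos <= self.length_of(chrom):
            raise ValidationError(f"position {chrom}:{pos} outside chromosome")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {
            "chromosomes": [[n, int(ln)] for n, ln in self.chromosomes],
            "centromeres": {k: int(v) for k, v in self.centromeres.items()},
            "mito_name": self.mito_name,
            "repeat_mask": [[iv.chrom, iv.start, iv.end] for iv in self.repeat_mask],
            "cds_annotation": [list(t) for t in self.cds_annotation],
        }
        if self.rdna_locus is not None:
            iv = self.rdna_locus
            d["rdna_locus"] = [iv.chrom, iv.start, iv.end]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeDef":
        rdna = d.get("rdna_locus")
        return cls(
            chromosomes=tuple((str(n), int(ln)) for n, ln in d["chromosomes"]),
            centromeres={str(k): int(v) for k, v in d.get("centromeres", {}).items()},
            rdna_locus=Interval(rdna[0], int(rdna[1]), int(rdna[2])) if rdna else None,
            mito_name=d.get("mito_name"),
            repeat_mask=tuple(
                Interval(c, int(s), int(e)) for c, s, e in d.get("repeat_mask", [])
            ),
            cds_annotation=tuple(
                (str(c), int(s), int(e), str(st))
                for c, s, e, st in d.get("cds_annotation", [])
            ),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenomeDef":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class MALine:
    """One mutation-accumulation line ("strain-condition-replicate")."""

    line_id: str
    background: str
    condition: str
    n_bottlenecks: int
    gens_per_bottleneck: float
    callable_sites: int
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.gens_per_bottleneck <= 0:
            raise ValidationError("gens_per_bottleneck must be > 0")
        if self.ploidy < 1:
            raise ValidationError("ploidy must be >= 1")
        if self.n_bottlenecks < 0 or self.callable_sites < 0:
            raise ValidationError("negative design quantity")

    @property
    def total_generations(self) -> float:
        g = self.n_bottlenecks * self.gens_per_bottleneck
        return float(g)


@dataclass(frozen=True)
class MALDesign:
    """The full MA experiment: a set of lines with unique identifiers."""

    lines: tuple[MALine, ...]

    def __post_init__(self) -> None:
        ids = [ln.line_id for ln in self.lines]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate line_id in design")

    def __iter__(self):
        return iter(self.lines)

    def __len__(self) -> int:
        return len(self.lines)

    def by_condition(self, condition: str) -> tuple[MALine, ...]:
        return tuple(ln for ln in self.lines if ln.condition == condition)

    def conditions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for ln in self.lines:
            if ln.condition not in seen:
                seen.append(ln.condition)
        return tuple(seen)


@dataclass(frozen=True)
class VariantCall:
    """One called substitution or small INDEL with caller metadata."""

    line_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    var_type: str  # substitution | insertion | deletion
    qual: float
    depth: int
    alt_fwd: int
    alt_rev: int
    callers: frozenset[str]
    in_ancestor: bool = False

    def __post_init__(self) -> None:
        if self.var_type not in ("substitution", "insertion", "deletion"):
            raise ValidationError(f"bad var_type {self.var_type!r}")
        if not self.ref or not self.alt:
            raise ValidationError("empty allele")
        if self.var_type == "substitution" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValidationError("substitution alleles must be single bases")
        if self.pos < 1:
            raise ValidationError("pos must be >= 1")
        if self.depth < 0 or self.alt_fwd < 0 or self.alt_rev < 0:
            raise ValidationError("negative read count")
        if self.alt_fwd + self.alt_rev > self.depth:
            raise ValidationError(
                f"alt support {self.alt_fwd}+{self.alt_rev} exceeds depth {self.depth} "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def alt_support(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


@dataclass
class DepthProfile:
    """Windowed sequencing depth, raw and normalized to the nuclear median.

    Backed by a DataFrame with columns chrom, start, end, raw_depth and
    (after :func:`normalize_depth`) norm_depth.  Windows are sorted and
    non-overlapping within each chromosome.
    """

    windows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DEPTH_COLUMNS if c not in self.windows.columns]
        if missing:
            raise FormatError(f"depth table missing columns: {missing}")
        w = self.windows.reset_index(drop=True)
        if (w["raw_depth"] < 0).any():
            raise ValidationError("negative raw depth")
        if "norm_depth" in w.columns and (w["norm_depth"].dropna() < 0).any():
            raise ValidationError("negative normalized depth")
        for chrom, grp in w.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (ends < starts).any():
                raise ValidationError(f"window end < start on {chrom}")
            if len(grp) > 1 and not (starts[1:] > ends[:-1]).all():
                raise ValidationError(f"overlapping or unsorted windows on {chrom}")
        self.windows = w

    def on(self, chrom: str) -> pd.DataFrame:
        return self.windows[self.windows["chrom"] == chrom]

    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.windows["chrom"].unique())


@dataclass
class MarkerTable:
    """Heterozygous parental markers with per-parent allele depths."""

    markers: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing:
            raise FormatError(f"marker table missing columns: {missing}")
        m = self.markers.reset_index(drop=True)
        if (m["depth_p1"] < 0).any() or (m["depth_p2"] < 0).any():
            raise ValidationError("negative marker depth")
        if (m["allele_p1"] == m["allele_p2"]).any():
            raise ValidationError("marker with identical parental alleles")
        for chrom, grp in m.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValidationError(f"marker positions not increasing on {chrom}")
        self.markers = m

    def on(self, chrom: str) -> pd.DataFrame:
        return self.markers[self.markers["chrom"] == chrom]

    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.markers["chrom"].unique())


# ---------------------------------------------------------------------------
# Variant table I/O


def _variant_from_row(row: dict, genome: GenomeDef | None) -> VariantCall:
    callers = frozenset(
        c for c in str(row["callers"]).split(",") if c and c != "nan"
    )
    call = VariantCall(
        line_id=str(row["line_id"]),
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        var_type=str(row["var_type"]),
        qual=float(row["qual"]),
        depth=int(row["depth"]),
        alt_fwd=int(row["alt_fwd"]),
        alt_rev=int(row["alt_rev"]),
        callers=callers,
        in_ancestor=_parse_bool(row["in_ancestor"]),
    )
    if genome is not None:
        genome.validate_position(call.chrom, call.pos)
    return call


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", ""):
        return False
    raise FormatError(f"cannot parse boolean {x!r}")


def read_variants(
    path: str | Path,
    format: str = "tsv",
    genome: GenomeDef | None = None,
    line_id: str | None = None,
    callers: Sequence[str] | None = None,
    strand_fields: tuple[str, str] = ("SAF", "SAR"),
) -> list[VariantCall]:
    """Read a variant table from TSV (canonical) or VCF.

    Records failing validation raise; nothing is silently dropped.  For
    VCF, quality comes from QUAL, depth from INFO/DP, strand-specific
    alt support from the INFO fields named by ``strand_fields``, and
    caller provenance from INFO/CALLERS (comma-separated) or, failing
    that, the ``callers`` argument supplied per file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"variant table missing columns: {missing}")
        return [_variant_from_row(row, genome) for row in df.to_dict("records")]
    if format == "vcf":
        return _read_vcf(path, genome, line_id, callers, strand_fields)
    raise FormatError(f"unknown variant format {format!r}")


def _read_vcf(path, genome, line_id, callers, strand_fields):
    from cyvcf2 import VCF

    saf, sar = strand_fields
    out: list[VariantCall] = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            if rec.QUAL is None:
                raise FormatError(f"VCF record without QUAL at {rec.CHROM}:{rec.POS}")
            depth = rec.INFO.get("DP")
            if depth is None:
                raise FormatError(f"VCF record without INFO/DP at {rec.CHROM}:{rec.POS}")
            fwd = rec.INFO.get(saf)
            rev = rec.INFO.get(sar)
            if fwd is None or rev is None:
                raise FormatError(
                    f"VCF record without strand counts {saf}/{sar} at {rec.CHROM}:{rec.POS}"
                )
            fwd = int(fwd[0] if isinstance(fwd, tuple) else fwd)
            rev = int(rev[0] if isinstance(rev, tuple) else rev)
            caller_info = rec.INFO.get("CALLERS")
            caller_set = (
                frozenset(str(caller_info).split(","))
                if caller_info is not None
                else frozenset(callers or ())
            )
            if len(rec.ALT) != 1:
                raise FormatError(
                    f"multi-allelic record at {rec.CHROM}:{rec.POS}; split before reading"
                )
            ref, alt = rec.REF, rec.ALT[0]
            if len(ref) == 1 and len(alt) == 1:
                var_type = "substitution"
            elif len(alt) > len(ref):
                var_type = "insertion"
            else:
                var_type = "deletion"
            call = VariantCall(
                line_id=line_id or "sample",
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=ref,
                alt=alt,
                var_type=var_type,
                qual=float(rec.QUAL),
                depth=int(depth),
                alt_fwd=fwd,
                alt_rev=rev,
                callers=caller_set,
                in_ancestor=bool(rec.INFO.get("ANCESTRAL") is not None),
            )
            if genome is not None:
                genome.validate_position(call.chrom, call.pos)
            out.append(call)
    finally:
        vcf.close()
    return out


def write_variants(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls as the canonical TSV (column order fixed)."""
    rows = []
    for c in calls:
        d = dataclasses.asdict(c)
        d["callers"] = ",".join(sorted(c.callers))
        d["in_ancestor"] = str(c.in_ancestor).lower()
        rows.append(d)
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Depth / marker / design table I/O


def read_depth_windows(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read raw depth windows from TSV (1-based) or BED-like (0-based).

    Returns a DataFrame with the canonical 1-based inclusive columns.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in DEPTH_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"depth table missing columns: {missing}")
        return df[list(dict.fromkeys(DEPTH_COLUMNS + [c for c in df.columns if c in ("norm_depth",)]))]
    if format == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "raw_depth"],
        )
        df["start"] = df["start"] + 1  # BED 0-based half-open -> 1-based inclusive
        return df
    raise FormatError(f"unknown depth format {format!r}")


def write_depth_profile(profile: DepthProfile, path: str | Path) -> None:
    profile.windows.to_csv(path, sep="\t", index=False)


def read_markers(path: str | Path) -> MarkerTable:
    df = pd.read_csv(path, sep="\t", dtype={"allele_p1": str, "allele_p2": str})
    return MarkerTable(df)


def write_markers(table: MarkerTable, path: str | Path) -> None:
    table.markers.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> MALDesign:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"design table missing columns: {missing}")
    lines = tuple(
        MALine(
            line_id=str(r["line_id"]),
            background=str(r["background"]),
            condition=str(r["condition"]),
            n_bottlenecks=int(r["n_bottlenecks"]),
            gens_per_bottleneck=float(r["gens_per_bottleneck"]),
            callable_sites=int(r["callable_sites"]),
            ploidy=int(r["ploidy"]),
        )
        for r in df.to_dict("records")
    )
    return MALDesign(lines)


def write_design(design: MALDesign, path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(ln) for ln in design.lines])
    df[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Depth normalization


def normalize_depth(raw_windows: pd.DataFrame, genome: GenomeDef) -> DepthProfile:
    """Normalize windowed depth to the genome-wide nuclear median.

    The median is computed once per sample over nuclear windows whose
    midpoint is outside the repeat mask; every window (nuclear and
    mitochondrial) is then divided by it, so mitochondrial copy number
    reads directly as a multiple of nuclear coverage.
    """
    df = raw_windows.copy().reset_index(drop=True)
    missing = [c for c in DEPTH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"depth table missing columns: {missing}")
    nuclear = df["chrom"] != genome.mito_name if genome.mito_name else pd.Series(True, index=df.index)
    mid = (df["start"] + df["end"]) // 2
    masked = pd.Series(
        [genome.in_repeat_mask(c, int(p)) for c, p in zip(df["chrom"], mid)],
        index=df.index,
    )
    if genome.rdna_locus is not None:
        in_rdna = pd.Series(
            [genome.rdna_locus.contains(c, int(p)) for c, p in zip(df["chrom"], mid)],
            index=df.index,
        )
        masked = masked | in_rdna
    ref = df.loc[nuclear & ~masked, "raw_depth"]
    if ref.empty or not (ref > 0).any():
        raise ValidationError("no positive nuclear depth to normalize against")
    med = float(ref.median())
    if med <= 0:
        raise ValidationError("nuclear median depth is zero")
    df["norm_depth"] = df["raw_depth"] / med
    return DepthProfile(df)
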