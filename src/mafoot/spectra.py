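"""Mutation spectra: six-class and trinucleotide (96-channel) substitution
classification, the 83-channel small-indel scheme, and summary ratios.

Substitutions are reported in the pyrimidine convention: a change whose
reference base is a purine is reverse-complemented (together with its
context) so that every channel has reference C or T.  The 96 channels
are the 6 pyrimidine classes x 16 flanking-base combinations, keyed
like ``"A[C>T]G"``.

Small indels use the standard 83-channel scheme: 1-bp indels by base
(C/T after pyrimidine collapse) and homopolymer run length; longer
indels by repeat-unit length and repeat count; deletions at non-repeat
junctions with flanking microhomology by microhomology length.
Channel keys follow the ``"1:Del:T:4"`` style, where the final number
counts repeat units of the indel motif *in addition to* the event
itself (so a single T deleted from a TTTT run is ``1:Del:T:3``) and,
for M channels, the microhomology length.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SIX_CLASSES",
    "SBS96_CHANNELS",
    "ID83_CHANNELS",
    "SpectrumCounts",
    "classify_substitution",
    "classify_indel",
    "ts_tv",
    "gc_at_bias",
    "cosine_similarity",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{cls}]{three}"
    for cls in SIX_CLASSES
    for five in "ACGT"
    for three in "ACGT"
)


def _id83_channels() -> tuple[str, ...]:
    chans: list[str] = []
    for base in ("C", "T"):
        chans += [f"1:Del:{base}:{n}" for n in range(6)]
    for base in ("C", "T"):
        chans += [f"1:Ins:{base}:{n}" for n in range(6)]
    for ln in (2, 3, 4, 5):
        chans += [f"{ln}:Del:R:{n}" for n in range(6)]
    for ln in (2, 3, 4, 5):
        chans += [f"{ln}:Ins:R:{n}" for n in range(6)]
    for ln, max_mh in ((2, 1), (3, 2), (4, 3), (5, 5)):
        chans += [f"{ln}:Del:M:{m}" for m in range(1, max_mh + 1)]
    return tuple(chans)


ID83_CHANNELS: tuple[str, ...] = _id83_channels()
assert len(ID83_CHANNELS) == 83


def _revcomp(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as e:
        raise ValueError(f"ambiguous base {e.args[0]!r}") from None


def classify_substitution(ref: str, alt: str, context: str) -> tuple[str, str]:
    """Classify a single-base substitution.

    Parameters
    ----------
    ref, alt
        Single reference/alternate bases (A/C/G/T), distinct.
    context
        The trinucleotide centered on the site, reference strand; its
        middle base must equal ``ref``.

    Returns
    -------
    (six_class, channel96)
        e.g. ``("C>T", "A[C>T]A")``.  Purine-reference changes are
        reverse-complemented to the pyrimidine convention.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not center on ref {ref!r}")
    for b in ref + alt + context:
        if b not in "ACGT":
            raise ValueError(f"ambiguous base {b!r}")
    if ref in "AG":  # purine reference: flip to the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = _revcomp(context)
    cls = f"{ref}>{alt}"
    return cls, f"{context[0]}[{cls}]{context[2]}"


def _adjacent_repeats(seq: str, flank_5p: str, flank_3p: str) -> int:
    """Copies of ``seq`` tiled immediately upstream plus downstream."""
    n = 0
    k = len(seq)
    i = 0
    while flank_3p[i : i + k] == seq and len(flank_3p) >= i + k:
        n += 1
        i += k
    i = len(flank_5p)
    while i - k >= 0 and flank_5p[i - k : i] == seq:
        n += 1
        i -= k
    return n


def _microhomology(seq: str, flank_5p: str, flank_3p: str) -> int:
    """Longest partial match of the deleted sequence at either junction."""
    k = len(seq)
    mh_down = 0
    for m in range(k - 1, 0, -1):
        if flank_3p[:m] == seq[:m]:
            mh_down = m
            break
    mh_up = 0
    for m in range(k - 1, 0, -1):
        if flank_5p[-m:] == seq[-m:] and len(flank_5p) >= m:
            mh_up = m
            break
    return max(mh_down, mh_up)


def classify_indel(
    seq: str, var_type: str, flank_5p: str, flank_3p: str
) -> str:
    """Classify a small insertion/deletion into its 83-channel key.

    Parameters
    ----------
    seq
        The inserted or deleted bases (no anchor base).
    var_type
        ``"insertion"`` or ``"deletion"``.
    flank_5p, flank_3p
        Reference sequence immediately up/downstream of the event
        (the deleted bases themselves excluded); >= 25 bp recommended
        so repeat counts are not truncated.
    """
    seq = seq.upper()
    flank_5p, flank_3p = flank_5p.upper(), flank_3p.upper()
    if var_type not in ("insertion", "deletion"):
        raise ValueError(f"bad indel type {var_type!r}")
    if not seq or any(b not in "ACGT" for b in seq + flank_5p + flank_3p):
        raise ValueError("indel/flank sequence must be non-empty A/C/G/T")
    if not flank_5p or not flank_3p:
        raise ValueError("flanking context unavailable")
    op = "Ins" if var_type == "insertion" else "Del"
    n_rep = _adjacent_repeats(seq, flank_5p, flank_3p)
    if len(seq) == 1:
        base = seq if seq in "CT" else _COMPLEMENT[seq]
        return f"1:{op}:{base}:{min(n_rep, 5)}"
    ln = min(len(seq), 5)
    if op == "Del" and n_rep == 0:
        mh = _microhomology(seq, flank_5p, flank_3p)
        if mh >= 1:
            cap = 5 if ln == 5 else ln - 1
            return f"{ln}:Del:M:{min(mh, cap)}"
    return f"{ln}:{op}:R:{min(n_rep, 5)}"


@dataclass
class SpectrumCounts:
    """Counts of substitutions by six-class and 96-channel context.

    The two tabulations always agree: six-class counts are the channel
    counts marginalized over context.
    """

    context96: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.context96) - set(SBS96_CHANNELS)
        if bad:
            raise ValueError(f"unknown channels: {sorted(bad)[:3]}...")
        self.context96 = {
            ch: int(self.context96.get(ch, 0)) for ch in SBS96_CHANNELS
        }
        if any(v < 0 for v in self.context96.values()):
            raise ValueError("negative channel count")

    @classmethod
    def from_substitutions(
        cls, subs: Iterable[tuple[str, str, str]]
    ) -> "SpectrumCounts":
        """Tabulate ``(ref, alt, trinucleotide_context)`` triples."""
        counts: Counter[str] = Counter()
        for ref, alt, ctx in subs:
            _, chan = classify_substitution(ref, alt, ctx)
            counts[chan] += 1
        return cls(dict(counts))

    @property
    def six_class(self) -> dict[str, int]:
        out = {c: 0 for c in SIX_CLASSES}
        for chan, n in self.context96.items():
            out[chan[2:5]] += n
        return out

    @property
    def total(self) -> int:
        return sum(self.context96.values())

    def as_vector(self) -> np.ndarray:
        return np.array([self.context96[ch] for ch in SBS96_CHANNELS], dtype=float)

    def fractions(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            raise ValueError("empty spectrum")
        return {c: n / tot for c, n in self.six_class.items()}


def ts_tv(spec: SpectrumCounts) -> float:
    """Transition/transversion ratio; 0.5 when all six classes are equal."""
    six = spec.six_class
    ts = six["C>T"] + six["T>C"]
    tv = six["C>A"] + six["C>G"] + six["T>A"] + six["T>G"]
    if tv == 0:
        raise ZeroDivisionError("no transversions: Ts/Tv undefined")
    return ts / tv


def gc_at_bias(spec: SpectrumCounts) -> float:
    """Ratio of GC-to-AT over AT-to-GC substitution counts."""
    six = spec.six_class
    gc_at = six["C>T"] + six["C>A"]
    at_gc = six["T>C"] + six["T>G"]
    if at_gc == 0:
        raise ZeroDivisionError("no AT-to-GC changes: bias undefined")
    return gc_at / at_gc


def cosine_similarity(a: np.ndarray | Mapping[str, float], b: np.ndarray | Mapping[str, float]) -> float:
    """Cosine similarity between two spectra (vectors or channel maps)."""
    if isinstance(a, Mapping):
        a = np.array([a.get(ch, 0.0) for ch in SBS96_CHANNELS])
    if isinstance(b, Mapping):
        b = np.array([b.get(ch, 0.0) for ch in SBS96_CHANNELS])
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm spectrum")
    return float(np.dot(a, b) / (na * nb))
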