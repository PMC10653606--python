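"""Acceptance criteria for called substitutions and small INDELs.

A call passes only if every criterion holds:

* called by at least two independent callers;
* quality score strictly greater than 50;
* sequencing depth strictly greater than 10;
* at least 6 alt-supporting reads, with at least one on each strand;
* outside repeat-masked regions (telomeres included in the mask);
* absent from the ancestor of its line.

Thresholds are strict inequalities (qual = 50 fails, depth = 10
fails).  The "6 reads" requirement counts alt-supporting reads — the
minimal literal reading — not total depth.  Verdicts carry one reason
code per violated rule so filter behaviour is auditable per record;
the filter never raises on a failing record.  INDELs are filtered
with the same thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome import GenomeDef, VariantCall

__all__ = ["FilterVerdict", "FILTER_REASONS", "filter_substitutions", "filter_indels"]

FILTER_REASONS = (
    "single_caller",
    "low_qual",
    "low_depth",
    "low_support",
    "one_strand",
    "repeat_region",
    "ancestral",
)

MIN_CALLERS = 2
MIN_QUAL = 50.0  # strict: must be > 50
MIN_DEPTH = 10  # strict: must be > 10
MIN_ALT_SUPPORT = 6  # >= 6 alt reads, both strands represented


@dataclass(frozen=True)
class FilterVerdict:
    """Per-record outcome: passes iff no reason codes accrued."""

    variant: VariantCall
    reasons: frozenset[str]

    @property
    def passed(self) -> bool:
        return not self.reasons


def _verdict(
    call: VariantCall,
    ancestor_keys: set[tuple[str, int, str]],
    genome: GenomeDef | None,
) -> FilterVerdict:
    reasons: set[str] = set()
    if len(call.callers) < MIN_CALLERS:
        reasons.add("single_caller")
    if not call.qual > MIN_QUAL:
        reasons.add("low_qual")
    if not call.depth > MIN_DEPTH:
        reasons.add("low_depth")
    if call.alt_support < MIN_ALT_SUPPORT:
        reasons.add("low_support")
    if call.alt_fwd < 1 or call.alt_rev < 1:
        reasons.add("one_strand")
    if genome is not None and genome.in_repeat_mask(call.chrom, call.pos):
        reasons.add("repeat_region")
    if call.in_ancestor or call.key in ancestor_keys:
        reasons.add("ancestral")
    return FilterVerdict(variant=call, reasons=frozenset(reasons))


def filter_substitutions(
    calls: Iterable[VariantCall],
    ancestor_calls: Sequence[VariantCall] = (),
    genome: GenomeDef | None = None,
) -> list[FilterVerdict]:
    """Apply all substitution acceptance criteria; one verdict per call.

    ``ancestor_calls`` are matched by (chrom, pos, alt).  Passing the
    genome enables the repeat-mask criterion; without it the mask rule
    cannot fire.  Order-independent and idempotent: verdicts depend
    only on the individual record and the ancestor key set.
    """
    ancestor_keys = {c.key for c in ancestor_calls}
    return [_verdict(c, ancestor_keys, genome) for c in calls]


# INDELs share thresholds with substitutions: the calling criteria are
# stated for substitutions only, and extending them unchanged is the
# most conservative uniform choice.
filter_indels = filter_substitutions
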