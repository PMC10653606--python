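"""Apply the substitution acceptance criteria to a toy call set.

A call passes only with dual-caller support, quality > 50, depth > 10,
>= 6 alt reads on both strands, outside repeats, absent in ancestor.
"""

from mafoot.filters import filter_substitutions
from mafoot.genome import VariantCall


def call(pos, **kw):
    base = dict(line_id="NA/WE-HU-1", chrom="chr1", pos=pos, ref="C", alt="T",
                var_type="substitution", qual=300.0, depth=90, alt_fwd=25,
                alt_rev=27, callers=frozenset({"freebayes", "samtools"}))
    base.update(kw)
    return VariantCall(**base)


calls = [
    call(1000),                                   # clean
    call(2000, qual=50.0),                        # boundary quality fails
    call(3000, callers=frozenset({"freebayes"})),  # one caller only
    call(4000, alt_fwd=8, alt_rev=0),             # all support on one strand
    call(5000, depth=10, alt_fwd=4, alt_rev=4),   # depth at the boundary
]
for verdict in filter_substitutions(calls):
    status = "PASS" if verdict.passed else "fail: " + ",".join(sorted(verdict.reasons))
    print(f"pos {verdict.variant.pos}: {status}")
# Only the first record passes; each of the others trips exactly the
# criterion it was constructed to violate (boundaries are exclusive).
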