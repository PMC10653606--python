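"""Statistical tests and expectation calculations for MA-line analyses.

Includes the spectrum-weighted expectation for the fraction of
non-synonymous / genic substitutions under neutrality, an exact 2x2
test of observed against expected functional fractions, rank-sum group
comparisons, and a Monte-Carlo test for whether several events
co-occurring in one line is compatible with independent placement.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .spectra import SBS96_CHANNELS, classify_substitution

__all__ = [
    "expected_functional_fractions",
    "neutrality_test",
    "compare_groups",
    "cooccurrence_test",
    "benjamini_hochberg",
]

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def _spectrum_weights(spectrum96) -> dict[str, float]:
    if isinstance(spectrum96, Mapping):
        w = {ch: float(spectrum96.get(ch, 0.0)) for ch in SBS96_CHANNELS}
    else:
        vec = np.asarray(spectrum96, dtype=float)
        if vec.shape != (96,):
            raise ValueError("spectrum96 must have 96 entries")
        w = dict(zip(SBS96_CHANNELS, vec))
    tot = sum(w.values())
    if tot <= 0:
        raise ValueError("spectrum weights must have positive mass")
    return {k: v / tot for k, v in w.items()}


def expected_functional_fractions(
    cds_annotation: Sequence[tuple[str, int, int, str]],
    genome_sequence: Mapping[str, str],
    spectrum96,
) -> tuple[float, float]:
    """Neutral expectations for non-synonymous and genic substitution fractions.

    Every possible single-base change at every site is weighted by its
    96-channel spectrum weight (via its reference-strand trinucleotide
    context).  The non-synonymous expectation is taken over coding
    sites and counts amino-acid-changing substitutions, with stop gain
    and loss counted as non-synonymous.  The genic expectation is the
    weighted fraction of all genome-wide changes that land in annotated
    coding intervals.  Sites lacking a full trinucleotide context
    (chromosome ends) are skipped.

    Parameters
    ----------
    cds_annotation
        ``(chrom, start, end, strand)`` coding intervals, 1-based
        inclusive, lengths multiples of 3, frame starting at the
        interval edge (5' edge for "+", 3' edge for "-").
    genome_sequence
        Mapping of chromosome name to reference sequence.
    spectrum96
        Channel weights (mapping or length-96 vector); normalized
        internally.

    Returns
    -------
    (expected_nonsyn_fraction, expected_genic_fraction)
    """
    weights = _spectrum_weights(spectrum96)
    if not cds_annotation:
        raise ValueError("no CDS intervals")

    # --- non-synonymous expectation over coding sites -----------------
    w_coding = 0.0
    w_nonsyn = 0.0
    for chrom, start, end, strand in cds_annotation:
        seq = genome_sequence[chrom]
        if not 1 <= start <= end <= len(seq):
            raise ValueError(f"CDS outside {chrom}")
        if (end - start + 1) % 3 != 0:
            raise ValueError(f"CDS length not a multiple of 3: {chrom}:{start}-{end}")
        cds = seq[start - 1 : end].upper()
        if strand == "-":
            cds = _revcomp(cds)
        elif strand != "+":
            raise ValueError(f"bad strand {strand!r}")
        for i, base in enumerate(cds):
            # genomic (reference-strand) position of this CDS base
            gpos = start + i if strand == "+" else end - i
            if gpos < 2 or gpos > len(seq) - 1:
                continue
            ctx = seq[gpos - 2 : gpos + 1].upper()
            codon_i = i // 3
            codon = cds[3 * codon_i : 3 * codon_i + 3]
            aa = _CODON_TABLE[codon]
            within = i % 3
            for alt in "ACGT":
                if alt == base:
                    continue
                g_ref = ctx[1]
                g_alt = alt if strand == "+" else _COMPLEMENT[alt]
                _, chan = classify_substitution(g_ref, g_alt, ctx)
                w = weights[chan]
                mut_codon = codon[:within] + alt + codon[within + 1 :]
                w_coding += w
                if _CODON_TABLE[mut_codon] != aa:
                    w_nonsyn += w
    if w_coding == 0:
        raise ValueError("no weighted coding changes (check spectrum/CDS)")
    expected_nonsyn = w_nonsyn / w_coding

    # --- genic expectation over all genome-wide sites -----------------
    genic_mask: dict[str, np.ndarray] = {}
    for chrom, seqstr in genome_sequence.items():
        genic_mask[chrom] = np.zeros(len(seqstr), dtype=bool)
    for chrom, start, end, _strand in cds_annotation:
        genic_mask[chrom][start - 1 : end] = True

    w_total = 0.0
    w_genic = 0.0
    chan_index = {ch: i for i, ch in enumerate(SBS96_CHANNELS)}
    wvec = np.array([weights[ch] for ch in SBS96_CHANNELS])
    base_code = {"A": 0, "C": 1, "G": 2, "T": 3}
    # precompute channel index for (context code, alt code); -1 = invalid
    bases = "ACGT"
    lut = np.full((64, 4), -1, dtype=int)
    for l in bases:
        for m in bases:
            for r in bases:
                code = 16 * base_code[l] + 4 * base_code[m] + base_code[r]
                for alt in bases:
                    if alt == m:
                        continue
                    _, chan = classify_substitution(m, alt, l + m + r)
                    lut[code, base_code[alt]] = chan_index[chan]
    for chrom, seqstr in genome_sequence.items():
        codes = np.array([base_code.get(b, -1) for b in seqstr.upper()], dtype=int)
        if len(codes) < 3:
            continue
        # context code for interior positions
        inner = slice(1, len(codes) - 1)
        ok = (codes[:-2] >= 0) & (codes[1:-1] >= 0) & (codes[2:] >= 0)
        ctx_code = 16 * codes[:-2] + 4 * codes[1:-1] + codes[2:]
        genic = genic_mask[chrom][inner]
        for a in range(4):
            chans = lut[ctx_code[ok], a]
            site_w = np.where(chans >= 0, wvec[np.clip(chans, 0, None)], 0.0)
            w_total += site_w.sum()
            w_genic += site_w[genic[ok]].sum()
    if w_total == 0:
        raise ValueError("no weighted genome-wide changes")
    return expected_nonsyn, w_genic / w_total


def neutrality_test(
    obs_nonsyn: int, obs_syn: int, expected_fraction: float
) -> float:
    """Exact 2x2 test of observed functional split against expectation.

    Compares (obs_nonsyn, obs_syn) with the expected split of the same
    total by Fisher's exact test (two-sided).  A p-value of 1 means the
    observed proportion matches the neutral expectation.
    """
    if obs_nonsyn < 0 or obs_syn < 0:
        raise ValueError("negative counts")
    total = obs_nonsyn + obs_syn
    if total == 0:
        raise ValueError("no observations")
    if not 0.0 <= expected_fraction <= 1.0:
        raise ValueError("expected_fraction must be in [0, 1]")
    exp_nonsyn = round(expected_fraction * total)
    table = [[obs_nonsyn, obs_syn], [exp_nonsyn, total - exp_nonsyn]]
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def compare_groups(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U (rank-sum) p-value.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's automatic policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)


def cooccurrence_test(
    total_events: int,
    n_lines: int,
    k_in_one_line: int,
    reps: int = 100_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo probability that any line collects >= k of the events.

    Under the null the ``total_events`` events are assigned to the
    ``n_lines`` lines independently and uniformly.  The p-value uses the
    add-one (permutation) correction (count+1)/(reps+1).  ``k`` larger
    than the total is impossible and returns 0 analytically.
    """
    if total_events < 0 or n_lines < 1 or reps < 1:
        raise ValueError("bad test parameters")
    if k_in_one_line > total_events:
        return 0.0
    if k_in_one_line <= 0:
        return 1.0
    rng = np.random.default_rng(seed)
    p = np.full(n_lines, 1.0 / n_lines)
    hits = 0
    chunk = max(1, min(reps, int(2e7) // max(n_lines, 1)))
    done = 0
    while done < reps:
        n = min(chunk, reps - done)
        counts = rng.multinomial(total_events, p, size=n)
        hits += int((counts.max(axis=1) >= k_in_one_line).sum())
        done += n
    return (hits + 1) / (reps + 1)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default
    in pipeline reports, matching the single-test convention used for
    the per-condition comparisons)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out
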