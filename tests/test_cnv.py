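"""Coverage-based karyotype, segmental CNV, rDNA and mtDNA estimation."""

import numpy as np
import pandas as pd
import pytest

from mafoot.cnv import (
    call_chromosome_cn,
    mtdna_estimate,
    rdna_copy_number,
    segment_cnv,
)
from mafoot.genome import DepthProfile, Interval, ValidationError
from mafoot.simulate import SimulationConfig, simulate_depth, study_design


def flat_profile(genome, level=1.0, window=10_000, chrom_levels=None):
    rows = []
    for chrom in genome.nuclear_chromosomes():
        L = genome.length_of(chrom)
        lv = (chrom_levels or {}).get(chrom, level)
        for s in range(1, L, window):
            e = min(s + window - 1, L)
            rows.append((chrom, s, e, lv * 100, lv))
    return DepthProfile(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "raw_depth", "norm_depth"]
    ))


@pytest.fixture(scope="module")
def sim_cfg(genome):
    return SimulationConfig(
        genome=genome,
        design=study_design(callable_sites=1_000_000,
                            lines_per_condition={"YPD": 1}),
        seed=3,
    )


class TestChromosomeCN:
    def test_uniform_gain_and_loss(self, genome):
        prof = flat_profile(genome, chrom_levels={"chr1": 1.5, "chr2": 0.5})
        kar = call_chromosome_cn(prof, genome, ploidy=2)
        assert kar.cn("chr1") == 3 and kar.cn("chr2") == 1
        assert ("chr1", "gain", 1) in kar.events
        assert ("chr2", "loss", 1) in kar.events
        assert kar.cn("chr3") == 2

    def test_half_and_half_is_mosaic(self, genome):
        prof = flat_profile(genome)
        w = prof.windows.copy()
        sel = w["chrom"] == "chr1"
        idx = w[sel].index
        w.loc[idx[: len(idx) // 2], "norm_depth"] = 1.5
        kar = call_chromosome_cn(DepthProfile(w), genome, ploidy=2)
        assert kar.cn("chr1") is None  # mosaic/segmental flag

    def test_too_few_windows_errors(self, genome):
        prof = flat_profile(genome, window=100_000)
        with pytest.raises(ValidationError):
            call_chromosome_cn(prof, genome, ploidy=2)

    @pytest.mark.parametrize("cn", [0, 1, 2, 3, 4])
    def test_exact_recovery_under_noise(self, genome, sim_cfg, cn):
        """log-normal noise sd 0.05 never flips an integer call."""
        from dataclasses import replace

        cfg = replace(sim_cfg, depth_noise_sd=0.05)
        kar_true = {c: 2 for c in genome.nuclear_chromosomes()}
        kar_true["chr2"] = cn
        for seed in range(10):
            rng = np.random.default_rng(seed)
            prof = simulate_depth(kar_true, cfg, ploidy=2, rng=rng)
            kar = call_chromosome_cn(prof, genome, ploidy=2)
            assert kar.cn("chr2") == cn
            assert all(kar.cn(c) == 2 for c in genome.nuclear_chromosomes()
                       if c != "chr2")


class TestSegmentCNV:
    def test_step_profile_yields_one_segment_with_breakpoint(self, genome):
        prof = flat_profile(genome)
        w = prof.windows.copy()
        sel = (w["chrom"] == "chr1") & (w["start"] >= 200_001)
        w.loc[sel, "norm_depth"] = 1.5
        segs = segment_cnv(DepthProfile(w), genome, ploidy=2)
        [seg] = segs
        assert seg.chrom == "chr1" and seg.copy_number == 3
        assert seg.start == 200_001
        # breakpoint interval brackets the true step at 200000/200001
        assert seg.breakpoint_up[0] <= 200_000 <= seg.breakpoint_up[1] + 1

    def test_short_excursions_suppressed(self, genome):
        prof = flat_profile(genome)
        w = prof.windows.copy()
        sel = (w["chrom"] == "chr1") & w["start"].between(100_001, 150_000)
        assert sel.sum() == 5
        w.loc[sel, "norm_depth"] = 1.5
        assert segment_cnv(DepthProfile(w), genome, ploidy=2,
                           min_windows=10) == []

    def test_merge_across_small_gaps(self, genome):
        prof = flat_profile(genome, window=1_000)
        w = prof.windows.copy()
        sel = (w["chrom"] == "chr1") & w["start"].between(100_001, 160_000)
        w.loc[sel, "norm_depth"] = 1.5
        gap = (w["chrom"] == "chr1") & w["start"].between(130_001, 131_000)
        w.loc[gap, "norm_depth"] = 1.0
        [seg] = segment_cnv(DepthProfile(w), genome, ploidy=2, merge_gap=2)
        assert seg.start == 100_001 and seg.end == 160_000

    def test_noise_alone_rarely_calls_segments(self, genome, sim_cfg):
        from dataclasses import replace

        cfg = replace(sim_cfg, depth_noise_sd=0.05)
        kar = {c: 2 for c in genome.nuclear_chromosomes()}
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            prof = simulate_depth(kar, cfg, ploidy=2, rng=rng)
            hits += bool(segment_cnv(prof, genome, ploidy=2))
        assert hits == 0

    def test_breakpoints_contain_true_simulated_boundary(self, genome, sim_cfg):
        cfg = sim_cfg
        kar = {c: 2 for c in genome.nuclear_chromosomes()}
        true_seg = ("chr2", 100_001, 220_000, 3)
        prof = simulate_depth(kar, cfg, ploidy=2,
                              rng=np.random.default_rng(0), seg_cnvs=[true_seg])
        [seg] = [s for s in segment_cnv(prof, genome, ploidy=2)
                 if s.chrom == "chr2"]
        assert seg.breakpoint_up[0] <= true_seg[1] <= seg.breakpoint_up[1] + 1
        assert seg.breakpoint_down[0] - 1 <= true_seg[2] <= seg.breakpoint_down[1]


class TestRdna:
    def test_identity_when_sample_equals_ancestor(self, genome):
        prof = flat_profile(genome)
        w = prof.windows.copy()
        rd = genome.rdna_locus
        sel = (w["chrom"] == rd.chrom) & ((w["start"] + w["end"]) // 2).between(
            rd.start, rd.end
        )
        w.loc[sel, "norm_depth"] = 150.0
        prof = DepthProfile(w)
        est = rdna_copy_number(prof, prof, genome, chrXII_cn=2, ploidy=2)
        assert est.per_sample == pytest.approx(1.0)
        assert est.per_chrXII == pytest.approx(1.0)

    def test_chromosome_gain_rescales_per_chromosome(self, genome):
        """per-sample 1.05 with three copies of the rDNA chromosome
        means 0.70 repeats per chromosome."""
        anc = flat_profile(genome)
        wa = anc.windows.copy()
        rd = genome.rdna_locus
        sel = (wa["chrom"] == rd.chrom) & ((wa["start"] + wa["end"]) // 2).between(
            rd.start, rd.end
        )
        wa.loc[sel, "norm_depth"] = 100.0
        anc = DepthProfile(wa)
        ws = wa.copy()
        ws.loc[sel, "norm_depth"] = 105.0
        sample = DepthProfile(ws)
        est = rdna_copy_number(sample, anc, genome, chrXII_cn=3, ploidy=2)
        assert est.per_sample == pytest.approx(1.05)
        assert est.per_chrXII == pytest.approx(0.70)

    def test_zero_ancestor_errors(self, genome):
        prof = flat_profile(genome)
        w = prof.windows.copy()
        rd = genome.rdna_locus
        sel = (w["chrom"] == rd.chrom) & ((w["start"] + w["end"]) // 2).between(
            rd.start, rd.end
        )
        w.loc[sel, "norm_depth"] = 0.0
        with pytest.raises(ValidationError):
            rdna_copy_number(prof, DepthProfile(w), genome, 2, 2)

    def test_scale_invariance(self, genome, sim_cfg):
        """The estimate uses normalized depth only, so overall coverage
        cancels (noiseless profiles at different raw depth agree)."""
        from dataclasses import replace

        cfg = replace(sim_cfg, depth_noise_sd=0.0)
        kar = {c: 2 for c in genome.nuclear_chromosomes()}
        prof = simulate_depth(kar, cfg, ploidy=2,
                              rng=np.random.default_rng(2), rdna_repeats=120.0)
        anc = simulate_depth(kar, cfg, ploidy=2,
                             rng=np.random.default_rng(3), rdna_repeats=150.0)
        est = rdna_copy_number(prof, anc, genome, 2, 2)
        assert est.per_sample == pytest.approx(120 / 150, rel=1e-9)


def mito_profile(genome, level, absent=None, window=100):
    rows = []
    for chrom in genome.nuclear_chromosomes():
        L = genome.length_of(chrom)
        for s in range(1, L, 10_000):
            rows.append((chrom, s, min(s + 9_999, L), 100.0, 1.0))
    L = genome.length_of(genome.mito_name)
    for s in range(1, L, window):
        e = min(s + window - 1, L)
        lv = 0.0 if (absent and absent[0] <= s <= absent[1]) else level
        rows.append((genome.mito_name, s, e, lv * 100, lv))
    return DepthProfile(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "raw_depth", "norm_depth"]
    ))


@pytest.fixture(scope="module")
def mito_genes(genome):
    L = genome.length_of(genome.mito_name)
    return {
        "ATP6": Interval(genome.mito_name, int(0.1 * L), int(0.1 * L) + 999),
        "COX2": Interval(genome.mito_name, int(0.4 * L), int(0.4 * L) + 999),
        "COX3": Interval(genome.mito_name, int(0.7 * L), int(0.7 * L) + 999),
    }


class TestMtdna:
    def test_intact_copy_number(self, genome, mito_genes):
        est = mtdna_estimate(mito_profile(genome, 20.0), genome, mito_genes)
        assert est.copy_number == pytest.approx(20.0)
        assert est.status == "intact"
        assert est.presence_fraction == 1.0

    def test_total_loss(self, genome, mito_genes):
        est = mtdna_estimate(mito_profile(genome, 0.0), genome, mito_genes)
        assert est.status == "lost"
        assert est.presence_fraction == 0.0

    def test_heteroplasmy_retained_segment(self, genome, mito_genes):
        # 10 kb retained out of 75 kb
        est = mtdna_estimate(
            mito_profile(genome, 20.0, absent=(10_001, 75_000)),
            genome, mito_genes,
        )
        assert est.status == "heteroplasmic"
        [seg] = est.retained_segments
        assert seg[1] - seg[0] + 1 == pytest.approx(10_000, abs=100)

    def test_missing_gene_coverage_errors(self, genome, mito_genes):
        prof = mito_profile(genome, 20.0)
        w = prof.windows[prof.windows["chrom"] != genome.mito_name]
        with pytest.raises(ValidationError):
            mtdna_estimate(DepthProfile(w), genome, mito_genes)
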