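"""LOH genotyping, segmentation, classification and overlap testing."""

import numpy as np
import pytest
from scipy import stats as sps

from mafoot.genome import GenomeDef, Interval, ValidationError
from mafoot.loh import (
    breakpoint_intervals,
    call_marker_state,
    classify_loh,
    detect_loh,
    loh_statistics,
    permutation_overlap_test,
    segment_loh,
)
from mafoot.simulate import study_design


class TestMarkerState:
    @pytest.mark.parametrize(
        "d1,d2,state",
        [
            (10, 10, "het"),
            (20, 0, "homP1"),
            (0, 20, "homP2"),
            (3, 2, "missing"),  # depth below minimum
            (19, 1, "homP1"),  # 0.95 >= 0.9
            (17, 3, "het"),  # minor fraction exactly at the 0.15 bound
            (87, 13, "missing"),  # 0.87: neither het nor hom
        ],
    )
    def test_thresholds(self, d1, d2, state):
        assert call_marker_state(d1, d2) == state


class TestSegmentation:
    def test_all_het_yields_nothing(self):
        assert segment_loh(["het"] * 5, [10, 20, 30, 40, 50]) == []

    def test_run_flanked_by_het(self):
        states = ["het"] + ["homP1"] * 5 + ["het"]
        pos = [10, 20, 30, 40, 50, 60, 70]
        [seg] = segment_loh(states, pos, chrom="chr1", line_id="L")
        assert (seg.start, seg.end, seg.parent, seg.n_markers) == (20, 60, "P1", 5)

    def test_single_marker_run_excluded(self):
        states = ["het", "homP1", "het"]
        assert segment_loh(states, [1, 2, 3]) == []

    def test_missing_markers_are_transparent(self):
        states = ["homP1", "missing", "homP1"]
        [seg] = segment_loh(states, [10, 20, 30])
        assert (seg.start, seg.end, seg.n_markers) == (10, 30, 2)

    def test_parent_switch_breaks_run(self):
        states = ["homP1", "homP1", "homP2", "homP2"]
        segs = segment_loh(states, [10, 20, 30, 40])
        assert [(s.parent, s.start, s.end) for s in segs] == [
            ("P1", 10, 20), ("P2", 30, 40),
        ]


class TestClassification:
    def markers(self):
        return list(range(100, 1100, 100))  # 100..1000

    def make_seg(self, start, end, n=3):
        from mafoot.loh import LOHSegment

        return LOHSegment(line_id="L", chrom="chr1", parent="P1",
                          start=start, end=end, n_markers=n)

    def test_covering_all_markers_with_cn_loss(self):
        seg = self.make_seg(100, 1000)
        assert classify_loh(seg, self.markers(), chromosome_cn=1) == "chromosome_loss"

    def test_covering_all_markers_at_full_cn_is_terminal(self):
        seg = self.make_seg(100, 1000)
        assert classify_loh(seg, self.markers(), chromosome_cn=2) == "terminal"

    def test_reaching_either_end_is_terminal(self):
        assert classify_loh(self.make_seg(500, 1000), self.markers(), 2) == "terminal"
        assert classify_loh(self.make_seg(100, 300), self.markers(), 2) == "terminal"

    def test_internal_run_is_interstitial(self):
        assert classify_loh(self.make_seg(300, 700), self.markers(), 2) == "interstitial"


class TestBreakpointFormulas:
    def test_literal_formula(self):
        up, down = breakpoint_intervals(100, 520, 120, 500)
        assert up == (80, 120)
        assert down == (500, 540)

    def test_degenerate_point(self):
        up, down = breakpoint_intervals(100, 500, 100, 500)
        assert up == (100, 100)
        assert down == (500, 500)

    def test_clipping_at_chromosome_edges(self):
        up, down = breakpoint_intervals(5, 500, 120, 400, chrom_length=550)
        assert up[0] == 1  # 5 - 115 < 1 clipped
        assert down == (400, 550)  # 500 + 100 clipped to length

    def test_ordering_violation(self):
        with pytest.raises(ValidationError):
            breakpoint_intervals(200, 500, 100, 400)


class TestStatistics:
    def test_empty_is_all_zero(self, genome, small_design):
        st = loh_statistics([], small_design, genome)
        assert st.overall_rate == 0.0
        assert all(v == 0.0 for v in st.rates.values())
        assert all(v == 0.0 for v in st.genome_fraction.values())

    def test_rate_and_fraction_arithmetic(self, genome):
        from mafoot.loh import LOHSegment

        design = study_design(callable_sites=1_000_000,
                              lines_per_condition={"HU": 24})
        lid = design.lines[0].line_id
        segs = [
            LOHSegment(line_id=lid, chrom="chr1", parent="P1",
                       start=1, end=100_000, n_markers=10,
                       loh_class="interstitial")
            for _ in range(1)
        ] * 12
        st = loh_statistics(segs, design, genome, condition="HU")
        assert st.rates["interstitial"] == pytest.approx(12 / (24 * 1200))
        # one 100-kb tract in a 1.6-Mb nuclear genome
        assert st.genome_fraction[lid] == pytest.approx(12 * 100_000 / 1_600_000)

    def test_non_diploid_lines_excluded(self, genome):
        from mafoot.genome import MALDesign, MALine

        design = MALDesign((
            MALine("a-YPD-1", "NA/WE", "YPD", 120, 23.0, 1_000_000, ploidy=2),
            MALine("b-YPD-1", "NA/WE", "YPD", 120, 23.0, 1_000_000, ploidy=1),
        ))
        st = loh_statistics([], design, genome)
        assert st.n_lines == 1


class TestRecoveryFromSimulation:
    def test_exact_recovery_at_marker_resolution(self, sim_result):
        """Noiseless simulated LOH events are recovered with identical
        coordinates, parent and class."""
        truth = sim_result.truth
        genome = sim_result.config.genome
        checked = 0
        for lid, ld in sim_result.lines.items():
            if ld.markers is None:
                continue
            cn = {c: 2 for c in genome.nuclear_chromosomes()}
            aneu = truth["aneuploidy"]
            for _, r in aneu[aneu["line_id"] == lid].iterrows():
                cn[r["chrom"]] += 1 if r["event"] == "gain" else -1
            got = sorted(
                (s.chrom, s.start, s.end, s.parent, s.loh_class)
                for s in detect_loh(ld.markers, lid, genome, cn)
            )
            want = sorted(
                (r["chrom"], int(r["start"]), int(r["end"]), r["parent"], r["class"])
                for _, r in truth["loh"][truth["loh"]["line_id"] == lid].iterrows()
            )
            assert got == want
            checked += 1
        assert checked >= 4

    def test_terminal_tracts_longer_than_interstitial(self, sim_result):
        loh = sim_result.truth["loh"]
        term = loh[loh["class"] == "terminal"]
        inter = loh[loh["class"] == "interstitial"]
        assert len(term) >= 2 and len(inter) >= 2
        assert (term["end"] - term["start"]).mean() > (
            inter["end"] - inter["start"]
        ).mean()


class TestPermutationOverlap:
    @pytest.fixture()
    def flat_genome(self):
        return GenomeDef(chromosomes=(("chr1", 1_000_000), ("chr2", 1_000_000)))

    def test_query_equals_sparse_reference(self, flat_genome):
        regions = [Interval("chr1", s, s + 499) for s in range(1000, 5001, 1000)]
        p, z, obs = permutation_overlap_test(
            regions, regions, flat_genome, ntimes=1000, seed=4
        )
        assert obs == len(regions)
        assert p == pytest.approx(1 / 1001)
        assert z > 3

    def test_disjoint_chromosomes(self, flat_genome):
        q = [Interval("chr1", 100, 199)]
        r = [Interval("chr2", 100, 199)]
        p, z, obs = permutation_overlap_test(q, r, flat_genome, ntimes=200, seed=1)
        assert obs == 0
        assert p == 1.0

    def test_zero_permutations_rejected(self, flat_genome):
        q = [Interval("chr1", 1, 10)]
        with pytest.raises(ValidationError):
            permutation_overlap_test(q, q, flat_genome, ntimes=0)

    def test_region_longer_than_chromosome_rejected(self):
        g = GenomeDef(chromosomes=(("chr1", 100),))
        with pytest.raises(ValidationError):
            permutation_overlap_test(
                [Interval("chr1", 1, 150)], [], g, ntimes=10
            )
        # length-100 region on length-100 chromosome is fine
        p, _, _ = permutation_overlap_test(
            [Interval("chr1", 1, 100)], [Interval("chr1", 50, 60)], g,
            ntimes=10, seed=0,
        )
        assert p == pytest.approx(1.0)

    def test_null_pvalues_are_uniform(self, flat_genome):
        """Uniformly re-placed queries give approximately uniform
        p-values when the overlap count has enough resolution (many
        query regions); sparse designs are conservative because the
        count statistic is coarsely discrete."""
        rng = np.random.default_rng(12)
        pvals = []
        for i in range(200):
            ref = [Interval("chr1", int(s), int(s) + 1999)
                   for s in rng.integers(1, 990_000, size=120)]
            qs = rng.integers(1, 995_000, size=100)
            q = [Interval("chr1", int(s), int(s) + 2999) for s in qs]
            p, _, _ = permutation_overlap_test(
                q, ref, flat_genome, ntimes=199, seed=int(rng.integers(2**31)),
            )
            pvals.append(p)
        ks = sps.kstest(pvals, "uniform").pvalue
        assert ks > 0.01
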