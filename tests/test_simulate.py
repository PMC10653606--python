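"""Synthetic-data generator: contracts, determinism, statistical structure."""

import math

import numpy as np
import pandas as pd
import pytest

from mafoot.genome import MALDesign, MALine
from mafoot.simulate import (
    SimulationConfig,
    simulate_depth,
    simulate_fluctuation,
    simulate_mal,
    study_design,
    uniform_spectrum96,
    ypd_spectrum96,
)


def quiet_config(genome, design, seed=1, **kw):
    base = dict(
        genome=genome, design=design, seed=seed,
        sub_rate=0.0, indel_rate=0.0, aneu_gain_rate=0.0, aneu_loss_rate=0.0,
        seg_cnv_rate=0.0, loh_rate_interstitial=0.0, loh_rate_terminal=0.0,
        mtdna_loss_prob=0.0, mtdna_het_prob=0.0, depth_noise_sd=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="module")
def tiny_design():
    return study_design(
        callable_sites=1_000_000, lines_per_condition={"YPD": 2, "HU": 1, "RM": 1}
    )


class TestConfig:
    def test_spectrum_must_sum_to_one(self, genome, tiny_design):
        spec = uniform_spectrum96()
        spec["A[C>A]A"] += 0.1
        with pytest.raises(Exception):
            SimulationConfig(genome=genome, design=tiny_design, seed=1, spectrum96=spec)

    def test_negative_rate_rejected(self, genome, tiny_design):
        with pytest.raises(Exception):
            SimulationConfig(genome=genome, design=tiny_design, seed=1, sub_rate=-1e-9)

    def test_default_spectrum_reproduces_drug_free_ratios(self):
        spec = ypd_spectrum96()
        assert sum(spec.values()) == pytest.approx(1.0)
        six = {}
        for ch, w in spec.items():
            six[ch[2:5]] = six.get(ch[2:5], 0.0) + w
        tstv = (six["C>T"] + six["T>C"]) / (
            six["C>A"] + six["C>G"] + six["T>A"] + six["T>G"]
        )
        assert tstv == pytest.approx(0.93, abs=0.02)
        assert (six["C>T"] + six["C>A"]) / (six["T>C"] + six["T>G"]) == pytest.approx(
            2.58, abs=0.05
        )


class TestSimulateMal:
    def test_all_rates_zero_gives_empty_and_flat(self, genome, tiny_design):
        res = simulate_mal(quiet_config(genome, tiny_design))
        assert all(len(ld.variants) == 0 for ld in res.lines.values())
        for ld in res.lines.values():
            nuc = ld.depth.windows[ld.depth.windows["chrom"] != genome.mito_name]
            rdna = genome.rdna_locus
            mid = (nuc["start"] + nuc["end"]) // 2
            outside = ~((nuc["chrom"] == rdna.chrom) & mid.between(rdna.start, rdna.end))
            assert np.allclose(nuc.loc[outside, "norm_depth"], 1.0)

    def test_same_seed_is_byte_identical(self, genome, tiny_design, tmp_path):
        from mafoot.simulate import write_simulation

        for d in ("a", "b"):
            res = simulate_mal(quiet_config(genome, tiny_design, seed=33,
                                            sub_rate=2e-8, loh_rate_interstitial=3e-4))
            write_simulation(res, tmp_path / d)
        for p in sorted((tmp_path / "a").rglob("*")):
            if p.is_file():
                q = tmp_path / "b" / p.relative_to(tmp_path / "a")
                assert p.read_bytes() == q.read_bytes(), p.name

    def test_adding_a_line_leaves_others_unchanged(self, genome):
        d1 = study_design(callable_sites=1_000_000,
                          lines_per_condition={"YPD": 2})
        d2 = study_design(callable_sites=1_000_000,
                          lines_per_condition={"YPD": 3})
        r1 = simulate_mal(quiet_config(genome, d1, seed=5, sub_rate=2e-8))
        r2 = simulate_mal(quiet_config(genome, d2, seed=5, sub_rate=2e-8))
        for lid in r1.lines:
            v1 = r1.lines[lid].variants
            v2 = r2.lines[lid].variants
            assert v1 == v2

    def test_substitution_counts_are_poisson_in_design(self, genome):
        """Total substitutions across lines ~ Poisson with mean
        rate x sites x ploidy x generations summed over lines."""
        design = study_design(callable_sites=12_000_000,
                              lines_per_condition={"HU": 24})
        cfg = quiet_config(genome, design, seed=77, sub_rate=1e-9)
        res = simulate_mal(cfg)
        mean = 1e-9 * 12e6 * 2 * 1200 * 24  # 691.2
        total = len(res.truth["substitutions"])
        assert abs(total - mean) < 3 * math.sqrt(mean)

    def test_event_counts_scale_linearly_in_generations(self, genome):
        """Slope of mean LOH count vs generations is the configured rate."""
        rate = 2e-3
        counts = []
        gens = []
        for n_bn in (20, 60, 120):
            design = MALDesign(tuple(
                MALine(line_id=f"NA/WE-YPD-{i}", background="NA/WE",
                       condition="YPD", n_bottlenecks=n_bn,
                       gens_per_bottleneck=23.0, callable_sites=1_000_000)
                for i in range(20)
            ))
            cfg = quiet_config(genome, design, seed=n_bn,
                               loh_rate_interstitial=rate)
            res = simulate_mal(cfg)
            counts.append(len(res.truth["loh"]) / 20)
            gens.append(n_bn * 23.0)
        slope = np.polyfit(gens, counts, 1)[0]
        # placement rejections lose a few events; Poisson noise dominates
        assert slope == pytest.approx(rate, rel=0.25)

    def test_truth_events_recoverable_when_noiseless(self, sim_result):
        """Every truth aneuploidy is visible in the emitted depth table."""
        genome = sim_result.config.genome
        aneu = sim_result.truth["aneuploidy"]
        for lid, ld in sim_result.lines.items():
            expected = {c: 2 for c in genome.nuclear_chromosomes()}
            for _, r in aneu[aneu["line_id"] == lid].iterrows():
                expected[r["chrom"]] += 1 if r["event"] == "gain" else -1
            segs = sim_result.truth["segmental_cnv"]
            seg_chroms = set(segs[segs["line_id"] == lid]["chrom"])
            for chrom, cn in expected.items():
                if chrom in seg_chroms:
                    continue
                w = ld.depth.on(chrom)
                mid = (w["start"] + w["end"]) // 2
                rdna = genome.rdna_locus
                sel = ~((chrom == rdna.chrom) & mid.between(rdna.start, rdna.end))
                med = w.loc[sel, "norm_depth"].median()
                assert med == pytest.approx(cn / 2, abs=1e-9)


class TestSimulateDepth:
    def test_noiseless_trisomy_sits_at_1_5(self, genome, tiny_design):
        cfg = quiet_config(genome, tiny_design)
        kar = {c: 2 for c in genome.nuclear_chromosomes()}
        kar["chr2"] = 3
        prof = simulate_depth(kar, cfg, ploidy=2)
        assert np.allclose(prof.on("chr2")["norm_depth"], 1.5)

    def test_mito_presence_mask_fraction(self, genome, tiny_design):
        cfg = quiet_config(genome, tiny_design)
        kar = {c: 2 for c in genome.nuclear_chromosomes()}
        prof = simulate_depth(kar, cfg, ploidy=2, mtdna_copy=20.0,
                              mtdna_presence=(1, 10_000))
        mito = prof.on(genome.mito_name)
        present = (mito["norm_depth"] > 0).mean()
        assert present == pytest.approx(10_000 / 75_000, abs=0.01)

    def test_median_concentrates_under_noise(self, genome, tiny_design):
        cfg = quiet_config(genome, tiny_design, depth_noise_sd=0.05)
        kar = {c: 2 for c in genome.nuclear_chromosomes()}
        kar["chr1"] = 3
        rng = np.random.default_rng(4)
        meds = []
        for _ in range(20):
            prof = simulate_depth(kar, cfg, ploidy=2, rng=rng)
            meds.append(prof.on("chr1")["norm_depth"].median())
        assert all(1.45 < m < 1.55 for m in meds)


class TestSimulateFluctuation:
    def test_zero_m_gives_all_zeros(self):
        assert (simulate_fluctuation(0.0, 100, 1e7, seed=1) == 0).all()

    def test_zero_fraction_matches_poisson_closed_form(self):
        counts = simulate_fluctuation(1.0, 100_000, 1e9, seed=2)
        p0 = (counts == 0).mean()
        se = math.sqrt(math.exp(-1) * (1 - math.exp(-1)) / 100_000)
        assert abs(p0 - math.exp(-1)) < 3 * se

    def test_seed_reproducibility(self):
        a = simulate_fluctuation(0.5, 1000, 1e7, seed=9)
        b = simulate_fluctuation(0.5, 1000, 1e7, seed=9)
        assert (a == b).all()
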