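import pytest

from mafoot.genome import MALine
from mafoot.simulate import SimulationConfig, demo_genome, simulate_mal, study_design


@pytest.fixture(scope="session")
def genome():
    return demo_genome()


@pytest.fixture(scope="session")
def small_design():
    """Two hybrid + one homozygous line per condition, reduced callable
    sites so per-line mutation counts stay small and fast."""
    return study_design(
        callable_sites=1_500_000,
        lines_per_condition={"YPD": 3, "HU": 3, "RM": 3},
    )


@pytest.fixture(scope="session")
def sim_result(genome, small_design):
    """One shared simulation exercising every event type, with a slice
    of calls degraded against each filter criterion."""
    cfg = SimulationConfig(
        genome=genome,
        design=small_design,
        seed=20240901,
        sub_rate=2e-8,
        indel_rate=2e-9,
        aneu_gain_rate=2e-4,
        aneu_loss_rate=1e-4,
        seg_cnv_rate=1e-4,
        loh_rate_interstitial=4e-4,
        loh_rate_terminal=2e-4,
        mtdna_loss_prob=0.3,
        mtdna_het_prob=0.3,
        depth_noise_sd=0.0,
        degrade_fractions={
            "single_caller": 0.05,
            "low_qual": 0.05,
            "low_depth": 0.05,
            "low_support": 0.05,
            "one_strand": 0.05,
            "repeat_region": 0.05,
            "ancestral": 0.05,
        },
    )
    return simulate_mal(cfg)


@pytest.fixture()
def diploid_line():
    return MALine(
        line_id="NA/WE-YPD-1",
        background="NA/WE",
        condition="YPD",
        n_bottlenecks=120,
        gens_per_bottleneck=23.0,
        callable_sites=12_000_000,
        ploidy=2,
    )
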