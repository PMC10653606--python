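"""Generate a synthetic mutation-accumulation dataset with known truth.

Builds a small three-condition design (drug-free YPD, hydroxyurea,
rapamycin) over a demo genome, simulates substitutions, aneuploidies,
LOH and mitochondrial events, and prints what was planted.
"""

from mafoot.simulate import SimulationConfig, demo_genome, simulate_mal, study_design

config = SimulationConfig(
    genome=demo_genome(),
    design=study_design(callable_sites=1_500_000,
                        lines_per_condition={"YPD": 4, "HU": 4, "RM": 4}),
    seed=11,
    sub_rate=2e-8,            # substitutions / base / generation
    aneu_gain_rate=2e-4,      # whole-chromosome gains / line / generation
    aneu_loss_rate=1e-4,
    loh_rate_interstitial=4e-4,
    loh_rate_terminal=2e-4,
    mtdna_loss_prob=0.2,      # per-line probability of losing mtDNA
)
result = simulate_mal(config)

print(f"simulated {len(result.lines)} lines")
for name, df in result.truth.items():
    print(f"  truth {name}: {len(df)} rows")
line = next(ld for ld in result.lines.values() if ld.markers is not None)
print(f"example hybrid line {line.line_id}: {len(line.variants)} observed calls, "
      f"{len(line.depth.windows)} depth windows, {len(line.markers.markers)} markers")
# Truth tables carry exact event coordinates and per-call degradation
# labels, so every downstream estimator can be scored against them.
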