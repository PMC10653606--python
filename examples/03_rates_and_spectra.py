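"""Generation accounting, per-base rates with exact Poisson CIs, and
substitution spectrum summaries.
"""

from mafoot.generations import arm_generations, total_experiment_generations
from mafoot.rates import event_rate, per_base_rate
from mafoot.simulate import study_design
from mafoot.spectra import SpectrumCounts, classify_substitution, gc_at_bias, ts_tv

# A colony of 2^23 cells spans 23 generations; 120 bottlenecks -> 2760.
print("generations per drug-free line:", arm_generations(120, 23))
print("whole experiment:", total_experiment_generations(study_design()),
      "generations across 96 lines")

# 13 substitutions over 12 Mb callable diploid sites and 2760 generations:
est = per_base_rate(13, 12e6, ploidy=2, total_line_generations=2760)
print(f"rate {est.rate:.3g} /base/generation "
      f"(95% CI {est.ci_low:.3g}..{est.ci_high:.3g})")

# mtDNA loss events: 10 events over 24 lines x 1200 generations.
print(f"mtDNA loss rate {event_rate(10, 24, 1200):.3g} /line/generation")

# Spectrum: classify calls into the 96-channel pyrimidine convention.
subs = [("G", "T", "AGA"), ("C", "T", "ACG"), ("A", "G", "TAT"),
        ("C", "T", "GCA"), ("C", "A", "ACA"), ("T", "G", "ATT")]
spec = SpectrumCounts.from_substitutions(subs)
print("six-class counts:", {k: v for k, v in spec.six_class.items() if v})
print(f"Ts/Tv {ts_tv(spec):.2f} (0.5 = no transition bias), "
      f"GC->AT bias {gc_at_bias(spec):.2f}")
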