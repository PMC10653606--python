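"""Mutation-rate estimators with exact Poisson confidence intervals.

Per-base rates divide the mutation count by the number of site-copies
at risk over the whole line history: callable_sites x ploidy x total
generations.  Counting site-copies (rather than sites) makes rates of
lines with different ploidy comparable; it is configurable by passing
ploidy=1.  Event rates (aneuploidy, mtDNA loss, LOH classes) divide an
event count by lines x generations/line.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["RateEstimate", "poisson_ci", "per_base_rate", "event_rate"]


@dataclass(frozen=True)
class RateEstimate:
    """A rate with its exact (Garwood) Poisson 95% confidence interval."""

    rate: float
    ci_low: float
    ci_high: float
    n_events: int
    denominator: float

    def contains(self, true_rate: float) -> bool:
        return self.ci_low <= true_rate <= self.ci_high


def poisson_ci(k: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson count.

    Lower bound is 0 at k=0; the upper bound at k=0 is -ln(alpha/2)
    (3.689 at 95%).  Uses the chi-square quantile form.
    """
    if k < 0:
        raise ValueError("negative count")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else stats.chi2.ppf(alpha / 2, 2 * k) / 2.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2.0
    return float(lo), float(hi)


def per_base_rate(
    n_mutations: int,
    callable_sites: float,
    ploidy: int,
    total_line_generations: float,
    conf: float = 0.95,
) -> RateEstimate:
    """Mutations per base (site-copy) per generation, with exact Poisson CI.

    ``total_line_generations`` is the summed generations over the lines
    contributing ``n_mutations``; the denominator is
    callable_sites x ploidy x total_line_generations.
    """
    if n_mutations < 0:
        raise ValueError("negative mutation count")
    denom = callable_sites * ploidy * total_line_generations
    if denom <= 0:
        raise ValueError("rate denominator must be positive")
    lo, hi = poisson_ci(n_mutations, conf)
    return RateEstimate(
        rate=n_mutations / denom,
        ci_low=lo / denom,
        ci_high=hi / denom,
        n_events=n_mutations,
        denominator=denom,
    )


def event_rate(k_events: int, n_lines: int, gens_per_line: float) -> float:
    """Events per line per generation (aneuploidy, mtDNA loss, LOH...)."""
    if n_lines <= 0 or gens_per_line <= 0:
        raise ValueError("n_lines and gens_per_line must be positive")
    if k_events < 0:
        raise ValueError("negative event count")
    return k_events / (n_lines * gens_per_line)
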