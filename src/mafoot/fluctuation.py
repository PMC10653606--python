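"""Luria-Delbrück fluctuation-assay estimation of mutation rates.

Parallel cultures grown from small inocula are plated on selective
medium; the distribution of mutant colony counts across cultures
follows the Luria-Delbrück distribution with parameter m, the expected
number of mutation events per culture.  The per-cell, per-generation
mutation rate is then m / Nt for final population size Nt (each of the
~Nt cell divisions giving one chance to mutate).

The likelihood uses the Ma-Sandri-Sarkar recursion

    p_0 = exp(-m),   p_r = (m / r) * sum_{i=0}^{r-1} p_i / (r - i + 1)

with m estimated by bounded scalar maximum likelihood; the p0 method
(m = -ln fraction of cultures without mutants) serves as a closed-form
cross-check on zero-heavy data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "FluctuationExperiment",
    "ld_pmf",
    "estimate_m_p0",
    "estimate_m_mle",
    "rate_from_m",
]


@dataclass(frozen=True)
class FluctuationExperiment:
    """Mutant counts per culture plus the final population size."""

    counts: tuple[int, ...]
    Nt: float

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("no cultures")
        if any(c < 0 for c in self.counts):
            raise ValueError("negative mutant count")
        if self.Nt <= 0:
            raise ValueError("Nt must be positive")

    @property
    def n_cultures(self) -> int:
        return len(self.counts)

    def mutation_rate(self, method: str = "mle") -> float:
        m = estimate_m_mle(self.counts) if method == "mle" else estimate_m_p0(self.counts)
        return rate_from_m(m, self.Nt)


def ld_pmf(m: float, r_max: int) -> np.ndarray:
    """Luria-Delbrück probabilities p_0..p_r_max (Ma-Sandri-Sarkar)."""
    if m < 0:
        raise ValueError("m must be >= 0")
    if r_max < 0:
        raise ValueError("r_max must be >= 0")
    p = np.zeros(r_max + 1)
    p[0] = math.exp(-m)
    for r in range(1, r_max + 1):
        i = np.arange(r)
        p[r] = (m / r) * np.sum(p[:r] / (r - i + 1))
    return p


def estimate_m_p0(counts) -> float:
    """p0 method: m = -ln(fraction of cultures with zero mutants)."""
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("no cultures")
    zeros = int((counts == 0).sum())
    if zeros == 0:
        raise ValueError("p0 method needs at least one zero-count culture")
    return -math.log(zeros / counts.size)


def estimate_m_mle(counts, cap: int | None = None) -> float:
    """Maximum-likelihood m under the Luria-Delbrück distribution.

    Counts above ``cap`` (default 10x the largest observed count, but
    never more than 1000) are pooled into a single tail term
    P(R > cap), which bounds the quadratic pmf recursion length without
    discarding cultures; the heavy Luria-Delbrück tail makes jackpot
    cultures individually uninformative beyond their being large.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("no cultures")
    if (counts < 0).any():
        raise ValueError("negative mutant count")
    cmax = int(counts.max())
    if cmax == 0:
        return 0.0
    if cap is None:
        cap = min(10 * cmax, 1000)
    cap = int(cap)
    body = counts[counts <= cap]
    n_tail = int((counts > cap).sum())
    vals, mult = np.unique(body, return_counts=True)

    def negloglik(m: float) -> float:
        p = ld_pmf(m, cap)
        p = np.clip(p, 1e-300, None)
        ll = float(np.sum(mult * np.log(p[vals])))
        if n_tail:
            tail = max(1.0 - float(p.sum()), 1e-300)
            ll += n_tail * math.log(tail)
        return -ll

    mean = float(counts.mean())
    hi = max(10.0, 3.0 * mean)
    res = minimize_scalar(negloglik, bounds=(1e-8, hi), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def rate_from_m(m: float, Nt: float) -> float:
    """Mutation rate per cell per generation: m / Nt."""
    if Nt <= 0:
        raise ValueError("Nt must be positive")
    if m < 0:
        raise ValueError("m must be >= 0")
    return m / Nt
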