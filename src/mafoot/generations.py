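"""Generation accounting for bottlenecked mutation-accumulation lines.

Each passage restreaks a line from a random single cell, so the number
of cell divisions between bottlenecks is the number of doublings needed
to build the colony: a colony of N cells grown from one cell without
death spans G = log2(N) generations.  Totals per line are products
(bottlenecks x generations/bottleneck) and experiment totals are sums
over lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .genome import MALDesign

__all__ = [
    "GenerationModel",
    "generations_per_bottleneck",
    "arm_generations",
    "total_experiment_generations",
]


def generations_per_bottleneck(n_cells: float) -> float:
    """Generations spanned by one single-cell bottleneck: log2 of colony size."""
    if n_cells < 1:
        raise ValueError(f"colony size must be >= 1 cell, got {n_cells}")
    return math.log2(n_cells)


def arm_generations(n_bottlenecks: int, gens_per_bottleneck: float) -> float:
    """Total generations of one line (arm): bottlenecks x generations each."""
    if n_bottlenecks < 0 or gens_per_bottleneck < 0:
        raise ValueError("negative generation inputs")
    total = n_bottlenecks * gens_per_bottleneck
    # keep exact integers exact (120 * 23 -> 2760, not 2759.999...)
    return float(total)


def total_experiment_generations(design: MALDesign) -> float:
    """Sum of per-line total generations over the whole experiment."""
    return float(sum(ln.total_generations for ln in design))


@dataclass(frozen=True)
class GenerationModel:
    """Bottleneck growth model: colony size N implies G = log2(N)."""

    n_cells_per_colony: float
    n_bottlenecks: int

    @property
    def gens_per_bottleneck(self) -> float:
        return generations_per_bottleneck(self.n_cells_per_colony)

    @property
    def total_generations(self) -> float:
        return arm_generations(self.n_bottlenecks, self.gens_per_bottleneck)
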