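"""Mutational-signature refitting by non-negative least squares with
strict backward elimination.

Refitting decomposes an observed 96-channel (or 83-channel indel)
spectrum as a non-negative combination of catalog signatures.  Plain
NNLS tends to spread small spurious exposures over many signatures, so
a strict loop prunes them: at each step the signature whose removal
costs the least reconstruction cosine similarity is dropped and the
remainder refitted, as long as that cost stays below a cutoff
(default 0.004).  Only refitting is provided; no de-novo extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .spectra import cosine_similarity

__all__ = ["SignatureFit", "fit_signatures_strict", "read_signature_catalog"]


@dataclass
class SignatureFit:
    """Result of strict signature refitting."""

    exposures: dict[str, float]  # retained signature -> contribution (counts)
    reconstruction: np.ndarray
    cosine: float
    removed: tuple[str, ...]

    @property
    def retained(self) -> tuple[str, ...]:
        return tuple(self.exposures)

    def relative_exposures(self) -> dict[str, float]:
        tot = sum(self.exposures.values())
        if tot == 0:
            return {k: 0.0 for k in self.exposures}
        return {k: v / tot for k, v in self.exposures.items()}


def read_signature_catalog(path) -> pd.DataFrame:
    """Read a signature catalog TSV: first column channel key, one column
    per signature.  Columns are normalized to sum to 1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError("empty signature catalog")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative catalog entry")
    return df / df.sum(axis=0)


def _nnls_fit(profile: np.ndarray, mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    coef, _ = nnls(mat, profile)
    return coef, mat @ coef


def fit_signatures_strict(
    profile96,
    catalog: pd.DataFrame,
    cutoff: float = 0.004,
) -> SignatureFit:
    """Fit a spectrum against a signature catalog, pruning weak signatures.

    Parameters
    ----------
    profile96
        Observed channel counts, as a vector aligned with the catalog
        rows or a mapping from channel key to count.
    catalog
        DataFrame, rows = channels, columns = signatures; columns are
        (re)normalized to unit sum.
    cutoff
        Maximum tolerated decrease in reconstruction cosine similarity
        per removal step.

    Returns
    -------
    SignatureFit with non-negative exposures over the retained
    signatures, the reconstruction, its cosine similarity to the
    profile, and the pruned signatures in removal order.
    """
    if catalog.shape[1] == 0:
        raise ValueError("empty signature catalog")
    if isinstance(profile96, dict):
        profile = np.array([float(profile96.get(ch, 0.0)) for ch in catalog.index])
    else:
        profile = np.asarray(profile96, dtype=float)
    if profile.shape != (catalog.shape[0],):
        raise ValueError(
            f"profile length {profile.shape} does not match catalog rows {catalog.shape[0]}"
        )
    if (profile < 0).any():
        raise ValueError("negative profile entry")
    if not profile.any():
        raise ValueError("all-zero profile")
    colsums = catalog.sum(axis=0)
    if (colsums <= 0).any():
        raise ValueError("catalog column with zero mass")
    catalog = catalog / colsums

    names = list(catalog.columns)
    mat = catalog.to_numpy(dtype=float)
    kept = list(range(len(names)))
    removed: list[str] = []

    coef, recon = _nnls_fit(profile, mat[:, kept])
    cos = cosine_similarity(profile, recon)

    while len(kept) > 1:
        # try removing each retained signature; keep the cheapest removal
        best_j, best_cos, best_fit = None, -np.inf, None
        for j in range(len(kept)):
            trial = kept[:j] + kept[j + 1 :]
            c, r = _nnls_fit(profile, mat[:, trial])
            cs = cosine_similarity(profile, r)
            if cs > best_cos:
                best_j, best_cos, best_fit = j, cs, (c, r)
        if cos - best_cos < cutoff:
            removed.append(names[kept.pop(best_j)])
            coef, recon = best_fit
            cos = best_cos
        else:
            break

    exposures = {names[i]: float(c) for i, c in zip(kept, coef)}
    return SignatureFit(
        exposures=exposures,
        reconstruction=recon,
        cosine=float(cos),
        removed=tuple(removed),
    )
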