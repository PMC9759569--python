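"""Diversity indices from time-averaged relative abundances."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import _as_values
from .exceptions import InputError


@dataclass
class DiversityIndices:
    richness: int        #: number of species with positive temporal mean
    shannon: float       #: H = -sum q_i ln q_i (natural log)
    inv_simpson: float   #: 1 / sum q_i^2


def diversity_indices(X) -> DiversityIndices:
    """Richness, Shannon H and inverse Simpson from temporal mean abundances.

    Relative abundances q_i = mu_i / mu_tot are computed from each species'
    mean over the whole series (species pooled over years, not per-year).
    """
    values = _as_values(X)
    mu = values.mean(axis=0)
    mu = mu[mu > 0]
    if mu.size == 0:
        raise InputError("no species with positive mean abundance")
    q = mu / mu.sum()
    shannon = float(-(q * np.log(q)).sum())
    inv_simpson = float(1.0 / (q ** 2).sum())
    return DiversityIndices(richness=int(mu.size), shannon=shannon,
                            inv_simpson=inv_simpson)
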