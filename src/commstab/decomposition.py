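"""Multiplicative decomposition of community temporal stability.

Community stability S_com = mu_tot / sigma_tot (the inverse CV of total
biomass) factors exactly as

    S_com = Phi * S_pop            Phi  = sum_i sigma_i / sigma_tot
    Phi   = SAE * CPE              SAE  = sum_i sigma_i / sqrt(sum_i sigma_i^2)
                                   CPE  = sqrt(sum_i sigma_i^2) / sigma_tot
    SAE   = EVN * sqrt(S)          (sqrt(S) is SAE at perfect variance evenness)

where S_pop = mu_tot / sum_i sigma_i is the stability of a perfectly
synchronous community, Phi is the Loreau-de Mazancourt asynchrony index,
SAE the statistical-averaging (portfolio) effect, CPE the compensatory
effect (CPE = 1/sqrt(phi) for the classic variance ratio phi), and
EVN the evenness-of-variances effect.  theta = 1/Phi^2 is the
Loreau-de Mazancourt synchrony statistic sigma_tot^2 / (sum_i sigma_i)^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator

from .community import CommunityMatrix, MomentSet, _as_values, species_moments, _REL_ZERO
from .exceptions import DegenerateDataError

logger = logging.getLogger(__name__)

#: canonical ordering of the decomposition fields in tabular output
COMPONENT_FIELDS = (
    "s_com", "s_pop", "phi", "sae", "cpe",
    "var_ratio", "sae_even", "evn", "theta",
)


@dataclass
class StabilityComponents:
    """The primary decomposition of one plot (all quantities dimensionless)."""

    s_com: float        #: community stability mu_tot / sigma_tot
    s_pop: float        #: population stability mu_tot / sum(sigma_i)
    phi: float          #: asynchrony, sum(sigma_i) / sigma_tot
    sae: float          #: statistical-averaging effect, in [1, sqrt(S)]
    cpe: float          #: compensatory effect, 1/sqrt(var_ratio)
    var_ratio: float    #: classic variance ratio sigma_tot^2 / sum(sigma_i^2)
    sae_even: float     #: sqrt(S), SAE under perfect variance evenness
    evn: float          #: evenness effect SAE / sqrt(S), in (0, 1]
    theta: float        #: Loreau-de Mazancourt synchrony, 1/phi^2
    n_species: int      #: richness S actually used

    def as_dict(self) -> dict:
        return asdict(self)


def components_from_moments(
    mu_tot: float,
    sds: np.ndarray,
    v_tot: float,
) -> StabilityComponents:
    """Evaluate the decomposition from first and second moments.

    Works for sample moments (a fitted plot) and for population moments
    (the analytic oracle of a simulation scenario) alike.
    """
    sds = np.asarray(sds, dtype=float)
    S = int(sds.size)
    sum_sd = float(sds.sum())
    sum_var = float((sds ** 2).sum())
    if sum_var <= 0:
        raise DegenerateDataError("degenerate community: zero total variance")
    if v_tot <= _REL_ZERO * sum_var:
        # perfectly compensatory: total biomass has no variance, CV undefined
        raise DegenerateDataError("zero total variance")
    sigma_tot = float(np.sqrt(v_tot))
    if S == 1:
        logger.info("single-species community: Phi = SAE = CPE = 1 by construction")
        s = mu_tot / sigma_tot
        return StabilityComponents(
            s_com=s, s_pop=s, phi=1.0, sae=1.0, cpe=1.0,
            var_ratio=1.0, sae_even=1.0, evn=1.0, theta=1.0, n_species=1,
        )
    s_com = mu_tot / sigma_tot
    s_pop = mu_tot / sum_sd
    phi = sum_sd / sigma_tot
    sae = sum_sd / np.sqrt(sum_var)
    cpe = np.sqrt(sum_var) / sigma_tot
    var_ratio = v_tot / sum_var
    sae_even = float(np.sqrt(S))
    return StabilityComponents(
        s_com=float(s_com), s_pop=float(s_pop), phi=float(phi),
        sae=float(sae), cpe=float(cpe), var_ratio=float(var_ratio),
        sae_even=sae_even, evn=float(sae / sae_even), theta=float(1.0 / phi ** 2),
        n_species=S,
    )


class StabilityDecomposition(BaseEstimator):
    """Estimator computing the stability decomposition of one plot.

    Parameters
    ----------
    ddof : int, default 1
        Delta degrees of freedom of the temporal variances and covariances
        (1 = sample moments).  All components are ratios of moments computed
        with the same ddof.

    Attributes
    ----------
    moments_ : MomentSet
        Temporal moments of the fitted plot.
    components_ : StabilityComponents
    s_com_, s_pop_, phi_, sae_, cpe_, var_ratio_, sae_even_, evn_, theta_ : float
        The individual components, mirrored from ``components_``.
    n_species_ : int

    Examples
    --------
    >>> import numpy as np
    >>> X = np.column_stack([[2, 4, 2, 4], [1, 3, 3, 1]])
    >>> dec = StabilityDecomposition().fit(X)
    >>> round(dec.cpe_, 12)   # zero sample covariance -> CPE = 1
    1.0
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        """Compute the decomposition of a (time, species) matrix.

        ``X`` may be a CommunityMatrix, a wide DataFrame (rows = years,
        columns = species) or a plain (T, S) array.
        """
        m = species_moments(X, ddof=self.ddof)
        comp = components_from_moments(m.mu_tot, m.sds, m.v_tot)
        self.moments_ = m
        self.components_ = comp
        self.n_species_ = comp.n_species
        for name in COMPONENT_FIELDS:
            setattr(self, name + "_", getattr(comp, name))
        return self

    def score(self, X=None, y=None) -> float:
        """Community stability of the fitted plot (higher = more stable)."""
        return self.s_com_


# -- thin functional wrappers ------------------------------------------------

def decompose(X, ddof: int = 1) -> StabilityComponents:
    """Full stability decomposition of one plot."""
    return StabilityDecomposition(ddof=ddof).fit(X).components_


def variance_ratio(X, ddof: int = 1) -> float:
    """Classic variance ratio phi = sigma_tot^2 / sum_i sigma_i^2 (= 1/CPE^2)."""
    return decompose(X, ddof=ddof).var_ratio


def loreau_theta(X, ddof: int = 1) -> float:
    """Loreau-de Mazancourt synchrony theta = sigma_tot^2 / (sum_i sigma_i)^2."""
    return decompose(X, ddof=ddof).theta


def s_com_ip(moments: MomentSet) -> float:
    """Stability of the independent-populations community, mu_tot / sqrt(sum v_i)."""
    return moments.mu_tot / np.sqrt(moments.sum_variances())
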