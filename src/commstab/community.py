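"""The species-by-time abundance record of a single plot and its temporal moments.

A :class:`CommunityMatrix` holds the biomass (or percent-cover) time series
x_i(t) of the S species recorded in one plot over T census years.  All
stability statistics are functions of the temporal moments of these series:
per-species means mu_i, standard deviations sigma_i, and the full S x S
covariance matrix v_ij, summarised in a :class:`MomentSet`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, InputError

logger = logging.getLogger(__name__)

#: covariance totals below this fraction of the summed species variances are
#: treated as numerically zero (sigma_tot undefined)
_REL_ZERO = 1e-12


@dataclass
class CommunityMatrix:
    """One plot's species-by-time abundance record.

    Parameters
    ----------
    values : (T, S) array
        Abundance of each species (columns) at each time point (rows).
        Absence is coded 0.  Species that are zero at every time point are
        dropped at construction (logged).
    species : sequence of str
        Species identifiers, one per column.
    times : sequence
        Time labels (years), one per row.
    plot_id, site_id : str
        Identifiers used for grouping and reporting.
    """

    values: np.ndarray
    species: list[str]
    times: list
    plot_id: str = "plot"
    site_id: str = "site"
    units: str = "abundance"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InputError("values must be a 2-D time-by-species array")
        self.species = [str(s) for s in self.species]
        self.times = list(self.times)
        if v.shape != (len(self.times), len(self.species)):
            raise InputError(
                f"values shape {v.shape} does not match "
                f"{len(self.times)} times x {len(self.species)} species"
            )
        if np.isnan(v).any():
            raise InputError(
                f"plot {self.plot_id!r}: missing values are not allowed; "
                "complete years are required"
            )
        if v.shape[0] < 2:
            raise InputError(f"plot {self.plot_id!r}: need at least 2 time points")
        if v.shape[1] < 1:
            raise InputError(f"plot {self.plot_id!r}: need at least 1 species")
        # drop species never observed in this plot
        nonzero = (v != 0).any(axis=0)
        if not nonzero.all():
            dropped = [s for s, keep in zip(self.species, nonzero) if not keep]
            logger.info(
                "plot %s: dropping %d all-zero species column(s): %s",
                self.plot_id, len(dropped), ", ".join(dropped),
            )
            v = v[:, nonzero]
            self.species = [s for s, keep in zip(self.species, nonzero) if keep]
            if v.shape[1] == 0:
                raise InputError(f"plot {self.plot_id!r}: all species columns are zero")
        if v.shape[0] < 10:
            logger.warning(
                "plot %s: only %d time points; stability estimates from short "
                "series are noisy", self.plot_id, v.shape[0],
            )
        self.values = v

    # -- basic views -------------------------------------------------------
    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    def series(self, species: str) -> np.ndarray:
        """Time series of one species."""
        try:
            j = self.species.index(str(species))
        except ValueError:
            raise InputError(f"species {species!r} not in plot {self.plot_id!r}")
        return self.values[:, j]

    def total(self) -> np.ndarray:
        """Total community abundance x_tot(t)."""
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with columns site, plot, year, species, abundance."""
        wide = pd.DataFrame(self.values, index=self.times, columns=self.species)
        long = wide.stack().rename("abundance").reset_index()
        long.columns = ["year", "species", "abundance"]
        long.insert(0, "plot", self.plot_id)
        long.insert(0, "site", self.site_id)
        return long

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        plot_id: str = "plot",
        site_id: str = "site",
        units: str = "abundance",
    ) -> "CommunityMatrix":
        """Build from a long-format frame with columns year, species, abundance."""
        wide = df.pivot_table(
            index="year", columns="species", values="abundance",
            aggfunc="sum", fill_value=0.0,
        ).sort_index()
        return cls(
            values=wide.to_numpy(dtype=float),
            species=list(wide.columns),
            times=list(wide.index),
            plot_id=plot_id,
            site_id=site_id,
            units=units,
        )


@dataclass
class MomentSet:
    """Temporal sample moments of one plot.

    ``cov`` uses the same denominator as the per-species variances (ddof),
    so ``cov[i, i] == variances[i]`` exactly and
    ``v_tot == cov.sum() == sigma_tot**2``.
    """

    means: np.ndarray
    sds: np.ndarray
    variances: np.ndarray
    cov: np.ndarray
    mu_tot: float
    v_tot: float
    sigma_tot: float
    ddof: int = 1
    n_times: int = field(default=0)

    def sum_sds(self) -> float:
        return float(self.sds.sum())

    def sum_variances(self) -> float:
        return float(self.variances.sum())


def _as_values(X) -> np.ndarray:
    """Accept a CommunityMatrix, DataFrame or (T, S) array; return the array."""
    if isinstance(X, CommunityMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    v = np.asarray(X, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if v.ndim != 2:
        raise InputError("expected a (time, species) matrix")
    if np.isnan(v).any():
        raise InputError("missing values are not allowed")
    return v


def species_moments(X, ddof: int = 1) -> MomentSet:
    """Temporal means, sds and the full covariance matrix of a plot.

    Raises
    ------
    DegenerateDataError
        If every species is constant through time (sigma_tot = 0, so the
        community coefficient of variation is undefined).
    """
    v = _as_values(X)
    T, S = v.shape
    if T <= ddof:
        raise InputError(f"need more than {ddof} time points for ddof={ddof}")
    means = v.mean(axis=0)
    cov = np.atleast_2d(np.cov(v, rowvar=False, ddof=ddof))
    variances = np.diag(cov).copy()
    sds = np.sqrt(variances)
    if not (variances > 0).any():
        raise DegenerateDataError("degenerate community: zero total variance")
    v_tot = float(cov.sum())
    mu_tot = float(means.sum())
    sigma_tot = float(np.sqrt(max(v_tot, 0.0)))
    return MomentSet(
        means=means, sds=sds, variances=variances, cov=cov,
        mu_tot=mu_tot, v_tot=v_tot, sigma_tot=sigma_tot,
        ddof=ddof, n_times=T,
    )
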