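"""AAFT surrogate series and the bootstrap confidence interval for CPE.

The amplitude-adjusted Fourier transform (AAFT) produces a resampled series
that is an exact permutation of the input values (so the marginal
distribution, mean and sd are preserved exactly) while approximately
preserving the input's power spectrum, with randomised Fourier phases.
Surrogating every species column of a plot independently instantiates the
null hypothesis that species fluctuate independently while each keeps its
own autocorrelation and value distribution; the distribution of
CPE^(i) = S_com / S_com_ip^(i) over surrogate datasets then yields a
confidence interval for the compensatory effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .community import species_moments, _as_values
from .decomposition import components_from_moments
from .exceptions import DegenerateDataError, InputError

logger = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    """CPE point estimate with an AAFT-surrogate quantile confidence interval."""

    cpe_point: float
    n_surrogates: int
    ci_levels: tuple[float, float]
    ci: tuple[float, float]
    cpe_samples: np.ndarray = field(repr=False)
    seed: int | None = None


@lru_cache(maxsize=128)
def _normal_scores(n: int) -> np.ndarray:
    """Van der Waerden scores Phi^-1(k/(n+1)), k = 1..n (cached, read-only)."""
    scores = stats.norm.ppf(np.arange(1, n + 1) / (n + 1.0))
    scores.setflags(write=False)
    return scores


def aaft_surrogate(series, rng: np.random.Generator) -> np.ndarray:
    """One AAFT surrogate of a time series.

    Steps: map the ranks of the input onto deterministic normal scores
    (ties broken by a random permutation), randomise the Fourier phases of
    the Gaussianised series under Hermitian symmetry (DC kept, the Nyquist
    bin for even length gets a random sign), then map the ranks of the
    phase-randomised series back onto the sorted original values.  The
    output is therefore an exact permutation of the input.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise InputError("aaft_surrogate expects a 1-D series")
    n = x.size
    if n < 3:
        raise InputError("need a series of length >= 3")
    if np.ptp(x) == 0:
        raise DegenerateDataError("cannot surrogate constant series")

    # ranks with random tie-breaking
    order = np.lexsort((rng.permutation(n), x))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)

    # Gaussianise via van der Waerden normal scores
    g = _normal_scores(n)[ranks]

    # Hermitian phase randomisation
    G = np.fft.rfft(g)
    phases = rng.uniform(0.0, 2.0 * np.pi, G.size)
    rot = np.exp(1j * phases)
    rot[0] = 1.0
    if n % 2 == 0:
        rot[-1] = 1.0 if rng.random() < 0.5 else -1.0
    gs = np.fft.irfft(G * rot, n)

    # back-transform: rank-remap onto the original sorted values
    out = np.empty(n)
    out[np.argsort(gs, kind="stable")] = x[order]
    return out


def surrogate_dataset(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Surrogate every species column independently; constant columns pass through."""
    T, S = values.shape
    out = np.empty_like(values, dtype=float)
    for j in range(S):
        col = values[:, j]
        if np.ptp(col) == 0:
            logger.warning("constant species column %d left unsurrogated", j)
            out[:, j] = col
        else:
            out[:, j] = aaft_surrogate(col, rng)
    return out


class CPEBootstrap(BaseEstimator):
    """AAFT bootstrap for the compensatory effect of one plot.

    For each of ``n_surrogates`` datasets, every species column is replaced
    by an independent AAFT surrogate and the stability of the surrogate
    community, S_com_ip^(i), is computed; CPE^(i) = S_com / S_com_ip^(i).
    Because each surrogate is an exact permutation of its column, per-species
    means and sds (hence S_pop and sum_i sigma_i) are identical across
    surrogate datasets.

    Parameters
    ----------
    n_surrogates : int, default 1000
    ci_levels : (float, float), default (0.025, 0.975)
        Empirical quantile levels of the CPE^(i) distribution (linear
        interpolation of order statistics).
    random_state : int, Generator or None

    Attributes
    ----------
    cpe_point_ : float
    ci_ : (float, float)
    cpe_samples_ : ndarray of shape (n_surrogates,)
    result_ : BootstrapResult
    """

    def __init__(self, n_surrogates: int = 1000,
                 ci_levels: tuple[float, float] = (0.025, 0.975),
                 ddof: int = 1, random_state=None):
        self.n_surrogates = n_surrogates
        self.ci_levels = ci_levels
        self.ddof = ddof
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.n_surrogates < 1:
            raise InputError("need at least 1 surrogate")
        lo, hi = self.ci_levels
        if not (0 <= lo < hi <= 1):
            raise InputError("ci_levels must satisfy 0 <= lo < hi <= 1")
        rng = self.random_state if isinstance(self.random_state, np.random.Generator) \
            else np.random.default_rng(self.random_state)
        seed = self.random_state if isinstance(self.random_state, (int, np.integer)) else None

        values = _as_values(X)
        m = species_moments(values, ddof=self.ddof)
        comp = components_from_moments(m.mu_tot, m.sds, m.v_tot)

        samples = np.empty(self.n_surrogates)
        for i in range(self.n_surrogates):
            sur = surrogate_dataset(values, rng)
            tot = sur.sum(axis=1)
            sd_tot = tot.std(ddof=self.ddof)
            if sd_tot <= 0:
                raise DegenerateDataError("surrogate dataset has zero total variance")
            s_com_ip_i = tot.mean() / sd_tot
            samples[i] = comp.s_com / s_com_ip_i

        ci = tuple(float(q) for q in np.quantile(samples, [lo, hi]))
        self.cpe_point_ = comp.cpe
        self.cpe_samples_ = samples
        self.ci_ = ci
        self.result_ = BootstrapResult(
            cpe_point=comp.cpe, n_surrogates=self.n_surrogates,
            ci_levels=(lo, hi), ci=ci, cpe_samples=samples, seed=seed,
        )
        return self


def bootstrap_cpe(X, n: int = 1000, ci_levels=(0.025, 0.975), ddof: int = 1,
                  random_state=None) -> BootstrapResult:
    """Functional wrapper around :class:`CPEBootstrap`."""
    est = CPEBootstrap(n_surrogates=n, ci_levels=tuple(ci_levels), ddof=ddof,
                       random_state=random_state).fit(X)
    return est.result_
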