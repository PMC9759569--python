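"""Secondary decomposition CPE = CPE_env x CPE_int via surrogate communities.

Compensatory dynamics (CPE != 1) can arise from differential species
responses to shared environmental fluctuation, or from species interactions.
To separate the two, a surrogate community stability S_com_sur is built in
which interaction-driven covariance is eliminated but environment-driven
covariance is kept: between-species covariances are replaced by covariances
with series of the same species taken from *other* plots (which share the
environment but cannot interact with the focal plot's populations), or from
monocultures grown alongside the mixtures.  Then

    CPE_env = S_com_sur / S_com_ip      CPE_int = S_com / S_com_sur

so that CPE_env * CPE_int = CPE exactly for a single surrogate draw.

Donor series are affinely rescaled to the focal species' mean and sd before
covariances are taken, so only their correlation structure matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .community import CommunityMatrix, species_moments
from .decomposition import components_from_moments, s_com_ip
from .exceptions import DegenerateDataError, InputError

logger = logging.getLogger(__name__)


@dataclass
class SurrogateCovariance:
    """The surrogate covariance matrix C of one donor-plot construction.

    Diagonal entries are the focal plot's species variances; off-diagonal
    C[i, j] = cov(x_i, Z_j) with Z_j the rescaled donor series of species j.
    C is generally asymmetric because Z_i and Z_j may come from different
    donor plots; it is summed over ordered pairs exactly as constructed.
    """

    C: np.ndarray
    donor_map: dict[str, str]


@dataclass
class SecondaryComponents:
    """CPE split into environmental and interaction parts (means over repeats)."""

    s_com: float
    s_com_ip: float       #: mu_tot / sqrt(sum_i v_i), independent-populations stability
    s_com_sur: float      #: surrogate community stability (mean over repeats)
    cpe: float
    cpe_env: float        #: S_com_sur / S_com_ip
    cpe_int: float        #: S_com / S_com_sur
    method: str           #: "donor_plot" or "monoculture"
    n_repeats: int
    seed: int | None
    cpe_env_samples: np.ndarray = field(repr=False, default=None)
    cpe_int_samples: np.ndarray = field(repr=False, default=None)


def rescale_to_reference(z, ref_mean: float, ref_sd: float, ddof: int = 1) -> np.ndarray:
    """Affinely map a series to a reference mean and sd.

    The output is (z - mean(z)) / sd(z) * ref_sd + ref_mean, so its
    correlations with any other series equal those of ``z``.
    """
    z = np.asarray(z, dtype=float)
    sd = z.std(ddof=ddof)
    if sd == 0:
        raise DegenerateDataError("constant donor series")
    if ref_sd < 0:
        raise InputError("reference sd must be non-negative")
    return (z - z.mean()) / sd * ref_sd + ref_mean


def _check_same_times(focal: CommunityMatrix, other_times: Sequence, what: str) -> None:
    if list(other_times) != list(focal.times):
        raise InputError(
            f"{what} must cover the same time points as the focal plot "
            f"({len(other_times)} vs {len(focal.times)})"
        )


def surrogate_stability_from_plots(
    focal: CommunityMatrix,
    donors: Sequence[CommunityMatrix],
    rng: np.random.Generator,
    ddof: int = 1,
) -> tuple[float, SurrogateCovariance]:
    """One draw of the donor-plot surrogate community stability.

    For each focal species j, a donor plot containing species j (with
    positive variance there) is chosen uniformly at random; its series is
    rescaled to the focal species-j mean and sd and used to form the
    surrogate covariance column C[:, j].  Species with no donor anywhere
    contribute zero off-diagonal covariance (independence fallback, logged).
    """
    if not donors:
        raise InputError("donor-plot surrogate needs at least one donor plot")
    m = species_moments(focal, ddof=ddof)
    x = focal.values
    S = focal.n_species
    C = np.diag(m.variances).astype(float)
    donor_map: dict[str, str] = {}
    for j, sp in enumerate(focal.species):
        eligible = []
        for d in donors:
            if d.plot_id == focal.plot_id and d.site_id == focal.site_id:
                continue
            if sp in d.species:
                zj = d.series(sp)
                if zj.std(ddof=ddof) > 0:
                    eligible.append((d, zj))
        if not eligible:
            donor_map[sp] = "none"
            logger.warning(
                "plot %s: species %s has no donor plot; treating its "
                "between-species covariances as zero", focal.plot_id, sp,
            )
            C[:, j][np.arange(S) != j] = 0.0
            continue
        d, zj = eligible[int(rng.integers(len(eligible)))]
        _check_same_times(focal, d.times, f"donor plot {d.plot_id!r}")
        donor_map[sp] = d.plot_id
        if m.sds[j] > 0:
            Zj = rescale_to_reference(zj, m.means[j], m.sds[j], ddof=ddof)
        else:
            Zj = np.full(focal.n_times, m.means[j])
        for i in range(S):
            if i != j:
                C[i, j] = _cov(x[:, i], Zj, ddof)
    total = float(C.sum())
    if total <= 0:
        raise DegenerateDataError("non-positive surrogate variance")
    s_sur = m.mu_tot / np.sqrt(total)
    return float(s_sur), SurrogateCovariance(C=C, donor_map=donor_map)


def _cov(a: np.ndarray, b: np.ndarray, ddof: int) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / (a.size - ddof))


def surrogate_stability_from_monocultures(
    X: CommunityMatrix,
    monocultures: Mapping[str, Sequence[np.ndarray]],
    rng: np.random.Generator,
    ddof: int = 1,
) -> float:
    """One draw of the monoculture surrogate community stability.

    Each focal species i must have at least one monoculture series y_i over
    the same time points; one is selected uniformly at random, rescaled to
    the focal mean(x_i) and sd(x_i), and the surrogate stability is the
    inverse CV of the summed rescaled series:
    S_com_sur = mean(Y_tot) / sd(Y_tot), with mean(Y_tot) = mu_tot by
    construction.
    """
    m = species_moments(X, ddof=ddof)
    T = X.n_times
    y_tot = np.zeros(T)
    for i, sp in enumerate(X.species):
        series_list = list(monocultures.get(sp, []))
        if not series_list:
            raise InputError(
                f"no monoculture series for species {sp!r}; the monoculture "
                "method requires full coverage (use the donor-plot method otherwise)"
            )
        y = np.asarray(series_list[int(rng.integers(len(series_list)))], dtype=float)
        if y.size != T:
            raise InputError(
                f"monoculture series for {sp!r} has length {y.size}, expected {T}"
            )
        if m.sds[i] > 0:
            Y = rescale_to_reference(y, m.means[i], m.sds[i], ddof=ddof)
        else:
            Y = np.full(T, m.means[i])
        y_tot += Y
    sd_tot = y_tot.std(ddof=ddof)
    if sd_tot <= 0:
        raise DegenerateDataError("zero total variance in surrogate community")
    return float(y_tot.mean() / sd_tot)


class SecondaryDecomposition(BaseEstimator):
    """Estimator splitting CPE into CPE_env and CPE_int via surrogates.

    Parameters
    ----------
    method : {"monoculture", "donor_plot"}
        Source of the non-interacting surrogate series.
    n_repeats : int or None
        Number of random donor/monoculture selections averaged over.
        Defaults to 100 for the monoculture method and 1 for donor plots.
    average : {"arithmetic", "geometric"}
        How CPE_env and CPE_int are averaged over repeats.  The arithmetic
        mean of the ratios is the conventional choice; the geometric mean
        preserves CPE_env * CPE_int = CPE across repeats.
    random_state : int, Generator or None
        Seed for donor/monoculture selection.

    Attributes
    ----------
    cpe_env_, cpe_int_, s_com_sur_, s_com_ip_, cpe_, s_com_ : float
    components_ : SecondaryComponents
    """

    def __init__(self, method: str = "monoculture", n_repeats: int | None = None,
                 average: str = "arithmetic", ddof: int = 1, random_state=None):
        self.method = method
        self.n_repeats = n_repeats
        self.average = average
        self.ddof = ddof
        self.random_state = random_state

    def fit(self, X: CommunityMatrix, y=None, *, donors=None, monocultures=None):
        if self.method not in ("monoculture", "donor_plot"):
            raise InputError(f"unknown method {self.method!r}")
        if self.average not in ("arithmetic", "geometric"):
            raise InputError(f"unknown average {self.average!r}")
        n_rep = self.n_repeats
        if n_rep is None:
            n_rep = 100 if self.method == "monoculture" else 1
        if n_rep < 1:
            raise InputError("n_repeats must be >= 1")
        rng = _as_generator(self.random_state)
        seed = self.random_state if isinstance(self.random_state, (int, np.integer)) else None

        m = species_moments(X, ddof=self.ddof)
        comp = components_from_moments(m.mu_tot, m.sds, m.v_tot)
        sc_ip = s_com_ip(m)

        sur, env, inter = [], [], []
        errors: list[Exception] = []
        for _ in range(n_rep):
            try:
                if self.method == "monoculture":
                    if monocultures is None:
                        raise InputError("monoculture method requires monocultures=")
                    s = surrogate_stability_from_monocultures(
                        X, monocultures, rng, ddof=self.ddof)
                else:
                    if donors is None:
                        raise InputError("donor_plot method requires donors=")
                    s, _ = surrogate_stability_from_plots(
                        X, donors, rng, ddof=self.ddof)
            except (InputError,) as exc:
                raise
            except DegenerateDataError as exc:
                errors.append(exc)
                continue
            sur.append(s)
            env.append(s / sc_ip)
            inter.append(comp.s_com / s)
        if not sur:
            raise DegenerateDataError(
                f"all {n_rep} surrogate repeats failed; last error: {errors[-1]}"
            )
        env = np.asarray(env)
        inter = np.asarray(inter)
        if self.average == "arithmetic":
            cpe_env, cpe_int = float(env.mean()), float(inter.mean())
        else:
            cpe_env = float(np.exp(np.log(env).mean()))
            cpe_int = float(np.exp(np.log(inter).mean()))

        self.components_ = SecondaryComponents(
            s_com=comp.s_com, s_com_ip=sc_ip, s_com_sur=float(np.mean(sur)),
            cpe=comp.cpe, cpe_env=cpe_env, cpe_int=cpe_int,
            method=self.method, n_repeats=len(sur), seed=seed,
            cpe_env_samples=env, cpe_int_samples=inter,
        )
        self.s_com_ = comp.s_com
        self.cpe_ = comp.cpe
        self.s_com_ip_ = sc_ip
        self.s_com_sur_ = self.components_.s_com_sur
        self.cpe_env_ = cpe_env
        self.cpe_int_ = cpe_int
        return self


def _as_generator(random_state) -> np.random.Generator:
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


def secondary_decompose(
    X: CommunityMatrix,
    *,
    method: str = "monoculture",
    donors: Sequence[CommunityMatrix] | None = None,
    monocultures: Mapping[str, Sequence[np.ndarray]] | None = None,
    n_repeats: int | None = None,
    average: str = "arithmetic",
    ddof: int = 1,
    random_state=None,
) -> SecondaryComponents:
    """Functional wrapper around :class:`SecondaryDecomposition`."""
    est = SecondaryDecomposition(
        method=method, n_repeats=n_repeats, average=average,
        ddof=ddof, random_state=random_state,
    )
    est.fit(X, donors=donors, monocultures=monocultures)
    return est.components_
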