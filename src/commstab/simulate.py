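"""Moment-specified Gaussian community simulator with analytic ground truth.

Abundances in each plot follow

    x(t) = mu + B e(t) + u(t) + d(t)

where e(t) ~ N(0, I_K) is an environmental driver shared by all plots (and
monocultures) of the site, B the S x K matrix of species-specific
environmental loadings, u(t) zero-mean noise carrying the interaction
covariance Sigma_int (plot-specific), and d(t) independent demographic
noise with variances D.  The total species covariance is therefore

    Sigma = B B' + Sigma_int + diag(D)

and every decomposition component has a closed form in (mu, Sigma), which
:func:`analytic_components` evaluates — the oracle against which the sample
estimators are validated.  Matched monocultures share the same e(t) but have
their own demographic noise, mirroring single-species plots grown alongside
mixtures.

Draws are Gaussian without truncation at zero: truncation would distort the
moment structure the oracle relies on, at the cost of occasional negative
abundances when a species' mean is small relative to its sd.  A lognormal
option is available for realism but has no closed-form compensatory-effect
oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .community import CommunityMatrix
from .decomposition import StabilityComponents, components_from_moments
from .exceptions import DegenerateDataError, InputError

logger = logging.getLogger(__name__)


@dataclass
class SimScenario:
    """Generative parameters of one simulated site.

    Attributes
    ----------
    mu : (S,) array of positive species mean abundances (e.g. g/m^2)
    env_loadings : (S, K) array B of responses to K shared drivers
    interaction_cov : (S, S) symmetric matrix Sigma_int; competitive
        interactions appear as negative off-diagonal entries
    dem_var : (S,) positive demographic variances D
    T : number of census years per plot
    n_plots : replicate mixture plots sharing the driver
    n_monocultures : matched monoculture plots per species
    lognormal : if True, draws are exponentiated after matching log-scale
        moments (no closed-form oracle for the compensatory effect)
    """

    mu: np.ndarray
    env_loadings: np.ndarray
    interaction_cov: np.ndarray
    dem_var: np.ndarray
    T: int = 30
    n_plots: int = 1
    n_monocultures: int = 1
    seed: int | None = None
    site_id: str = "sim"
    lognormal: bool = False
    #: override for the monoculture noise variances; None matches the
    #: mixture's non-environmental variance (see mono_var). Setting it lower
    #: reproduces the demographic-stochasticity bias of monoculture surrogates
    mono_dem_var: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.env_loadings = np.atleast_2d(np.asarray(self.env_loadings, dtype=float))
        self.interaction_cov = np.asarray(self.interaction_cov, dtype=float)
        self.dem_var = np.asarray(self.dem_var, dtype=float)
        S = self.mu.size
        if self.env_loadings.shape[0] != S:
            raise InputError("env_loadings must have one row per species")
        if self.interaction_cov.shape != (S, S):
            raise InputError("interaction_cov must be S x S")
        if not np.allclose(self.interaction_cov, self.interaction_cov.T):
            raise InputError("interaction_cov must be symmetric")
        if self.dem_var.shape != (S,) or (self.dem_var < 0).any():
            raise InputError("dem_var must be length-S and non-negative")
        if (self.mu <= 0).any():
            raise InputError("species means must be positive")
        if self.T < 2 or self.n_plots < 1:
            raise InputError("need T >= 2 and n_plots >= 1")
        sigma = self.total_cov
        eig = np.linalg.eigvalsh(sigma)
        scale = max(abs(eig[-1]), 1.0)
        if eig[0] < -1e-10 * scale:
            raise InputError(
                f"total covariance is not positive semidefinite "
                f"(eigenvalue {eig[0]:.6g})"
            )
        if (np.diag(sigma) <= 0).any():
            raise InputError("total covariance must have a positive diagonal")
        # interaction + demographic noise is drawn jointly with covariance
        # Sigma_int + diag(D); Sigma_int alone need not be PSD (its diagonal
        # is typically 0) as long as the demographic variances absorb it
        resid = self.interaction_cov + np.diag(self.dem_var)
        lam = np.linalg.eigvalsh(resid)
        if lam[0] < -1e-10 * scale:
            raise InputError(
                f"interaction_cov + diag(dem_var) is not positive semidefinite "
                f"(eigenvalue {lam[0]:.6g}); weaken interactions or increase "
                "demographic variances"
            )

    @property
    def S(self) -> int:
        return self.mu.size

    @property
    def K(self) -> int:
        return self.env_loadings.shape[1]

    @property
    def total_cov(self) -> np.ndarray:
        """Sigma = B B' + Sigma_int + diag(D)."""
        B = self.env_loadings
        return B @ B.T + self.interaction_cov + np.diag(self.dem_var)

    @property
    def mono_var(self) -> np.ndarray:
        """Per-species monoculture noise variance (matches the mixture's
        non-environmental variance, so correlations agree absent interactions)."""
        if self.mono_dem_var is not None:
            v = np.asarray(self.mono_dem_var, dtype=float)
            if v.shape != (self.S,) or (v < 0).any():
                raise InputError("mono_dem_var must be length-S and non-negative")
            return v
        return self.dem_var + np.diag(self.interaction_cov)


def _psd_factor(A: np.ndarray) -> np.ndarray:
    """L with L L' = A for a PSD matrix (eigen clipping at zero)."""
    w, Q = np.linalg.eigh(A)
    w = np.clip(w, 0.0, None)
    return Q * np.sqrt(w)


def simulate_site(
    scn: SimScenario, rng: np.random.Generator | None = None
) -> tuple[list[CommunityMatrix], dict[str, list[np.ndarray]]]:
    """Simulate one site: replicate mixture plots plus matched monocultures.

    All plots and monocultures of the site share a single realisation of the
    environmental driver e(t); interaction and demographic noise are drawn
    independently per plot.  Returns the list of plots and a map
    species -> list of monoculture series.
    """
    if rng is None:
        rng = np.random.default_rng(scn.seed)
    S, K, T = scn.S, scn.K, scn.T
    species = [f"sp{i + 1}" for i in range(S)]
    e = rng.standard_normal((T, K))
    env = e @ scn.env_loadings.T                        # (T, S)

    L_resid = _psd_factor(scn.interaction_cov + np.diag(scn.dem_var))

    plots = []
    for p in range(scn.n_plots):
        r = rng.standard_normal((T, S)) @ L_resid.T
        x = scn.mu + env + r
        if scn.lognormal:
            x = _to_lognormal(x, scn.mu, np.sqrt(np.diag(scn.total_cov)))
        plots.append(CommunityMatrix(
            values=x, species=species, times=list(range(1, T + 1)),
            plot_id=f"{scn.site_id}-p{p + 1}", site_id=scn.site_id,
        ))

    mono_sd = np.sqrt(scn.mono_var)
    monocultures: dict[str, list[np.ndarray]] = {sp: [] for sp in species}
    for _ in range(scn.n_monocultures):
        noise = rng.standard_normal((T, S)) * mono_sd
        y = scn.mu + env + noise
        if scn.lognormal:
            y = _to_lognormal(y, scn.mu, np.sqrt(np.diag(scn.total_cov)))
        for i, sp in enumerate(species):
            monocultures[sp].append(y[:, i])
    return plots, monocultures


def _to_lognormal(x: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Map Gaussian draws to lognormal with the same mean and sd per species."""
    z = (x - mu) / sd
    cv2 = (sd / mu) ** 2
    s = np.sqrt(np.log1p(cv2))
    m = np.log(mu) - 0.5 * s ** 2
    return np.exp(m + s * z)


def analytic_components(scn: SimScenario) -> StabilityComponents:
    """Population-level decomposition implied by (mu, Sigma) — the oracle."""
    if scn.lognormal:
        logger.warning("analytic components refer to the Gaussian moment "
                       "specification; lognormal draws match mean/sd but not "
                       "covariances exactly")
    sigma = scn.total_cov
    v_tot = float(sigma.sum())
    if v_tot <= 0:
        raise DegenerateDataError("degenerate scenario: zero total variance")
    return components_from_moments(
        float(scn.mu.sum()), np.sqrt(np.diag(sigma)), v_tot)


def analytic_secondary(scn: SimScenario) -> dict[str, float]:
    """Expected surrogate stability and CPE_env/CPE_int of the scenario.

    A surrogate built from another plot (or monoculture) shares only the
    environmental driver with the focal plot, so its expected between-species
    covariances are those of B B'; per-species variances are pinned to the
    focal values by the rescaling.
    """
    sigma = scn.total_cov
    B = scn.env_loadings
    sigma_sur = B @ B.T
    np.fill_diagonal(sigma_sur, np.diag(sigma))
    v_sur = float(sigma_sur.sum())
    if v_sur <= 0:
        raise DegenerateDataError("non-positive surrogate variance in scenario")
    mu_tot = float(scn.mu.sum())
    comp = analytic_components(scn)
    s_sur = mu_tot / np.sqrt(v_sur)
    s_ip = mu_tot / np.sqrt(float(np.diag(sigma).sum()))
    return {
        "s_com_sur": float(s_sur),
        "s_com_ip": float(s_ip),
        "cpe_env": float(s_sur / s_ip),
        "cpe_int": float(comp.s_com / s_sur),
    }


def make_scenario(
    S: int = 8,
    T: int = 30,
    n_plots: int = 10,
    n_monocultures: int = 2,
    env_frac: float = 0.4,
    int_frac: float = 0.08,
    cv: float = 0.35,
    mean_range: tuple[float, float] = (20.0, 100.0),
    n_drivers: int = 1,
    seed: int = 0,
    site_id: str = "sim",
    **kwargs,
) -> SimScenario:
    """Build a grassland-like scenario from interpretable fractions.

    Species means are geometrically spaced across ``mean_range`` (g/m^2) and
    each species has temporal coefficient of variation ``cv``.  A fraction
    ``env_frac`` of each species' variance is driven by ``n_drivers`` shared
    environmental drivers with mixed-sign loadings (differential responses),
    ``int_frac`` scales competitive (negative) pairwise covariances, and the
    remainder is demographic.  The sign pattern and loading jitter are drawn
    reproducibly from ``seed``.
    """
    if not 0 <= env_frac < 1:
        raise InputError("env_frac must be in [0, 1)")
    if int_frac < 0:
        raise InputError("int_frac must be >= 0")
    prng = np.random.default_rng(seed)
    mu = np.geomspace(mean_range[1], mean_range[0], S)
    sd = cv * mu
    var = sd ** 2

    if env_frac > 0:
        raw = prng.uniform(0.5, 1.0, (S, n_drivers)) * prng.choice([-1.0, 1.0], (S, n_drivers))
        raw /= np.linalg.norm(raw, axis=1, keepdims=True)
        B = raw * (np.sqrt(env_frac) * sd)[:, None]
    else:
        B = np.zeros((S, n_drivers))

    sigma_int = np.zeros((S, S))
    if int_frac > 0 and S > 1:
        a = np.sqrt(int_frac) * sd
        sigma_int = -(np.outer(a, a) - np.diag(a ** 2)) / (S - 1)

    dem_var = var - env_frac * var
    return SimScenario(
        mu=mu, env_loadings=B, interaction_cov=sigma_int, dem_var=dem_var,
        T=T, n_plots=n_plots, n_monocultures=n_monocultures, seed=seed,
        site_id=site_id, **kwargs,
    )
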