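# Methods

## The decomposition

All quantities are ratios of temporal moments of a single plot's
species-by-time abundance matrix. With per-species means μ_i, standard
deviations σ_i and covariance matrix v (S × S), and μ_tot = Σμ_i,
v_tot = Σ_ij v_ij, σ_tot = √v_tot:

| quantity | definition | reading |
|---|---|---|
| S_com | μ_tot/σ_tot | community stability (inverse CV of total biomass) |
| S_pop | μ_tot/Σσ_i | stability under perfect synchrony |
| Φ | Σσ_i/σ_tot | asynchrony; S_com = Φ·S_pop |
| SAE | Σσ_i/√(Σσ_i²) | statistical averaging; ∈ [1, √S] |
| CPE | √(Σσ_i²)/σ_tot | compensatory effect; Φ = SAE·CPE |
| φ | σ_tot²/Σσ_i² | classic variance ratio; CPE = 1/√φ |
| EVN | SAE/√S | evenness-of-variances effect; ∈ (0, 1] |
| θ | σ_tot²/(Σσ_i)² | Loreau–de Mazancourt synchrony; θ = 1/Φ² |

All identities are algebraic, so they hold to float precision for *any*
non-degenerate data; the test suite fuzzes them at 1e-10 relative.

**Moment conventions.** Variances, sds and covariances all use the sample
denominator T − 1 (`ddof=1`), applied uniformly so that the covariance
diagonal equals the variances exactly and v_tot = σ_tot² by construction.
Because every component is a ratio of same-order moment sums, the choice of
denominator cancels; it is exposed as `ddof` for sensitivity checks.

**Degenerate inputs.** All-zero species columns are dropped at construction
(logged). Constant-but-present species are retained — a zero σ_i contributes
nothing to any σ sum. A community in which every species is constant, or a
perfectly compensatory one with v_tot = 0 (v_tot below 1e-12 of Σσ_i²
numerically), has an undefined CV and raises `DegenerateDataError`.
Single-species plots return the degenerate decomposition
Φ = SAE = CPE = EVN = θ = 1 rather than erroring; the analysis layer
excludes them from diversity regressions via `min_richness` (default 2),
since a one-species plot carries no averaging or compensation to decompose.
Series need T ≥ 2 (hard error); T < 10 draws a log warning because moment
ratios from very short series are noisy (typical survey series run one to
three decades). Missing values are an error — no gap filling or detrending
is performed.

## Secondary decomposition, CPE = CPE_env × CPE_int

Compensatory structure can come from differential responses to a shared
environment or from species interactions. The surrogate construction
replaces each between-species covariance by the covariance between the focal
series x_i and a rescaled series Z_j of species j taken from a source that
shares the environment but cannot interact with the focal populations:

- **Donor plots** (observational designs): Z_j is species j's series from a
  randomly chosen other plot of the same site,
  affinely rescaled to the focal mean(x_j) and sd(x_j). The surrogate
  covariance matrix C has the focal variances on the diagonal and
  C_ij = cov(x_i, Z_j) off it; S_com_sur = μ_tot/√(Σ_ij C_ij). C is used
  exactly as constructed — it is generally asymmetric because Z_i and Z_j
  may come from different donors, and no symmetrisation is applied; the sum
  runs over ordered pairs. A species with no donor anywhere contributes zero
  off-diagonal covariance (independence fallback, logged) rather than
  aborting the plot. A non-positive Σ_ij C_ij is an error.
- **Monocultures** (biodiversity experiments): each species' series from a
  randomly chosen matched monoculture is rescaled to the focal mean/sd and
  summed; S_com_sur = mean(ΣY_i)/sd(ΣY_i), with mean(ΣY_i) = μ_tot exactly
  by construction. Every focal species must have a monoculture (error
  otherwise; the donor method is the fallback design).

Then CPE_env = S_com_sur/S_com_ip (with S_com_ip = μ_tot/√(Σσ_i²), the
stability of the hypothetical independent-populations community) and
CPE_int = S_com/S_com_sur, so CPE_env·CPE_int = CPE exactly for a single
draw. Random selection among eligible donors/monocultures is repeated
(default 100 repeats for monocultures, 1 for donor plots) and the two ratios
are averaged arithmetically; a geometric option preserves the product
identity across repeats, since the quantities are multiplicative. The seed
is a required, recorded input.

Known caveat, deliberately not corrected: demographic stochasticity is
stronger in mixtures (lower per-species abundance) than in monocultures, so
monoculture surrogates can overstate between-species correlation and
understate S_com_sur, biasing CPE_env down and CPE_int up — more so at high
richness. The simulator exposes this through independent demographic noise
in mixtures and monocultures; no correction is attempted because none is
identified.

## AAFT bootstrap for CPE

Each species column is replaced by an amplitude-adjusted Fourier-transform
surrogate: ranks are mapped onto deterministic van der Waerden normal scores
(ties broken by a seeded random permutation), the Gaussianised series'
Fourier phases are randomised under Hermitian symmetry (DC preserved; the
Nyquist bin of even-length series gets a random sign so it stays real), and
the result is rank-remapped onto the original sorted values. The output is
an exact permutation of the input — marginal distribution, mean and sd are
preserved exactly, the power spectrum approximately — while independent
phases across species destroy cross-correlation. Surrogating all columns
therefore instantiates the null "species fluctuate independently, each with
its own autocorrelation and distribution".

For each surrogate dataset i, S_com_ip^(i) is its community stability and
CPE^(i) = S_com/S_com_ip^(i); per-species means and sds (hence S_pop) are
invariant across surrogates by the permutation property. The CI is the
(0.025, 0.975) empirical quantile pair of the CPE^(i) sample (linear
interpolation of order statistics; levels configurable) from 1000 surrogates
by default. Constant columns are passed through unchanged with a warning.
Calibration under the independence null and power against perfect synchrony
are measured in the acceptance suite (coverage ≈ 94–97% at nominal 95% with
200 surrogates; detection of duplicated-species synchrony ≈ 100% at T = 64).

## Diversity and regressions

Richness counts species with positive temporal mean; Shannon H = −Σq ln q
(natural log) and inverse Simpson 1/Σq² use relative abundances
q_i = μ_i/μ_tot from time-averaged means (a per-year-then-average option was
considered and rejected as the default: the decomposition itself is built on
whole-series moments). All components are log10-transformed. Site mode
averages plot-level log10 values per site and reports the standard error
across plots; site-level diversity is the mean of plot-level (transformed)
diversity, paralleling the component averaging. Regressions are unweighted
OLS (statsmodels) of each log10 component on log10 richness, untransformed
Shannon (it already embeds a log), or log10 inverse Simpson. Slope
additivity — slope(logΦ) = slope(logSAE) + slope(logCPE) and
slope(logS_com) = slope(logΦ) + slope(logS_pop) — is an exact consequence
of OLS linearity and is verified at 1e-8 by `check_slope_additivity`.
Significance stars (0.05/0.01/0.001) are formatting only.

## Simulator

`simulate_site` draws, for one site, x(t) = μ + B e(t) + r(t) per plot,
where e(t) ~ N(0, I_K) is shared by all plots and monocultures of the site,
B holds species-specific environmental loadings, and r(t) ~ N(0,
Σ_int + diag(D)) is the plot-specific interaction-plus-demographic residual
(drawing the two jointly is distributionally identical to separate draws and
requires only that their summed covariance be PSD, which is validated with
the offending eigenvalue reported). Total covariance is
Σ = BBᵀ + Σ_int + diag(D); `analytic_components` evaluates the decomposition
on (μ, Σ) and `analytic_secondary` on the environment-only covariance BBᵀ
(with the focal diagonal), giving the expected S_com_sur, CPE_env and
CPE_int of the surrogate methods. Monocultures share e(t) and receive
independent noise with variance D_i + (Σ_int)_ii, matching the mixture's
non-environmental variance so that, absent interactions, mixture and
monoculture correlations agree — the assumption underlying the monoculture
surrogate.

`make_scenario` builds grassland-like scenarios from interpretable
fractions: species means geometrically spaced over 20–100 g/m² (defaults),
per-species CV 0.35, a fraction `env_frac` = 0.4 of each variance from
shared drivers with mixed-sign loadings (differential environmental
responses), pairwise competitive correlation −`int_frac`/(S−1) with
`int_frac` = 0.08, the remainder demographic. These defaults produce
moderate asynchrony (Φ ≈ 1.5–3.5), SAE well below its √S ceiling and CPE on
both sides of 1 depending on the sign mix — the regimes the decomposition is
meant to distinguish.

What the generator emulates: replicated plots sharing an environmental
driver, species-specific loadings, interaction-induced covariance,
demographic noise, matched monocultures. What it does not: abundance
distributions are Gaussian without truncation at zero (truncation would
break the closed-form oracle; negative values can occur when μ_i is small
relative to σ_i, and the CSV reader requires `allow_negative` to ingest
such files — empirical data remain non-negative by validation). A lognormal
option matches means and sds but has no closed-form CPE oracle. There are no
mechanistic dynamics (no density dependence, no Lotka–Volterra), no trends,
no observation error. Passing parameter-recovery tests therefore
demonstrates estimator correctness under the stated moment structure, not
robustness to real-data pathologies such as zeros, skew or trends.

## Numerical choices

- Sample moments with ddof = 1 throughout, including inside the affine
  rescaling (the target sd is attained exactly under the same convention).
- Degeneracy threshold: v_tot ≤ 1e-12 × Σσ_i² is treated as zero total
  variance.
- AAFT tie-breaking uses a seeded permutation so results are reproducible
  and unbiased for tied ranks (percent-cover data are often discretised).
- Quantiles use NumPy's default linear interpolation.
- PSD factorisation of residual covariances uses eigen-decomposition with
  clipping at zero (tolerance 1e-10 relative to the largest eigenvalue).
- Donor selection is uniform over eligible plots (positive-variance series
  of the species, excluding the focal plot); generators accept either an
  integer seed (recorded in outputs) or a shared `numpy.random.Generator`.

## Problem sizes used in validation

Identity fuzzing uses 1000 random communities (S ∈ [2, 8], T ∈ [5, 39]).
Parameter recovery uses S = 8 at T = 2000 (5% tolerance) and the error
ratio between T = 200 and T = 2000 (expected ≈ √10). Secondary-decomposition
recovery uses S = 6, T = 1000, 100 repeats, 10 plots, 3 monocultures per
species. Bootstrap calibration uses 200 communities (S = 5, T = 30) at 200
surrogates each, and 100 synchrony-power seeds at T = 64. These sizes make
Monte-Carlo noise small relative to the stated tolerances while keeping the
full validation run around half a minute.

## Known limitations

- The surrogate methods inherit the monoculture/demographic bias described
  above; results for CPE_env/CPE_int in small, diverse plots should be read
  with that sign of bias in mind.
- The donor-plot method assumes donor plots are true environmental
  replicates of the focal plot; spatial heterogeneity within a site weakens
  the environmental covariance the surrogate is meant to carry.
- No frequency-specific (wavelet) synchrony, detrending, rarefaction,
  errors-in-variables or mixed-effects regression; the analysis layer is
  deliberately plain OLS on log-transformed ratios.
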