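# commstab

Decomposition of the temporal stability of ecological communities into
statistical-averaging, compensatory, evenness, environmental and interaction
components — with surrogate-based inference and a simulator that knows the
true answer.

## The problem

Long-term surveys and biodiversity experiments repeatedly find that more
diverse plant communities have more stable total biomass. The usual
explanation routes the effect through *asynchrony*: fluctuations of different
species partially cancel. But asynchrony conflates two very different
mechanisms — **compensatory dynamics** (negative covariances among species,
a biological mechanism arising from species interactions or opposite
responses to the environment) and **statistical averaging** (the portfolio
effect: many independently fluctuating species are jointly steadier than
few, a purely statistical mechanism). This package implements a multiplicative
decomposition that separates them, so one can ask *which* mechanism carries
a diversity–stability relationship.

## The decomposition

For one plot, let x_i(t) be the biomass of species i = 1..S over T years,
with temporal means μ_i, standard deviations σ_i, covariances v_ij,
μ_tot = Σμ_i, σ_tot = √(Σ_ij v_ij). Community stability is the inverse CV of
total biomass, and it factors exactly:

    S_com = μ_tot / σ_tot = Φ · S_pop,        Φ = Σσ_i / σ_tot
    Φ     = SAE · CPE,                         SAE = Σσ_i / √(Σσ_i²)
                                               CPE = √(Σσ_i²) / σ_tot
    SAE   = EVN · √S                           (√S = SAE at equal variances)

- **S_pop** = μ_tot/Σσ_i — population stability; what S_com would be if all
  species were perfectly synchronous.
- **Φ** — the Loreau–de Mazancourt asynchrony index (θ = 1/Φ² is their
  synchrony statistic).
- **SAE** ∈ [1, √S] — statistical-averaging (portfolio) effect; CPE = 1/√φ
  where φ = σ_tot²/Σσ_i² is the classic variance ratio, so CPE > 1 indicates
  compensatory (negatively covarying) dynamics and CPE < 1 synchrony.
- **EVN** ∈ (0, 1] — the penalty unequal species variances impose on SAE.

Because everything is multiplicative, log10 components are additive, and OLS
slopes of each log component against log richness add exactly to the slope
of log S_com — so a diversity–stability slope can be attributed to its parts.

Two further tools:

- **CPE = CPE_env × CPE_int** — a secondary split obtained by building a
  *surrogate community* whose between-species covariances come from series
  of the same species in *other* plots (or matched monocultures): those
  share the environment but cannot interact, so the surrogate stability
  isolates the environmental channel.
- **AAFT bootstrap** — each species series is resampled by an
  amplitude-adjusted Fourier transform (exact value permutation, spectrum
  approximately preserved, phases randomised), instantiating the
  independent-species null and yielding a quantile CI for CPE.

A Gaussian community simulator (`make_scenario`, `simulate_site`) generates
replicate plots and matched monocultures with tunable environmental,
interaction and demographic covariance, and `analytic_components` /
`analytic_secondary` return the closed-form expected value of every
component, so all estimators are testable without any external data.

## Worked example

```python
import numpy as np
from commstab import decompose

X = np.column_stack([[2, 4, 2, 4], [1, 3, 3, 1]])   # two species, four years
c = decompose(X)
print(f"S_com={c.s_com:.4f}  S_pop={c.s_pop:.4f}  Phi={c.phi:.4f}  "
      f"SAE={c.sae:.4f}  CPE={c.cpe:.4f}  theta={c.theta:.4f}")
```

```
S_com=3.0619  S_pop=2.1651  Phi=1.4142  SAE=1.4142  CPE=1.0000  theta=0.5000
```

These two species have equal variances and zero sample covariance, so the
compensatory effect is exactly 1 (no covariance structure), the whole
asynchrony Φ = √2 is pure statistical averaging at its ceiling √S, and
community stability exceeds population stability by exactly that factor.

With simulated data the estimates can be checked against the generative truth:

```python
from commstab import (make_scenario, simulate_site, analytic_components,
                      secondary_decompose, bootstrap_cpe)

scn = make_scenario(S=6, T=200, n_plots=8, n_monocultures=2, seed=42)
plots, monos = simulate_site(scn)
truth, est = analytic_components(scn), decompose(plots[0])
print(f"analytic: Phi={truth.phi:.3f}  SAE={truth.sae:.3f}  CPE={truth.cpe:.3f}")
print(f"sample:   Phi={est.phi:.3f}  SAE={est.sae:.3f}  CPE={est.cpe:.3f}")
sec = secondary_decompose(plots[0], method="monoculture", monocultures=monos,
                          n_repeats=100, random_state=0)
print(f"CPE_env={sec.cpe_env:.3f}  CPE_int={sec.cpe_int:.3f}")
res = bootstrap_cpe(plots[0], n=1000, random_state=0)
print(f"CPE={res.cpe_point:.3f}  95% CI=({res.ci[0]:.3f}, {res.ci[1]:.3f})")
```

```
analytic: Phi=1.544  SAE=2.163  CPE=0.714
sample:   Phi=1.668  SAE=2.160  CPE=0.772
CPE_env=0.719  CPE_int=1.074
CPE=0.772  95% CI=(0.709, 0.829)
```

Here the mixed-sign environmental loadings plus weak competition make the
community mildly synchronous overall (CPE < 1, CI excluding 1), and the
secondary split attributes the synchrony to the environmental channel
(CPE_env ≈ 0.72) while interactions are mildly compensatory (CPE_int > 1).

The estimators are scikit-learn style (`StabilityDecomposition`,
`SecondaryDecomposition`, `CPEBootstrap` — `fit` on a years × species
matrix, fitted attributes like `cpe_`), and a CLI covers the pipeline for
long-format CSV files (columns `site,plot,year,species,abundance`):

```bash
commstab simulate --config scenario.yaml --seed 3 -o sim/
commstab decompose sim/plots.csv --allow-negative -o components.csv
commstab secondary sim/plots.csv --method monoculture \
    --monocultures sim/monocultures.csv --allow-negative -o secondary.csv
commstab bootstrap sim/plots.csv --n 1000 --seed 7 --allow-negative -o boot.csv
commstab regress sim/plots.csv --mode plot --index shannon --allow-negative -o reg.csv
```

Exit codes: 0 success, 2 input error, 3 degenerate data.

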