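# occrich

Estimating the *total* number of species in a community — including species
never detected at any site, on any visit — from spatially replicated
detection/non-detection surveys, using a multispecies occupancy–detection
model with data augmentation, together with the simulation machinery needed
to judge when such estimates can be trusted.

The package is aimed at ecologists and biodiversity statisticians who work
with repeat-visit community survey data (e.g. breeding-bird atlases, ant
traps, butterfly transects) and want either (a) a posterior for total
richness *N* with imperfect detection accounted for, or (b) a way to probe,
by simulation, how sensitive that posterior is to sample size, priors and
distributional assumptions.

## The model

For species *k* at site *i* with repeat visits *j*:

```
z_ik  ~ Bernoulli(w_k ψ_ik)         presence/absence
y_ijk ~ Bernoulli(z_ik p_ijk)       detection (no false positives)

logit(ψ_ik) = β0k + β1k x_1i + ...  occupancy
logit(p_ijk) = α0k + α1k v_1ij + ...  detectability
β·k ~ N(µ_β, σ_β),  α·k ~ N(µ_α, σ_α)   species random effects
```

The observed *n* species are padded with *M − n* all-zero "potential
species". Each of the *M* species carries a community-membership indicator
`w_k ~ Bernoulli(Ω)`, and total richness is the derived quantity
`N = Σ_k w_k`. Because never-detected species are only identified through
the lower tails of the random-effect distributions, *N* is exquisitely
sensitive to priors and to distributional assumptions — quantifying that
sensitivity is what most of this repository does.

The survey-design side is summarised by two closed forms: the cumulative
per-site detection probability `p* = 1 − (1−p)^J` and the probability that a
species is missed entirely, `m = (1 − ψ p*)^S`.

Inference is by a Metropolis-within-Gibbs sampler written here in
vectorized NumPy: membership indicators are updated with presence states
marginalized out (collapsed conditional), presence is refreshed by exact
Gibbs, species-level coefficients use adaptive random-walk Metropolis,
hyper-means are conjugate, hyper-scales are slice-sampled, and Ω is
conjugate Beta. Intercept-only models (the usual case) run on per-species
sufficient statistics, so a full sweep is O(S·M).

## Layout

- `src/occrich/` — the library: `simulate` (communities, surveys, five
  assumption-violating detectability families), `richness` (missed-species
  calculators, posterior richness summaries, per-site and region richness),
  `model` (the augmented model and sampler), `priors` (the three prior
  regimes), `diagnostics` (classic R̂, augmentation adequacy),
  `evaluate` (scenario grids and performance metrics), `io` (CSV formats,
  covariate standardization).
- `analysis/01…05_*.py` — numbered drivers that run the simulation
  analyses at desk scale and write tables under `results/`.
- `tests/` — unit, property and acceptance tests (enumeration, quadrature
  and grid oracles live in `tests/_oracles.py`).

## Worked example

`python analysis/03_fit_ideal_example.py` simulates a 50-species community
(logit ψ ~ N(−1, 0.3), logit p ~ N(−2, 1)) surveyed at 50 sites × 4 visits
and fits it with the recommended priors (set 3, adaptive augmentation):

```
simulated 50 species; 50 present in the sample, 47 detected
posterior median N = 50, 95% CI [47, 57] (truth 50, detected 47); augmented by 50, max R-hat 1.011
```

Three species were never detected; the posterior centres on the true 50 and
its lower bound equals the 47 actually seen (N can never be below the count
of observed species). `analysis/01_expected_missed_table.py` prints the
expected missed percentages for every design (e.g. a sparse 25-site,
2-visit survey of the low-occupancy scenario misses 50% of species — a
regime in which richness estimates become unreliable and prior-dominated,
as `analysis/04_prior_sensitivity.py` demonstrates).

Equivalent in code:

```python
from occrich import *
from occrich.model import MCMCConfig

spec = ScenarioSpec(n_species=50, S=50, J=4, seed=7, **OCC1)
data, truth = simulate_dataset(spec, replicate=0)
detected, _ = data.drop_undetected()
draws, summary, n_aug = fit_dataset(detected, make_prior_set(3),
                                    MCMCConfig(seed=11))
print(summary.median, summary.ci_low, summary.ci_high)
```

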