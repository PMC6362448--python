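# Methods

## Model

The package implements the community occupancy–detection model with data
augmentation. Detection/non-detection data `y[i, j, k]` over `S` sites,
`J` visits and `n` observed species are padded with `M − n` all-zero
pseudo-species. The augmented model is

- `w_k ~ Bernoulli(Ω)` — community membership, `k = 1..M`;
- `z_ik ~ Bernoulli(w_k ψ_ik)` — presence;
- `y_ijk ~ Bernoulli(z_ik p_ijk)` — detection, with no false positives
  (absence forces all-zero records);
- logit-linear predictors for `ψ` and `p` whose species-level coefficients
  are draws from normal hyperdistributions, `β·k ~ N(µ_β, σ_β)` etc.
  Throughout, `N(m, s)` means mean `m` and **standard deviation** `s`.

Total richness is the derived count `N = Σ_k w_k`; its posterior includes
species never detected anywhere. Site-level summaries are the expected
richness `Σ_k w_k ψ_ik` and the data-conditional richness `Σ_k z_ik`;
`region_richness` counts, per posterior draw, the species with at least one
occupied site in a user-chosen site set, which restricts the richness
statement to a defined region instead of the open "community" N whose
spatial scope is only implicitly defined by the site-sampling design.

Assumptions worth keeping in mind: sites are a random sample of a very
large region; all species in the target group are detectable in principle;
occupancy and detection heterogeneity across species is logit-normal; no
false positives; closure within the survey season. The parts of real data
these assumptions gloss over (spatial structure, observer effects,
phylogenetic clustering of traits) are exactly what the violation
machinery below is for probing.

## Sampler

A bespoke Metropolis-within-Gibbs sampler (vectorized over species):

1. **Species effects.** Random-walk Metropolis per coefficient, proposals
   shared-scale across species and adapted toward ~30% acceptance
   (inside the 20–45% band) during burn-in only; adaptation is frozen
   afterwards so the stationary distribution is untouched. For intercept-only
   models the Bernoulli likelihoods collapse onto sufficient statistics
   (occupied-site counts `Σ_i z_ik`, detection trials `Σ_i J_i z_ik`, total
   detections), making a sweep O(S·M) regardless of J. Coefficients of
   current non-members (`w_k = 0`) and detection coefficients of species with
   no occupied sites are drawn directly from their hyperdistribution — their
   exact conditional — which keeps all M species informative for the
   hyperparameter update.
2. **Hyperparameters.** `µ` by conjugate normal draws; `σ` by univariate
   slice sampling (stepping-out plus shrinkage) under the uniform prior on
   `(0, U]` — exact and tuning-free. If a hyper-`σ` sits within 1% of `U`
   in more than 1% of draws the run warns that the prior bound is active.
3. **Membership.** For undetected species, `w_k` is updated with its
   presence row marginalized out:
   `P(w_k=1 | ·) = Ω Π_i (1 − ψ_ik p*_ik) / (Ω Π_i (…) + 1 − Ω)`,
   then `z` is refreshed given `w` by exact Gibbs (detections force
   `z = 1`). The collapsed update avoids the absorbing `w=0/z=0`
   configuration of a naive joint scan and mixes the binary indicators far
   better than an uncollapsed sampler would in data-rich scenarios.
4. **Ω.** Conjugate `Beta(a + Σw, b + M − Σw)`.

Chains start from the observed detections (`z = D`, observed species
`w = 1`, augmented `w = 0`), with intercepts at naive logit frequencies.
Default settings (`MCMCConfig`): 3 chains × 6,000 iterations, 1,500
burn-in, thinning 3 — desk-scale settings that the recovery tests show are
ample for the model sizes used here (M up to ~550).
Convergence is the classic two-part Gelman–Rubin R̂ on the retained draws
(threshold 1.1), computed pooled across chains; when any monitored scalar
fails, additional same-length blocks are drawn (earlier blocks discarded as
burn-in) up to `max_extra_blocks`, after which the result is returned
flagged `converged=False` rather than silently. R̂ is reported as `+inf`
when some chains are frozen while others move, and `nan` when every draw is
identical (a pinned parameter such as N in a fully-detected community — not
a mixing failure).

Determinism: every chain derives its generator from
`SeedSequence(config.seed).spawn`, and each simulated dataset from
`default_rng([scenario_seed, replicate])`, so any grid cell is reproducible
in isolation.

## Data augmentation adequacy

`M` is an artificial ceiling on N. After a fit, the interval between the
lowest sampled N and M is split into 10 equal sections; augmentation is
adequate when the top section holds < 1% of posterior mass. The grid driver
raises the number of pseudo-species through the schedule 50, 100, 200, 350,
500 until the rule passes (500 is the cap; a posterior still pressed
against it is flagged, which is itself a diagnostic of runaway richness
estimates).

## Prior regimes

| set | hyper-mean prior | hyper-sd prior | Ω prior | reading |
|-----|------------------|----------------|---------|---------|
| 1 | N(0, 31) | U(0, 5] | Beta(1, 1) | wide common practice; implies N ~ discrete-uniform{0..M} |
| 2 | N(0, 2.25) | U(0, 5] | Beta(1, 1) | logit-scale means kept inside ±5 |
| 3 | N(0, 2.25) | U(0, 5] | Beta(0.001, 1) | additionally shrinks Ω toward 0 |

`2.25` is taken as a standard deviation (consistent with the N(mean, sd)
notation used for the simulation scenarios); if one prefers the
variance reading (sd 1.5), any custom `PriorSet` expresses it. The σ
support bound is likewise configurable for analyses that need U = 10.

## Synthetic data

The generator produces communities matching the model's own assumptions:
`n_species` species with logit-normal occupancy (`Occ1`: N(−1, 0.3), mean
ψ ≈ 0.27; `Occ2`: N(−2, 0.6), mean ψ ≈ 0.13) and ideal detectability
logit-normal N(−2, 1) (mean p ≈ 0.155), constant across sites and visits;
Bernoulli presence at S sites and Bernoulli detection over J visits.
Five alternative detectability families deliberately violate the fitted
model's logit-normality, all defined on the logit scale:

- `heavy_tail` — Student-t (df 3, scale 0.8): fatter tails;
- `steep_tail` — normal truncated to ±~1.2 sd: lighter tails;
- `skewed` — skew-normal (shape 4);
- `bimodal_near_zero` — equal mixture with modes near p ≈ 0.03 and 0.30;
- `bimodal_away_from_zero` — equal mixture with modes near p ≈ 0.20 and
  0.60, i.e. no genuinely hard-to-detect species.

Exact parametric shapes for these families are a design choice of this
package (only their qualitative character — tail weight, skew, modality —
and their target missed fractions are externally specified);
`tune_detectability_location` shifts a family's location by root-finding on
a common-random-numbers Monte-Carlo estimate of the expected missed
fraction, so a scenario can be pinned to, say, 9% or 2% of species missed at
S = 25. The generator does not emulate spatially varying occupancy,
abundance-mediated detection, observer effects, or correlation between
occupancy and detectability across species — so passing tests here speak to
estimator behaviour under the model's own world plus the listed violations,
not to every failure mode of field data.

## Closed-form calculators

`cumulative_detection` (`p* = 1 − (1−p)^J`), `prob_missed`
(`m = (1 − ψ p*)^S`), and their community expectations
`expected_missed_fraction` / `expected_absent_fraction` (Monte-Carlo means
over the scenario distributions, with standard errors; a warning fires
below 10⁴ draws where integer-percent rounding becomes unreliable).
Percentages are rounded half-away-from-zero. The posterior median of the
discrete N uses the lower median (smallest value with CDF ≥ 0.5) for
deterministic tie-breaking; intervals are equal-tailed 2.5%/97.5% quantiles
with the inverted-CDF convention.

## Numerical choices and degenerate inputs

- All Bernoulli log-likelihoods go through `logaddexp` (no exp overflow);
  detectability draws are clipped to (1e-12, 1 − 1e-12) so extreme logit
  values cannot saturate to exactly 0/1.
- Ω draws are clipped away from exact 0/1 (Beta(0.001, ·) underflows in
  floating point); the membership logit handles the clipped values.
- A fully detected community with M = n pins N = n exactly; a survey with
  every visit masked yields a vacuous likelihood and returns the prior
  (used to verify the implied discrete-uniform prior on N under set 1).
- Non-finite Metropolis log-posteriors reject the proposal.
- Missing visits are masked: the likelihood is a product over conducted
  visits only, and per-site visit counts enter the sufficient statistics.
- Covariates standardize to mean 0, population variance 1; quadratic terms
  are squares of the standardized linear term and are not re-standardized.
- All-zero observed species columns are indistinguishable from augmented
  pseudo-species and are dropped (with a report) before augmentation.

## Problem sizes

Analyses and tests run at desk scale by design: 50-species communities,
3 replicates per cell, 3 chains × 6,000 iterations. The sufficient-statistic
sweep makes a single ideal-scenario fit (S = 150, J = 6, M ≈ 150) take a few
seconds, and the full bundled analysis set a few minutes. Larger
communities, replicate counts, and the 50,000-iteration chain lengths of a
full-scale study are reachable through the same `ScenarioSpec`/`MCMCConfig`
knobs.

## Known limitations

- The sampler asserts posterior correctness (verified against brute-force
  enumeration on small instances), not mechanical equivalence with
  BUGS/JAGS samplers of the same model; chain autocorrelation structure
  will differ (the collapsed membership update generally mixes better).
- No occupancy–detection random-effect correlation, no false positives, no
  multi-season dynamics, no abundance-based formulations.
- Expected site richness requires retaining per-draw `ψ` (and conditional
  richness per-draw `z`), which is memory-heavy for large S × M; retention
  is off by default.
- With very diffuse priors and sparse data the posterior of N genuinely has
  no usable upper bound; the package reports the truncation (adequacy flag)
  rather than hiding it.
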