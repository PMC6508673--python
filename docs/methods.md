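# Methods

This note records the models, algorithms, defaults and numerical
choices behind `ghostbirds`, and what the synthetic-data checks do and
do not establish about real data.

## The occupancy model

Detection histories `y[i, j, k]` (site i = 1..M, occasion j = 1..J,
species k = 1..K) are modelled with a latent occupancy state per
site × species:

    z_ik ~ Bernoulli(psi_ik)
    y_ijk | z_ik ~ Bernoulli(z_ik * p_ijk)

    logit(p_ijk)  = alpha0_k + alphaA_k * RouteA_i + alphaB_k * RouteB_i
    logit(psi_ik) = beta0_k + beta1_k * midstory_i + beta2_k * canopy_i
                    + beta3_k * burned_i

Covariates: standardized midstory (4.5–10 m) and canopy (20–30 m)
return-density fractions and a binary burned flag on occupancy; the
observer route (two named routes vs off-route reference, dummy-coded
with two contrasts) on detection. Detection depends on the site only
through its route, so each site × species cell's likelihood reduces to
a binomial kernel in the detection count — used throughout for speed.

Species coefficients are random effects: each coefficient family
(detection intercept, route contrast, occupancy intercept, midstory,
canopy, burned — the two route contrasts share one family) has a
community mean and standard deviation. Hyperpriors: Normal(0, variance
1000) on each community mean; half-normal(scale 2.25) on each community
sd. The half-normal scale is configurable (`SamplerConfig.hyper_sd_scale`);
2.25 keeps ~95% of prior mass on sds below ~4.5 logit units, which is
weakly informative for community random effects and avoids the heavy
upper tail that makes vague inverse-gamma variance priors misbehave
with modest K.

Multi-year survey data are treated as pooled occasions of a single
season (occupancy assumed static over the pooled span); sites surveyed
fewer times contribute only their observed occasions, encoded as a
per-site prefix of valid occasions and `-1` elsewhere.

### Sampler

`sample_posterior` is an adaptive Metropolis-within-Gibbs sampler with
latent-state augmentation:

1. `z_ik` from its closed-form full conditional (1 given any detection;
   otherwise posterior odds `psi (1-p)^n : 1-psi`).
2. Each species-coefficient slot by random-walk Metropolis, proposed
   jointly across species and accepted per species (valid because
   species are conditionally independent given the hyperparameters and
   z). Detection slots use the z-weighted route-aggregated binomial
   statistics; occupancy slots the Bernoulli likelihood of the current
   z field, updated incrementally per column.
3. Community means by conjugate normal draws; community sds by
   random-walk on log sigma with the half-normal prior and log-scale
   Jacobian.

Proposal scales (one per coefficient slot per species, one per
community sd) adapt every 50 burn-in iterations by
`scale *= exp(rate - 0.3)` clipped to [0.5, 2] per update, targeting
roughly 20–40% acceptance; adaptation stops at the end of burn-in, so
the retained chain is a valid Markov chain. Chains are seeded by
`numpy.random.SeedSequence(seed).spawn(chains)` and bit-reproducible.
`iterations` counts post-burn-in iterations (retained draws per chain =
iterations / thin); the reference protocol is 3 chains × 20,000
iterations after 5,000 burn-in, thinned to every 5th.

Initialization: z starts at 1 wherever the species was detected and
Bernoulli(0.5) elsewhere; coefficients start at the hyperprior means
plus Normal(0, 0.5) per-chain jitter so the chains are overdispersed
and the Gelman–Rubin diagnostic is meaningful. If the initial state has
non-finite likelihood the chain re-initializes (bounded retries).

### Non-hierarchical mode and the single-species check

`SamplerConfig(hierarchical=False)` replaces the community level with
independent Normal(0, `hyper_mean_var`) priors on every coefficient.
This exists for single-species fits, where a subtlety matters: with a
very diffuse prior on the logit scale (variance 1000), the
single-species posterior is dominated by the `psi -> 1` ridge — an
all-zero history is explained equally well by absence or by
non-detection, and the likelihood does not decay as `logit(psi) -> inf`,
so a "vague" prior places most of its mass there. The packaged
correctness check therefore uses a weakly informative prior
(variance 4) on both logits and compares the sampler against a 2-D
grid integration of the *same* posterior; agreement is required within
3 Monte-Carlo standard errors (estimated from between-chain variation
of the chain means). The hierarchical community model does not suffer
this pathology because the learned community sd regularizes every
species.

### Diagnostics and summaries

- Gelman–Rubin: the classic (non-split, non-rank-normalized) potential
  scale reduction factor `sqrt(((n-1)/n W + B/n) / W)`; parameters with
  zero within-chain variance are reported NaN.
- Posterior summaries: mean, sd, and the central 95% interval at the
  2.5/97.5% quantiles of pooled post-burn-in draws under numpy's
  linear-interpolation quantile rule (draws 1..100 give 3.475, 97.525).
- Support classification: an effect is *strong* iff its 95% interval
  excludes 0 strictly; an endpoint exactly at 0 counts as overlap
  (weak). Direction is the sign of the posterior mean. The support
  count table reports, per vegetation covariate and for the
  either/both rollups, species counts by sign with strong counts
  alongside.

## Ghost-forest classification

`fit_logistic` is a plain Newton/IRLS logistic MLE with
`AIC = 2k − 2 logLik`. Perfect or quasi-perfect separation (divergence
or |coef| > 30) is flagged with a warning and refitted with a ridge of
1e-6 so the pipeline never crashes on degenerate draws; rank-deficient
designs raise. `stepwise_select` implements the constrained forward
search: step 1 keeps the AIC-best single metric; later steps consider
only metrics with |Pearson r| < 0.5 against *every* already-selected
metric (the conservative generalization of gating against the step-1
pick), and accept the best candidate only if it strictly lowers AIC.
Validation uses a class-stratified 60/40 split (scikit-learn),
classification at predicted probability ≥ 0.5, and reports
sensitivity = TP/(TP+FN) on the ghost class and specificity =
TN/(TN+FP). Variable selection runs on the full table; the selected
model is refit on the training split before holdout scoring.

## The synthetic landscape

The generator's job is to reproduce the statistical structure the
analysis assumes, at configurable scale. Seven metric surfaces live on
a 12-m grid; spatial autocorrelation comes from Gaussian-filtered white
noise (kernel sd 4 cells ≈ 50 m by default). The correlation structure
is deliberate and mirrors what LiDAR summaries of closed-canopy forest
show:

- heights (mean, max, sd) and canopy density share a dominant
  "stature" factor, making them mutually correlated above the 0.5 gate;
- midstory density and lower-canopy density carry mostly their own
  factors, so they remain eligible alongside the selected metrics;
- total density is the sum of band fractions plus an understory term.

The ghost transition is a *clustered* set of cells (threshold of a
smoothed field) inside the low-lying unburned stratum — real ghost
forests are contiguous stands, and clustering is what lets the signal
survive 4× block aggregation. Transition cells have midstory and canopy
density multiplied by a per-cell, per-layer severity factor drawn
uniformly from (0.05, 0.55) (mean 0.3). Heterogeneous severity is
essential: a single sharp factor makes the ghost/unaffected classes
nearly separable and drives the sampled midstory–canopy correlation
above the 0.5 gate, neither of which matches field experience
(published validation accuracies for such classifiers sit well below
1). Returns lost from the two bands are removed from the total density
as well, offset by an understory compensation factor U(0.3, 1.2) — the
opened canopy lets salt-tolerant shrubs proliferate, which is why total
density is a poor ghost predictor in practice. Heights are left
unchanged in transition cells (snags stand). Burned cells get an
independent knock-down: all band densities × U(0.15, 0.5), heights
× U(0.5, 0.8).

The biomass-change proxy is `sum(band density × band mid-height)` per
epoch; only the *sign* of its change is used to label cells, so any
monotone structural index would serve. Ghost labels for classifier
training are sampled inside the low-lying unburned stratum at a minimum
spacing of 200 m by default (the synthetic correlation length, ~50 m,
is shorter than a real landscape's, so this spacing already gives
near-independent points; study designs on real terrain use 400 m).

Surveys: points are placed by greedy blue-noise sampling (random
candidate order, disk blocking) at a 400-m minimum spacing by default;
156 points split roughly 21%/21%/58% over route A / route B /
off-route. Route points get 3 occasions (annual visits pooled);
off-route points draw 1–3 occasions uniformly. Community defaults give
mean occupancy ≈ 0.4 and mean detection ≈ 0.5 at the covariate means,
with a negative community-mean burned effect and positive canopy
effect; between-species sds (0.5–1.0) are large enough that species
take either sign of every effect.

What the generator does *not* emulate: LiDAR measurement/registration
noise, within-season phenology, year effects in detection, spatial
autocorrelation in occupancy beyond the shared covariates, and any
coupling between severity and distance to shoreline. Passing tests
establish internal correctness and calibration under the model's own
assumptions — not robustness to the violations above.

## Habitat-change accounting

Prediction rasters are aggregated by block mean (majority vote for the
burned flag; a coarse cell is valid when ≥ half its fine cells are),
the default factor 4 turning 12-m cells into 48-m cells of 0.2304 ha.
Occupancy is predicted per species from posterior-mean coefficients,
with the *survey-site* standardization constants applied to both
epochs, and the burned covariate held at its observed status in both
predictions so Δψ isolates vegetation-structure change. Δψ = later −
baseline is classified loss where Δψ < −0.3 and gain where Δψ > +0.3,
both strict (a cell at exactly −0.3 is unchanged); hectares are cell
counts × cell area within each stratum mask (whole area, burned,
unburned low-lying, plus caller-supplied extras such as the
ghost-transition stratum). Full posterior propagation (classifying
per-draw predictions) is possible by calling `predict_occupancy` per
draw, but posterior means are the default, matching how such maps are
usually reported.

## Problem sizes used in the packaged checks

The test and acceptance runs use scaled study conditions chosen to keep
the full suite fast while leaving every estimate informative: landscape
grids of 240–480 cells per side (2.9–5.8 km), 248 classifier points, up
to 156 survey points, communities of 12–30 species, and chains of
3,000–5,000 post-burn-in iterations (the parameter-recovery study: 20
replicates of K=30, M=150, J=3 at 3 × 4,000/1,000/5). The reference
protocol (56 species, 3 × 20,000 iterations) runs unchanged through the
same API.

## Known limitations

- The sampler is tuned for community-sized problems (K up to ~10²,
  M up to ~10³); very sparse species mix through the hierarchy and can
  need longer chains for stable species-level intervals.
- The Gelman–Rubin implementation is the classic PSRF; rank-normalized
  split-R-hat would be stricter for heavy-tailed posteriors.
- The stepwise procedure is greedy by construction; on data whose
  signal is spread across many weakly correlated metrics it can stop
  short of the exhaustive-search optimum (the packaged equivalence
  check quantifies this on generator conditions: ≥ 95% agreement).
- Hectare outputs scale with the synthetic grid, so only their signs,
  orderings and ratios — not magnitudes — are comparable across
  landscapes of different size.
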