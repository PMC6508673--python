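# ghostbirds

Tools for quantifying how forest-bird communities respond to the
"ghost forests" left behind by saltwater exposure as sea level rises,
and for translating those responses into decadal habitat-change maps.

Rising sea level kills coastal trees faster than they regenerate,
leaving stands of snags with thinned midstory (4.5–10 m) and canopy
(20–30 m) vegetation. Birds are sampled by repeat point counts, which
miss species that are present — so presence must be inferred through a
detection model. This package implements the full analysis chain as a
reusable, tested library:

- **`ghostbirds.synthdata`** — synthetic two-epoch landscapes of seven
  LiDAR-style vegetation-structure metrics on a 12-m grid, clustered
  ghost-forest transitions, fire perimeters, survey designs and
  detection histories with the model's exact generative structure. Every
  downstream stage is testable without any data download.
- **`ghostbirds.ghostforest`** — logistic classification of ghost vs
  unaffected forest with a correlation-gated stepwise AIC selection
  (candidates must have |Pearson r| < 0.5 with every selected metric;
  a step is accepted only if it strictly lowers AIC), validated by
  holdout sensitivity/specificity.
- **`ghostbirds.occmodel`** — the core model: a Bayesian hierarchical
  multi-species occupancy model

  ```
  z_ik ~ Bernoulli(psi_ik),  y_ijk | z_ik ~ Bernoulli(z_ik * p_ijk)
  logit(p_ijk)  = alpha0_k + alphaA_k RouteA_i + alphaB_k RouteB_i
  logit(psi_ik) = beta0_k + beta1_k midstory_i + beta2_k canopy_i + beta3_k burned_i
  ```

  with species coefficients as normal random effects under
  community-level hyperparameters, fitted by an adaptive
  Metropolis-within-Gibbs sampler with latent-state augmentation;
  Gelman–Rubin diagnostics, posterior summaries and 95%-credible-interval
  support classification included.
- **`ghostbirds.community_metrics`** — site richness as the within-draw
  sum of latent states, richness-on-structure regressions, and
  group-averaged Partners-in-Flight conservation-priority scores.
- **`ghostbirds.habitat_change`** — per-species occupancy prediction
  over both covariate epochs at 48-m resolution, Δψ thresholded at ±0.3
  (strict), and loss/gain/net hectares (0.2304 ha per cell) per spatial
  stratum: whole area, burned perimeter, unburned low-lying forest.

## Worked example

```python
import ghostbirds as gb

landscape = gb.simulate_landscape(dims=(420, 420), seed=1)
survey    = gb.sample_sites(landscape, n_sites=120, min_spacing=300, seed=2)
design    = gb.build_site_design(landscape, survey)
params    = gb.draw_community_params(gb.default_community_hyper(), 20, seed=3)
y         = gb.simulate_detections(params, survey, design, seed=4)

cfg  = gb.SamplerConfig(chains=3, iterations=3000, burn_in=1000, thin=5)
post = gb.sample_posterior(y, design, cfg, seed=5)
print(gb.gelman_rubin(post).max())          # ~1.01: chains agree
rich = gb.richness_posterior(post)
print(rich.median.min(), rich.median.max()) # e.g. 3 .. 14 of 20 species
```

Running `python examples/03_fit_occupancy_model.py` (which executes the
code above plus summaries) prints, among other lines:

```
max R-hat over community hyperparameters: 1.016
community means (true value in brackets):
  mu_beta_can     0.74  [0.22, 1.32]   (truth 0.50)
  mu_beta_burn   -0.57  [-1.95, 0.54]   (truth -0.50)
```

i.e. the fitted community-level canopy and burned effects bracket the
values the community was simulated from, with R-hat ≈ 1 confirming the
three chains converged to the same posterior. The other scripts in
`examples/` demonstrate landscape simulation, the ghost-forest
classifier (stepwise AIC table plus holdout sensitivity/specificity),
richness regressions, and the stratified habitat-change table.

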