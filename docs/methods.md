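# Methods

`wfdisp` implements a before–during–after assessment of whether marine top
predators are displaced from an offshore wind farm, using boat-based
line-transect survey data. The pipeline has four stages: segmentation of the
survey logs into fixed-length effort units, hierarchical Bayesian count
modelling with phase-varying spatial smooths, posterior prediction of
relative-abundance surfaces per development phase, and a cell-wise
credible-interval change test. A synthetic-survey generator with known ground
truth closes the loop for validation.

## Survey segmentation

GPS track points (one every 30 s) are projected from WGS84 to UTM zone 30N.
The projection is the standard Krüger series carried to sixth order in the
third flattening — sub-millimetre accuracy over the zone — with the inverse
solved by fixed-point iteration on the conformal latitude.

Each transect's polyline is divided into half-open chainage intervals
`[kL, (k+1)L)` with `L` = 600 m (guillemot) or 1 km (harbour porpoise).
Design choices where the field protocol is underdetermined:

- The final partial segment is retained with its true length; the models use
  `log(effort/L)` as an offset so partial segments remain comparable.
- A trailing sliver under 1 m is treated as coordinate-rounding noise and
  absorbed into the preceding segment; a genuine near-empty segment would
  otherwise enter the model with an offset of about −11 on the log scale.
- Sighting positions are interpolated in time between the bracketing GPS
  fixes (the observation clock is synchronised to the GPS); a sighting landing
  exactly on a boundary belongs to the following segment.
- Sea state is carried forward from the most recent record at or before the
  segment's midpoint time (records are taken at the start of each transect
  and every 15 min); Beaufort 0–2 is classified *good*, 3–5 *poor*.
- Only guillemots recorded on the sea are counted; birds in flight are
  excluded as transients. Porpoise records have no behaviour filter.
- The encounter rate in the effort ledger is the mean over surveys of each
  survey's individuals-per-km, with its standard error across surveys.
  A ratio-of-totals is *not* used: with unequal survey efforts the two
  definitions differ, and the per-survey mean respects the survey as the
  natural replication unit.
- Footprint membership of a segment or grid cell is decided by its midpoint
  (point-in-polygon); partial overlap is not prorated.

## Count models

Let `y_i` be the count in segment `i`, with phase `p(i)`, position `s_i`
(UTM, km), survey `u(i)` and transect-within-survey `t(i)`.

**Guillemot (NB GAMM).** `y_i ~ NB(mu_i, theta)` in the mean–dispersion
parameterization, `Var = mu + mu^2/theta`, with

```
log mu_i = beta_{p(i)} + f_{p(i)}(s_i) + b_{u(i)} + c_{t(i)} + log(effort_i/L)
```

**Harbour porpoise (ZIP GAMM).** Excess zeros arise from sampling error,
availability (animals underwater) and detectability; the latter worsens in
poor sea states. So `y_i ~ ZIP(mu_i, pi_i)` with the same count-part linear
predictor and

```
logit pi_i = gamma_0 + gamma_cond * [condition_i = poor]
```

The zero part deliberately carries no spatial or phase terms: survey
condition is the one mechanism with a clear a-priori link to false zeros, and
a richer binary part would be confounded with the count-part smooths at this
sample size.

`b_u ~ N(0, sigma_survey^2)` and `c_t ~ N(0, sigma_transect^2)` are nested
random effects absorbing spatio-temporal dependence between segments of the
same survey and transect.

### Spatial smooths

`f_p` is a low-rank thin-plate-type smooth, one per development phase
(factor-by expansion), built from radial kernels `eta(r) = r^2 log r` at
knots chosen as a farthest-point (space-filling) subset of the observed
segment midpoints, plus unpenalized linear terms. The penalty is the kernel
Gram matrix on the knots projected off the knot-linear span, which makes it
positive semi-definite; its null directions duplicate the unpenalized linear
span and are dropped. Penalized columns are sum-to-zero centred over the
observed rows so the phase intercepts stay identifiable.

For sampling, the penalized subspace is whitened (eigendecomposition of the
penalty) and — importantly — the whitened columns are standardised to unit
standard deviation over the observed rows. The smooth coefficients are then
i.i.d. `N(0, tau_p^2)` with one smoothing SD per phase. The standardisation
makes `tau` scale-free: the Gram penalty's absolute magnitude depends on the
coordinate units and knot layout, and without the rescale a fixed prior on
`tau` implies an arbitrary (here: far too strong) amount of smoothing. This
mirrors the penalty rescaling that penalized-likelihood GAM software performs
before estimating smoothing parameters.

Default rank is 25 knots per smooth; at the ~300 km² study design this gives
roughly 2.5 km knot spacing, enough to track features at the scale of the
wind-farm footprint while keeping the posterior dimension tractable on one
CPU.

### Priors

All proper and weakly informative: `N(0, 10^2)` on the intercept, phase
contrasts, per-phase linear trends and zero-part coefficients; half-`N(0, 2^2)`
on `sigma_survey`, `sigma_transect` and each `tau_p`; `Gamma(0.01, 0.01)` on
the NB size `theta`. Random effects and smooth coefficients are non-centred
(`b = sigma * b_raw`).

### Sampling and diagnostics

The joint posterior is sampled with an in-package No-U-Turn sampler
(multinomial dynamic HMC) with dual-averaging step-size adaptation and a
windowed diagonal mass-matrix estimate; the model supplies analytic
gradients, so each leapfrog step costs two dense matrix–vector products.
Defaults: 3 chains, 1 000 warmup + 1 000 draws, target acceptance 0.8.
Convergence is summarised by split R-hat and bulk ESS (arviz); a fit with
max R-hat > 1.1 is flagged and the pipeline exit status degrades. The
replicate-based validation tests use 2 chains × (300 + 300) draws and 15–25
knots; those sizes give interval estimates accurate to well within the
tolerances being tested while keeping a full validation run on one CPU under
half an hour.

Numerical notes: the linear predictor is clipped at ±30 before
exponentiation (no posterior mass is near that bound; it only guards warmup
excursions); the NB log-pmf switches to an asymptotic expansion of
`logGamma(theta+y) − logGamma(theta)` above `theta = 1e7`, where the direct
difference loses ~1e-6 absolute accuracy; the exact NB deviates from its
Poisson limit by `~y(y−1)/(2 theta)`, which the tests assert rather than a
tighter bound no exact implementation could meet.

### Reported parameters

Contrasts follow the conventional table rows — construction vs
preconstruction, operation vs construction (derived from draws), operation vs
preconstruction — as posterior means with equal-tailed 95% credible
intervals, on the link ("raw") scale and after the inverse link
("response level": rate ratios for log, probabilities for logit). A
predictor is *significant* when its raw 95% interval excludes zero.

## Prediction and the displacement test

Surfaces are predicted per phase on a regular grid of cell centres
(0.36 km² cells for guillemot, 1 km² for porpoise) clipped to the convex
hull of surveyed midpoints — thin-plate smooths extrapolate poorly
off-support. Predictions are population-level relative abundance: random
effects at zero, full nominal effort, and good sea state for the ZIP model
(`E[y] = (1 − pi0_good) * mu`). Per-cell posterior mean, SD, and 2.5/97.5%
quantiles are stored, along with the full draw matrix.

The change map between phases A and B reports the difference of posterior
means and flags a cell significant when the two phases' marginal 95%
intervals are disjoint. This non-overlap rule is conservative (two intervals
can overlap while the difference's own interval excludes zero, roughly a
whole z-unit of extra stringency); the difference-interval variant is exposed
as `rule="difference"` without being the default. The footprint summary
averages member cells per draw, so its interval reflects posterior
dependence between cells.

## Synthetic surveys

The generator emulates the study design: 10 parallel transects, 18 km long
and 2 km apart (~360 km² with survey coverage), a centred square footprint
(default 13 km²), three development phases, vessel at 5 m/s logging fixes
every 30 s, sea state sampled at the start of each transect and every 15 min
from a symmetric ±1 random walk on Beaufort 0–5 (uniform stationary law, so
half the effort is in poor conditions), guillemot counts NB and porpoise
counts ZIP with condition-dependent extra zeros, and sightings emitted as
timestamped records (occasionally split within a segment) so the
interpolation and summing code paths are exercised. Latent log-intensity
surfaces are single draws of a squared-exponential Gaussian process
(length-scale 5 km, log-SD 0.5 by default), one per phase or shared.

Default effect sizes are test settings, not estimates of any real system:
baseline mean counts near 2 per segment and phase contrasts of ±0.5 on the
log scale give desk-scale power. What the generator does *not* emulate:
animal movement and vessel avoidance, flock-size distributions, tidal or
seasonal cycles, detection distance effects (the models target relative, not
absolute, abundance). Passing recovery tests therefore demonstrate that the
estimator inverts its own generative assumptions at realistic sample sizes —
not that those assumptions hold for any particular field data set.

Two presets define the validation scenarios:

- `recovery_scenario`: 9 km (guillemot) / 6 km (porpoise) transects with two
  surveys per phase — 900 and 360 segments per replicate respectively — a
  single shared surface and survey/transect SDs of 0.1, so phase contrasts
  are identified mainly by the counts.
- `displacement_test_scenario`: equal phase intercepts, shared surface,
  three surveys per phase, a 25 km² footprint and a 70% construction-phase
  intensity reduction inside it. The reduction applies in full inside the
  footprint and decays to zero over a 2 km cosine taper outside, reflecting
  avoidance that extends beyond the turbine area; a hard-edged step at the
  polygon boundary is not representable by any smooth of this rank (a
  penalized-likelihood GAM attenuates it equally), whereas the tapered
  feature is detected reliably. Because the phases share every other
  ingredient, any flagged decline in the pre-vs-operation map is a false
  positive by construction, which is what the specificity half of the
  displacement test checks.

## Known limitations

- The binary (zero) part of the ZIP model is intercept + condition only;
  spatially varying availability would be absorbed by the count-part smooth.
- The non-overlap significance rule's conservatism means footprint-scale
  effects need either strong signals or many surveys to flag; the footprint
  summary (a posterior interval on the footprint mean ratio) is the more
  sensitive quantity.
- Knot placement is data-driven; two fits of different segmentations of the
  same region use different bases. The knots and centring constants are
  stored with the fit, so predictions from a saved fit are exactly
  reproducible.
- Counts are treated as independent between transects given the random
  effects; double-counting of individuals moving between transects is not
  modelled.
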