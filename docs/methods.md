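# Methods

This note documents the models, the synthetic data they are tested against,
and the numerical and design choices a user should know before trusting —
or extending — the pipeline.

## Modelling scale and state variable

Plant state is crown projected area (cm²), modelled throughout on the log
scale z = log(area). Areas span four orders of magnitude between emerged
seedlings (~1–3 cm²) and large adults (several hundred cm²), so the log
scale keeps growth increments roughly homoscedastic and makes positivity of
projected sizes automatic (no floor parameter is needed for "growth as a
size difference": the response is the log-size increment, and
`predict_rate` for growth returns z plus the predicted increment). A raw
area scale would require a variance model and an explicit positivity floor;
it is not implemented.

## Vital-rate regressions

Each of the four rates is a generalized linear mixed model with a Gaussian
plot random intercept:

| rate | family/link | response | size terms |
|---|---|---|---|
| survival | binomial-logit | survived to next census | z, z² |
| growth | Gaussian-identity | z_next − z (survivors) | z |
| reproduction | binomial-logit | flowered at all | z |
| fecundity | Poisson-log | plot-year seedling total | z |

Fixed covariates: block indicator, intraspecific and interspecific cover
indices (plot-level summed cover fractions, the focal plant excluded from
its own intra index), winter minimum temperature (°C), spring rainfall (mm)
and summer water balance P − 2T (mm). Reproduction models never contain
summer water balance (both species complete flowering before June).
Covariates enter unstandardized, so coefficient magnitudes are per-unit
(e.g. per mm of spring rain). Cover indices are clipped at 1.0 (full
cover), consistently in the generator, the design assembly and the dynamic
projection: beyond full cover the index has no further meaning, and the
packaged positive intra coefficients would otherwise create an unbounded
feedback.

**Fecundity observation model.** Seedlings are counted per plot and year
and allocated to adults deterministically (by size for HS; by size ×
flowering-degree weight 0.6/0.3/0.1 for LS, with the log relative degree
weight entering the model as an offset). Because the allocated per-plant
values are exact shares of a single count, fitting them as independent
Poisson observations overstates the information. The package instead
maximises the exact likelihood of the observation process: the plot-year
total is Poisson with mean Σᵢ exp(xᵢβ + offsetᵢ) over that plot-year's
flowering adults. The coefficients and link are identical to a per-plant
Poisson regression; only the information accounting differs. Per-plant
allocated fecundities remain available (and conserve the plot count
exactly) for reporting and exploration.

**Estimation.** Binomial and Poisson mixed models are maximised by adaptive
Gauss–Hermite quadrature (15 nodes; one node is the Laplace approximation)
over the per-plot random intercept, with covariates internally standardized
for the optimizer and mapped back. The Gaussian growth model uses
statsmodels MixedLM (ML for AIC comparisons; the selected model is
readjusted with REML, which is defined only for the Gaussian family).
Standard errors are the more conservative of the model-based (observed
information) and plot-clustered sandwich estimates, guarding against
within-plot dependence beyond the random intercept. Information matrices
are inverted with an eigenvalue floor: a direction with numerically zero
curvature (e.g. a block indicator when one block recorded no seedlings at
all — complete separation) honestly reports an enormous standard error
rather than failing. Standardized coefficients are boxed at ±30 so
separated fits still converge in the identified subspace; a variance
component collapsing to zero falls back to the fixed-effects GLM.

**Selection.** Candidates are all additive subsets of the six optional
covariates (size terms always included). Among converged candidates within
2 AIC units of the best, the fewest-parameter model wins (ties by lower
AIC, then term order, making selection order-invariant); block and the
interspecific index are forced back in if they appear anywhere in that
plausible set, because block is part of the design and the interspecific
interaction is the scientific focus. Non-converged fits carry infinite AIC
and can never be selected.

## Packaged coefficient defaults

`data/default_coefficients.json` holds the default fixed-effect estimates
(with standard errors) per species × rate × term. Size terms and intercepts
are configuration, not part of that file: intercepts are calibrated so each
rate hits a life-history anchor at a reference covariate point — annual
adult survival 0.80 (HS, a 4–6-year-lived shrub) and 0.92 (LS, which lives
beyond 20 years), flowering probability 0.5–0.6, and fecundity 4.5 (HS) /
4.0 (LS) emerged seedlings per fully-flowering reference adult, which
reproduces field-scale average emergence (tens of seedlings m⁻² yr⁻¹).
Survival size slopes are set so recruit-sized plants establish at roughly
the observed first-summer rates (~22 % HS, ~12 % LS).

## The synthetic census generator

`simulate_population` emulates the monitoring design: 2 blocks × 50 plots
of 0.5 × 0.5 m, 9 annual censuses, initial densities 16 (HS) and 2.4 (LS)
individuals m⁻². Each year, per plant: survival and flowering are Bernoulli
draws from the logistic predictors (LS flowering is ordinal via a latent
logistic with cut-points at 0, 1.2, 2.4 — the binary "flowered" margin is
then exactly logistic, so the reproduction model is correctly specified);
growth adds Gaussian noise to the predicted log-size increment; plot-year
seedling counts are Poisson with mean equal to the summed per-adult
expected fecundities, and seedlings enter the next census as individuals at
log-normal recruit sizes, so first-year seedling mortality is expressed
through the ordinary survival transition — exactly as the kernel assumes.
Interaction indices are recomputed from the simulated covers every year,
so the data contain the same density feedback the dynamic model projects.

Climate years are independent uniforms within configurable ranges. The
default range widths are set jointly with the per-unit coefficient
magnitudes so vital-rate excursions stay in the regime the field data show;
the summer-water-balance width (±3 mm) bounds the boom-to-bust emergence
ratio near the observed extremes. A plot-year's expected emergence is
additionally capped at 100 × the observed field maxima — a numeric safety
rail against runaway boom years that essentially never binds (a binding cap
would censor the fecundity model's own mean structure, and is logged).

What the generator does **not** emulate: the soil seed bank (the
recruitment-pulse multiplier is the only proxy), spatially explicit
dispersal (allocation is plot-level), temporal climate autocorrelation
(scenarios resample whole years, so only range coverage matters), and any
year random effects. Passing tests therefore show the pipeline recovers the
structure it assumes — not that the assumed structure is complete for real
field data.

## Kernels and numerics

Midpoint rule, 200 mesh cells by default, over [log(0.5 × smallest size),
log(1.2 × largest size)] when derived from data. Growth columns are
renormalized to their on-mesh mass; renormalization below 0.995 is logged
(at the upper edge it acts as a size ceiling and can never inflate a column
above its survival rate), and a mass below 10⁻⁴ — a mesh that misses the
growth density entirely — is an error. The recruit-size density must
retain ≥ 0.99 of its mass on the mesh, else the mesh is rejected as too
narrow. λ uses power iteration (tolerance 10⁻¹²) with a direct eigensolve
fallback for non-converging (e.g. periodic) matrices. Kernel construction
is pure: identical inputs give bit-identical matrices. The fecundity
kernel carries no separate establishment probability because fecundity is
calibrated on emerged seedlings; growth variance is a single
size-independent residual SD (no variance model is reported for these
data).

## Coupled projection and scenarios

Covers entering year-t kernels come from the state at the start of year t;
covers are recomputed from projected abundances only for the next
iteration. Cover is clipped at 1.0 with a logged event. With the
interaction flag off, each species' interspecific covariate is frozen at
its initial-year value (configurable to 0): switching the flag off cancels
the feedback, not necessarily the covariate. The recruitment multiplier
scales the fecundity component only.

Scenario climate rules draw, per transition, the designated favourable year
with its nominal probability (1/3 HS, 1/4 LS; 1/3 for the unfavourable
year) and otherwise uniformly over the *remaining* pool years, so the
designated-year frequency is exactly nominal; the combined rules draw the
favourable year first, then the unfavourable year on 1/3 of the remaining
mass. The favourable mask (which triggers recruitment pulses, applied to
both species — wet-year pulses are community-wide) marks exactly the
favourable draws. The sampler consumes a fixed amount of randomness per
transition regardless of rule or outcome, so scenario variants under one
master seed are compared with common random numbers, and replicates are
seeded counter-style from (seed, replicate index) — results are independent
of execution order and of how many replicates run.

Reference years are designated from the species-level IPMs: per-species λ
argmax over the pool for the favourable years; for the unfavourable year,
the year minimizing the worse of the two species' λ ranks (unfavourable
years were synchronous between the species in the field — a year merely
catastrophic for one species is not "the" unfavourable year).

Initial abundance vectors default to each species' stable size distribution
under the mean pool climate, scaled to the requested density — the
synthetic stand-in for an observed standing population, which contains
recruits as well as adults. An adult-only initial vector (available as
`initial_structure="adult"`) induces a multi-year transient in which years
of low fecundity *raise* measured total-density growth (fewer low-survival
seedlings dilute the count), distorting 14-transition scenario contrasts.

The stochastic growth rate is the mean annual log change of total density,
(1/T) log(N_T/N_0); it reduces to log λ in the deterministic limit and
returns −∞ (flagged, summarized separately) on extinction. Scenario
summaries report medians and linearly-interpolated quartiles over
replicates and are exactly recomputable from the stored per-replicate
values.

## Known limitations

* Coefficient recovery from the feedback-coupled generator is slightly
  anti-conservative for a few fecundity coefficients: covariates computed
  from past population states are informative about the plot random
  effects, which random-effect ML assumes away, and the packaged Block B
  fecundity effect (−4.731) is extreme enough that a replicate study's B
  block can record no seedlings at all, leaving that contrast
  Wald-unfriendly. See the test suite's recovery check for the measured
  coverage.
* The AIC battery fits 2⁶ candidates per rate; on full-size data a complete
  `fit_all_rates` run takes minutes. The CLI exposes `--candidate-pool` to
  restrict enumeration.
* Scenario experiments at the full design (100 replicates, all rules ×
  multipliers × blocks × flags) are embarrassingly parallel but run
  serially here.
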