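# shrubipm

Climate- and cover-dependent integral projection models (IPMs) for two
interacting semiarid shrubs — *Helianthemum squamatum* (`HS`) and *Lepidium
subulatum* (`LS`), the dominant gypsum specialists of central-Spanish shrub
communities — built as a tested, reusable pipeline for exploring how
climatic variability and plant–plant interactions jointly shape population
persistence and coexistence.

The package is aimed at plant demographers and community ecologists who want
to run this class of multispecies dynamic IPM end to end without field data:
a synthetic-census generator with the exact generative structure the vital
rate regressions assume stands in for the demographic monitoring.

## The model

**Vital rates (step 1).** Four regressions per species, each with a plot
random intercept: survival (binomial-logit, quadratic in log crown area z),
growth (Gaussian on the log-size increment), probability of reproduction
(binomial-logit; never includes summer water balance, as both species flower
before June) and fecundity (Poisson-log). Fixed effects are block, the
intra- and interspecific cover indices, and three annual climate covariates:
winter minimum temperature (°C), spring rainfall (mm, February–May) and
summer water balance *P* − 2*T* (mm, June–September). Candidate models are
all additive covariate subsets; selection uses AIC with the ΔAIC < 2
parsimony rule, forcing block and the interspecific index back into the
winner when they appear in the plausible set, and a REML readjustment of the
selected Gaussian model. Per-plant fecundity is allocated from plot-level
seedling counts in proportion to size (HS) or size × flowering-degree weight
(60/30/10 % for high/medium/low; LS); the fitted likelihood is the exact one
of that observation process — Poisson on plot-year totals with mean
Σᵢ exp(xᵢβ). Binomial/Poisson mixed models are maximised by adaptive
Gauss–Hermite quadrature over the plot intercepts.

**Species-level IPMs (step 2).** The kernel

  n(y, t+1) = ∫ [ s(x) g(y|x) + f(y, x) ] n(x, t) dx

is discretized with the midpoint rule on a 200 × 200 mesh over log crown
area. The survival–growth part P multiplies survival by a Gaussian growth
density (renormalized column-wise so no probability is evicted past the mesh
edges); the fecundity part F places per-capita emerged seedlings,
p_repro(x) · fec(x), at a recruit-size density. The dominant eigenvalue λ of
K = P + F is the deterministic per-year growth rate; λ is mapped over
observed climate years and over the full intra × inter cover plane.

**Multispecies dynamic IPM and scenarios (step 3).** The two species are
coupled by recomputing cover fractions from each other's size-structured
abundance every iteration (interspecific feedback can be frozen at a
baseline to "switch the interaction off"). Stochastic simulations resample
whole climate years from a 16-year pool — uniformly, or enriched so 1 in 3
years is the HS-favourable year, 1 in 4 the LS-favourable year, or 1 in 3
the unfavourable year — with recruitment pulses (2/5/10 × the fecundity
kernel) in favourable years. Each scenario runs 100 replicates of 14 annual
transitions and is summarized by the stochastic population growth rate
log λ_s = (1/T) log(N_T/N_0) per species.

## Worked example

```python
import math
import shrubipm as s

cfg = s.default_config()                       # packaged coefficient defaults
model_sets = {sp: s.model_set_from_config(cfg, sp) for sp in ("HS", "LS")}
grid = s.build_grid(math.log(0.1), math.log(1500.0), 200)

pool = s.default_climate_pool(model_sets, seed=0, grid=grid)
print("favourable years:", dict(pool.favourable), "unfavourable:", pool.unfavourable)

series = s.lambda_vs_climate(model_sets["HS"], pool.years, covers=(0.30, 0.30), grid=grid)
print(series.head(3).to_string(index=False))

spec = s.ScenarioSpec(climate_rule="favourable_HS", recruit_multiplier=5.0,
                      n_replicates=20)
res = s.run_scenario(spec, model_sets, pool, master_seed=0, grid=grid,
                     keep_trajectories=False)
print(res.summary.to_string(index=False))
```

prints

```
favourable years: {'HS': 2000, 'LS': 2004} unfavourable: 2012
 year   lambda
 2000 0.957592
 2001 0.795865
 2002 0.863905
species    median       q25       q75  n_extinct  n_replicates
     HS -0.092981 -0.122588 -0.056241          0            20
     LS -0.004049 -0.037784  0.015690          0            20
```

The first block designates the reference years of the synthetic climate pool
from the species-level IPMs (the per-species λ argmax and a year bad for
both). The λ series shows the deterministic growth rate each climate year
would impose at 30 % covers (all below 1 here: in ordinary years both
populations shrink without recruitment pulses). The scenario summary gives
median and quartile stochastic growth rates over 20 replicates when
HS-favourable years are enriched to 1-in-3 and recruitment rises fivefold in
those years — both species are lifted close to stationarity (log λ_s ≈ 0),
and no replicate went extinct.

A command-line surface wraps the same pipeline
(`shrubipm simulate-data | fit | build-ipm | lambda-grid | project |
scenarios | summarize`); see `shrubipm --help`.

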