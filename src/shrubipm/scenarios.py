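"""Stochastic climate/ecology scenario experiments.

A scenario pairs a climate-sampling rule with an ecological setting (initial
densities, recruitment multiplier, interaction flag, block) and is run as
independent replicated projections of the coupled dynamic IPM, summarized by
the stochastic population growth rate per species.

Climate rules resample whole observed (here: synthetic pool) years:

* ``random``         -- uniform over the pool;
* ``favourable_HS``  -- the HS-favourable year with probability 1/3,
                        otherwise uniform over the remaining years;
* ``favourable_LS``  -- the LS-favourable year with probability 1/4;
* ``unfavourable``   -- the unfavourable year with probability 1/3;
* ``combined_HS`` / ``combined_LS`` -- the favourable draw first at its
  nominal probability, then the unfavourable year with probability 1/3 of
  the remaining mass, otherwise uniform over the rest.

The favourable-year mask drives the recruitment multiplier (pulse years).
Replicates are seeded counter-style from (master seed, replicate index), so
per-replicate results are independent of execution order, and the climate
stream of a replicate does not depend on the multiplier or the interaction
flag -- scenario variants are compared under common random numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .ipm_core import (
    IPMGrid,
    SpeciesModelSet,
    build_grid,
    build_kernel,
    lambda_vs_climate,
    stable_size_distribution,
)
from .multispecies import (
    CoupledState,
    PopulationState,
    initial_state_from_density,
    run_projection,
    trajectory_frame,
)
from .synthetic_data import SPECIES, ClimateYear, generate_climate_series

logger = logging.getLogger("shrubipm")

__all__ = [
    "CLIMATE_RULES",
    "FAVOURABLE_PROB",
    "ClimatePool",
    "ScenarioSpec",
    "SimulationResult",
    "sample_climate_sequence",
    "stochastic_growth_rate",
    "run_scenario",
    "run_scenario_battery",
    "default_battery",
    "density_battery",
    "compare_lambda_series",
    "default_climate_pool",
    "identify_reference_years",
]

CLIMATE_RULES = ("random", "favourable_HS", "favourable_LS", "unfavourable",
                 "combined_HS", "combined_LS")

#: Enrichment probabilities: 1 of every 3 years is the HS-favourable year,
#: 1 of every 4 the LS-favourable year, 1 of every 3 the unfavourable year.
FAVOURABLE_PROB = {"HS": 1.0 / 3.0, "LS": 1.0 / 4.0}
UNFAVOURABLE_PROB = 1.0 / 3.0

RECRUIT_MULTIPLIERS = (1.0, 2.0, 5.0, 10.0)


@dataclass(frozen=True)
class ClimatePool:
    """The pool of resampled years plus the designated reference years."""

    years: tuple[ClimateYear, ...]
    favourable: Mapping[str, int]  # species -> pool year label
    unfavourable: int

    def __post_init__(self) -> None:
        labels = {c.year for c in self.years}
        if len(self.years) < 3:
            raise ValueError("climate pool needs at least 3 years")
        for sp, y in self.favourable.items():
            if y not in labels:
                raise ValueError(f"favourable year {y} for {sp} not in pool")
        if self.unfavourable not in labels:
            raise ValueError(f"unfavourable year {self.unfavourable} not in pool")

    def by_year(self, year: int) -> ClimateYear:
        for c in self.years:
            if c.year == year:
                return c
        raise KeyError(year)


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully specified climate-ecology scenario.

    Defaults follow the study design: 100 replicates of 14 annual
    transitions, observed-range initial densities, no recruitment pulse.
    """

    name: str = "scenario"
    climate_rule: str = "random"
    recruit_multiplier: float = 1.0
    initial_density: Mapping[str, float] = field(
        default_factory=lambda: {"HS": 16.0, "LS": 2.4})
    interaction_on: bool = True
    block: str = "A"
    n_replicates: int = 100
    n_transitions: int = 14
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.climate_rule not in CLIMATE_RULES:
            raise ValueError(f"unknown climate rule {self.climate_rule!r}")
        if self.recruit_multiplier < 0:
            raise ValueError("recruit_multiplier must be >= 0")
        for sp, d in self.initial_density.items():
            if d < 0:
                raise ValueError(f"initial density for {sp} must be >= 0")
        if self.n_replicates < 1 or self.n_transitions < 1:
            raise ValueError("n_replicates and n_transitions must be >= 1")


@dataclass(frozen=True)
class SimulationResult:
    """Replicated stochastic-growth-rate output of one scenario."""

    spec: ScenarioSpec
    replicates: pd.DataFrame   # replicate, species, log_lambda_s, extinct
    trajectories: pd.DataFrame  # replicate, year, species, total_density, cover
    summary: pd.DataFrame      # species, median, q25, q75, n_extinct, n_failed

    def recompute_summary(self) -> pd.DataFrame:
        return _summarize(self.replicates)


# ---------------------------------------------------------------------------
# Climate sampling
# ---------------------------------------------------------------------------


def sample_climate_sequence(
    rule: str,
    pool: ClimatePool,
    n_transitions: int,
    rng: int | np.random.Generator,
) -> tuple[list[ClimateYear], np.ndarray]:
    """Draw a climate sequence under `rule`; the boolean mask marks the
    favourable (pulse-eligible) years."""
    if rule not in CLIMATE_RULES:
        raise ValueError(f"unknown climate rule {rule!r}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    years = [c.year for c in pool.years]
    fav = pool.favourable.get(rule.split("_")[-1]) if "_" in rule else None
    unfav = pool.unfavourable

    seq: list[ClimateYear] = []
    mask = np.zeros(n_transitions, dtype=bool)
    for t in range(n_transitions):
        # fixed randomness consumption per transition (one uniform, one large
        # integer) regardless of the rule or its outcome, so different rules
        # under the same seed are compared with common random numbers
        u = rng.random()
        j = int(rng.integers(0, 2 ** 62))
        if rule == "random":
            year = years[j % len(years)]
        elif rule in ("favourable_HS", "favourable_LS"):
            p = FAVOURABLE_PROB[rule.split("_")[-1]]
            if u < p:
                year, mask[t] = fav, True
            else:
                rest = [y for y in years if y != fav]
                year = rest[j % len(rest)]
        elif rule == "unfavourable":
            if u < UNFAVOURABLE_PROB:
                year = unfav
            else:
                rest = [y for y in years if y != unfav]
                year = rest[j % len(rest)]
        else:  # combined_HS / combined_LS
            p = FAVOURABLE_PROB[rule.split("_")[-1]]
            if u < p:
                year, mask[t] = fav, True
            elif u < p + (1.0 - p) * UNFAVOURABLE_PROB:
                year = unfav
            else:
                rest = [y for y in years if y not in (fav, unfav)]
                year = rest[j % len(rest)]
        seq.append(pool.by_year(year))
    return seq, mask


def stochastic_growth_rate(total_densities: Sequence[float]) -> float:
    """Mean annual log change of total density over a trajectory:
    (1/T) log(N_T / N_0). Extinction (N hits 0) gives -inf."""
    N = np.asarray(total_densities, float)
    if len(N) < 2:
        raise ValueError("trajectory needs at least 2 years")
    if N[0] <= 0:
        raise ValueError("initial total density must be > 0")
    if np.any(N[1:] <= 0):
        return -math.inf
    T = len(N) - 1
    return float((math.log(N[-1]) - math.log(N[0])) / T)


# ---------------------------------------------------------------------------
# Scenario runs
# ---------------------------------------------------------------------------


def _summarize(replicates: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for sp, g in replicates.groupby("species"):
        ok = g[np.isfinite(g["log_lambda_s"])]
        vals = ok["log_lambda_s"].to_numpy()
        rows.append({
            "species": sp,
            "median": float(np.median(vals)) if len(vals) else math.nan,
            "q25": float(np.quantile(vals, 0.25)) if len(vals) else math.nan,
            "q75": float(np.quantile(vals, 0.75)) if len(vals) else math.nan,
            "n_extinct": int(g["extinct"].sum()),
            "n_replicates": int(len(g)),
        })
    return pd.DataFrame(rows)


def run_scenario(
    spec: ScenarioSpec,
    model_sets: Mapping[str, SpeciesModelSet],
    pool: ClimatePool,
    master_seed: int = 0,
    grid: IPMGrid | None = None,
    initial_structure: str = "stable",
    initial_size_log_mean: Mapping[str, float] | None = None,
    initial_size_log_sd: Mapping[str, float] | None = None,
    keep_trajectories: bool = True,
) -> SimulationResult:
    """Run `spec.n_replicates` independent seeded projections.

    The initial abundance vector spreads each species' initial density over
    the mesh using its stable size distribution under the mean pool climate
    (the synthetic stand-in for an observed standing population, which
    contains recruits as well as adults); ``initial_structure="adult"``
    instead uses an adult-only Gaussian log-size profile. Quartiles use
    linear interpolation; extinct replicates (-inf growth rate) are counted
    separately and excluded from the quantile summaries.
    """
    seed = spec.seed if spec.seed is not None else master_seed
    if grid is None:
        grid = build_grid(math.log(0.1), math.log(1500.0))
    if initial_structure == "stable":
        mean_climate = ClimateYear(
            year=0,
            winter_min_temp=float(np.mean([c.winter_min_temp for c in pool.years])),
            spring_rainfall=float(np.mean([c.spring_rainfall for c in pool.years])),
            summer_water_balance=float(np.mean([c.summer_water_balance
                                                for c in pool.years])))
        states = {}
        for sp in SPECIES:
            kern = build_kernel(model_sets[sp], mean_climate, 0.30, 0.30,
                                spec.block, grid)
            w = stable_size_distribution(kern)
            states[sp] = PopulationState(
                species=sp, abundance=spec.initial_density[sp] * w, grid=grid)
        init = CoupledState(hs=states["HS"], ls=states["LS"], block=spec.block,
                            interaction_on=spec.interaction_on)
    elif initial_structure == "adult":
        mu = initial_size_log_mean or {"HS": 4.0, "LS": 4.5}
        sd = initial_size_log_sd or {"HS": 0.7, "LS": 0.7}
        init = CoupledState(
            hs=initial_state_from_density("HS", spec.initial_density["HS"], grid,
                                          mu["HS"], sd["HS"]),
            ls=initial_state_from_density("LS", spec.initial_density["LS"], grid,
                                          mu["LS"], sd["LS"]),
            block=spec.block, interaction_on=spec.interaction_on,
        )
    else:
        raise ValueError(f"unknown initial_structure {initial_structure!r}")
    rep_rows = []
    traj_frames = []
    for rep in range(spec.n_replicates):
        # counter-based seeding: the climate stream depends only on
        # (seed, replicate, rule), so scenario variants share randomness
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        seq, mask = sample_climate_sequence(spec.climate_rule, pool,
                                            spec.n_transitions, rng)
        mults = np.where(mask, spec.recruit_multiplier, 1.0)
        try:
            traj = run_projection(init, model_sets, seq, recruit_multipliers=mults)
        except FloatingPointError as exc:
            logger.warning("replicate %d of %s failed: %s", rep, spec.name, exc)
            for sp in SPECIES:
                rep_rows.append({"replicate": rep, "species": sp,
                                 "log_lambda_s": math.nan, "extinct": False,
                                 "failed": True})
            continue
        frame = trajectory_frame(traj, replicate=rep)
        if keep_trajectories:
            traj_frames.append(frame)
        for sp in SPECIES:
            dens = frame[frame["species"] == sp]["total_density"].to_numpy()
            ll = stochastic_growth_rate(dens)
            rep_rows.append({"replicate": rep, "species": sp, "log_lambda_s": ll,
                             "extinct": not math.isfinite(ll), "failed": False})
    replicates = pd.DataFrame(rep_rows)
    trajectories = (pd.concat(traj_frames, ignore_index=True)
                    if traj_frames else pd.DataFrame())
    return SimulationResult(spec=spec, replicates=replicates,
                            trajectories=trajectories,
                            summary=_summarize(replicates))


def run_scenario_battery(
    specs: Sequence[ScenarioSpec],
    model_sets: Mapping[str, SpeciesModelSet],
    pool: ClimatePool,
    master_seed: int = 0,
    grid: IPMGrid | None = None,
) -> pd.DataFrame:
    """Run every scenario; one tidy summary row per scenario x species.

    Individual scenario failures are recorded (all-NaN summaries) and the
    battery continues.
    """
    if len(specs) == 0:
        raise ValueError("empty scenario list")
    rows = []
    for spec in specs:
        try:
            res = run_scenario(spec, model_sets, pool, master_seed=master_seed,
                               grid=grid, keep_trajectories=False)
            summ = res.summary
        except Exception as exc:
            logger.error("scenario %s failed: %s", spec.name, exc)
            summ = pd.DataFrame([{"species": sp, "median": math.nan,
                                  "q25": math.nan, "q75": math.nan,
                                  "n_extinct": -1, "n_replicates": 0}
                                 for sp in SPECIES])
        for _, r in summ.iterrows():
            rows.append({
                "scenario": spec.name, "climate_rule": spec.climate_rule,
                "recruit_multiplier": spec.recruit_multiplier,
                "block": spec.block, "interaction_on": spec.interaction_on,
                "initial_density_HS": spec.initial_density["HS"],
                "initial_density_LS": spec.initial_density["LS"],
                **r.to_dict(),
            })
    return pd.DataFrame(rows)


def default_battery(
    n_replicates: int = 100,
    n_transitions: int = 14,
    blocks: Sequence[str] = ("A", "B"),
    interaction: Sequence[bool] = (True, False),
) -> list[ScenarioSpec]:
    """The 24 core climate-recruitment scenarios (6 climate rules x 4 recruit
    multipliers), expanded over blocks and interaction settings."""
    rules = ("random", "favourable_HS", "favourable_LS", "unfavourable",
             "combined_HS", "combined_LS")
    specs = []
    i = 0
    for rule in rules:
        for mult in RECRUIT_MULTIPLIERS:
            i += 1
            for block in blocks:
                for flag in interaction:
                    specs.append(ScenarioSpec(
                        name=f"sim{i:02d}_{rule}_x{mult:g}_{block}_"
                             f"{'int' if flag else 'noint'}",
                        climate_rule=rule, recruit_multiplier=mult,
                        block=block, interaction_on=flag,
                        n_replicates=n_replicates, n_transitions=n_transitions))
    return specs


def density_battery(
    n_replicates: int = 100,
    n_transitions: int = 14,
    recruit_multiplier: float = 10.0,
    rules: Sequence[str] = ("random", "favourable_HS", "favourable_LS"),
    blocks: Sequence[str] = ("A", "B"),
    interaction: Sequence[bool] = (True, False),
) -> list[ScenarioSpec]:
    """The initial-density experiments: 2-2, 2-20, 20-2, 20-20 individuals
    per m2, under tenfold recruitment pulses."""
    combos = [(2.0, 2.0), (2.0, 20.0), (20.0, 2.0), (20.0, 20.0)]
    specs = []
    for rule in rules:
        for dh, dl in combos:
            for block in blocks:
                for flag in interaction:
                    specs.append(ScenarioSpec(
                        name=f"dens_{rule}_HS{dh:g}_LS{dl:g}_{block}_"
                             f"{'int' if flag else 'noint'}",
                        climate_rule=rule, recruit_multiplier=recruit_multiplier,
                        initial_density={"HS": dh, "LS": dl},
                        block=block, interaction_on=flag,
                        n_replicates=n_replicates, n_transitions=n_transitions))
    return specs


# ---------------------------------------------------------------------------
# Pool construction and series comparison
# ---------------------------------------------------------------------------


def identify_reference_years(
    model_sets: Mapping[str, SpeciesModelSet],
    years: Sequence[ClimateYear],
    covers: tuple[float, float] = (0.30, 0.30),
    block: str = "A",
    grid: IPMGrid | None = None,
) -> tuple[Mapping[str, int], int]:
    """Designate favourable years (per-species argmax of deterministic
    lambda over the pool) and the unfavourable year, mirroring how the
    reference years were picked from the species-level models.

    Unfavourable years were synchronous between the species in the field, so
    the designated year is the one minimizing the worse of the two species'
    lambda ranks -- a year that is bad for both, not merely catastrophic for
    one (ties broken by the lower mean lambda)."""
    lams = {sp: lambda_vs_climate(model_sets[sp], years, covers, block, grid)
            for sp in SPECIES}
    favourable = {sp: int(lams[sp].loc[lams[sp]["lambda"].idxmax(), "year"])
                  for sp in SPECIES}
    ranks = {sp: lams[sp]["lambda"].rank().to_numpy() for sp in SPECIES}
    worse = np.maximum(ranks["HS"], ranks["LS"])
    mean_lam = (lams["HS"]["lambda"].to_numpy() + lams["LS"]["lambda"].to_numpy()) / 2
    order = sorted(range(len(worse)), key=lambda i: (worse[i], mean_lam[i]))
    unfavourable = int(lams["HS"].loc[order[0], "year"])
    return favourable, unfavourable


def default_climate_pool(
    model_sets: Mapping[str, SpeciesModelSet],
    n_years: int = 16,
    seed: int = 0,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    start_year: int = 2000,
    grid: IPMGrid | None = None,
) -> ClimatePool:
    """A synthetic 16-year pool (the length of the observed climate record)
    with reference years designated from the species-level models."""
    years = tuple(generate_climate_series(n_years, ranges, seed, start_year=start_year))
    favourable, unfavourable = identify_reference_years(model_sets, years, grid=grid)
    return ClimatePool(years=years, favourable=favourable, unfavourable=unfavourable)


def compare_lambda_series(series_a: Sequence[float], series_b: Sequence[float]) -> float:
    """Spearman rank correlation between two lambda series (ties mid-ranked).

    Constant series have no rank ordering; the correlation is undefined and
    returned as NaN with a logged warning.
    """
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("series must have equal length >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        logger.warning("Spearman correlation undefined for a constant series")
        return math.nan
    rho = spearmanr(a, b).statistic
    return float(rho)
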