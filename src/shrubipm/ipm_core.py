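"""Integral projection model kernels and deterministic growth rates.

The kernel K(y, x) = s(x) g(y|x) + f(y, x) maps the size distribution
n(x, t) to n(y, t+1) by integrating over the size domain [T, U]; here size
is log crown area. The integral is discretized with the midpoint rule on a
200-point mesh (the package default), giving the usual matrix iteration
n(t+1) = K n(t) whose dominant eigenvalue is the deterministic per-year
population growth rate lambda.

Components:

* P[j, i] = s(z_i) g(z_j | z_i) h   -- survival times a Gaussian growth
  density centred on the predicted next size, renormalized column-wise to
  its on-mesh mass so that no probability is lost to eviction;
* F[j, i] = p_repro(z_i) fec(z_i) c(z_j)  -- per-capita emerged seedlings
  placed at recruit sizes, with c a recruit-size density renormalized to
  integrate to one on the mesh.

Fecundity was calibrated on emerged seedlings, so the kernel carries no
separate establishment probability: first-year seedling mortality is simply
the survival transition applied to small sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .synthetic_data import ClimateYear, GeneratorConfig
from .vital_rates import VitalRateModel, predict_rate

logger = logging.getLogger("shrubipm")

__all__ = [
    "IPMGrid",
    "IPMKernel",
    "SpeciesModelSet",
    "build_grid",
    "grid_from_sizes",
    "discretize_kernel",
    "build_kernel",
    "dominant_lambda",
    "dominant_eigen",
    "lambda_vs_climate",
    "lambda_cover_surface",
    "model_set_from_config",
]

DEFAULT_N_MESH = 200

#: Minimum on-mesh mass of the growth density before renormalization is
#: considered an error rather than a logged correction. Upper-edge columns
#: legitimately lose most of their mass when predicted growth pushes past the
#: bound (renormalization there acts as a size ceiling, and can never inflate
#: a column above its survival rate); an essentially zero overlap, by
#: contrast, means the mesh does not contain the growth density at all.
MIN_GROWTH_MASS = 1e-4
#: Columns whose retained mass falls below this are logged.
WARN_GROWTH_MASS = 0.995
#: Minimum on-mesh mass of the recruit-size density (mesh too narrow below).
MIN_RECRUIT_MASS = 0.99


@dataclass(frozen=True)
class IPMGrid:
    """Midpoint mesh over the size domain [lower, upper] (log cm2)."""

    lower: float
    upper: float
    n_mesh: int = DEFAULT_N_MESH

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError(f"inverted bounds ({self.lower}, {self.upper})")
        if self.n_mesh < 2:
            raise ValueError("n_mesh must be >= 2")

    @property
    def h(self) -> float:
        return (self.upper - self.lower) / self.n_mesh

    @property
    def midpoints(self) -> np.ndarray:
        i = np.arange(self.n_mesh)
        return self.lower + (i + 0.5) * self.h

    @property
    def areas_cm2(self) -> np.ndarray:
        """Crown areas at the midpoints (the mesh lives on log area)."""
        return np.exp(self.midpoints)


@dataclass(frozen=True)
class IPMKernel:
    """Discretized kernel with its survival-growth (P) and fecundity (F)
    components and the covariate context it was built under."""

    grid: IPMGrid
    P: np.ndarray
    F: np.ndarray
    context: Mapping[str, float] = field(default_factory=dict)

    @property
    def K(self) -> np.ndarray:
        return self.P + self.F

    def __post_init__(self) -> None:
        n = self.grid.n_mesh
        for name, M in (("P", self.P), ("F", self.F)):
            if M.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}, got {M.shape}")
            if np.any(M < 0):
                raise ValueError(f"{name} has negative entries")


def build_grid(lower: float, upper: float, n_mesh: int = DEFAULT_N_MESH) -> IPMGrid:
    """Midpoint mesh: z_i = lower + (i - 1/2) h, h = (upper - lower)/n."""
    return IPMGrid(lower=lower, upper=upper, n_mesh=n_mesh)


def grid_from_sizes(sizes_cm2: Sequence[float], n_mesh: int = DEFAULT_N_MESH) -> IPMGrid:
    """Default integration limits from observed sizes: half the smallest to
    1.2 times the largest crown area, on the log scale."""
    sizes = np.asarray(sizes_cm2, float)
    if len(sizes) == 0 or np.any(sizes <= 0):
        raise ValueError("sizes must be a non-empty positive array")
    return build_grid(math.log(0.5 * sizes.min()), math.log(1.2 * sizes.max()), n_mesh)


def discretize_kernel(fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
                      grid: IPMGrid) -> np.ndarray:
    """Midpoint discretization of an arbitrary continuous kernel fn(y, x):
    K[j, i] = fn(z_j, z_i) h. Used for analytic validation kernels."""
    z = grid.midpoints
    zy, zx = np.meshgrid(z, z, indexing="ij")
    return fn(zy, zx) * grid.h


@dataclass(frozen=True)
class SpeciesModelSet:
    """The four selected vital-rate models of one species plus the recruit
    size distribution (mean/SD of log crown area) the kernel needs."""

    species: str
    survival: VitalRateModel
    growth: VitalRateModel
    reproduction: VitalRateModel
    fecundity: VitalRateModel
    recruit_log_mean: float
    recruit_log_sd: float

    def __post_init__(self) -> None:
        if self.recruit_log_sd <= 0:
            raise ValueError("recruit_log_sd must be > 0")
        if self.growth.sigma_resid is None or self.growth.sigma_resid <= 0:
            raise ValueError("growth model must carry a positive residual SD")


def model_set_from_config(config: GeneratorConfig, species: str) -> SpeciesModelSet:
    """The generative-twin model set: kernels built from the exact
    coefficients the synthetic censuses were generated with."""
    from .vital_rates import true_models_from_config

    models = true_models_from_config(config, species)
    return SpeciesModelSet(
        species=species,
        survival=models["survival"], growth=models["growth"],
        reproduction=models["reproduction"], fecundity=models["fecundity"],
        recruit_log_mean=config.recruit_size_log_mean[species],
        recruit_log_sd=config.recruit_size_log_sd[species],
    )


def _context(climate: ClimateYear, intra: float, inter: float, block: str) -> dict:
    return {
        "blockB": 1.0 if block == "B" else 0.0,
        "intra": float(intra),
        "inter": float(inter),
        "winter_temp": climate.winter_min_temp,
        "spring_rain": climate.spring_rainfall,
        "summer_wb": climate.summer_water_balance,
        "year": climate.year,
    }


def recruit_density(model_set: SpeciesModelSet, grid: IPMGrid) -> np.ndarray:
    """Recruit-size weights on the mesh, truncated-renormalized to sum to 1."""
    c = norm.pdf(grid.midpoints, model_set.recruit_log_mean, model_set.recruit_log_sd)
    mass = float(c.sum() * grid.h)
    if mass < MIN_RECRUIT_MASS:
        raise ValueError(
            f"recruit-size density retains only {mass:.3f} of its mass on the mesh; "
            "widen the integration limits")
    w = c * grid.h
    return w / w.sum()


def build_kernel(
    model_set: SpeciesModelSet,
    climate: ClimateYear,
    intra: float,
    inter: float,
    block: str = "A",
    grid: IPMGrid | None = None,
    recruit_multiplier: float = 1.0,
) -> IPMKernel:
    """Discretized kernel for one covariate context.

    `intra` and `inter` are plot-level cover fractions; `recruit_multiplier`
    scales the fecundity component only (recruitment pulses).
    """
    if grid is None:
        grid = build_grid(math.log(0.1), math.log(1000.0))
    if recruit_multiplier < 0:
        raise ValueError("recruit_multiplier must be >= 0")
    ctx = _context(climate, intra, inter, block)
    z = grid.midpoints
    cov = {k: v for k, v in ctx.items() if k != "year"}
    cov["size"] = z

    s = np.asarray(predict_rate(model_set.survival, cov), float)
    mean_next = np.asarray(predict_rate(model_set.growth, cov), float)
    sd = float(model_set.growth.sigma_resid)
    G = norm.pdf(z[:, None], mean_next[None, :], sd) * grid.h
    mass = G.sum(axis=0)
    if np.any(mass < MIN_GROWTH_MASS):
        worst = float(mass.min())
        raise ValueError(
            f"growth density retains only {worst:.3f} of its mass on the mesh; "
            "the integration limits are too narrow")
    n_evicted = int(np.sum(mass < WARN_GROWTH_MASS))
    if n_evicted:
        logger.info(
            "%s kernel: renormalized %d/%d growth columns with on-mesh mass < %.3f "
            "(min %.3f)", model_set.species, n_evicted, grid.n_mesh,
            WARN_GROWTH_MASS, float(mass.min()))
    G /= mass[None, :]
    P = G * s[None, :]

    p_flower = np.asarray(predict_rate(model_set.reproduction, cov), float)
    fec = np.asarray(predict_rate(model_set.fecundity, cov), float)
    c_norm = recruit_density(model_set, grid)
    F = recruit_multiplier * np.outer(c_norm, p_flower * fec)
    return IPMKernel(grid=grid, P=P, F=F, context=ctx)


# ---------------------------------------------------------------------------
# Growth rates
# ---------------------------------------------------------------------------


def dominant_eigen(matrix: np.ndarray, tol: float = 1e-12,
                   max_iter: int = 2000) -> tuple[float, np.ndarray]:
    """Dominant eigenvalue and right eigenvector of a non-negative matrix.

    Power iteration with a direct eigensolve fallback when it stalls
    (e.g. equal-magnitude eigenvalues).
    """
    A = np.asarray(matrix, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    if np.any(A < 0):
        raise ValueError("kernel matrix must be non-negative")
    n = A.shape[0]
    w = np.full(n, 1.0 / n)
    lam = 0.0
    for _ in range(max_iter):
        v = A @ w
        new = float(v.sum())
        if new == 0.0:
            return 0.0, w
        v /= new
        if abs(new - lam) < tol * max(1.0, abs(new)) and np.max(np.abs(v - w)) < tol:
            return new, v
        lam, w = new, v
    vals, vecs = np.linalg.eig(A)
    k = int(np.argmax(np.abs(vals)))
    lam = float(np.abs(vals[k]))
    vec = np.abs(np.real(vecs[:, k]))
    s = vec.sum()
    return lam, (vec / s if s > 0 else vec)


def dominant_lambda(kernel: IPMKernel | np.ndarray) -> float:
    """Deterministic per-year population growth rate of a kernel."""
    A = kernel.K if isinstance(kernel, IPMKernel) else np.asarray(kernel, float)
    lam, _ = dominant_eigen(A)
    return lam


def stable_size_distribution(kernel: IPMKernel | np.ndarray) -> np.ndarray:
    A = kernel.K if isinstance(kernel, IPMKernel) else np.asarray(kernel, float)
    _, w = dominant_eigen(A)
    return w


def lambda_vs_climate(
    model_set: SpeciesModelSet,
    climate_table: Sequence[ClimateYear],
    covers: tuple[float, float] = (0.30, 0.30),
    block: str = "A",
    grid: IPMGrid | None = None,
) -> pd.DataFrame:
    """Per-year deterministic lambda at fixed covers (default 30 %/30 %)."""
    if len(climate_table) == 0:
        raise ValueError("climate_table must be non-empty")
    intra, inter = covers
    rows = [
        {"year": c.year,
         "lambda": dominant_lambda(build_kernel(model_set, c, intra, inter, block, grid))}
        for c in climate_table
    ]
    return pd.DataFrame(rows)


def lambda_cover_surface(
    model_set: SpeciesModelSet,
    climate: ClimateYear,
    intra_values: Sequence[float],
    inter_values: Sequence[float],
    block: str = "A",
    grid: IPMGrid | None = None,
) -> pd.DataFrame:
    """Tidy lambda over every intra x inter cover combination.

    ``on_contour`` flags cells where lambda crosses 1 relative to a grid
    neighbour (the coexistence boundary of the surface plots).
    """
    intra_values = np.asarray(intra_values, float)
    inter_values = np.asarray(inter_values, float)
    for v in (intra_values, inter_values):
        if np.any((v < 0) | (v > 1)):
            raise ValueError("cover values must lie in [0, 1]")
    lam = np.empty((len(intra_values), len(inter_values)))
    for i, a in enumerate(intra_values):
        for j, b in enumerate(inter_values):
            lam[i, j] = dominant_lambda(build_kernel(model_set, climate, a, b, block, grid))
    sign = np.sign(lam - 1.0)
    on_contour = np.zeros_like(lam, dtype=bool)
    on_contour[:-1, :] |= sign[:-1, :] != sign[1:, :]
    on_contour[1:, :] |= sign[1:, :] != sign[:-1, :]
    on_contour[:, :-1] |= sign[:, :-1] != sign[:, 1:]
    on_contour[:, 1:] |= sign[:, 1:] != sign[:, :-1]
    rows = []
    for i, a in enumerate(intra_values):
        for j, b in enumerate(inter_values):
            rows.append({"intra": a, "inter": b, "lambda": lam[i, j],
                         "on_contour": bool(on_contour[i, j])})
    return pd.DataFrame(rows)
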