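"""Vital-rate computation, regression fitting and AIC model selection.

Derived quantities (summer water balance, plot-level interaction indices,
per-adult fecundity allocated from seedling counts) feed four regressions per
species: survival (binomial-logit, quadratic in size), growth (Gaussian on
the log-size increment), probability of reproduction (binomial-logit, never
including summer water balance) and fecundity (Poisson-log; the likelihood
is evaluated on plot-year seedling totals, the scale the counts were
observed on, with mean summed over the flowering adults' per-plant
intensities). Every model carries a plot random intercept; the
binomial/Poisson marginal likelihood is maximised with an adaptive
Gauss-Hermite approximation of the per-plot integrals (Laplace at one
quadrature node), the Gaussian model through statsmodels MixedLM.

Model selection follows the Delta-AIC < 2 parsimony rule: among candidates
within 2 AIC units of the best, the one with fewest parameters wins; block
and the interspecific index are forced back into the winner when they appear
anywhere in that set, because block is part of the design and the
interspecific interaction is the scientific focus.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .synthetic_data import (
    DEGREE_WEIGHTS,
    OPTIONAL_TERMS,
    PLOT_AREA_CM2,
    RATES,
    SPECIES,
    ClimateYear,
    GeneratorConfig,
    IndividualRecord,
    PlotCensus,
)

logger = logging.getLogger("shrubipm")

__all__ = [
    "InteractionIndices",
    "VitalRateModel",
    "CandidateSet",
    "UnassignableSeedlingsError",
    "summer_water_balance",
    "interaction_indices",
    "fecundity_per_plant",
    "build_design",
    "fit_vital_rate",
    "select_model",
    "predict_rate",
    "candidate_terms",
    "fit_and_select",
    "fit_all_rates",
    "true_models_from_config",
    "load_default_coefficients",
    "models_to_json",
]

RATE_FAMILY = {
    "survival": "binomial",
    "growth": "gaussian",
    "reproduction": "binomial",
    "fecundity": "poisson",
}


class UnassignableSeedlingsError(ValueError):
    """Seedlings observed in a plot-year with no positive allocation weight."""


@dataclass(frozen=True)
class InteractionIndices:
    """Plot-level competition indices for one focal plant (cover fractions)."""

    intra: float
    inter: float

    def __post_init__(self) -> None:
        if self.intra < -1e-12 or self.inter < -1e-12:
            raise ValueError("interaction indices must be >= 0")


@dataclass(frozen=True)
class VitalRateModel:
    """A fitted (or configured) regression for one vital rate of one species.

    `coefficients` maps term name -> estimate and always contains
    ``intercept``; size terms are ``size`` (log area) and, for survival,
    ``size2``. `sigma_plot` is the plot random-intercept SD, `sigma_resid`
    the Gaussian residual SD (growth only).
    """

    species: str
    rate: str
    family: str
    terms: tuple[str, ...]
    coefficients: Mapping[str, float]
    se: Mapping[str, float] = field(default_factory=dict)
    sigma_plot: float = 0.0
    sigma_resid: float | None = None
    aic: float = math.nan
    n_obs: int = 0
    converged: bool = True
    method: str = "configured"

    def __post_init__(self) -> None:
        if self.rate not in RATES:
            raise ValueError(f"unknown rate {self.rate!r}")
        if self.family != RATE_FAMILY[self.rate]:
            raise ValueError(
                f"{self.rate} must use the {RATE_FAMILY[self.rate]} family, got {self.family}")
        if self.rate == "reproduction" and "summer_wb" in self.terms:
            raise ValueError("reproduction models never contain summer_wb")
        if "intercept" not in self.coefficients:
            raise ValueError("coefficients must include an intercept")

    @property
    def n_params(self) -> int:
        # fixed effects + random-intercept SD (+ residual SD for gaussian)
        return len(self.coefficients) + 1 + (1 if self.family == "gaussian" else 0)


@dataclass(frozen=True)
class CandidateSet:
    """The additive candidate subsets to fit for one rate (size always in)."""

    rate: str
    subsets: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        for sub in self.subsets:
            for t in sub:
                if t not in OPTIONAL_TERMS:
                    raise ValueError(f"unknown candidate term {t!r}")
            if self.rate == "reproduction" and "summer_wb" in sub:
                raise ValueError("reproduction candidates never contain summer_wb")


def candidate_terms(rate: str, pool: Sequence[str] = OPTIONAL_TERMS) -> CandidateSet:
    """All additive subsets of `pool` (minus summer_wb for reproduction)."""
    pool = [t for t in pool if not (rate == "reproduction" and t == "summer_wb")]
    subsets = []
    for r in range(len(pool) + 1):
        subsets.extend(itertools.combinations(pool, r))
    return CandidateSet(rate=rate, subsets=tuple(subsets))


# ---------------------------------------------------------------------------
# Derived demographic quantities
# ---------------------------------------------------------------------------


def summer_water_balance(rain_mm: float, mean_temp_c: float) -> float:
    """P - 2T: accumulated June-September rainfall minus twice the mean
    temperature; the study system's drought covariate (mm)."""
    if rain_mm < 0:
        raise ValueError(f"rainfall must be >= 0, got {rain_mm}")
    return rain_mm - 2.0 * mean_temp_c


def interaction_indices(
    focal_plant,
    plot_plants: Sequence,
    plot_area: float = PLOT_AREA_CM2,
) -> InteractionIndices:
    """Intra/interspecific cover indices for `focal_plant` within its plot.

    intra sums conspecific covers excluding the focal plant itself; inter
    sums covers of the other focal species. Plants need only expose
    ``species`` and ``size`` (crown area, cm2); covers are size/plot_area.
    """
    if not any(p is focal_plant for p in plot_plants):
        raise ValueError("focal plant is not a member of plot_plants")
    intra = 0.0
    inter = 0.0
    for p in plot_plants:
        if p is focal_plant:
            continue
        if p.species == focal_plant.species:
            intra += p.size / plot_area
        elif p.species in SPECIES:
            inter += p.size / plot_area
    return InteractionIndices(intra=intra, inter=inter)


def _allocation_weights(adults: Sequence, species: str) -> np.ndarray:
    sizes = np.array([a.size if hasattr(a, "size") else a[0] for a in adults], dtype=float)
    flow = [a.flowering if hasattr(a, "flowering") else a[1] for a in adults]
    if species == "HS":
        w = sizes * np.array([float(f) for f in flow])
    else:
        w = sizes * np.array([DEGREE_WEIGHTS[f] for f in flow])
    return w


def fecundity_per_plant(
    plot_seedlings: float, adults: Sequence, species: str
) -> np.ndarray:
    """Allocate a plot-year seedling count to adults, conserving the total.

    HS seedlings are split in proportion to size among flowering adults; LS
    seedlings in proportion to size times flowering-degree weight (60/30/10 %
    for high/medium/low, zero for none). The returned vector sums exactly to
    `plot_seedlings`.
    """
    if plot_seedlings < 0:
        raise ValueError("plot_seedlings must be >= 0")
    w = _allocation_weights(adults, species)
    if plot_seedlings == 0:
        return np.zeros_like(w)
    total = w.sum()
    if total <= 0:
        raise UnassignableSeedlingsError(
            f"{plot_seedlings} {species} seedlings but no positive allocation weight")
    fec = plot_seedlings * (w / total)
    # pin the floating-point residual onto the heaviest adults so the
    # conservation invariant holds exactly; rounding can 2-cycle on a single
    # index, so walk through candidates by decreasing weight
    for k in np.argsort(-w):
        for _ in range(4):
            resid = plot_seedlings - fec.sum()
            if resid == 0.0:
                return fec
            if fec[k] + resid < 0.0:
                break
            fec[k] += resid
    return fec


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------


def build_design(
    records: Sequence[IndividualRecord],
    climate: Sequence[ClimateYear],
    censuses: Sequence[PlotCensus] | None = None,
    plot_area: float = PLOT_AREA_CM2,
) -> pd.DataFrame:
    """One modelling row per plant-year: responses, covariates and indices.

    `size` is log crown area (the modelling scale); `growth` the log-size
    increment for survivors; `fecundity` the allocated seedling share for
    year-t adults from the year-t+1 seedling census, with `fec_offset` the
    log relative degree weight (zero for HS). Plot-years whose seedlings
    cannot be assigned (no flowering adult) get NaN fecundity and are
    reported via the package logger.
    """
    clim = {c.year: c for c in climate}
    missing = sorted({r.year for r in records} - set(clim))
    if missing:
        raise ValueError(f"no climate data for record years {missing}")
    seed_lookup: dict[tuple[str, int, str], int] = {}
    if censuses is not None:
        for c in censuses:
            for sp, n in c.seedling_count.items():
                seed_lookup[(c.plot_id, c.year, sp)] = n

    rows = []
    by_plot_year: dict[tuple[str, int], list[IndividualRecord]] = {}
    for r in records:
        by_plot_year.setdefault((r.plot_id, r.year), []).append(r)

    for (plot_id, year), group in by_plot_year.items():
        c = clim[year]
        cover = {sp: sum(r.size for r in group if r.species == sp) / plot_area
                 for sp in SPECIES}
        for sp in SPECIES:
            members = [r for r in group if r.species == sp]
            if not members:
                continue
            other = "LS" if sp == "HS" else "HS"
            n_seed = seed_lookup.get((plot_id, year + 1, sp)) if censuses is not None else None
            fec = None
            if n_seed is not None:
                try:
                    fec = fecundity_per_plant(n_seed, members, sp)
                except UnassignableSeedlingsError:
                    logger.warning(
                        "unassignable seedlings: plot %s year %d species %s (n=%d); "
                        "plot-year excluded from fecundity fitting",
                        plot_id, year + 1, sp, n_seed)
                    fec = None
            for i, r in enumerate(members):
                own = r.size / plot_area
                z = math.log(r.size)
                if sp == "HS":
                    weight_pos = r.flowering == 1
                    offset = 0.0
                else:
                    weight_pos = r.flowering != "none"
                    offset = (math.log(DEGREE_WEIGHTS[r.flowering] / DEGREE_WEIGHTS["high"])
                              if weight_pos else 0.0)
                rows.append({
                    "plant_id": r.plant_id, "species": sp, "block": r.block,
                    "plot_id": plot_id, "year": year,
                    "area_cm2": r.size, "size": z, "size2": z * z,
                    "blockB": 1.0 if r.block == "B" else 0.0,
                    # cover fractions, clipped at full cover like the
                    # dynamic projection's covariates
                    "intra": min(cover[sp] - own, 1.0),
                    "inter": min(cover[other], 1.0),
                    "winter_temp": c.winter_min_temp,
                    "spring_rain": c.spring_rainfall,
                    "summer_wb": c.summer_water_balance,
                    "surv": r.alive_next,
                    "growth": (math.log(r.size_next) - z) if r.alive_next else np.nan,
                    "flowered": r.flowered,
                    "fec_weight_positive": bool(weight_pos),
                    "fec_offset": offset,
                    "fecundity": (fec[i] if fec is not None else np.nan),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Random-intercept GLMM fitting (adaptive Gauss-Hermite marginal likelihood)
# ---------------------------------------------------------------------------


def _loglik_terms(family: str, y: np.ndarray, eta: np.ndarray):
    if family == "binomial":
        return y * eta - np.logaddexp(0.0, eta)
    if family == "poisson":
        return y * eta - np.exp(eta) - gammaln(y + 1.0)
    raise ValueError(family)


def _dloglik(family: str, y: np.ndarray, eta: np.ndarray):
    if family == "binomial":
        p = 1.0 / (1.0 + np.exp(-eta))
        return y - p, -p * (1.0 - p)
    mu = np.exp(eta)
    return y - mu, -mu


def _standardizer(X: np.ndarray):
    """Center/scale the non-intercept columns for optimization, returning
    (X_std, A) with A the linear map taking standardized-scale coefficients
    back to the original scale (beta_orig = A @ beta_std)."""
    k = X.shape[1]
    m = X[:, 1:].mean(axis=0)
    sd = X[:, 1:].std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    m = np.where(X[:, 1:].std(axis=0) > 1e-12, m, 0.0)
    Xs = X.copy()
    Xs[:, 1:] = (X[:, 1:] - m) / sd
    A = np.eye(k)
    A[0, 1:] = -m / sd
    A[np.arange(1, k), np.arange(1, k)] = 1.0 / sd
    return Xs, A


class _AGQProblem:
    """Negative marginal log-likelihood over (beta, log sigma_plot).

    Observations within a group (plot) share a Gaussian random intercept that
    is integrated out per group with adaptive Gauss-Hermite quadrature. When
    `member_obs` is given, the design matrix rows are *members* of composite
    observations and the observation-level linear predictor is
    log sum_i exp(x_i beta + off_i) over each observation's members --- the
    exact mean structure of a count observed as a plot-year total of
    per-plant Poisson intensities (fecundity).
    """

    def __init__(self, y, X, group_idx, family, offset=None, n_quad=15,
                 member_obs=None):
        X = np.asarray(X, float)
        offset = np.zeros(X.shape[0]) if offset is None else np.asarray(offset, float)
        y = np.asarray(y, float)
        group_idx = np.asarray(group_idx)
        if member_obs is None:
            order = np.argsort(group_idx, kind="stable")
            self.y = y[order]
            self.X = X[order]
            self.offset = offset[order]
            g = group_idx[order]
            self._member_starts = None
        else:
            member_obs = np.asarray(member_obs)
            obs_order = np.argsort(group_idx, kind="stable")
            rank = np.empty(len(obs_order), dtype=int)
            rank[obs_order] = np.arange(len(obs_order))
            m_order = np.argsort(rank[member_obs], kind="stable")
            self.X = X[m_order]
            self.offset = offset[m_order]
            mo = rank[member_obs][m_order]
            self._member_starts = np.flatnonzero(np.r_[True, mo[1:] != mo[:-1]])
            if len(self._member_starts) != len(y):
                raise ValueError("every observation needs at least one member")
            self.y = y[obs_order]
            g = group_idx[obs_order]
        self.starts = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
        self.n_groups = len(self.starts)
        self.group_of_obs = np.repeat(np.arange(self.n_groups),
                                      np.diff(np.r_[self.starts, len(g)]))
        self.family = family
        nodes, weights = hermgauss(n_quad)
        self.nodes = nodes
        self.logw = np.log(weights)
        self._u_warm = np.zeros(self.n_groups)

    def _eta0(self, beta: np.ndarray) -> np.ndarray:
        v = self.X @ beta + self.offset
        if self._member_starts is None:
            return v
        with np.errstate(over="ignore"):
            T = np.add.reduceat(np.exp(np.minimum(v, 700.0)), self._member_starts)
        return np.log(T)

    def _group_sum(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self.starts, axis=0)

    def nll(self, theta: np.ndarray) -> float:
        val = float(self.nll_by_group(theta).sum())
        return val if math.isfinite(val) else 1e12

    def nll_by_group(self, theta: np.ndarray) -> np.ndarray:
        beta, sigma = theta[:-1], math.exp(theta[-1])
        eta0 = self._eta0(beta)
        # Newton iterations for the per-group posterior mode of u ~ N(0,1),
        # warm-started from the previous evaluation
        u = self._u_warm.copy()
        for _ in range(25):
            d1, d2 = _dloglik(self.family, self.y, eta0 + sigma * u[self.group_of_obs])
            g1 = sigma * self._group_sum(d1) - u
            g2 = sigma * sigma * self._group_sum(d2) - 1.0
            step = g1 / g2
            step = np.clip(step, -2.0, 2.0)
            u -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        self._u_warm = u.copy()
        d1, d2 = _dloglik(self.family, self.y, eta0 + sigma * u[self.group_of_obs])
        curv = 1.0 - sigma * sigma * self._group_sum(d2)  # -q'' > 0
        tau = 1.0 / np.sqrt(curv)
        # adaptive nodes u_gk = u_g + sqrt(2) tau_g x_k
        ugk = u[:, None] + math.sqrt(2.0) * tau[:, None] * self.nodes[None, :]
        eta = eta0[:, None] + sigma * ugk[self.group_of_obs, :]
        ll = _loglik_terms(self.family, self.y[:, None], eta)
        S = self._group_sum(ll)  # (G, K)
        integrand = self.logw[None, :] + self.nodes[None, :] ** 2 + S - 0.5 * ugk ** 2
        log_int = (np.log(math.sqrt(2.0) * tau)
                   - 0.5 * math.log(2.0 * math.pi)
                   + logsumexp(integrand, axis=1))
        return -log_int

    def group_scores(self, theta: np.ndarray, step: float = 1e-5) -> np.ndarray:
        """Per-plot gradients of the marginal nll (central differences), for
        the plot-clustered robust covariance."""
        p = len(theta)
        S = np.empty((self.n_groups, p))
        for j in range(p):
            h = step * max(1.0, abs(theta[j]))
            e = np.zeros(p)
            e[j] = h
            S[:, j] = (self.nll_by_group(theta + e)
                       - self.nll_by_group(theta - e)) / (2.0 * h)
        return S


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    """Inverse of an information matrix with flat or indefinite directions
    floored: a direction with (numerically) zero curvature carries no
    information, so its variance is made enormous rather than the whole
    inversion failing -- the honest Wald interval for an unidentified
    coefficient (e.g. a completely separated block indicator) is effectively
    the whole real line."""
    Hs = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(Hs)
    floor = max(float(np.max(np.abs(w))), 1.0) * 1e-10
    w = np.where(w > floor, w, floor)
    return (V / w) @ V.T


def _numeric_hessian(fun: Callable[[np.ndarray], float], x: np.ndarray,
                     step: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    h = step * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _design_matrix(df: pd.DataFrame, rate: str, terms: Sequence[str]):
    cols = ["size"] + (["size2"] if rate == "survival" else []) + list(terms)
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in cols])
    return X, ["intercept"] + cols


def _rate_frame(df: pd.DataFrame, species: str, rate: str) -> pd.DataFrame:
    sub = df[df["species"] == species]
    if rate == "growth":
        return sub[sub["surv"] == 1].dropna(subset=["growth"])
    if rate == "fecundity":
        return sub[sub["fec_weight_positive"]].dropna(subset=["fecundity"])
    return sub


_RESPONSE = {"survival": "surv", "growth": "growth",
             "reproduction": "flowered", "fecundity": "fecundity"}


def fit_vital_rate(
    df: pd.DataFrame,
    rate: str,
    terms: Sequence[str] = (),
    species: str | None = None,
    n_quad: int = 15,
    reml: bool = False,
) -> VitalRateModel:
    """Fit one vital-rate regression with a plot random intercept.

    `df` is a design frame from :func:`build_design` (already restricted to
    one species, or pass `species`). Non-convergence yields a flagged model
    with infinite AIC rather than an exception, so selection can skip it.
    """
    if species is not None:
        sub = _rate_frame(df, species, rate)
    else:
        sp = df["species"].unique()
        if len(sp) != 1:
            raise ValueError("design frame mixes species; pass species=")
        species = str(sp[0])
        sub = _rate_frame(df, species, rate)
    if rate == "reproduction" and "summer_wb" in terms:
        raise ValueError("reproduction models never contain summer_wb")
    if sub["plot_id"].nunique() < 2:
        raise ValueError("need at least 2 plots to fit a plot random intercept")
    family = RATE_FAMILY[rate]
    y = sub[_RESPONSE[rate]].to_numpy(float)
    X, names = _design_matrix(sub, rate, terms)
    groups, group_idx = np.unique(sub["plot_id"].to_numpy(), return_inverse=True)

    if family == "gaussian":
        return _fit_gaussian(y, X, names, sub["plot_id"].to_numpy(), species, rate,
                             tuple(terms), reml=reml)
    if rate == "fecundity":
        # The seedling count is observed per plot-year and split among
        # flowering adults deterministically, so the exact likelihood is
        # Poisson on the plot-year totals with mean sum_i exp(x_i beta):
        # fit that, rather than pretending the allocated shares are
        # independent counts.
        offset = sub["fec_offset"].to_numpy(float)
        obs_codes, _ = pd.factorize(
            pd.Series(zip(sub["plot_id"], sub["year"])), sort=True)
        y_obs = np.bincount(obs_codes, weights=y)
        first = np.full(obs_codes.max() + 1, -1, dtype=int)
        for i, c in enumerate(obs_codes):
            if first[c] < 0:
                first[c] = i
        obs_group = group_idx[first]
        return _fit_glmm_agq(y_obs, X, names, obs_group, "poisson", species,
                             rate, tuple(terms), offset=offset, n_quad=n_quad,
                             member_obs=obs_codes, start_y_member=y)
    return _fit_glmm_agq(y, X, names, group_idx, family, species, rate,
                         tuple(terms), n_quad=n_quad)


def _failed_model(species, rate, terms, names, n_obs, method) -> VitalRateModel:
    return VitalRateModel(
        species=species, rate=rate, family=RATE_FAMILY[rate], terms=tuple(terms),
        coefficients={n: math.nan for n in names}, se={}, sigma_plot=math.nan,
        aic=math.inf, n_obs=n_obs, converged=False, method=method)


def _gaussian_cluster_robust_se(y, Xs, groups, beta_s, scale, tau2, A):
    """Plot-clustered sandwich SEs for the mixed-model fixed effects, on the
    original covariate scale; the bread uses the fitted marginal covariance
    sigma^2 I + tau^2 J per plot (Woodbury inverse)."""
    try:
        uniq, idx = np.unique(np.asarray(groups), return_inverse=True)
        k = Xs.shape[1]
        bread = np.zeros((k, k))
        meat = np.zeros((k, k))
        r = y - Xs @ beta_s
        for g in range(len(uniq)):
            sel = idx == g
            Xg = Xs[sel]
            rg = r[sel]
            n_g = len(rg)
            c = tau2 / (scale * (scale + n_g * tau2)) if tau2 > 0 else 0.0
            XtVi = Xg.T / scale - c * np.outer(Xg.sum(axis=0), np.ones(n_g))
            bread += XtVi @ Xg
            sg = XtVi @ rg
            meat += np.outer(sg, sg)
        Binv = np.linalg.inv(bread)
        C = A @ (Binv @ meat @ Binv) @ A.T
        d = np.diag(C)
        if np.all(np.isfinite(d)) and np.all(d >= 0):
            return np.sqrt(d)
    except np.linalg.LinAlgError:
        pass
    return None


def _fit_gaussian(y, X, names, groups, species, rate, terms, reml=False) -> VitalRateModel:
    import warnings

    import statsmodels.api as sm

    k = X.shape[1]
    Xs, A = _standardizer(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, Xs, groups=groups)
            res = model.fit(reml=reml, method=["bfgs", "cg", "powell"], maxiter=2000)
        if not res.converged or not math.isfinite(res.llf):
            raise RuntimeError("MixedLM did not converge")
        beta = A @ np.asarray(res.fe_params, float)
        C = A @ np.asarray(res.cov_params())[:k, :k] @ A.T
        cov_re = np.atleast_2d(np.asarray(res.cov_re))
        aic = math.inf if reml else -2.0 * res.llf + 2.0 * (k + 2)
        se_arr = np.sqrt(np.maximum(np.diag(C), 0.0))
        rob = _gaussian_cluster_robust_se(
            y, Xs, groups, np.asarray(res.fe_params, float),
            float(res.scale), float(max(cov_re[0, 0], 0.0)), A)
        if rob is not None:
            se_arr = np.maximum(se_arr, rob)
        return VitalRateModel(
            species=species, rate=rate, family="gaussian", terms=terms,
            coefficients=dict(zip(names, beta)),
            se=dict(zip(names, se_arr)),
            sigma_plot=float(np.sqrt(max(cov_re[0, 0], 0.0))),
            sigma_resid=float(np.sqrt(res.scale)),
            aic=aic, n_obs=len(y), converged=True,
            method="mixedlm-reml" if reml else "mixedlm-ml")
    except Exception as exc:  # fixed-effects fallback
        logger.warning("MixedLM failed for %s/%s (%s); falling back to OLS",
                       species, rate, exc)
        try:
            res = sm.OLS(y, X).fit()
            sigma = float(np.sqrt(res.scale))
            k = X.shape[1]
            return VitalRateModel(
                species=species, rate=rate, family="gaussian", terms=terms,
                coefficients=dict(zip(names, np.asarray(res.params, float))),
                se=dict(zip(names, np.asarray(res.bse, float))),
                sigma_plot=0.0, sigma_resid=sigma,
                aic=-2.0 * res.llf + 2.0 * (k + 1), n_obs=len(y), converged=True,
                method="ols")
        except Exception:
            return _failed_model(species, rate, terms, names, len(y), "mixedlm")


def _glm_start(y, X, family, offset):
    import statsmodels.api as sm

    fam = sm.families.Binomial() if family == "binomial" else sm.families.Poisson()
    res = sm.GLM(y, X, family=fam, offset=offset).fit()
    return np.asarray(res.params, float), res


def _fit_glmm_agq(y, X, names, group_idx, family, species, rate, terms,
                  offset=None, n_quad=15, member_obs=None,
                  start_y_member=None) -> VitalRateModel:
    k = X.shape[1]
    Xs, A = _standardizer(X)
    prob = _AGQProblem(y, Xs, group_idx, family, offset=offset, n_quad=n_quad,
                       member_obs=member_obs)
    try:
        y_start = y if member_obs is None else start_y_member
        if y_start is None:
            raise ValueError("no member-level start response")
        beta0, glm_res = _glm_start(y_start, Xs, family, offset)
    except Exception:
        beta0, glm_res = np.zeros(k), None
    theta0 = np.r_[beta0, math.log(0.3)]
    # box on the standardized coefficients: plausible effects are far inside,
    # while a separated indicator (a block with no events at all) would
    # otherwise drift to -inf and exhaust the optimizer
    beta_box = 30.0
    theta0 = np.clip(theta0, -beta_box, beta_box)
    bounds = [(-beta_box, beta_box)] * k + [(math.log(1e-3), math.log(5.0))]
    try:
        res = minimize(prob.nll, theta0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "maxfun": 5000, "ftol": 1e-12,
                                "gtol": 1e-7})
    except Exception:
        return _failed_model(species, rate, terms, names, len(y), "agq")
    if not math.isfinite(res.fun):
        return _failed_model(species, rate, terms, names, len(y), "agq")
    theta = res.x
    sigma = math.exp(theta[-1])
    at_zero_boundary = theta[-1] <= math.log(1e-3) + 1e-6
    if at_zero_boundary and glm_res is not None and member_obs is None:
        # variance component collapsed: report the fixed-effects fit,
        # mapped back to the original covariate scale
        beta = A @ np.asarray(glm_res.params, float)
        C = A @ np.asarray(glm_res.cov_params()) @ A.T
        return VitalRateModel(
            species=species, rate=rate, family=family, terms=terms,
            coefficients=dict(zip(names, beta)),
            se=dict(zip(names, np.sqrt(np.maximum(np.diag(C), 0.0)))),
            sigma_plot=0.0, aic=float(glm_res.aic), n_obs=len(y),
            converged=True, method="glm")
    se = {}
    covs = []
    if at_zero_boundary:
        # the variance component sits on its bound: profile it out of the
        # information matrix instead of inverting a singular full Hessian
        tail = theta[-1]
        Hb = _numeric_hessian(lambda b: prob.nll(np.r_[b, tail]), theta[:k])
        covs.append(A @ _safe_inverse(Hb) @ A.T)
        sigma = 0.0
        H = np.eye(k + 1)
        H[:k, :k] = Hb
    else:
        H = _numeric_hessian(prob.nll, theta)
    Afull = np.eye(k + 1)
    Afull[:k, :k] = A
    covs.append((Afull @ _safe_inverse(H) @ Afull.T)[:k, :k])
    for C in covs:
        d = np.diag(C)
        if np.all(d > 0):
            se = dict(zip(names, np.sqrt(d)))
            break
    if se and not at_zero_boundary:
        # conservative inference: report the larger of the model-based and
        # plot-clustered sandwich standard error per coefficient, guarding
        # against within-plot dependence beyond the random intercept
        try:
            Hinv = _safe_inverse(H)
            Sg = prob.group_scores(theta)
            Crob = (Afull @ (Hinv @ (Sg.T @ Sg) @ Hinv) @ Afull.T)[:k, :k]
            d = np.diag(Crob)
            if np.all(np.isfinite(d)) and np.all(d >= 0):
                rob = np.sqrt(d)
                se = {n: max(se[n], float(r)) for n, r in zip(names, rob)}
        except np.linalg.LinAlgError:
            pass
    aic = 2.0 * res.fun + 2.0 * (k + 1)
    return VitalRateModel(
        species=species, rate=rate, family=family, terms=terms,
        coefficients=dict(zip(names, A @ theta[:k])), se=se,
        sigma_plot=sigma, aic=aic, n_obs=len(y),
        converged=bool(res.success) and bool(se), method="agq")


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


def select_model(
    candidate_fits: Sequence[VitalRateModel],
    refitter: Callable[[tuple[str, ...]], VitalRateModel] | None = None,
) -> VitalRateModel:
    """Delta-AIC < 2 parsimony selection with design-term forcing.

    Among converged candidates within 2 AIC units of the minimum, pick the
    one with fewest parameters (ties broken by lower AIC, then term order).
    If ``blockB`` or ``inter`` appears in any candidate of that set, the
    winner is refit with them forced in; the final model is then readjusted
    with REML (Gaussian family only) when a `refitter` is supplied.
    """
    fits = [f for f in candidate_fits if math.isfinite(f.aic)]
    if not fits:
        raise ValueError("no converged candidate model")
    best = min(f.aic for f in fits)
    plausible = [f for f in fits if f.aic - best < 2.0]
    chosen = min(plausible, key=lambda f: (f.n_params, f.aic, f.terms))
    forced = {t for f in plausible for t in ("blockB", "inter") if t in f.terms}
    need = forced - set(chosen.terms)
    final_terms = tuple(t for t in OPTIONAL_TERMS if t in set(chosen.terms) | forced)
    if refitter is None:
        if need:
            raise ValueError(
                f"terms {sorted(need)} must be forced into the selected model; "
                "supply a refitter")
        return chosen
    refit = refitter(final_terms)
    if not math.isfinite(refit.aic) and refit.family != "gaussian":
        logger.warning("forced refit failed for %s/%s; returning parsimony winner",
                       chosen.species, chosen.rate)
        return chosen
    return refit


def fit_and_select(
    df: pd.DataFrame,
    species: str,
    rate: str,
    candidates: CandidateSet | None = None,
    n_quad: int = 15,
) -> VitalRateModel:
    """Fit every candidate subset for one rate and apply the selection rule."""
    cands = candidates if candidates is not None else candidate_terms(rate)
    fits = [fit_vital_rate(df, rate, terms, species=species, n_quad=n_quad)
            for terms in cands.subsets]

    def refitter(terms: tuple[str, ...]) -> VitalRateModel:
        reml = RATE_FAMILY[rate] == "gaussian"
        model = fit_vital_rate(df, rate, terms, species=species, n_quad=n_quad,
                               reml=reml)
        if reml:
            # carry the ML AIC of the same term set forward for reporting
            ml = next((f for f in fits if set(f.terms) == set(terms)), None)
            if ml is not None and math.isfinite(ml.aic):
                object.__setattr__(model, "aic", ml.aic)
        return model

    return select_model(fits, refitter=refitter)


def fit_all_rates(
    df: pd.DataFrame,
    species: Sequence[str] = SPECIES,
    candidates: Mapping[str, CandidateSet] | None = None,
    n_quad: int = 15,
) -> dict[str, dict[str, VitalRateModel]]:
    """Selected model for every species x rate; the full model-step-1 stage."""
    out: dict[str, dict[str, VitalRateModel]] = {}
    for sp in species:
        out[sp] = {}
        for rate in RATES:
            cand = candidates.get(rate) if candidates else None
            out[sp][rate] = fit_and_select(df, sp, rate, candidates=cand, n_quad=n_quad)
    return out


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict_rate(model: VitalRateModel, covariates: Mapping[str, float | np.ndarray]):
    """Inverse-link prediction at `covariates` (must contain ``size`` on the
    modelling scale plus every optional term of the model).

    Growth returns the expected next size, i.e. size + predicted increment.
    """
    if "size" not in covariates:
        raise ValueError("missing covariate 'size'")
    size = np.asarray(covariates["size"], dtype=float)
    eta = np.full(size.shape or (), model.coefficients["intercept"], dtype=float)
    for term, beta in model.coefficients.items():
        if term == "intercept":
            continue
        if term == "size":
            val = size
        elif term == "size2":
            val = np.asarray(covariates.get("size2", size ** 2), dtype=float)
        else:
            if term not in covariates:
                raise ValueError(f"missing covariate {term!r} for {model.rate} model")
            val = np.asarray(covariates[term], dtype=float)
        eta = eta + beta * val
    if model.family == "binomial":
        return 1.0 / (1.0 + np.exp(-eta))
    if model.family == "poisson":
        return np.exp(eta)
    return size + eta  # gaussian growth: expected next size on the modelling scale


# ---------------------------------------------------------------------------
# Coefficient sets: packaged defaults and the generative twin
# ---------------------------------------------------------------------------


def load_default_coefficients() -> dict:
    """The packaged species x rate x term -> {estimate, se} coefficient file."""
    import json
    from importlib import resources

    with resources.files("shrubipm").joinpath("data/default_coefficients.json").open() as fh:
        return json.load(fh)["species"]


def true_models_from_config(
    config: GeneratorConfig, species: str
) -> dict[str, VitalRateModel]:
    """VitalRateModels carrying the generator's exact coefficients.

    These are the models the synthetic censuses were drawn from; projecting
    with them isolates the kernel/simulation machinery from fitting noise.
    """
    out = {}
    for rate in RATES:
        coefs = {"intercept": config.intercepts[species][rate]}
        coefs.update(config.size_coefficients[species][rate])
        terms = tuple(t for t in OPTIONAL_TERMS
                      if t in config.coefficients[species][rate])
        coefs.update({t: config.coefficients[species][rate][t] for t in terms})
        out[rate] = VitalRateModel(
            species=species, rate=rate, family=RATE_FAMILY[rate], terms=terms,
            coefficients=coefs, sigma_plot=config.sigma_plot[rate],
            sigma_resid=config.sigma_growth if rate == "growth" else None,
            method="generator")
    return out


def models_to_json(models: Mapping[str, Mapping[str, VitalRateModel]]) -> dict:
    """Serialize fitted models to the packaged coefficient-file schema."""
    out: dict = {"species": {}}
    for sp, rates in models.items():
        out["species"][sp] = {}
        for rate, m in rates.items():
            out["species"][sp][rate] = {
                t: {"estimate": float(m.coefficients[t]),
                    "se": float(m.se.get(t, math.nan))}
                for t in m.coefficients
            }
            out["species"][sp][rate]["_meta"] = {
                "family": m.family, "sigma_plot": float(m.sigma_plot),
                "sigma_resid": (None if m.sigma_resid is None else float(m.sigma_resid)),
                "aic": float(m.aic), "n_obs": int(m.n_obs), "method": m.method,
            }
    return out
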