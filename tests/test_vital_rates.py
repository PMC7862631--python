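"""Derived quantities, GLMM fitting, AIC selection and prediction."""

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import shrubipm as s
from shrubipm.vital_rates import (
    UnassignableSeedlingsError,
    VitalRateModel,
    _AGQProblem,
    build_design,
    candidate_terms,
    fecundity_per_plant,
    fit_vital_rate,
    interaction_indices,
    load_default_coefficients,
    predict_rate,
    select_model,
    summer_water_balance,
)


@dataclass
class _Plant:
    species: str
    size: float
    flowering: object = 1


class TestSummerWaterBalance:
    @pytest.mark.parametrize("rain,temp,expected", [
        (0.0, 0.0, 0.0),
        (100.0, 25.0, 50.0),
        (50.0, 30.0, -10.0),
    ])
    def test_formula(self, rain, temp, expected):
        assert summer_water_balance(rain, temp) == expected

    def test_negative_rainfall_rejected(self):
        with pytest.raises(ValueError):
            summer_water_balance(-1.0, 10.0)


class TestInteractionIndices:
    def test_mixed_plot_sums(self):
        # covers are size/plot_area; use plot_area = 1 so sizes are covers
        focal = _Plant("HS", 0.10)
        plot = [focal, _Plant("HS", 0.20), _Plant("HS", 0.30), _Plant("LS", 0.15)]
        idx = interaction_indices(focal, plot, plot_area=1.0)
        assert idx.intra == pytest.approx(0.50)
        assert idx.inter == pytest.approx(0.15)

    def test_lone_plant(self):
        focal = _Plant("HS", 0.4)
        idx = interaction_indices(focal, [focal], plot_area=1.0)
        assert (idx.intra, idx.inter) == (0.0, 0.0)

    def test_symmetry_among_equals(self):
        plants = [_Plant("LS", 0.2) for _ in range(3)]
        for focal in plants:
            idx = interaction_indices(focal, plants, plot_area=1.0)
            assert idx.intra == pytest.approx(0.4)

    def test_permutation_invariance(self):
        focal = _Plant("HS", 0.1)
        others = [_Plant("HS", 0.2), _Plant("LS", 0.3), _Plant("HS", 0.05)]
        a = interaction_indices(focal, [focal] + others, plot_area=1.0)
        b = interaction_indices(focal, others[::-1] + [focal], plot_area=1.0)
        assert a == b

    def test_focal_must_be_member(self):
        with pytest.raises(ValueError, match="member"):
            interaction_indices(_Plant("HS", 0.1), [_Plant("HS", 0.2)])


class TestFecundityAllocation:
    def test_hs_proportional_to_size(self):
        adults = [_Plant("HS", 100.0, 1), _Plant("HS", 300.0, 1)]
        fec = fecundity_per_plant(10, adults, "HS")
        assert fec == pytest.approx([2.5, 7.5])

    def test_ls_degree_weights(self):
        adults = [_Plant("LS", 50.0, "high"), _Plant("LS", 50.0, "low")]
        fec = fecundity_per_plant(10, adults, "LS")
        assert fec == pytest.approx([10 * 0.6 / 0.7, 10 * 0.1 / 0.7])

    def test_zero_seedlings(self):
        fec = fecundity_per_plant(0, [_Plant("HS", 10.0, 1)], "HS")
        assert np.all(fec == 0)

    def test_unassignable_flagged(self):
        with pytest.raises(UnassignableSeedlingsError):
            fecundity_per_plant(5, [_Plant("HS", 10.0, 0)], "HS")

    @given(
        n_seed=st.integers(1, 500),
        sizes=st.lists(st.floats(0.5, 500.0), min_size=1, max_size=12),
        degrees=st.data(),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_conservation_is_exact(self, n_seed, sizes, degrees):
        levels = ["none", "low", "medium", "high"]
        adults = [_Plant("LS", sz,
                         degrees.draw(st.sampled_from(levels), label="degree"))
                  for sz in sizes]
        if all(a.flowering == "none" for a in adults):
            adults[0].flowering = "high"
        fec = fecundity_per_plant(n_seed, adults, "LS")
        assert fec.sum() == n_seed
        assert np.all(fec >= 0)


class TestBuildDesign:
    def test_intra_excludes_self(self, small_design):
        df = small_design
        grp = df.groupby(["plot_id", "year", "species"])
        for (_, _, sp), g in grp:
            if len(g) < 2:
                continue
            total = g["area_cm2"].sum() / s.synthetic_data.PLOT_AREA_CM2
            expected = (total - g["area_cm2"] / s.synthetic_data.PLOT_AREA_CM2)
            assert np.allclose(g["intra"], np.minimum(expected, 1.0))
            break

    def test_growth_is_log_increment(self, small_dataset, small_design):
        records, _, _ = small_dataset
        alive = next(r for r in records if r.alive_next == 1)
        row = small_design[small_design["plant_id"] == alive.plant_id].iloc[0]
        assert row["growth"] == pytest.approx(
            math.log(alive.size_next) - math.log(alive.size))

    def test_missing_climate_year_rejected(self, small_dataset):
        records, censuses, climate = small_dataset
        with pytest.raises(ValueError, match="climate"):
            build_design(records, climate[:-1], censuses)


def _stub_fit(aic, terms=(), n_coef=None, species="HS", rate="survival"):
    coefs = {"intercept": 0.0, "size": 0.0}
    if rate == "survival":
        coefs["size2"] = 0.0
    for t in terms:
        coefs[t] = 0.0
    if n_coef is not None:
        for i in range(n_coef - len(coefs)):
            coefs[f"x{i}"] = 0.0
    return VitalRateModel(
        species=species, rate=rate, family="binomial", terms=tuple(terms),
        coefficients=coefs, aic=aic, method="stub")


class TestSelectModel:
    def test_parsimony_within_two_aic(self):
        fits = [_stub_fit(100.0, n_coef=5), _stub_fit(101.5, n_coef=3),
                _stub_fit(104.0, n_coef=4)]
        assert select_model(fits).aic == 101.5

    def test_single_candidate(self):
        fit = _stub_fit(50.0)
        assert select_model([fit]) is fit

    def test_parsimony_tie_breaks_on_aic(self):
        fits = [_stub_fit(100.0, n_coef=3), _stub_fit(101.9, n_coef=3)]
        assert select_model(fits).aic == 100.0

    def test_order_invariance(self):
        fits = [_stub_fit(100.0, n_coef=5), _stub_fit(101.5, n_coef=3),
                _stub_fit(104.0, n_coef=4)]
        assert select_model(fits[::-1]).aic == select_model(fits).aic

    def test_non_converged_never_selected(self):
        fits = [_stub_fit(math.inf), _stub_fit(200.0)]
        assert select_model(fits).aic == 200.0
        with pytest.raises(ValueError, match="converged"):
            select_model([_stub_fit(math.inf)])

    def test_design_terms_forced_back_in(self):
        lean = _stub_fit(100.0, terms=())
        rich = _stub_fit(100.5, terms=("blockB", "inter"))
        refits = []

        def refitter(terms):
            refits.append(terms)
            return _stub_fit(99.0, terms=terms)

        chosen = select_model([lean, rich], refitter=refitter)
        assert refits == [("blockB", "inter")]
        assert set(chosen.terms) == {"blockB", "inter"}

    def test_forcing_without_refitter_is_an_error(self):
        lean = _stub_fit(100.0, terms=())
        rich = _stub_fit(100.5, terms=("inter",))
        with pytest.raises(ValueError, match="refitter"):
            select_model([lean, rich])


class TestCandidates:
    def test_reproduction_pool_excludes_summer_wb(self):
        cand = candidate_terms("reproduction")
        assert all("summer_wb" not in sub for sub in cand.subsets)
        assert len(cand.subsets) == 2 ** 5

    def test_full_pool_size(self):
        assert len(candidate_terms("survival").subsets) == 2 ** 6


class TestFitVitalRate:
    def test_intercept_only_binomial_matches_saturated_mean(self):
        n = 1000
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "species": "HS", "plot_id": rng.choice(["p1", "p2", "p3", "p4"], n),
            "size": 0.0, "size2": 0.0, "surv": 1, "block": "A",
        })
        df.loc[0, "surv"] = 0
        m = fit_vital_rate(df, "survival", (), species="HS")
        p = 1.0 / (1.0 + math.exp(-m.coefficients["intercept"]))
        assert p == pytest.approx(0.999, abs=2e-3)

    def test_noise_free_growth_recovered_exactly(self):
        rng = np.random.default_rng(1)
        n = 200
        size = rng.uniform(0.0, 5.0, n)
        df = pd.DataFrame({
            "species": "HS", "plot_id": rng.choice(["p1", "p2"], n),
            "size": size, "surv": 1, "growth": -0.5 * size, "block": "A",
        })
        m = fit_vital_rate(df, "growth", (), species="HS")
        assert m.coefficients["size"] == pytest.approx(-0.5, abs=1e-8)
        assert m.coefficients["intercept"] == pytest.approx(0.0, abs=1e-8)

    def test_reproduction_refuses_summer_wb(self, small_design):
        with pytest.raises(ValueError, match="summer_wb"):
            fit_vital_rate(small_design, "reproduction", ("summer_wb",),
                           species="HS")

    def test_single_plot_rejected(self):
        df = pd.DataFrame({"species": "HS", "plot_id": "p1", "size": [1.0] * 10,
                           "size2": 1.0, "surv": 1, "block": "A"})
        with pytest.raises(ValueError, match="plots"):
            fit_vital_rate(df, "survival", (), species="HS")

    def test_recovers_generating_survival_coefficients(self, small_config,
                                                       small_design):
        """One-replicate sanity: every generating coefficient of the HS
        survival model within 4 SE of its estimate."""
        from shrubipm.vital_rates import true_models_from_config

        true = true_models_from_config(small_config, "HS")["survival"]
        m = fit_vital_rate(small_design, "survival", true.terms, species="HS")
        assert m.converged
        for t, tv in true.coefficients.items():
            assert abs(m.coefficients[t] - tv) < 4.0 * m.se[t], t


class TestAGQLikelihood:
    def test_marginal_likelihood_matches_brute_force_quadrature(self):
        """The AGQ marginal nll agrees with direct numerical integration of
        the per-plot integrals on a tiny binomial dataset."""
        from scipy.integrate import quad
        from scipy.stats import norm as normal

        rng = np.random.default_rng(4)
        n, G = 60, 6
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        groups = np.repeat(np.arange(G), n // G)
        beta = np.array([0.3, -0.7])
        sigma = 0.8
        u = rng.normal(0, 1, G)
        eta = X @ beta + sigma * u[groups]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)

        prob = _AGQProblem(y, X, groups, "binomial", n_quad=25)
        theta = np.r_[beta, math.log(sigma)]
        agq = -prob.nll(theta)

        def group_loglik(g):
            idx = groups == g
            Xg, yg = X[idx], y[idx]

            def integrand(ug):
                e = Xg @ beta + sigma * ug
                ll = np.sum(yg * e - np.logaddexp(0, e))
                return math.exp(ll) * normal.pdf(ug)

            val, _ = quad(integrand, -8, 8, limit=200)
            return math.log(val)

        brute = sum(group_loglik(g) for g in range(G))
        assert agq == pytest.approx(brute, abs=1e-8)


class TestPredictRate:
    def test_zero_coefficients_give_half(self):
        m = _stub_fit(0.0)
        assert predict_rate(m, {"size": 1.0}) == pytest.approx(0.5)

    def test_poisson_log_link(self):
        m = VitalRateModel(species="HS", rate="fecundity", family="poisson",
                           terms=(), coefficients={"intercept": math.log(2.0),
                                                   "size": 0.0})
        assert predict_rate(m, {"size": 3.0}) == pytest.approx(2.0)

    def test_growth_returns_size_plus_increment(self):
        m = VitalRateModel(species="HS", rate="growth", family="gaussian",
                           terms=(), coefficients={"intercept": 0.25, "size": 0.0},
                           sigma_resid=0.3)
        assert predict_rate(m, {"size": 2.0}) == pytest.approx(2.25)

    def test_dot_product_oracle_on_default_survival_coefficients(self):
        """Inverse-logit of a hand-computed dot product equals predict_rate to
        1e-12 for the packaged HS survival coefficients."""
        defaults = load_default_coefficients()
        coefs = {"intercept": -1.0, "size": 0.5, "size2": -0.04}
        coefs.update({t: v["estimate"] for t, v in defaults["HS"]["survival"].items()})
        m = VitalRateModel(species="HS", rate="survival", family="binomial",
                           terms=tuple(defaults["HS"]["survival"]),
                           coefficients=coefs)
        x = {"size": 3.7, "size2": 3.7 ** 2, "blockB": 1.0, "intra": 0.21,
             "inter": 0.08, "winter_temp": 1.3, "spring_rain": 131.0,
             "summer_wb": -33.5}
        eta = sum(coefs[t] * (1.0 if t == "intercept" else x[t]) for t in coefs)
        assert predict_rate(m, x) == pytest.approx(1 / (1 + math.exp(-eta)),
                                                   abs=1e-12)

    def test_missing_covariate_named(self):
        m = _stub_fit(0.0, terms=("inter",))
        with pytest.raises(ValueError, match="inter"):
            predict_rate(m, {"size": 1.0})


class TestDefaultCoefficients:
    def test_schema_and_reproduction_constraint(self):
        defaults = load_default_coefficients()
        assert set(defaults) == {"HS", "LS"}
        for sp, rates in defaults.items():
            assert set(rates) <= {"survival", "growth", "reproduction", "fecundity"}
            assert "summer_wb" not in rates["reproduction"]
            for terms in rates.values():
                for v in terms.values():
                    assert {"estimate", "se"} <= set(v)

    def test_spring_rain_survival_value(self):
        # the headline per-mm survival response used in parameter recovery
        defaults = load_default_coefficients()
        assert defaults["HS"]["survival"]["spring_rain"]["estimate"] == 0.073
        assert defaults["HS"]["survival"]["spring_rain"]["se"] == 0.004
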