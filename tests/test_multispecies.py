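"""Coupled projection: cover feedback, decoupling, density dependence."""

import math

import numpy as np
import pytest

import shrubipm as s
from shrubipm.ipm_core import build_grid, build_kernel, dominant_lambda
from shrubipm.multispecies import (
    CoupledState,
    PopulationState,
    cover_from_state,
    initial_state_from_density,
    run_projection,
    step_coupled,
    trajectory_frame,
)
from shrubipm.synthetic_data import GeneratorConfig


def _strip_terms(*terms):
    """Model sets whose coefficient sets drop the given covariates."""
    coefs = {sp: {r: {t: v for t, v in d.items() if t not in terms}
                  for r, d in rates.items()}
             for sp, rates in s.default_config().coefficients.items()}
    cfg = GeneratorConfig(coefficients=coefs)
    return {sp: s.model_set_from_config(cfg, sp) for sp in ("HS", "LS")}


@pytest.fixture(scope="module")
def grid():
    return build_grid(math.log(0.1), math.log(1500.0), 120)


def _coupled(grid, hs=16.0, ls=2.4, **kw):
    return CoupledState(
        hs=initial_state_from_density("HS", hs, grid, 4.0, 0.7),
        ls=initial_state_from_density("LS", ls, grid, 4.5, 0.7), **kw)


class TestCover:
    def test_two_plants_worked_example(self):
        grid = build_grid(math.log(100.0), math.log(600.0), 50)
        k = int(np.argmin(np.abs(grid.areas_cm2 - 250.0)))
        n = np.zeros(grid.n_mesh)
        n[k] = 2.0
        state = PopulationState("HS", n, grid)
        cover = cover_from_state(state, grid, reference_area=2500.0)
        assert cover == pytest.approx(2 * grid.areas_cm2[k] / 2500.0)

    def test_exact_arithmetic_with_midpoint_at_250(self):
        # choose bounds so a midpoint lands exactly on area 250 cm2
        z250 = math.log(250.0)
        grid = build_grid(z250 - 0.55, z250 + 0.45, 10)  # midpoint 6 is z250
        k = int(np.argmin(np.abs(grid.midpoints - z250)))
        assert grid.midpoints[k] == pytest.approx(z250, abs=1e-12)
        n = np.zeros(grid.n_mesh)
        n[k] = 2.0
        assert cover_from_state(PopulationState("HS", n, grid), grid,
                                reference_area=2500.0) == pytest.approx(0.2)

    def test_empty_state_has_zero_cover(self, grid):
        state = PopulationState("LS", np.zeros(grid.n_mesh), grid)
        assert cover_from_state(state, grid) == 0.0

    def test_cover_clipped_at_one(self, grid):
        n = np.full(grid.n_mesh, 1e4)
        state = PopulationState("HS", n, grid)
        assert cover_from_state(state, grid) == 1.0

    def test_grid_mismatch_rejected(self, grid):
        other = build_grid(0.0, 1.0, grid.n_mesh)
        state = PopulationState("HS", np.zeros(grid.n_mesh), grid)
        with pytest.raises(ValueError, match="grid"):
            cover_from_state(state, other)

    def test_cover_monotone_in_abundance(self, grid):
        rng = np.random.default_rng(0)
        n = rng.random(grid.n_mesh)
        state = PopulationState("HS", n, grid)
        base = cover_from_state(state, grid)
        for k in (0, grid.n_mesh // 2, grid.n_mesh - 1):
            bumped = n.copy()
            bumped[k] += 0.5
            assert cover_from_state(PopulationState("HS", bumped, grid),
                                    grid) >= base


class TestStateFromRecords:
    def test_census_density_round_trips(self, grid, small_dataset):
        """Binning first-year records onto the mesh preserves total density
        (individuals per m2 over the sampled plot area)."""
        from shrubipm.multispecies import state_from_records
        from shrubipm.synthetic_data import PLOT_AREA_CM2

        records, _, _ = small_dataset
        first = min(r.year for r in records)
        n_plots = len({r.plot_id for r in records if r.year == first})
        for sp in ("HS", "LS"):
            state = state_from_records(records, sp, grid)
            n_plants = sum(1 for r in records
                           if r.species == sp and r.year == first)
            expected = n_plants / (n_plots * PLOT_AREA_CM2 / 1e4)
            assert state.total_density == pytest.approx(expected)

    def test_no_records_rejected(self, grid):
        from shrubipm.multispecies import state_from_records

        with pytest.raises(ValueError, match="no records"):
            state_from_records([], "HS", grid)


class TestStepCoupled:
    def test_no_survival_no_recruits_means_extinction(self, grid, climate_pool):
        cfg = s.default_config()
        cfg.intercepts["HS"]["survival"] = -80.0
        cfg.intercepts["LS"]["survival"] = -80.0
        model_sets = {sp: s.model_set_from_config(cfg, sp) for sp in ("HS", "LS")}
        state = _coupled(grid)
        nxt = step_coupled(state, model_sets, climate_pool.years[0],
                           recruit_multiplier=0.0)
        assert nxt.hs.total_density == pytest.approx(0.0, abs=1e-12)
        assert nxt.ls.total_density == pytest.approx(0.0, abs=1e-12)

    def test_matches_manual_matrix_vector_product(self, grid, default_model_sets,
                                                  climate_pool):
        state = _coupled(grid)
        clim = climate_pool.years[2]
        nxt = step_coupled(state, default_model_sets, clim)
        for sp in ("HS", "LS"):
            kern = build_kernel(default_model_sets[sp], clim,
                                intra=state.cover(sp),
                                inter=state.cover("LS" if sp == "HS" else "HS"),
                                block="A", grid=grid)
            manual = kern.K @ state.state(sp).abundance
            assert np.array_equal(nxt.state(sp).abundance, manual)

    def test_two_bin_hand_computation(self, climate_pool):
        """On a 2-class mesh the projection is a hand-checkable 2x2 product."""
        grid2 = build_grid(math.log(0.5), math.log(400.0), 2)
        cfg = s.default_config(recruit_size_log_mean={"HS": 1.5, "LS": 1.5},
                               recruit_size_log_sd={"HS": 0.8, "LS": 0.8})
        ms = {sp: s.model_set_from_config(cfg, sp) for sp in ("HS", "LS")}
        state = CoupledState(
            hs=PopulationState("HS", np.array([3.0, 1.0]), grid2),
            ls=PopulationState("LS", np.array([0.5, 0.25]), grid2))
        clim = climate_pool.years[0]
        nxt = step_coupled(state, ms, clim)
        K = build_kernel(ms["HS"], clim, state.cover("HS"), state.cover("LS"),
                         "A", grid2).K
        by_hand = np.array([
            K[0, 0] * 3.0 + K[0, 1] * 1.0,
            K[1, 0] * 3.0 + K[1, 1] * 1.0,
        ])
        assert np.allclose(nxt.hs.abundance, by_hand, rtol=1e-15)

    def test_nonnegativity_preserved(self, grid, default_model_sets, climate_pool):
        state = _coupled(grid)
        for clim in climate_pool.years[:5]:
            state = step_coupled(state, default_model_sets, clim)
            assert np.all(state.hs.abundance >= 0)
            assert np.all(state.ls.abundance >= 0)


class TestDecoupling:
    def test_interaction_off_with_zero_inter_equals_independent_runs(self, grid,
                                                                     climate_pool):
        """With the feedback off and no interspecific coefficients, the
        coupled trajectory is bit-identical to projecting each species on
        its own."""
        model_sets = _strip_terms("inter")
        seq = list(climate_pool.years[:6])
        both = run_projection(_coupled(grid, interaction_on=False),
                              model_sets, seq)
        hs_alone = run_projection(_coupled(grid, ls=0.0, interaction_on=False),
                                  model_sets, seq)
        ls_alone = run_projection(_coupled(grid, hs=0.0, interaction_on=False),
                                  model_sets, seq)
        for t in range(len(seq) + 1):
            assert np.array_equal(both[t].hs.abundance, hs_alone[t].hs.abundance)
            assert np.array_equal(both[t].ls.abundance, ls_alone[t].ls.abundance)

    def test_interaction_flag_off_freezes_inter_covariate(self, grid,
                                                          default_model_sets,
                                                          climate_pool):
        state = _coupled(grid, interaction_on=False)
        baseline = state.baseline_inter["LS"]
        stepped = step_coupled(state, default_model_sets, climate_pool.years[0])
        assert stepped.inter_cover("LS") == baseline


class TestRunProjection:
    def test_fourteen_transitions_give_fifteen_states(self, grid,
                                                      default_model_sets,
                                                      climate_pool):
        seq = [climate_pool.years[i % len(climate_pool.years)] for i in range(14)]
        traj = run_projection(_coupled(grid), default_model_sets, seq)
        assert len(traj) == 15
        frame = trajectory_frame(traj)
        assert set(frame.columns) == {"year", "species", "total_density", "cover"}
        assert len(frame) == 30

    def test_zero_initial_abundance_stays_zero(self, grid, default_model_sets,
                                               climate_pool):
        traj = run_projection(_coupled(grid, hs=0.0, ls=0.0), default_model_sets,
                              list(climate_pool.years[:3]))
        assert all(t.hs.total_density == 0.0 and t.ls.total_density == 0.0
                   for t in traj)

    def test_density_independent_growth_follows_log_lambda(self, grid,
                                                           mean_climate):
        """Constant climate, no interaction terms: after a transient the log
        total density is affine in time with slope log lambda."""
        model_sets = _strip_terms("intra", "inter")
        kern = build_kernel(model_sets["HS"], mean_climate, 0.0, 0.0, "A", grid)
        lam = dominant_lambda(kern)
        seq = [mean_climate] * 60
        traj = run_projection(_coupled(grid, ls=0.0), model_sets, seq)
        dens = np.array([t.hs.total_density for t in traj])
        slopes = np.diff(np.log(dens[-5:]))
        assert np.allclose(slopes, math.log(lam), atol=1e-6)

    def test_mismatched_multiplier_length_rejected(self, grid, default_model_sets,
                                                   climate_pool):
        with pytest.raises(ValueError, match="length"):
            run_projection(_coupled(grid), default_model_sets,
                           list(climate_pool.years[:3]), recruit_multipliers=[1.0])


class TestDensityDependence:
    def test_negative_intra_fecundity_lowers_per_capita_growth(self, grid,
                                                               mean_climate):
        """With a negative intraspecific effect on fecundity, the one-year
        per-capita growth of a population declines as its density rises."""
        coefs = {sp: {r: {} for r in ("survival", "growth", "reproduction",
                                      "fecundity")} for sp in ("HS", "LS")}
        coefs["HS"]["fecundity"] = {"intra": -3.0}
        cfg = GeneratorConfig(coefficients=coefs)
        ms = {sp: s.model_set_from_config(cfg, sp) for sp in ("HS", "LS")}
        rates = []
        for dens in (2.0, 20.0):
            state = _coupled(grid, hs=dens, ls=0.0)
            nxt = step_coupled(state, ms, mean_climate)
            rates.append(nxt.hs.total_density / dens)
        assert rates[1] < rates[0]


class TestValidation:
    def test_negative_abundance_rejected(self, grid):
        with pytest.raises(ValueError):
            PopulationState("HS", np.full(grid.n_mesh, -1.0), grid)

    def test_nonfinite_step_reported_with_species(self, climate_pool):
        """Overflowing abundances raise a FloatingPointError naming the
        species rather than propagating silently."""
        from helpers import toy_model_set

        ms = toy_model_set(surv_p=0.5, repro_p=0.5, fec=1e30)
        grid2 = build_grid(-2.0, 3.0, 60)
        state = CoupledState(
            hs=initial_state_from_density("HS", 1.0, grid2, 0.5, 0.4),
            ls=initial_state_from_density("LS", 1.0, grid2, 0.5, 0.4))
        model_sets = {"HS": ms, "LS": ms}
        with pytest.raises(FloatingPointError, match="HS"):
            run_projection(state, model_sets, list(climate_pool.years)[:12])
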