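"""Grid construction, reaction/diffusion terms, integration and yields."""

import numpy as np
import pytest

from fibrolysis.model_core import (
    Conditions,
    KineticParams,
    MaterialGeometry,
    StateField,
    initial_state,
)
from fibrolysis.transport_solver import (
    build_grid,
    diffusion_terms,
    integrate,
    reaction_terms,
    simulate,
    total_mass,
    yields,
)


class TestGrid:
    def test_outer_radius_and_node_counts(self):
        geom = MaterialGeometry()
        grid = build_grid(geom)
        assert grid.n_total == 350
        assert grid.r[0] == 0.0
        assert grid.r[-1] == pytest.approx(3.75e-4 * 3.32)
        assert grid.r[grid.interface_index] == pytest.approx(geom.R_i)
        assert np.all(np.diff(grid.r) > 0)

    def test_annulus_to_disc_area_ratio(self):
        # hydrolysate annulus holds ~10x the fibre cross-section
        geom = MaterialGeometry()
        ratio = (geom.R_o**2 - geom.R_i**2) / geom.R_i**2
        assert ratio == pytest.approx(10.02, abs=0.01)

    def test_control_volumes_partition_the_domain(self):
        geom = MaterialGeometry(N=12, m=4, n_fibre=8, n_hydro=6)
        grid = build_grid(geom)
        assert grid.cv.sum() == pytest.approx(geom.R_o**2 / 2.0, rel=1e-12)
        # fibre-material measure is exactly the fibre cross-section
        fibre_measure = (grid.cv[: grid.n_fibre] * grid.fibre_fraction).sum()
        assert fibre_measure == pytest.approx(geom.R_i**2 / 2.0, rel=1e-12)
        assert grid.fibre_fraction[-1] < 1.0
        assert np.all(grid.fibre_fraction[:-1] == 1.0)

    def test_region_tags(self):
        geom = MaterialGeometry(N=12, m=4, n_fibre=8, n_hydro=6)
        grid = build_grid(geom)
        assert list(grid.region[:8]) == ["fibre"] * 8
        assert list(grid.region[8:]) == ["hydrolysate"] * 6


def _uniform_state(geom, chain, value):
    """State with one aqueous chain at a uniform concentration everywhere."""
    n_total = geom.n_fibre + geom.n_hydro
    state = StateField(
        furfural=np.zeros(n_total),
        aqueous=np.zeros((geom.m, n_total)),
        solid=np.zeros((geom.N - geom.m, geom.n_fibre)),
    )
    state.aqueous[chain - 1, :] = value
    return state


class TestReactionTerms:
    def setup_method(self):
        self.geom = MaterialGeometry(N=12, m=4, n_fibre=6, n_hydro=4)
        self.cond = Conditions(T=383.15, C_H=51.0)
        self.params = KineticParams(k_a=2e-4, k_b=3e-5, k_d=5e-7, alpha=0.0)

    def test_zero_state_gives_zero_rates(self):
        state = _uniform_state(self.geom, 2, 0.0)
        d_f, d_aq, d_sol = reaction_terms(state, self.params, self.cond, self.geom)
        assert not np.any(d_f) and not np.any(d_aq) and not np.any(d_sol)

    def test_dimer_scission_closed_form(self):
        """With only DP-2 chains present, d(phi_1)/dt = +k_b psi phi_2 and
        d(phi_2)/dt = -k_b psi phi_2 (2 Omega(1,1) = 1)."""
        state = _uniform_state(self.geom, 2, 10.0)
        d_f, d_aq, d_sol = reaction_terms(state, self.params, self.cond, self.geom)
        eps_v = 1.0 - self.geom.F_hat  # no solid left
        psi = np.full(state.n_total, self.cond.C_H)
        psi[: self.geom.n_fibre] = eps_v * self.cond.C_H
        np.testing.assert_allclose(d_aq[0], self.params.k_b * psi * 10.0, rtol=1e-12)
        np.testing.assert_allclose(d_aq[1], -self.params.k_b * psi * 10.0, rtol=1e-12)
        assert not np.any(d_aq[2:]) and not np.any(d_f) and not np.any(d_sol)

    def test_pointwise_mass_balance(self):
        """Scission and degradation only move mass between species: the
        summed rate is zero at every node."""
        rng = np.random.default_rng(7)
        geom = self.geom
        n_total = geom.n_fibre + geom.n_hydro
        state = StateField(
            furfural=rng.uniform(0, 5, n_total),
            aqueous=rng.uniform(0, 20, (geom.m, n_total)),
            solid=rng.uniform(0, 30, (geom.N - geom.m, geom.n_fibre)),
        )
        d_f, d_aq, d_sol = reaction_terms(state, self.params, self.cond, geom)
        total = d_f + d_aq.sum(axis=0)
        total[: geom.n_fibre] += d_sol.sum(axis=0)
        np.testing.assert_allclose(total, 0.0, atol=1e-12 * 30 * 51 * 2e-4)


class TestDiffusionTerms:
    def setup_method(self):
        self.geom = MaterialGeometry(N=12, m=4, n_fibre=8, n_hydro=6)
        self.cond = Conditions(T=383.15)
        self.grid = build_grid(self.geom)

    def test_uniform_concentration_no_flux(self):
        state = _uniform_state(self.geom, 2, 7.0)
        d_f, d_aq = diffusion_terms(state, self.cond, self.grid, self.geom)
        np.testing.assert_allclose(d_aq, 0.0, atol=1e-20)
        np.testing.assert_allclose(d_f, 0.0, atol=1e-20)

    def test_diffusion_conserves_each_species(self):
        rng = np.random.default_rng(11)
        n_total = self.grid.n_total
        state = StateField(
            furfural=rng.uniform(0, 5, n_total),
            aqueous=rng.uniform(0, 20, (self.geom.m, n_total)),
            solid=rng.uniform(0, 30, (self.geom.N - self.geom.m, self.geom.n_fibre)),
        )
        d_f, d_aq = diffusion_terms(state, self.cond, self.grid, self.geom)
        assert d_f @ self.grid.cv == pytest.approx(0.0, abs=1e-16)
        np.testing.assert_allclose(d_aq @ self.grid.cv, 0.0, atol=1e-16)

    def test_flux_runs_down_the_gradient(self):
        """Fibre loaded, hydrolysate empty: hydrolysate gains mass."""
        state = _uniform_state(self.geom, 1, 0.0)
        state.aqueous[0, : self.geom.n_fibre] = 50.0
        _, d_aq = diffusion_terms(state, self.cond, self.grid, self.geom)
        hydro = d_aq[0, self.geom.n_fibre :]
        assert hydro @ self.grid.cv[self.geom.n_fibre :] > 0


class TestIntegration:
    def test_zero_rates_keep_state_constant(self, small_geom):
        cond = Conditions(
            T=383.15, t_end=600.0, output_times=np.linspace(0, 600, 4)
        )
        params = KineticParams(k_a=0.0, k_b=0.0, k_d=0.0, alpha=0.2)
        grid = build_grid(small_geom)
        state0 = initial_state(
            small_geom, cond, params, fibre_fraction=grid.fibre_fraction
        )
        # no diffusion either: the only mobile-species gradients are zero
        traj = integrate(state0, params, cond, grid, small_geom)
        np.testing.assert_allclose(
            traj.states[-1].to_vector(), state0.to_vector(), atol=1e-8
        )

    def test_mass_conservation_along_trajectory(self, small_trajectory):
        geom, cond, params, traj = small_trajectory
        masses = [total_mass(s, traj.grid, geom, params) for s in traj.states]
        np.testing.assert_allclose(masses, masses[0], rtol=1e-7)

    def test_monotone_species_totals(self, small_trajectory):
        """Solid xylan only dissolves; furfural only accumulates."""
        geom, cond, params, traj = small_trajectory
        cv_f = traj.grid.cv[: traj.grid.n_fibre]
        solid = np.array([s.solid.sum(axis=0) @ cv_f for s in traj.states])
        furf = np.array([s.furfural @ traj.grid.cv for s in traj.states])
        assert np.all(np.diff(solid) <= 1e-12 * solid[0])
        assert np.all(np.diff(furf) >= -1e-16)

    def test_porosity_monotone_within_bounds(self, small_trajectory):
        geom, cond, params, traj = small_trajectory
        from fibrolysis.model_core import porosity

        interior = slice(0, traj.grid.n_fibre - 1)  # interface vertex is mixed
        eps_floor = geom.initial_porosity
        eps_ceil = 1.0 - geom.F_hat - params.alpha * geom.eps_N0
        previous = None
        for state in traj.states:
            eps = porosity(state.solid[:, interior], geom, params.alpha)
            assert np.all(eps >= eps_floor - 1e-9)
            assert np.all(eps <= eps_ceil + 1e-9)
            if previous is not None:
                assert np.all(eps >= previous - 1e-9)
            previous = eps

    def test_output_time_subset_consistency(self, small_geom):
        """Reporting times only sample the solution; they do not change it."""
        params = KineticParams(k_a=2e-4, k_b=2e-5, k_d=1e-8, alpha=0.1)
        t_end = 60 * 60.0
        dense = Conditions(T=383.15, t_end=t_end, output_times=np.linspace(0, t_end, 13))
        sparse = Conditions(T=383.15, t_end=t_end, output_times=np.linspace(0, t_end, 4))
        traj_dense = simulate(small_geom, dense, params)
        traj_sparse = simulate(small_geom, sparse, params)
        for t, state in zip(traj_sparse.times, traj_sparse.states):
            j = np.argmin(np.abs(traj_dense.times - t))
            np.testing.assert_allclose(
                state.to_vector(), traj_dense.states[j].to_vector(),
                rtol=1e-6, atol=1e-8,
            )


class TestYields:
    def test_initial_yields_are_zero(self, small_trajectory):
        geom, cond, params, traj = small_trajectory
        series = yields(traj, geom, params)
        for label, values in series.yields.items():
            assert values[0] == pytest.approx(0.0, abs=1e-12)

    def test_aqueous_yields_bounded_by_reactive_fraction(self, small_trajectory):
        geom, cond, params, traj = small_trajectory
        series = yields(traj, geom, params)
        total = sum(series.yields.values())
        assert np.all(total <= 100.0 * (1 - params.alpha) + 1e-6)

    def test_complete_scission_approaches_hydrolysate_partition(self):
        """k_d = 0, alpha = 0, long horizon: everything ends as xylose.
        Diffusion acts on the volume-averaged concentration, so the closed
        system equilibrates to uniform phi and the hydrolysate's share is
        its share of the cross-section measure (~91% at this geometry)."""
        geom = MaterialGeometry(N=12, m=4, n_fibre=6, n_hydro=8)
        t_end = 3000 * 60.0
        cond = Conditions(
            T=383.15, t_end=t_end, output_times=np.linspace(0, t_end, 13)
        )
        params = KineticParams(k_a=5e-4, k_b=5e-4, k_d=0.0, alpha=0.0)
        traj = simulate(geom, cond, params)
        series = yields(traj, geom, params)
        grid = traj.grid
        partition = 100.0 * grid.cv[grid.n_fibre :].sum() / grid.cv.sum()
        assert series.yields["X1"][-1] == pytest.approx(partition, abs=0.5)
        # every other species is extinct
        others = sum(
            v[-1] for k, v in series.yields.items() if k != "X1"
        )
        assert others < 0.1

    def test_solid_remnant_accounts_for_unreactive_fraction(self, small_trajectory):
        geom, cond, params, traj = small_trajectory
        series = yields(traj, geom, params, include_solid=True)
        assert series.yields["solid"][0] == pytest.approx(100.0, abs=1e-9)
        assert series.yields["solid"][-1] >= 100.0 * params.alpha - 1e-9
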