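"""Kinetic module: Maxwellian closure, moment round-trips, the stationary
BGK solver's limits, entropy profiles and the H-theorem along uniform
relaxation — each against an independent quadrature, refinement or ODE
oracle."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from entroage import (
    ConvergenceError,
    DegenerateStateError,
    DomainError,
    EntropyProfile,
    KineticState,
    MacroMoments,
    ParameterError,
    PhaseGrid,
    StructuralState,
    entropy_age_delta,
    equilibrium_entropy_profile,
    local_entropy_profile,
    maxwellian,
    moments_of,
    relax_uniform,
    solve_stationary_bgk,
    stationary_residual,
)
from conftest import random_mixture_state


def tile_state(grid, f_xi, tau=1.0):
    return KineticState(grid, np.tile(f_xi, (len(grid.x_nodes), 1)), tau)


class TestPhaseGrid:
    def test_regular_grid_invariants(self, grid):
        assert grid.x_nodes[0] == 0.0
        assert grid.L == 1.0
        assert not np.any(grid.xi_nodes == 0.0)
        assert grid.xi_weights.sum() == pytest.approx(2 * grid.xi_max, abs=1e-9)

    def test_odd_velocity_count_rejected(self):
        with pytest.raises(ParameterError):
            PhaseGrid.regular(nxi=31)

    def test_explicit_zero_node_rejected(self):
        with pytest.raises(ParameterError):
            PhaseGrid(x_nodes=[0.0, 1.0], xi_nodes=[-1.0, 0.0, 1.0],
                      xi_weights=[1.0, 1.0, 1.0])


class TestMaxwellian:
    def test_symmetric_at_zero_drift(self, grid):
        f = maxwellian(MacroMoments(1.0, 0.0, 1.0), grid)
        np.testing.assert_array_equal(f, f[::-1])

    def test_linear_in_density(self, grid):
        f1 = maxwellian(MacroMoments(1.0, 0.3, 0.8), grid)
        f2 = maxwellian(MacroMoments(2.0, 0.3, 0.8), grid)
        np.testing.assert_allclose(f2 / f1, 2.0, rtol=1e-14)

    def test_quadrature_recovers_density(self, grid):
        # xi grid spans +-8 sqrt(theta) at theta = 1
        f = maxwellian(MacroMoments(1.7, 0.4, 1.0), grid)
        assert f @ grid.xi_weights == pytest.approx(1.7, abs=1e-6)

    def test_invalid_moments_rejected(self):
        with pytest.raises(ParameterError):
            MacroMoments(0.0, 0.0, 1.0)
        with pytest.raises(ParameterError):
            MacroMoments(1.0, 0.0, -1.0)


class TestMoments:
    def test_round_trip(self, grid):
        state = tile_state(grid, maxwellian(MacroMoments(1.3, 0.2, 0.7), grid))
        m = moments_of(state)
        assert m.rho[0] == pytest.approx(1.3, abs=1e-6)
        assert m.u[0] == pytest.approx(0.2, abs=1e-6)
        assert m.theta[0] == pytest.approx(0.7, abs=1e-6)

    def test_doubling_scales_density_only(self, grid):
        f = maxwellian(MacroMoments(1.0, 0.5, 0.9), grid)
        m1 = moments_of(tile_state(grid, f))
        m2 = moments_of(tile_state(grid, 2 * f))
        np.testing.assert_allclose(m2.rho, 2 * m1.rho, rtol=1e-12)
        np.testing.assert_allclose(m2.u, m1.u, atol=1e-12)
        np.testing.assert_allclose(m2.theta, m1.theta, rtol=1e-12)

    def test_velocity_mirror_negates_u(self, grid):
        f = maxwellian(MacroMoments(1.0, 0.5, 0.9), grid)
        m1 = moments_of(tile_state(grid, f))
        m2 = moments_of(tile_state(grid, f[::-1]))  # GL nodes are symmetric
        np.testing.assert_allclose(m2.u, -m1.u, atol=1e-12)
        np.testing.assert_allclose(m2.rho, m1.rho, rtol=1e-12)
        np.testing.assert_allclose(m2.theta, m1.theta, rtol=1e-10)

    def test_zero_density_names_node(self, grid):
        values = np.tile(
            maxwellian(MacroMoments(1.0, 0.0, 1.0), grid),
            (len(grid.x_nodes), 1))
        values[4] = 0.0
        with pytest.raises(DegenerateStateError) as err:
            moments_of(KineticState(grid, values, 1.0))
        assert err.value.node == 4


class TestStationarySolver:
    def test_global_equilibrium_is_fixed_point(self, grid):
        m = MacroMoments(1.0, 0.0, 1.0)
        state = solve_stationary_bgk(m, m, tau=0.1, grid=grid, tol=1e-8)
        fM = maxwellian(m, grid)
        assert np.max(np.abs(state.values - fM[None, :])) < 1e-8

    def test_collisionless_limit_free_streams(self, grid):
        left = MacroMoments(1.0, 0.0, 1.0)
        right = MacroMoments(1.0, 0.0, 0.5)
        tau = 1e6 * grid.L / grid.xi_max
        state = solve_stationary_bgk(left, right, tau=tau, grid=grid)
        f_left = maxwellian(left, grid)
        f_right = maxwellian(right, grid)
        pos = grid.xi_nodes > 0
        assert np.max(np.abs(state.values[:, pos] - f_left[pos][None, :])) < 1e-3
        assert np.max(np.abs(state.values[:, ~pos] - f_right[~pos][None, :])) < 1e-3

    def test_grid_refinement_consistency(self):
        """First-order upwind profile converges with the mesh: the coarse
        solution tracks a 4x-refined reference."""
        left = MacroMoments(1.0, 0.0, 1.0)
        right = MacroMoments(1.0, 0.0, 0.5)
        coarse = PhaseGrid.regular(nx=17, nxi=32)
        fine = PhaseGrid.regular(nx=65, nxi=32)
        sc = solve_stationary_bgk(left, right, tau=0.1, grid=coarse)
        sf = solve_stationary_bgk(left, right, tau=0.1, grid=fine)
        rho_c = moments_of(sc).rho
        rho_f = np.interp(coarse.x_nodes, fine.x_nodes, moments_of(sf).rho)
        assert np.max(np.abs(rho_c - rho_f)) < 0.05

    def test_discrete_residual_below_tolerance(self, grid):
        state = solve_stationary_bgk(
            MacroMoments(1.0, 0.0, 1.0), MacroMoments(1.0, 0.0, 0.5),
            tau=0.1, grid=grid, tol=1e-8)
        assert stationary_residual(state) < 1e-5
        assert state.info["residual"] < 1e-8
        assert state.info["iterations"] >= 1

    def test_nonconvergence_carries_history(self, grid):
        with pytest.raises(ConvergenceError) as err:
            solve_stationary_bgk(
                MacroMoments(1.0, 0.0, 1.0), MacroMoments(1.0, 0.0, 0.5),
                tau=0.1, grid=grid, tol=1e-12, max_iter=3)
        assert len(err.value.residual_history) == 3


class TestEntropyProfiles:
    def test_unit_plateau_has_zero_entropy(self):
        grid = PhaseGrid.regular(nx=5, nxi=8, xi_max=1.0)  # interval length 2
        state = tile_state(grid, np.ones(8))
        np.testing.assert_allclose(local_entropy_profile(state).S, 0.0,
                                   atol=1e-14)

    def test_maxwellian_entropy_matches_fine_quadrature(self, grid):
        rho, u, theta = 1.3, 0.2, 0.7
        state = tile_state(grid, maxwellian(MacroMoments(rho, u, theta), grid))
        S = local_entropy_profile(state).S[0]

        def integrand(xi):
            f = rho / math.sqrt(2 * math.pi * theta) * math.exp(
                -((xi - u) ** 2) / (2 * theta))
            return -f * math.log(f) if f > 0 else 0.0

        oracle, _ = quad(integrand, -grid.xi_max, grid.xi_max, limit=200)
        assert S == pytest.approx(oracle, abs=1e-8)

    def test_scaling_matches_direct_summation(self, grid):
        f = maxwellian(MacroMoments(1.0, 0.0, 1.0), grid)
        c = 1.7
        state = tile_state(grid, c * f)
        direct = -sum(
            w * v * math.log(v)
            for w, v in zip(grid.xi_weights, c * f) if v > 0)
        assert local_entropy_profile(state).S[0] == pytest.approx(direct,
                                                                  rel=1e-12)

    def test_equilibrium_entropy_fixed_point(self, grid):
        state = tile_state(grid, maxwellian(MacroMoments(1.0, 0.0, 1.0), grid))
        S = local_entropy_profile(state).S
        S_eq = equilibrium_entropy_profile(state).S
        np.testing.assert_allclose(S_eq, S, atol=1e-9)

    def test_bimodal_state_strictly_below_equilibrium(self, grid):
        f = (maxwellian(MacroMoments(0.5, -2.0, 0.5), grid)
             + maxwellian(MacroMoments(0.5, 2.0, 0.5), grid))
        state = tile_state(grid, f)
        gap = equilibrium_entropy_profile(state).S - local_entropy_profile(state).S
        assert np.all(gap > 0)

    def test_random_states_never_exceed_equilibrium(self, fine_grid):
        rng = np.random.default_rng(5)
        for _ in range(30):
            state = random_mixture_state(fine_grid, rng)
            gap = (equilibrium_entropy_profile(state).S
                   - local_entropy_profile(state).S)
            assert np.min(gap) >= -1e-8


class TestEntropyAgeDelta:
    def test_identical_profiles_give_zero(self):
        x = np.linspace(0, 1, 20)
        prof = EntropyProfile(x_nodes=x, S=np.sin(x), L=1.0)
        assert entropy_age_delta(prof, prof, 1.0) == 0.0

    def test_constant_difference_integrates_to_c_L(self):
        x = np.linspace(0, 2, 40)
        young = EntropyProfile(x_nodes=x, S=np.cos(x), L=2.0)
        old = EntropyProfile(x_nodes=x, S=np.cos(x) + 0.3, L=2.0)
        assert entropy_age_delta(old, young, 1.5) == pytest.approx(0.3 * 1.5,
                                                                   abs=1e-12)

    def test_piecewise_linear_matches_riemann_oracle(self):
        rng = np.random.default_rng(9)
        x_old = np.sort(rng.uniform(0, 1, 15))
        x_old[0], x_old[-1] = 0.0, 1.0
        x_young = np.sort(rng.uniform(0, 1, 23))
        x_young[0], x_young[-1] = 0.0, 1.0
        old = EntropyProfile(x_nodes=x_old, S=rng.uniform(0, 2, 15), L=1.0)
        young = EntropyProfile(x_nodes=x_young, S=rng.uniform(0, 2, 23), L=1.0)
        L_old = 0.85

        xs = np.linspace(0, L_old, 100_001)
        diff = (np.interp(xs, old.x_nodes, old.S)
                - np.interp(xs, young.x_nodes, young.S))
        oracle = float(np.sum(0.5 * (diff[1:] + diff[:-1]) * np.diff(xs)))

        assert entropy_age_delta(old, young, L_old) == pytest.approx(oracle,
                                                                     abs=1e-6)

    def test_antisymmetric_under_swap(self):
        x = np.linspace(0, 1, 30)
        a = EntropyProfile(x_nodes=x, S=x**2, L=1.0)
        b = EntropyProfile(x_nodes=x, S=np.sqrt(x), L=1.0)
        assert entropy_age_delta(a, b, 1.0) == pytest.approx(
            -entropy_age_delta(b, a, 1.0), abs=1e-12)

    def test_domain_exceeding_support_rejected(self):
        x = np.linspace(0, 0.5, 10)
        short = EntropyProfile(x_nodes=x, S=np.ones(10), L=0.5)
        full = EntropyProfile(x_nodes=np.linspace(0, 1, 10), S=np.ones(10), L=1.0)
        with pytest.raises(DomainError):
            entropy_age_delta(full, short, 0.9)


class TestUniformRelaxation:
    def test_initial_and_asymptotic_states(self, fine_grid):
        rng = np.random.default_rng(2)
        f0 = random_mixture_state(fine_grid, rng)
        T = 0.6
        states = relax_uniform(f0, T, [0.0, 1e6 * T])
        np.testing.assert_array_equal(states[0].values, f0.values)
        fM = maxwellian(moments_of(f0), fine_grid)
        assert np.max(np.abs(states[1].values - fM)) < 1e-9

    def test_matches_independent_ode_integration(self, fine_grid):
        rng = np.random.default_rng(4)
        f0 = random_mixture_state(fine_grid, rng)
        T = 0.5
        times = [0.1, 0.4, 0.9, 1.7, 3.0]
        states = relax_uniform(f0, T, times)
        fM = maxwellian(moments_of(f0), fine_grid)
        y0 = f0.values.ravel()
        sol = solve_ivp(
            lambda t, y: (fM.ravel() - y) / T, (0.0, times[-1]), y0,
            t_eval=times, rtol=1e-11, atol=1e-12)
        for k, state in enumerate(states):
            assert np.max(np.abs(state.values.ravel() - sol.y[:, k])) < 1e-8

    def test_moments_conserved_along_trajectory(self, fine_grid):
        rng = np.random.default_rng(6)
        f0 = random_mixture_state(fine_grid, rng)
        m0 = moments_of(f0)
        for state in relax_uniform(f0, 1.0, np.linspace(0, 5, 8)):
            m = moments_of(state)
            assert np.max(np.abs(m.rho - m0.rho)) < 1e-9
            assert np.max(np.abs(m.u - m0.u)) < 1e-9
            assert np.max(np.abs(m.theta - m0.theta)) < 1e-9

    def test_entropy_nondecreasing_h_theorem(self, fine_grid):
        rng = np.random.default_rng(8)
        for _ in range(20):
            f0 = random_mixture_state(fine_grid, rng)
            states = relax_uniform(f0, 0.8, np.linspace(0, 6, 12))
            S = np.array([local_entropy_profile(s).S for s in states])
            assert np.min(np.diff(S, axis=0)) > -1e-9

    def test_negative_time_rejected(self, fine_grid):
        rng = np.random.default_rng(1)
        f0 = random_mixture_state(fine_grid, rng)
        with pytest.raises(ParameterError):
            relax_uniform(f0, 1.0, [-0.1, 0.5])


class TestStructuralState:
    def test_binwise_relaxation_approaches_equilibrium(self):
        rng = np.random.default_rng(12)
        f = rng.uniform(0.1, 1.0, size=(3, 4, 5))
        feq = rng.uniform(0.1, 1.0, size=(3, 4, 5))
        state = StructuralState(values=f, equilibrium=feq, timescale=2.0)
        early, late = state.relax([0.0, 100.0])
        np.testing.assert_allclose(early, f)
        np.testing.assert_allclose(late, feq, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(Exception):
            StructuralState(values=np.ones((2, 2)), equilibrium=np.ones(3),
                            timescale=1.0)
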