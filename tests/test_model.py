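"""Benthic-cover dynamics: derivatives, integration, regimes, calibration."""

import logging

import numpy as np
import pytest

import reefnet as rn
from reefnet.model import CalibrationResult


def single_reef_params(g, d, a=0.1, r=1.0, gamma=0.8, k=1.0, n=1.0):
    return rn.SystemParams(g=[g], d=[d], a=a, r=r, gamma=gamma, K=[[k]], N=[[n]])


class TestDerivatives:
    def test_bare_state_is_fixed_point(self, random_system):
        params, _ = random_system(0)
        dM, dC = rn.derivatives(rn.StateVector(np.zeros(5), np.zeros(5)), params)
        assert np.all(dM == 0.0) and np.all(dC == 0.0)

    def test_cover_closure_rate_sums_to_zero(self, random_system):
        params, state = random_system(1)
        dM, dC = rn.derivatives(state, params)
        dF = -dM - dC  # F eliminated algebraically, so this holds identically
        np.testing.assert_allclose(dM + dC + dF, 0.0, atol=1e-16)

    def test_single_reef_term_by_term(self):
        # independent arithmetic oracle: evaluate every term separately
        a, g, d, r, gamma = 0.1, 0.3, 0.05, 1.0, 0.8
        M, C = 0.2, 0.3
        F = 1.0 - M - C
        exp_dM = a * M * C - g * M / (M + F) + gamma * 1.0 * F * M
        exp_dC = r * 1.0 * F * C - a * M * C - d * C
        assert exp_dM == pytest.approx(0.0002857142857143058, abs=1e-15)
        assert exp_dC == pytest.approx(0.129, abs=1e-15)
        params = single_reef_params(g, d, a=a, r=r, gamma=gamma)
        dM, dC = rn.derivatives(rn.StateVector([M], [C]), params)
        assert dM[0] == pytest.approx(exp_dM, abs=1e-15)
        assert dC[0] == pytest.approx(exp_dC, abs=1e-15)

    def test_grazing_singularity_at_full_coral(self):
        params = single_reef_params(0.5, 0.1)
        dM, dC = rn.derivatives(rn.StateVector([0.0], [1.0]), params)
        assert np.isfinite(dM[0]) and np.isfinite(dC[0])
        assert dM[0] == 0.0  # no macroalgae, no free space: nothing to graze

    def test_dimension_mismatch(self, random_system):
        params, _ = random_system(0)
        with pytest.raises(ValueError):
            rn.derivatives(rn.StateVector([0.1], [0.1]), params)


class TestIntegrate:
    def test_bare_state_stays_bare(self, random_system):
        params, _ = random_system(2)
        traj = rn.integrate(rn.StateVector(np.zeros(5), np.zeros(5)), params, t_end=100)
        assert np.all(traj.final.M == 0.0) and np.all(traj.final.C == 0.0)

    def test_exchange_symmetry_of_identical_reefs(self):
        # two identical reefs, symmetric coupling, identical ICs
        K = N = np.array([[0.6, 0.2], [0.2, 0.6]])
        params = rn.SystemParams([0.3, 0.3], [0.44, 0.44], 0.1, 1.0, 0.8, K, N)
        traj = rn.integrate(rn.StateVector([0.2, 0.2], [0.3, 0.3]), params, t_end=500,
                            save_every=10)
        np.testing.assert_allclose(traj.M[:, 0], traj.M[:, 1], atol=1e-12)
        np.testing.assert_allclose(traj.C[:, 0], traj.C[:, 1], atol=1e-12)

    def test_adaptive_matches_fixed_step_rk4(self, random_system):
        params, state = random_system(11)
        t_end, dt = 100.0, 0.01
        y = np.concatenate([state.M, state.C])
        n = state.n_reefs

        def f(y):  # independent right-hand side for the oracle
            M, C = y[:n], y[n:]
            F = 1.0 - M - C
            graze = np.zeros(n)
            mask = (M + F) > 1e-12
            graze[mask] = params.g[mask] * M[mask] / (M + F)[mask]
            dM = params.a * M * C - graze + params.gamma * (params.N @ M) * F
            dC = params.r * (params.K @ C) * F - params.a * M * C - params.d * C
            return np.concatenate([dM, dC])

        for _ in range(int(round(t_end / dt))):
            k1 = f(y)
            k2 = f(y + dt / 2 * k1)
            k3 = f(y + dt / 2 * k2)
            k4 = f(y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

        traj = rn.integrate(state, params, t_end=t_end, save_every=t_end)
        adaptive = np.concatenate([traj.final.M, traj.final.C])
        assert np.max(np.abs(adaptive - y)) < 1e-4

    def test_simplex_conservation_and_bounds(self, random_system):
        params, state = random_system(4)
        traj = rn.integrate(state, params, t_end=2000, save_every=20)
        closure = traj.M + traj.C + traj.F - 1.0
        assert np.max(np.abs(closure)) < 1e-9
        assert np.all(traj.M >= -1e-9) and np.all(traj.M <= 1 + 1e-9)
        assert np.all(traj.C >= -1e-9) and np.all(traj.C <= 1 + 1e-9)

    def test_diagonal_connectivity_decouples_reefs(self, random_system):
        params, state = random_system(5)
        Kd = np.diag(np.diag(params.K))
        Nd = np.diag(np.diag(params.N))
        net = rn.SystemParams(params.g, params.d, params.a, params.r, params.gamma, Kd, Nd)
        traj = rn.integrate(state, net, t_end=500, save_every=10,
                            rtol=1e-10, atol=1e-12)
        for i in range(state.n_reefs):
            solo = rn.SystemParams([params.g[i]], [params.d[i]], params.a,
                                   params.r, params.gamma,
                                   [[Kd[i, i]]], [[Nd[i, i]]])
            ti = rn.integrate(rn.StateVector([state.M[i]], [state.C[i]]), solo,
                              t_end=500, save_every=10, rtol=1e-10, atol=1e-12)
            assert np.max(np.abs(ti.M[:, 0] - traj.M[:, i])) < 1e-8
            assert np.max(np.abs(ti.C[:, 0] - traj.C[:, i])) < 1e-8

    def test_invalid_inputs(self, random_system):
        params, state = random_system(0)
        with pytest.raises(ValueError):
            rn.integrate(state, params, t_end=-1)
        with pytest.raises(ValueError):
            rn.integrate(rn.StateVector([0.8], [0.8]), params)  # M+C>1 and mismatch


class TestEquilibrium:
    def test_bare_fixed_point_is_equilibrium(self, random_system):
        params, _ = random_system(6)
        traj = rn.integrate(rn.StateVector(np.zeros(5), np.zeros(5)), params, t_end=10)
        assert rn.check_equilibrium(traj)

    def test_truncated_run_is_not(self, random_system, caplog):
        params, state = random_system(7)
        traj = rn.integrate(state, params, t_end=1.0, save_every=1.0)
        dM, dC = rn.derivatives(traj.final, params)
        assert np.max(np.abs(np.concatenate([dM, dC]))) >= 1e-8
        with caplog.at_level(logging.WARNING):
            assert not rn.check_equilibrium(traj)
        assert "not at equilibrium" in caplog.text

    def test_infinite_tolerance_vacuous(self, random_system):
        params, state = random_system(8)
        traj = rn.integrate(state, params, t_end=1.0)
        assert rn.check_equilibrium(traj, tol=np.inf)


class TestIsolatedReefRegime:
    def test_scenario_medians_hit_the_three_regions(self):
        labels = [rn.isolated_reef_regime(g, d=0.44) for g in (0.1, 0.3, 0.5)]
        assert labels == ["macroalgal", "bistable", "coral"]

    def test_ungrazed_undying_reef_goes_macroalgal(self):
        assert rn.isolated_reef_regime(g=0.0, d=0.0) == "macroalgal"

    def test_very_high_grazing_is_coral(self):
        assert rn.isolated_reef_regime(g=5.0, d=0.44) == "coral"

    def test_regime_bands_ordered_with_two_transitions(self):
        grid = np.arange(0.05, 1.01, 0.05)
        labels = [rn.isolated_reef_regime(g, d=0.44, t_end=20000) for g in grid]
        # collapse consecutive duplicates: must be exactly M -> B -> C
        blocks = [labels[0]]
        for lab in labels[1:]:
            if lab != blocks[-1]:
                blocks.append(lab)
        assert blocks == ["macroalgal", "bistable", "coral"]

    def test_rejects_vector_input(self):
        with pytest.raises(ValueError):
            rn.isolated_reef_regime(np.array([0.1, 0.2]), 0.4)


class TestCalibration:
    def test_default_mortality_lies_in_feasible_window(self):
        cal = rn.calibrate_globals(d_grid=np.arange(0.30, 0.61, 0.02), t_end=3000)
        assert isinstance(cal, CalibrationResult)
        lo, hi = cal.d_feasible
        assert lo <= 0.44 <= hi
        assert lo <= cal.d_med <= hi

    def test_unreachable_target_raises(self):
        with pytest.raises(RuntimeError):
            rn.calibrate_globals(d_grid=[5.0], t_end=500)
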