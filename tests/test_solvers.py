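import numpy as np
import pytest

from phagedyn import (
    BurstProfile,
    SimulationGrid,
    Trajectory,
    build_distribution,
    curve_error,
    discretize_density,
    normalize_beta_max,
    run_with_convergence,
    simulate_dde,
    simulate_ddde,
    simulate_tc,
    tc_config_from_distribution,
)
from phagedyn.distributions import DiscretizedKernel
from phagedyn.montecarlo import ParameterRanges, sample_parameter_set


def rel_max_err(a, b):
    return np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-300))


class TestFixedDelayOracles:
    def test_logistic_closed_form(self, params):
        """Without phage and without decay, U follows the exact logistic curve."""
        p = params.with_(P_init=0.0, delta_U=0.0)
        grid = SimulationGrid(24.0, 2e-4)
        traj = simulate_dde(p, 1.0, grid)
        t = grid.times
        exact = p.K_C * p.U_init * np.exp(p.r_max * t) / (
            p.K_C + p.U_init * (np.exp(p.r_max * t) - 1.0)
        )
        assert rel_max_err(traj.U, exact) < 1e-3
        # RK4 nails it already at a coarse step
        traj4 = simulate_dde(p, 1.0, SimulationGrid(24.0, 1e-2), stepper="rk4")
        t4 = traj4.times
        exact4 = p.K_C * p.U_init * np.exp(p.r_max * t4) / (
            p.K_C + p.U_init * (np.exp(p.r_max * t4) - 1.0)
        )
        assert rel_max_err(traj4.U, exact4) < 1e-6

    def test_pure_phage_decay_without_hosts(self, params):
        p = params.with_(U_init=0.0)
        grid = SimulationGrid(24.0, 1e-3)
        traj = simulate_dde(p, 1.0, grid)
        exact = p.P_init * np.exp(-p.delta_P * grid.times)
        assert rel_max_err(traj.P, exact) < 1e-3
        assert np.all(traj.U == 0.0)
        assert np.all(traj.I == 0.0)

    def test_steady_state_with_decay(self, params):
        p = params.with_(P_init=0.0, delta_U=0.2)
        traj = simulate_dde(p, 1.0, SimulationGrid(96.0, 1e-2))
        expected = p.K_C * (1.0 - p.delta_U / p.r_max)
        assert traj.U[-1] == pytest.approx(expected, rel=1e-4)


class TestDeltaKernelEquivalence:
    def test_point_mass_kernel_matches_fixed_delay(self, rng):
        """A point-mass latent kernel collapses the distributed model onto the
        classic fixed-delay model, for random parameter draws."""
        ranges = ParameterRanges.default()
        n_checked = 0
        while n_checked < 20:
            draw = sample_parameter_set(ranges, rng)
            p = draw.kinetics
            tau = round(draw.tau_0 / 0.005) * 0.005
            if tau == 0.0:
                continue
            grid = SimulationGrid(12.0, 0.005)
            kernel = discretize_density(
                build_distribution("point-mass", tau, 0.0, 0.0), grid.dt
            )
            burst = BurstProfile("constant", p.beta_0_mean)
            t1 = simulate_ddde(p, kernel, burst, grid)
            t2 = simulate_dde(p, tau, grid)
            for s in ("U", "I", "P"):
                a, b = getattr(t1, s), getattr(t2, s)
                assert np.allclose(a, b, rtol=1e-6, atol=1e-300)
            n_checked += 1

    def test_no_phage_logistic_identical_across_solvers(self, params):
        p = params.with_(P_init=0.0)
        grid = SimulationGrid(24.0, 0.005)
        dist = build_distribution("gamma", 1.0, 0.3, 0.0)
        kernel = discretize_density(dist, grid.dt)
        burst = BurstProfile("constant", p.beta_0_mean)
        t_dde = simulate_dde(p, 1.0, grid)
        t_ddde = simulate_ddde(p, kernel, burst, grid)
        t_tc = simulate_tc(p, tc_config_from_distribution(1.0, 0.3), grid)
        assert np.allclose(t_ddde.U, t_dde.U, rtol=1e-12)
        assert np.allclose(t_tc.U, t_dde.U, rtol=1e-12)


def _two_delay_oracle(p, grid, tau_a, tau_b, beta):
    """Hand-built Euler integrator with two discrete delays, half weight each."""
    n = grid.n_steps
    dt = grid.dt
    U = np.zeros(n + 1)
    I = np.zeros(n + 1)
    P = np.zeros(n + 1)
    H = np.zeros(n + 1)
    U[0], P[0] = p.U_init, p.P_init
    ka, kb = round(tau_a / dt), round(tau_b / dt)
    sa, sb = np.exp(-p.delta_I * ka * dt), np.exp(-p.delta_I * kb * dt)
    for i in range(n):
        phi = p.phi_max * p.P_50 / (p.P_50 + P[i])
        H[i] = phi * U[i] * P[i]
        out = 0.0
        src = 0.0
        if i >= ka:
            out += 0.5 * sa * H[i - ka]
            src += 0.5 * beta * sa * H[i - ka]
        if i >= kb:
            out += 0.5 * sb * H[i - kb]
            src += 0.5 * beta * sb * H[i - kb]
        r = p.r_max * (1.0 - (U[i] + I[i]) / p.K_C)
        U[i + 1] = max(U[i] + dt * (r * U[i] - p.delta_U * U[i] - H[i]), 0.0)
        I[i + 1] = max(I[i] + dt * (H[i] - p.delta_I * I[i] - out), 0.0)
        P[i + 1] = max(
            P[i] + dt * (src - p.delta_P * P[i] - phi * (U[i] + I[i]) * P[i]), 0.0
        )
    return Trajectory(grid.times, U, I, P)


def test_two_point_kernel_matches_two_delay_oracle(params):
    """Linearity of the delay convolution: a {tau_a: 1/2, tau_b: 1/2} kernel
    equals the average of the two single-delay source terms."""
    grid = SimulationGrid(12.0, 0.005)
    tau_a, tau_b = 0.6, 1.4
    kernel = DiscretizedKernel(
        grid.dt,
        np.array([round(tau_a / grid.dt), round(tau_b / grid.dt)], dtype=np.int64),
        np.array([0.5, 0.5]),
    )
    burst = BurstProfile("constant", params.beta_0_mean)
    t1 = simulate_ddde(params, kernel, burst, grid)
    t2 = _two_delay_oracle(params, grid, tau_a, tau_b, params.beta_0_mean)
    for s in ("U", "I", "P"):
        assert np.allclose(getattr(t1, s), getattr(t2, s), rtol=1e-10)


def _mixture_expanded_solver(p, grid, kernel, beta_pair, beta_probs, phi_scales,
                             phi_probs):
    """Euler integrator with the burst-size and adsorption-rate mixtures kept
    explicit: every (beta_i, phi_j) component contributes its own term.

    The analytical reduction says only the conditional means matter; this
    solver never forms those means term-by-term.
    """
    n = grid.n_steps
    dt = grid.dt
    U = np.zeros(n + 1)
    I = np.zeros(n + 1)
    P = np.zeros(n + 1)
    # one history per phi component: H_j(s) = phi_j(s) U(s) P(s)
    Hs = np.zeros((len(phi_scales), n + 1))
    U[0], P[0] = p.U_init, p.P_init
    ks = kernel.offsets
    w = kernel.weights
    surv = np.exp(-p.delta_I * kernel.taus)
    for i in range(n):
        phi0 = p.phi_max * p.P_50 / (p.P_50 + P[i])
        phis = phi0 * np.asarray(phi_scales)
        for j, phij in enumerate(phis):
            Hs[j, i] = phij * U[i] * P[i]
        # adsorption loss: sum_j q_j phi_j U P
        ads = float(np.dot(phi_probs, Hs[:, i]))
        out = 0.0
        src = 0.0
        for m, k in enumerate(ks):
            if i >= k:
                # history mixture over phi at the infection time
                h = float(np.dot(phi_probs, Hs[:, i - k]))
                out += surv[m] * w[m] * h
                for beta, pb in zip(beta_pair, beta_probs):
                    src += pb * beta * surv[m] * w[m] * h
        r = p.r_max * (1.0 - (U[i] + I[i]) / p.K_C)
        ads_all = float(np.dot(phi_probs, phis)) * (U[i] + I[i]) * P[i]
        U[i + 1] = max(U[i] + dt * (r * U[i] - p.delta_U * U[i] - ads), 0.0)
        I[i + 1] = max(I[i] + dt * (ads - p.delta_I * I[i] - out), 0.0)
        P[i + 1] = max(P[i] + dt * (src - p.delta_P * P[i] - ads_all), 0.0)
    return Trajectory(grid.times, U, I, P)


def test_mixture_distributions_reduce_to_their_means(params):
    """Two-point burst and adsorption mixtures reproduce the mean-based
    distributed model to near machine precision: only the conditional means
    of beta and phi enter the population dynamics."""
    grid = SimulationGrid(12.0, 0.01)
    dist = build_distribution("gamma", 1.0, 0.3, 0.0)
    kernel = discretize_density(dist, grid.dt)
    beta_mean = params.beta_0_mean
    # mixture {0.5 beta: 1/2, 1.5 beta: 1/2} has mean beta; same trick for phi
    t_mix = _mixture_expanded_solver(
        params, grid, kernel,
        beta_pair=(0.5 * beta_mean, 1.5 * beta_mean), beta_probs=(0.5, 0.5),
        phi_scales=(0.4, 1.6), phi_probs=(0.5, 0.5),
    )
    t_mean = simulate_ddde(
        params, kernel, BurstProfile("constant", beta_mean), grid
    )
    for s in ("U", "I", "P"):
        a, b = getattr(t_mix, s), getattr(t_mean, s)
        assert np.allclose(a, b, rtol=1e-8, atol=1e-300)


class TestTransitCompartments:
    @pytest.mark.parametrize(
        "tau_0, rsd, N, k_tr",
        [(1.0, 0.25, 16, 16.0), (2.0, 0.10, 100, 50.0), (1.0, 0.50, 4, 4.0)],
    )
    def test_chain_matching_arithmetic(self, tau_0, rsd, N, k_tr):
        tc = tc_config_from_distribution(tau_0, rsd)
        assert tc.N == N
        assert tc.k_tr == pytest.approx(k_tr)

    def test_zero_rsd_rejected(self):
        with pytest.raises(ValueError):
            tc_config_from_distribution(1.0, 0.0)

    @pytest.mark.parametrize("N", [4, 16, 25])
    def test_erlang_equivalence_with_gamma_kernel(self, params, N):
        """The linear chain trick: N transit compartments = gamma latent kernel
        with shape N (constant burst), within the 1% convergence criterion."""
        rsd = 1.0 / np.sqrt(N)
        dist = build_distribution("gamma", 1.0, rsd, 0.0)
        burst = BurstProfile("constant", params.beta_0_mean)
        tc = tc_config_from_distribution(1.0, rsd)
        assert tc.N == N
        grid = SimulationGrid(24.0, 0.002)
        t_tc = simulate_tc(params, tc, grid)
        t_ddde = simulate_ddde(
            params, discretize_density(dist, grid.dt), burst, grid
        )
        assert curve_error(t_tc, t_ddde, "bacterial") < 1.0
        assert curve_error(t_tc, t_ddde, "viral") < 1.0


class TestSteppers:
    def test_euler_and_rk4_agree_at_converged_step(self, params, lognormal_dist,
                                                   lognormal_burst):
        grid = SimulationGrid(24.0, 0.002)
        kernel = discretize_density(lognormal_dist, grid.dt)
        t_e = simulate_ddde(params, kernel, lognormal_burst, grid)
        t_r = simulate_ddde(params, kernel, lognormal_burst, grid, stepper="rk4")
        assert curve_error(t_e, t_r, "bacterial") < 1.0
        assert curve_error(t_e, t_r, "viral") < 1.0

    def test_unknown_stepper_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_dde(params, 1.0, SimulationGrid(1.0, 0.01), stepper="heun")


class TestConvergenceControl:
    def test_smooth_logistic_converges_quickly(self, params):
        p = params.with_(P_init=0.0)

        def sim(grid):
            return simulate_dde(p, 1.0, grid)

        res = run_with_convergence(sim, 24.0, dt_initial=0.1)
        assert res.converged
        assert res.n_halvings <= 3

    def test_trivial_criterion_returns_after_first_halving(self, params):
        def sim(grid):
            return simulate_dde(params, 1.0, grid)

        res = run_with_convergence(sim, 12.0, dt_initial=0.05, criterion=100.0)
        assert res.converged
        assert res.n_halvings == 1

    def test_exhausted_halvings_reported_not_raised(self, params):
        def sim(grid):
            return simulate_dde(params, 1.0, grid)

        res = run_with_convergence(
            sim, 12.0, dt_initial=0.05, criterion=1e-9, max_halvings=2
        )
        assert res.converged is False

    def test_refinement_errors_decrease_monotonically(self, params, lognormal_dist,
                                                      lognormal_burst):
        def sim(grid):
            kernel = discretize_density(lognormal_dist, grid.dt)
            return simulate_ddde(params, kernel, lognormal_burst, grid)

        res = run_with_convergence(
            sim, 24.0, dt_initial=0.04, criterion=1e-9, max_halvings=4
        )
        errs = [max(be, ve) for _, be, ve in res.history]
        assert len(errs) >= 3
        assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:]))


class TestTrajectoryContracts:
    def test_nonnegativity_and_initial_conditions(self, rng):
        ranges = ParameterRanges.default()
        for _ in range(10):
            draw = sample_parameter_set(ranges, rng)
            p = draw.kinetics
            grid = SimulationGrid(12.0, 0.005)
            traj = simulate_dde(p, max(round(draw.tau_0 / grid.dt), 1) * grid.dt,
                                grid)
            assert np.all(traj.U >= 0)
            assert np.all(traj.I >= 0)
            assert np.all(traj.P >= 0)
            assert traj.U[0] == p.U_init
            assert traj.I[0] == 0.0
            assert traj.P[0] == p.P_init

    def test_kernel_grid_mismatch_rejected(self, params, lognormal_dist):
        kernel = discretize_density(lognormal_dist, 0.01)
        burst = BurstProfile("constant", params.beta_0_mean)
        with pytest.raises(ValueError):
            simulate_ddde(params, kernel, burst, SimulationGrid(1.0, 0.005))

    def test_csv_round_trip(self, params, tmp_path):
        import pandas as pd

        traj = simulate_dde(params, 1.0, SimulationGrid(1.0, 0.01))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["time_h", "U", "I", "P"]
        assert np.allclose(df["P"], traj.P)
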