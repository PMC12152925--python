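import numpy as np
import pytest
from scipy.stats import norm

from rmfilter.systems import (FitnessParams, NonlinearSystem1D,
                              TimeDiscretization)
from rmfilter.observations import (SignalPath, brownian_increments,
                                   ito_observation, observation_derivative,
                                   piecewise_linear_brownian)
from rmfilter.ck_pde import (CFLError, GridDensity, SpatialGrid, ck_solve,
                             density_distance, fitness_eval, gaussian_on_grid,
                             grid_moments, zakai_solve)


def _linear_sys(G=0.0, H=1.0, Sigma=0.0, Xi=1.0):
    return NonlinearSystem1D(g=lambda x: G * np.asarray(x, float),
                             h=lambda x: H * np.asarray(x, float),
                             Sigma=Sigma, Xi=Xi)


class TestFitnessEval:
    def test_local_case_is_z_independent(self):
        fp = FitnessParams(r=1.5, s=0.0)
        h = lambda x: 2.0 * np.asarray(x, float)
        for z in (-3.0, 0.0, 7.0):
            val = fitness_eval(fp, h, ydot=1.0, x=0.7, z=z, xi=2.0)
            assert val == pytest.approx(-(1.5 / 2) * (1.4 - 1.0) ** 2 / 2.0)

    def test_hand_example(self):
        # h(x)=x, Xi=1, ydot=0, r=2, s=1: f(x,z) = -x^2 + x z, f(1,2) = 1
        fp = FitnessParams(r=2.0, s=1.0)
        h = lambda x: np.asarray(x, float)
        assert fitness_eval(fp, h, 0.0, 1.0, 2.0) == pytest.approx(1.0)

    def test_diagonal_identity(self):
        # f(x, x) = (s - r/2) (h(x) - ydot)^2 / Xi
        fp = FitnessParams(r=1.3, s=-0.4)
        h = lambda x: np.sin(np.asarray(x, float))
        for x in (-1.0, 0.3, 2.0):
            expect = (fp.s - fp.r / 2) * (np.sin(x) - 0.2) ** 2 / 0.7
            assert fitness_eval(fp, h, 0.2, x, x, xi=0.7) == pytest.approx(expect)

    def test_singular_xi_rejected(self):
        with pytest.raises(ValueError):
            fitness_eval(FitnessParams(1.0, 0.0), lambda x: x, 0.0, 1.0, 1.0,
                         xi=0.0)


class TestGridMoments:
    def test_standard_normal(self):
        grid = SpatialGrid(-8.0, 8.0, 801)
        d = gaussian_on_grid(grid, 0.0, 1.0)
        mean, var = grid_moments(d)
        assert abs(mean) < 1e-9
        assert var == pytest.approx(1.0, abs=1e-6)

    def test_shifted_narrow_normal(self):
        grid = SpatialGrid(-8.0, 8.0, 1601)
        d = gaussian_on_grid(grid, 2.0, 0.3)
        mean, var = grid_moments(d)
        assert mean == pytest.approx(2.0, abs=1e-6)
        assert var == pytest.approx(0.3, abs=1e-6)

    def test_zero_mass_rejected(self):
        grid = SpatialGrid(-1.0, 1.0, 11)
        with pytest.raises(ValueError):
            grid_moments(GridDensity(grid, np.zeros(11)))


class TestDensityDistance:
    def test_identical_densities(self):
        grid = SpatialGrid(-5.0, 5.0, 201)
        d = gaussian_on_grid(grid, 0.0, 1.0)
        l1, linf = density_distance(d, d)
        assert l1 == 0.0 and linf == 0.0

    def test_disjoint_boxes(self):
        grid = SpatialGrid(0.0, 4.0, 4001)
        a = np.where((grid.x >= 0.5) & (grid.x <= 1.5), 1.0, 0.0)
        b = np.where((grid.x >= 2.5) & (grid.x <= 3.5), 1.0, 0.0)
        l1, _ = density_distance(GridDensity(grid, a), GridDensity(grid, b))
        assert l1 == pytest.approx(2.0, abs=5e-3)

    def test_shifted_gaussians_closed_form(self):
        # L1(N(0,1), N(mu,1)) = 2 (2 Phi(mu/2) - 1)
        grid = SpatialGrid(-10.0, 10.0, 4001)
        a = gaussian_on_grid(grid, 0.0, 1.0)
        b = gaussian_on_grid(grid, 0.1, 1.0)
        l1, _ = density_distance(a, b)
        assert l1 == pytest.approx(2 * (2 * norm.cdf(0.05) - 1), abs=1e-4)

    def test_grid_mismatch_rejected(self):
        a = gaussian_on_grid(SpatialGrid(-5, 5, 101), 0, 1)
        b = gaussian_on_grid(SpatialGrid(-5, 5, 201), 0, 1)
        with pytest.raises(ValueError):
            density_distance(a, b)


class TestCkSolve:
    def test_pure_mutation_conserves_mass(self):
        # h = 0: replication vanishes, log-mass stays 0 to 1e-8
        sys1d = NonlinearSystem1D(g=lambda x: np.zeros_like(x),
                                  h=lambda x: np.zeros_like(x),
                                  Sigma=0.2, Xi=1.0)
        grid = SpatialGrid(-8.0, 8.0, 401)
        tg = TimeDiscretization(T=1.0, dt=2e-4, delta_d=0.1)
        p0 = gaussian_on_grid(grid, 0.0, 0.5)
        obs = piecewise_linear_brownian(tg, seed=0)
        traj = ck_solve(sys1d, FitnessParams(1.0, 0.0), obs, grid, tg,
                        mode="unnormalized", p0=p0)
        assert abs(traj.log_mass[-1]) < 1e-8
        assert traj.boundary_mass < 1e-10

    def test_cfl_violation_raises(self):
        sys1d = _linear_sys(Sigma=1.0)
        grid = SpatialGrid(-5.0, 5.0, 801)
        tg = TimeDiscretization(T=0.1, dt=1e-3, delta_d=1e-2)
        p0 = gaussian_on_grid(grid, 0.0, 1.0)
        obs = piecewise_linear_brownian(tg, seed=0)
        with pytest.raises(CFLError):
            ck_solve(sys1d, FitnessParams(1.0, 0.0), obs, grid, tg,
                     mode="unnormalized", p0=p0)

    def test_exponential_tilt_oracle(self):
        # g=0, Sigma=0, s=0, static ydot: p_t  is proportional to e^{t f} p_0
        sys1d = _linear_sys(H=1.0, Xi=1.0)
        grid = SpatialGrid(-4.0, 4.0, 401)
        T, dt = 0.1, 1e-6
        tg = TimeDiscretization(T=T, dt=dt, delta_d=T)
        p0 = gaussian_on_grid(grid, 0.3, 0.2)
        fp = FitnessParams(r=1.0, s=0.0)
        ydot = 0.0
        obs = observation_derivative(
            SignalPath(times=tg.times, states=np.zeros((tg.n_steps + 1, 1))),
            sys1d, tg, increments=np.zeros((tg.n_steps, 1)))
        assert np.allclose(obs.xi, 0.0)
        traj = ck_solve(sys1d, fp, obs, grid, tg, mode="normalized", p0=p0)
        f = -(fp.r / 2) * (grid.x - ydot) ** 2
        tilt = np.exp(T * f) * p0.values
        tilt /= np.trapezoid(tilt, dx=grid.dx)
        assert np.max(np.abs(traj.final().values - tilt)) < 1e-6

    def test_normalized_equals_unnormalized_after_scaling(self):
        # rho = mu / integral(mu): the linear (unnormalized) form matches the
        # replicator form for local fitness (s = 0), any r
        sys1d = _linear_sys(G=-0.3, H=1.0, Sigma=0.1, Xi=0.5)
        grid = SpatialGrid(-4.0, 4.0, 401)
        tg = TimeDiscretization(T=0.2, dt=5e-5, delta_d=2e-2)
        p0 = gaussian_on_grid(grid, 0.0, 0.4)
        obs = observation_derivative(
            SignalPath(times=tg.times, states=np.full((tg.n_steps + 1, 1), 0.8)),
            sys1d, tg, seed=3)
        fp = FitnessParams(r=1.3, s=0.0)
        a = ck_solve(sys1d, fp, obs, grid, tg, mode="normalized", p0=p0)
        b = ck_solve(sys1d, fp, obs, grid, tg, mode="unnormalized", p0=p0)
        l1, _ = density_distance(a.final(), b.final())
        assert l1 < 5e-4   # O(dt) agreement of the two discretised forms

    def test_grid_moments_track_moment_odes(self):
        # linear-Gaussian problem: grid mean/variance vs the (r,s) moment
        # ODEs driven by the same windowed observation derivative
        G, H, Sigma, Xi = -0.2, 1.0, 0.5, 0.5
        sys1d = _linear_sys(G=G, H=H, Sigma=Sigma, Xi=Xi)
        grid = SpatialGrid(-5.0, 5.0, 1201)
        tg = TimeDiscretization(T=0.5, dt=2.5e-5, delta_d=1e-2)
        m0, C0 = 0.3, 0.3
        p0 = gaussian_on_grid(grid, m0, C0)
        fp = FitnessParams(r=1.2, s=-0.6)
        states = np.full((tg.n_steps + 1, 1), 1.0)
        obs = observation_derivative(SignalPath(times=tg.times, states=states),
                                     sys1d, tg, seed=11)
        traj = ck_solve(sys1d, fp, obs, grid, tg, mode="normalized", p0=p0)
        # Euler moment ODEs with the same driver
        ydot = obs.derivative_at_steps(tg)[:, 0]
        m, C = m0, C0
        ms = [m]
        Cs = [C]
        for k in range(tg.n_steps):
            K = C * H / Xi
            m = m + tg.dt * (G * m + (fp.r - fp.s) * K * (ydot[k] - H * m))
            C = C + tg.dt * (2 * G * C + Sigma - fp.r * C**2 * H**2 / Xi)
            ms.append(m)
            Cs.append(C)
        ms, Cs = np.array(ms), np.array(Cs)
        assert np.max(np.abs(traj.means - ms)) / np.max(np.abs(ms)) < 1e-3
        assert np.max(np.abs(traj.variances - Cs)) / np.max(Cs) < 1e-3


class TestZakaiSolve:
    def test_modes_coincide_at_kalman_parameters(self):
        sys1d = _linear_sys(G=0.0, H=2.0, Sigma=0.0, Xi=1.0)
        grid = SpatialGrid(-3.0, 7.0, 401)
        tg = TimeDiscretization(T=0.05, dt=1e-4, delta_d=5e-3)
        p0 = gaussian_on_grid(grid, 0.0, 0.3)
        states = np.full((tg.n_steps + 1, 1), 5.0)
        sig = SignalPath(times=tg.times, states=states)
        ito = ito_observation(sig, sys1d, tg, seed=2)
        fp = FitnessParams(1.0, 0.0)
        a = zakai_solve(sys1d, fp, ito, grid, tg, mode="ito_paper", p0=p0)
        b = zakai_solve(sys1d, fp, ito, grid, tg, mode="stratonovich", p0=p0)
        np.testing.assert_allclose(a.final().values, b.final().values,
                                   rtol=0, atol=1e-12)
        c = zakai_solve(sys1d, fp, ito, grid, tg, mode="ito_naive", p0=p0)
        assert np.max(np.abs(c.final().values - a.final().values)) > 1e-4

    def test_kalman_bucy_moments_recovered(self):
        # normalized grid moments of the r=1, s=0 Zakai solution match the
        # Kalman-Bucy mean/covariance driven by the same dZ
        G, H, Sigma, Xi = -0.1, 1.0, 0.5, 4.0
        sys1d = _linear_sys(G=G, H=H, Sigma=Sigma, Xi=Xi)
        grid = SpatialGrid(-4.0, 4.0, 1201)
        tg = TimeDiscretization(T=0.5, dt=2e-5, delta_d=1e-2)
        p0 = gaussian_on_grid(grid, 0.3, 0.3)
        states = np.full((tg.n_steps + 1, 1), 1.0)
        sig = SignalPath(times=tg.times, states=states)
        ito = ito_observation(sig, sys1d, tg, seed=21)
        traj = zakai_solve(sys1d, FitnessParams(1.0, 0.0), ito, grid, tg,
                           mode="ito_paper", p0=p0)
        m, C = 0.3, 0.3
        ms, Cs = [m], [C]
        for k in range(tg.n_steps):
            K = C * H / Xi
            m = m + tg.dt * G * m + K * (ito.dZ[k, 0] - H * m * tg.dt)
            C = C + tg.dt * (2 * G * C + Sigma - C**2 * H**2 / Xi)
            ms.append(m)
            Cs.append(C)
        ms, Cs = np.array(ms), np.array(Cs)
        assert np.max(np.abs(traj.means - ms)) / np.max(np.abs(ms)) < 1e-3
        assert np.max(np.abs(traj.variances - Cs)) / np.max(Cs) < 1e-3
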