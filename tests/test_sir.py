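"""Network SIR model: agent rule, field solvers, local limits, scenario."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import netkin as nk
from netkin import sir
from netkin.errors import ParameterError, StabilityError


@pytest.fixture(scope="module")
def fig1_network_traj():
    return sir.fig1_scenario().run("network")


class TestSIRRule:
    def test_all_susceptible_no_events(self):
        rule = sir.sir_rule(nk.Kernel.constant(1.0), beta=0.5)
        ens = nk.AgentEnsemble(np.linspace(0, 0.9, 10),
                               np.zeros(10, dtype=int), "categorical")
        out, log = nk.simulate_boltzmann(ens, rule, nk.Kernel.constant(1.0),
                                         5.0, 0, log_events=True)
        assert np.all(out.states == sir.S)
        assert log.n_unary_events == 0  # no infected, so no removals

    def test_pure_death_rate(self):
        """All infected, no susceptibles: I decays at mean exponential rate
        beta (pure death process)."""
        beta, t_end, N = 0.5, 2.0, 300
        rule = sir.sir_rule(nk.Kernel.constant(1.0), beta=beta)
        fracs = []
        for seed in range(10):
            ens = nk.AgentEnsemble(np.linspace(0, 0.99, N),
                                   np.full(N, sir.I), "categorical")
            out, _ = nk.simulate_boltzmann(ens, rule, nk.Kernel.constant(1.0),
                                           t_end, seed)
            fracs.append(np.mean(out.states == sir.I))
        expected = np.exp(-beta * t_end)
        se = np.std(fracs) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - expected) < 4 * se + 0.01

    def test_susceptibles_nonincreasing(self):
        rule = sir.sir_rule(nk.Kernel.constant(1.0), beta=0.2)
        rng = np.random.default_rng(1)
        states = (rng.random(100) < 0.3).astype(int)
        ens = nk.AgentEnsemble(rng.random(100), states, "categorical")
        out, log = nk.simulate_boltzmann(
            ens, rule, nk.Kernel.constant(3.0), 3.0, 5,
            snapshot_every_events=10,
        )
        s_counts = [np.sum(s == sir.S) for s in log.snapshots]
        assert np.all(np.diff(s_counts) <= 0)
        # and R only grows
        r_counts = [np.sum(s == sir.R) for s in log.snapshots]
        assert np.all(np.diff(r_counts) >= 0)


class TestSolveSIRNetwork:
    def test_no_infected_static(self, grid100):
        km = nk.discretize_kernel(nk.Kernel.triangular(0.3, 0.2), grid100)
        f = sir.SIRFields(u=np.ones(100), v=np.zeros(100), beta=0.1)
        traj = sir.solve_sir_network(f, km, 2.0)
        assert np.abs(traj.states[-1] - traj.states[0]).max() == 0.0

    def test_no_susceptibles_exponential_decay(self, grid100):
        """u = 0: v follows the discrete pure-decay recursion exactly."""
        km = nk.discretize_kernel(nk.Kernel.triangular(0.3, 0.2), grid100)
        v0 = sir.peak_initial_infected(grid100)
        f = sir.SIRFields(u=np.zeros(100), v=v0, beta=0.1)
        dt = 0.01
        traj = sir.solve_sir_network(f, km, 2.0, dt=dt)
        n_steps = len(traj.times) - 1
        assert traj.states[-1][:, 1] == pytest.approx(
            v0 * (1 - 0.1 * dt) ** n_steps, rel=1e-12
        )

    def test_two_forms_agree(self, grid100, rng):
        """The direct integral form and the reaction-diffusion rewriting
        (alpha u v + u L_w v) are algebraically identical."""
        km = nk.discretize_kernel(nk.Kernel.triangular(0.3, 0.2), grid100)
        u = rng.random(100)
        v = rng.random(100) * 0.1
        d1 = sir.sir_network_rhs(u, v, km, 0.1, form="direct")
        d2 = sir.sir_network_rhs(u, v, km, 0.1, form="reaction_diffusion")
        for a, b in zip(d1, d2):
            assert a == pytest.approx(b, abs=1e-14)

    def test_fig1_invariants(self, fig1_network_traj):
        traj = fig1_network_traj
        u = traj.states[:, :, 0]
        v = traj.states[:, :, 1]
        total = traj.states.sum(axis=2)
        assert (u + v).min() >= 0.0
        assert np.all(u + v <= (u + v)[0] + 1e-12)
        assert np.all(np.diff(u, axis=0) <= 1e-12)
        assert np.abs(total - total[0]).max() <= 1e-8

    def test_shape_mismatch(self, grid100):
        km = nk.discretize_kernel(nk.Kernel.constant(1.0), grid100)
        with pytest.raises(ParameterError):
            sir.solve_sir_network(
                sir.SIRFields(u=np.ones(50), v=np.zeros(50)), km, 1.0
            )


class TestSolveSIRRdComparison:
    def test_zero_diffusivity_reduces_to_pointwise_ode(self, grid100):
        km = nk.discretize_kernel(nk.Kernel.triangular(0.3, 0.2), grid100)
        v0 = sir.peak_initial_infected(grid100)
        f = sir.SIRFields(u=np.ones(100), v=v0, beta=0.1, D1=0.0, D2=0.0)
        traj = sir.solve_sir_rd_comparison(f, km, 2.0, dt=0.005, scheme="rk4")
        alpha = float(km.row_integral[0])

        def rhs(t, y):
            u, v = y[:100], y[100:]
            return np.concatenate([-alpha * u * v,
                                   alpha * u * v - 0.1 * v])

        sol = solve_ivp(rhs, (0, 2.0), np.concatenate([f.u, v0]),
                        rtol=1e-10, atol=1e-12)
        assert traj.states[-1][:, 0] == pytest.approx(sol.y[:100, -1],
                                                      abs=1e-8)
        assert traj.states[-1][:, 1] == pytest.approx(sol.y[100:, -1],
                                                      abs=1e-8)

    def test_constant_u_stays_constant_without_infection(self, grid100):
        km = nk.discretize_kernel(nk.Kernel.triangular(0.3, 0.2), grid100)
        f = sir.SIRFields(u=np.full(100, 0.8), v=np.zeros(100), beta=0.1)
        traj = sir.solve_sir_rd_comparison(f, km, 2.0)
        assert np.abs(traj.states[-1][:, 0] - 0.8).max() < 1e-13

    def test_mass_budget(self, grid100):
        """int u + int v + beta int_0^t int v ds is conserved (the nonlocal
        Laplacian integrates to zero for the symmetric kernel)."""
        km = nk.discretize_kernel(nk.Kernel.triangular(0.3, 0.2), grid100)
        v0 = sir.peak_initial_infected(grid100)
        f = sir.SIRFields(u=np.ones(100), v=v0, beta=0.1)
        dt = 0.01
        traj = sir.solve_sir_rd_comparison(f, km, 3.0, dt=dt)
        h = grid100.spacing
        uv = (traj.states[:, :, 0] + traj.states[:, :, 1]).sum(axis=1) * h
        # discrete time integral of beta * int v (left endpoint, matching
        # explicit Euler)
        v_int = traj.states[:, :, 1].sum(axis=1) * h
        removed = 0.1 * dt * np.cumsum(v_int[:-1])
        budget = uv[1:] + removed
        assert budget == pytest.approx(np.full(len(budget), uv[0]), abs=1e-10)


class TestSolveSIRLocal:
    def test_leading_order_matches_ode_oracle(self, grid100):
        v0 = sir.peak_initial_infected(grid100)
        f = sir.SIRFields(u=np.ones(100), v=v0, beta=0.1)
        traj = sir.solve_sir_local(f, grid100, 2.0, dt=0.005,
                                   variant="leading_order", alpha=1.0,
                                   scheme="rk4")

        def rhs(t, y):
            u, v = y[:100], y[100:]
            return np.concatenate([-u * v, u * v - 0.1 * v])

        sol = solve_ivp(rhs, (0, 2.0), np.concatenate([f.u, v0]),
                        rtol=1e-10, atol=1e-12)
        assert traj.states[-1][:, 0] == pytest.approx(sol.y[:100, -1],
                                                      abs=1e-7)

    def test_degenerate_sign_violation(self):
        """A concave infected bump with Lap v < -alpha v makes du/dt
        positive somewhere — the failure mode of the naive local limit."""
        grid = nk.SpatialGrid.uniform(100)
        v0 = 0.1 * np.exp(-((grid.points - 0.5) ** 2) / (2 * 0.05**2))
        # check the premise at the bump's shoulder region
        lap = (np.roll(v0, -1) - 2 * v0 + np.roll(v0, 1)) / grid.spacing**2
        alpha = 0.012
        assert (lap < -alpha * v0).any()
        f = sir.SIRFields(u=np.ones(100), v=v0, beta=0.1)
        traj = sir.solve_sir_local(f, grid, 1e-3, dt=2e-5,
                                   variant="degenerate", alpha=alpha)
        assert traj.meta["du_sign_violations"].any()
        u = traj.states[:, :, 0]
        assert (u[-1] > u[0] + 1e-12).any()  # susceptibles actually grew

    def test_no_infected_constant_u(self):
        grid = nk.SpatialGrid.uniform(50)
        f = sir.SIRFields(u=np.ones(50), v=np.zeros(50), beta=0.1)
        for variant in ("degenerate", "leading_order"):
            traj = sir.solve_sir_local(f, grid, 0.5, dt=0.01, variant=variant)
            assert np.abs(traj.states[-1][:, 0] - 1.0).max() == 0.0


class TestFig1Scenario:
    def test_packaged_values(self):
        sc = sir.fig1_scenario()
        kern = sc.kernel()
        assert nk.evaluate_kernel(kern, 0.3, 0.3) == pytest.approx(0.06)
        km = sc.kernel_matrix()
        assert km.row_integral == pytest.approx(np.full(100, 0.012))
        assert sc.grid().n == 100
        assert sc.beta == 0.1 and sc.dt == 0.01

    def test_network_vs_rd_contrast(self, fig1_network_traj):
        """The comparison model disperses susceptibles (dip at the seed)
        while the network model keeps u monotone in time; the network
        model ends with more cumulative infections."""
        sc = sir.fig1_scenario()
        trd = sc.run("rd")
        trn = fig1_network_traj
        h = 0.01
        seed_idx = 50
        # rd: local dip of u at the seed position
        assert trd.states[-1][seed_idx, 0] < trd.states[-1][0, 0] - 1e-9
        # network: u pointwise monotone in time
        assert np.all(np.diff(trn.states[:, :, 0], axis=0) <= 1e-12)
        # cumulative infections (removed mass) larger for the network model
        rn = trn.states[-1][:, 2].sum() * h
        rr = trd.states[-1][:, 2].sum() * h
        assert rn > rr


class TestAgentFieldConsistency:
    def test_agents_track_pde_fields(self):
        """Binned S/I fractions of a 2000-agent simulation track the
        network PDE fields within (generous, seed-frozen) Monte-Carlo
        bands for a supercritical outbreak."""
        n, N, beta, t_end, amp = 50, 2000, 0.5, 2.0, 50.0
        grid = nk.SpatialGrid.uniform(n)
        kern = nk.Kernel.triangular(amp, 0.2)
        km = nk.discretize_kernel(kern, grid, density=np.ones(n))
        u0 = np.ones(n)
        v0 = 0.3 * np.exp(-((grid.points - 0.5) ** 2) / (2 * 0.05**2))
        traj = sir.solve_sir_network(sir.SIRFields(u=u0, v=v0, beta=beta),
                                     km, t_end, dt=0.005)
        mass = (u0 + v0).sum() * grid.spacing
        eta = (u0 + v0) * grid.spacing / mass
        rule = sir.sir_rule(kern, beta)
        kern_agents = nk.Kernel.triangular(amp * mass, 0.2)
        bins = np.linspace(0, 1, 11)
        vhats, uhats = [], []
        for seed in (11, 12, 13, 14, 15):
            rng = np.random.default_rng(seed)
            cells = rng.choice(n, size=N, p=eta)
            pos = grid.points[cells]
            p_inf = v0[cells] / (u0[cells] + v0[cells])
            states = (rng.random(N) < p_inf).astype(int)
            ens = nk.AgentEnsemble(pos, states, "categorical")
            out, _ = nk.simulate_boltzmann(ens, rule, kern_agents, t_end,
                                           seed)
            scale = mass / (N * 0.1)
            vhats.append(np.histogram(pos[out.states == sir.I],
                                      bins=bins)[0] * scale)
            uhats.append(np.histogram(pos[out.states == sir.S],
                                      bins=bins)[0] * scale)
        v_pde = traj.states[-1][:, 1].reshape(10, 5).mean(axis=1)
        u_pde = traj.states[-1][:, 0].reshape(10, 5).mean(axis=1)
        assert np.abs(np.mean(vhats, axis=0) - v_pde).max() < 0.25
        assert np.abs(np.mean(uhats, axis=0) - u_pde).max() < 0.25
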