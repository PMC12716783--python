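import numpy as np
import pytest

from hepsim.agents import NEA, Agents
from hepsim.demography import PopulationParams
from hepsim.engine import (PRESETS, InitCenter, PopulationConfig,
                           ScenarioConfig, density_field, init_population,
                           load_preset, perturb_scenario, rate_of_change,
                           run_ensemble, run_simulation, threshold_fractions)
from hepsim.errors import ConfigError, ParameterError
from hepsim.landscape_io import GridSpec
from hepsim.mobility import MobilityParams
from conftest import uniform_land_grid


@pytest.fixture
def flat_scenario():
    """Uniform all-land habitat with a constant accessible HEP."""
    grid, land = uniform_land_grid(16, 16)
    phi = {"warm": np.full(grid.shape, 0.5)}
    lon, lat = grid.xy_to_lonlat(160.0, 160.0)
    pop = PopulationConfig(
        demography=PopulationParams(C=2.0, ro=0.02),
        mobility=MobilityParams(dt_response=2.0),
        phi_ac=phi,
        init=[InitCenter(lon, lat, 200, 0.3)])
    return ScenarioConfig(grid=grid, land_mask=land,
                          populations={"NEA": pop},
                          timeline=[(0.0, "warm")], t_end=50.0,
                          spinup_exclude=10.0, seed=5)


class TestPresets:
    def test_all_presets_load(self):
        for name in PRESETS:
            p = load_preset(name)
            assert p.mobility.alpha == pytest.approx(1250.0)
            assert p.mobility.sigma == pytest.approx(15.0)

    @pytest.mark.parametrize("name,C,ro", [
        ("ExpNEA-H", 3.0, 0.05), ("ExpNEA-C", 2.0, 0.02),
        ("ExpNEA-L", 1.0, 0.01), ("ExpAUR-C", 3.0, 0.02),
        ("ExpMIX-C", 2.0, 0.02),
    ])
    def test_preset_table(self, name, C, ro):
        p = load_preset(name)
        assert p.demography.C == C
        assert p.demography.ro == ro

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigError):
            load_preset("ExpFOO")


class TestInitPopulation:
    def test_exact_count_all_on_land(self, rng):
        grid, land = uniform_land_grid(20, 20)
        land[:, :3] = False
        agents = init_population([InitCenter(*grid.xy_to_lonlat(200, 200), 1000,
                                             0.5)],
                                 grid, land, 15.0, rng)
        assert agents.n_alive == 1000
        iy, ix = grid.cell_of(agents.x, agents.y)
        assert land[iy, ix].all()

    def test_sample_mean_near_center(self, rng):
        grid, land = uniform_land_grid(30, 30)
        cx, cy = 300.0, 300.0
        lon, lat = grid.xy_to_lonlat(cx, cy)
        std_deg = 0.3
        agents = init_population([InitCenter(lon, lat, 1000, std_deg)], grid,
                                 land, 15.0, rng)
        std_km = grid.deg_to_km(std_deg)
        tol = 3 * std_km / np.sqrt(1000)
        assert abs(agents.x.mean() - cx) < tol
        assert abs(agents.y.mean() - cy) < tol

    def test_velocity_magnitudes_are_sigma(self, rng):
        grid, land = uniform_land_grid()
        lon, lat = grid.xy_to_lonlat(100, 80)
        agents = init_population([InitCenter(lon, lat, 50, 0.2)], grid, land,
                                 15.0, rng)
        assert np.allclose(np.hypot(agents.u, agents.v), 15.0)

    def test_mostly_sea_center_warns(self, rng):
        grid, land = uniform_land_grid(20, 20)
        land[:] = False
        land[0, 0] = True
        lon, lat = grid.xy_to_lonlat(350, 350)
        with pytest.warns(UserWarning, match="land"):
            with pytest.raises(ParameterError):
                init_population([InitCenter(lon, lat, 10, 0.1)], grid, land,
                                15.0, rng)


class TestDensityField:
    def test_pdu_conversion(self, small_grid):
        agents = Agents()
        x = np.full(8, small_grid.origin_x + 30.0)
        y = np.full(8, small_grid.origin_y + 30.0)
        agents.add(NEA, x, y, np.zeros(8), np.zeros(8))
        rho = density_field(agents, small_grid)
        assert rho[1, 1] == pytest.approx(2.0)   # 8 agents / 4 = 2 PDU

    def test_empty_domain_zero(self, small_grid):
        assert density_field(Agents(), small_grid).sum() == 0.0

    def test_total_density_conserves_count(self, small_grid, rng):
        agents = Agents()
        n = 137
        agents.add(NEA, rng.uniform(0, small_grid.x_max, n),
                   rng.uniform(0, small_grid.y_max, n), np.zeros(n),
                   np.zeros(n))
        rho = density_field(agents, small_grid)
        assert rho.sum() * small_grid.cell_area_km2 / 100.0 == pytest.approx(n)


class TestRunSimulation:
    def test_zero_populations_empty_output(self):
        grid, land = uniform_land_grid()
        scen = ScenarioConfig(grid=grid, land_mask=land, populations={},
                              timeline=[(0.0, "warm")], t_end=10.0, seed=0)
        out = run_simulation(scen)
        assert out.pop_series == {}
        assert out.agents.n_alive == 0

    def test_population_grows_toward_capacity(self, flat_scenario):
        flat_scenario.t_end = 400.0
        out = run_simulation(flat_scenario, np.random.default_rng(3))
        # capacity = C * phi * area: 2 * 0.5 * 4 agents/cell * 256 cells
        capacity = 2.0 * 0.5 * 4 * 256
        final = out.pop_series["NEA"][-1]
        assert final > 0.5 * capacity
        assert final < 1.3 * capacity

    def test_period_switch_halves_equilibrium(self):
        # cold-period Phi_Ac at half the warm value roughly halves the
        # population after the switch (carrying capacity is linear in Phi_Ac)
        grid, land = uniform_land_grid(12, 12)
        phi = {"warm": np.full(grid.shape, 0.6),
               "cold": np.full(grid.shape, 0.3)}
        lon, lat = grid.xy_to_lonlat(120.0, 120.0)
        pop = PopulationConfig(PopulationParams(C=2.0, ro=0.05),
                               MobilityParams(dt_response=2.0), phi,
                               [InitCenter(lon, lat, 300, 0.3)])
        scen = ScenarioConfig(grid=grid, land_mask=land,
                              populations={"NEA": pop},
                              timeline=[(0.0, "warm"), (400.0, "cold")],
                              t_end=800.0, seed=9)
        finals = []
        warm_eq = []
        for rep in range(6):
            out = run_simulation(scen, np.random.default_rng(100 + rep))
            warm_eq.append(np.mean(out.pop_series["NEA"][300:400]))
            finals.append(np.mean(out.pop_series["NEA"][700:]))
        ratio = np.mean(finals) / np.mean(warm_eq)
        assert 0.3 < ratio < 0.7

    def test_snapshots_written_at_cadence(self, flat_scenario):
        flat_scenario.snapshot_every = 20.0
        out = run_simulation(flat_scenario, np.random.default_rng(0))
        times = [t for t, _ in out.snapshots["NEA"]]
        assert times[0] == 0.0
        assert 20.0 in times and 40.0 in times

    def test_missing_period_field_rejected(self):
        grid, land = uniform_land_grid()
        pop = PopulationConfig(PopulationParams(C=2.0, ro=0.02),
                               MobilityParams(), {"warm": np.zeros(grid.shape)})
        with pytest.raises(ConfigError, match="cold"):
            ScenarioConfig(grid=grid, land_mask=land,
                           populations={"NEA": pop},
                           timeline=[(0.0, "warm"), (10.0, "cold")], t_end=20.0)


class TestEnsemble:
    def test_member_records_and_determinism(self, flat_scenario):
        a = run_ensemble(flat_scenario, n_members=3, seed=7)
        b = run_ensemble(flat_scenario, n_members=3, seed=7)
        assert a.n_members == 3
        assert len(a.member_params) == 3
        assert np.array_equal(a.member_series["NEA"], b.member_series["NEA"])

    def test_zero_perturbation_identical_parameters(self, flat_scenario):
        summ = run_ensemble(flat_scenario, n_members=3, perturb=0.0, seed=1)
        c_draws = [p["NEA"]["C"] for p in summ.member_params]
        assert np.allclose(c_draws, c_draws[0])

    def test_perturbation_within_band(self, flat_scenario, rng):
        member, log = perturb_scenario(flat_scenario, rng, perturb=0.1)
        for key in ("C", "ro", "rho_d"):
            base = getattr(flat_scenario.populations["NEA"].demography, key)
            drawn = log["NEA"][key]
            assert 0.9 * abs(base) <= abs(drawn) <= 1.1 * abs(base)
        # invariants survive perturbation
        assert member.populations["NEA"].demography.eta_g < 0

    def test_tau_clipped_to_dt(self, flat_scenario):
        # dt_response draws below dt are clipped to keep gamma*dt <= 1
        flat_scenario.populations["NEA"].mobility = MobilityParams(
            dt_response=1.0)
        summ = run_ensemble(flat_scenario, n_members=5, perturb=0.1, seed=2)
        taus = [p["NEA"]["dt_response"] for p in summ.member_params]
        assert all(t >= flat_scenario.dt for t in taus)


class TestStepProperties:
    def _equilibrium(self, scen, seeds):
        vals = []
        for s in seeds:
            out = run_simulation(scen, np.random.default_rng(s))
            vals.append(np.mean(out.pop_series["NEA"][-50:]))
        return np.array(vals)

    def test_spinup_convergence_across_initial_placements(self):
        # identical dynamics with different initial centres converge after
        # spin-up: a two-sample test on post-spin-up means is not rejected
        from scipy.stats import mannwhitneyu
        grid, land = uniform_land_grid(14, 14)
        phi = {"warm": np.full(grid.shape, 0.5)}
        dem = PopulationParams(C=2.0, ro=0.05)
        mob = MobilityParams(dt_response=2.0)

        def scen(cx, cy):
            lon, lat = grid.xy_to_lonlat(cx, cy)
            pop = PopulationConfig(dem, mob, phi,
                                   [InitCenter(lon, lat, 200, 0.3)])
            return ScenarioConfig(grid=grid, land_mask=land,
                                  populations={"NEA": pop},
                                  timeline=[(0.0, "warm")], t_end=400.0,
                                  spinup_exclude=300.0)

        a = self._equilibrium(scen(60.0, 60.0), range(10))
        b = self._equilibrium(scen(220.0, 220.0), range(100, 110))
        assert mannwhitneyu(a, b).pvalue > 0.01

    def test_step_order_swap_changes_equilibrium_below_5pct(self):
        grid, land = uniform_land_grid(14, 14)
        phi = {"warm": np.full(grid.shape, 0.5)}
        dem = PopulationParams(C=2.0, ro=0.05)
        mob = MobilityParams(dt_response=2.0)
        lon, lat = grid.xy_to_lonlat(140.0, 140.0)
        eq = {}
        for order in ("motion_first", "demography_first"):
            pop = PopulationConfig(dem, mob, phi,
                                   [InitCenter(lon, lat, 200, 0.3)])
            scen = ScenarioConfig(grid=grid, land_mask=land,
                                  populations={"NEA": pop},
                                  timeline=[(0.0, "warm")], t_end=400.0,
                                  spinup_exclude=300.0, step_order=order)
            eq[order] = self._equilibrium(scen, range(8)).mean()
        rel = abs(eq["motion_first"] - eq["demography_first"]) / eq["motion_first"]
        assert rel < 0.05


class TestDiagnostics:
    def test_stationary_series_zero_rate(self):
        f = np.full((4, 4), 1.5)
        snaps = [(0.0, f), (500.0, f.copy()), (1000.0, f.copy())]
        times, fields = rate_of_change(snaps, 500.0)
        assert np.allclose(fields[0], 0.0)

    def test_difference_quotient(self):
        a = np.zeros((3, 3))
        b = np.ones((3, 3))
        times, fields = rate_of_change([(0.0, a), (500.0, b)], 500.0)
        # 1 PDU over 500 yr = 0.2 PDU / 100 yr
        assert fields[0][0, 0] * 100 == pytest.approx(0.2)

    def test_time_reversal_antisymmetry(self, rng):
        snaps = [(t, rng.random((3, 3))) for t in (0.0, 500.0, 1000.0)]
        _, fwd = rate_of_change(snaps, 500.0)
        rev = [(1000.0 - t, f) for t, f in reversed(snaps)]
        _, bwd = rate_of_change(rev, 500.0)
        assert np.allclose(fwd[0], -bwd[1])

    def test_missing_snapshot_named(self):
        with pytest.raises(ParameterError, match="500"):
            rate_of_change([(0.0, np.zeros((2, 2)))], 500.0)

    def test_all_extinct_fractions(self):
        fr = threshold_fractions(np.zeros(10), [0, 30, 50])
        assert np.allclose(fr, 1.0)

    def test_fractions_nondecreasing(self, rng):
        minima = rng.integers(0, 100, 50).astype(float)
        fr = threshold_fractions(minima, [0, 10, 30, 50, 90])
        assert np.all(np.diff(fr) >= 0)

    def test_handbuilt_ensemble_exact(self):
        minima = np.array([0, 5, 12, 29, 30, 31, 49, 50, 77, 100], float)
        fr = threshold_fractions(minima, [0, 30, 50])
        brute = [np.mean(minima <= 0), np.mean(minima < 30),
                 np.mean(minima < 50)]
        assert np.allclose(fr, brute)

    def test_empty_window_rejected(self):
        with pytest.raises(ParameterError):
            threshold_fractions(np.array([]), [0])
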