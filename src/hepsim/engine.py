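"""Scenario assembly, time stepping, ensemble runs and diagnostics.

A scenario couples, per population, an accessible-HEP field for each
climate period with demographic and mobility parameters. Each yearly step:
(1) bin agents and compute per-population density; (2) derive the
demography fields (carrying capacity, attractiveness, available HEP) from
the period-active accessible HEP; (3) move agents (gradient drift + damped
random walk, reflective coasts); (4) apply births/deaths; (5) sample
admixture where NEA and AMH co-occupy cells; (6) record. Accessible-HEP
fields switch discretely at the timeline's period boundaries.

Ensembles rerun the scenario with every perturbable scalar parameter
multiplied by an independent uniform draw from [1 - p, 1 + p] (default
p = 0.1) and per-member random seeds, and reduce the member time series to
ensemble mean/std and extinction diagnostics. The first years of each run
(default 300) are a spin-up excluded from summary statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .admixture import AdmixtureConfig, find_cooccupancy, sample_admixture
from .agents import MIX, POP_CODES, POP_NAMES, Agents
from .demography import (PopulationParams, attractiveness, available_hep,
                         carrying_capacity, smooth_density, step_births_deaths)
from .errors import ConfigError, ParameterError
from .landscape_io import GridSpec
from .mobility import MobilityParams, step_motion

#: ensemble size used for production experiments
DEFAULT_ENSEMBLE_MEMBERS = 1000
DEFAULT_PERTURBATION = 0.10
DEFAULT_SPINUP_EXCLUDE = 300.0

#: initial population centres of the Neanderthal experiments
#: (lon deg, lat deg); N0 = 1000 total, std 1 degree
NEA_INIT_CENTERS = [(-3.93, 42.3), (-0.72, 40.03), (-5.54, 36.66), (-8.6, 39.2)]
NEA_INIT_N0 = 1000
NEA_INIT_STD_DEG = 1.0


# ---------------------------------------------------------------------------
# Experiment presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    population: str                # NEA | AMH | MIX
    demography: PopulationParams
    mobility: MobilityParams


def _preset(name, pop, C, ro):
    return ExperimentPreset(name, pop, PopulationParams(C=C, ro=ro),
                            MobilityParams())


#: the named experiments: alpha = 1250 (km/yr)^2, sigma = 15 km/yr throughout
PRESETS = {
    "ExpNEA-C": _preset("ExpNEA-C", "NEA", C=2.0, ro=0.02),
    "ExpNEA-H": _preset("ExpNEA-H", "NEA", C=3.0, ro=0.05),
    "ExpNEA-L": _preset("ExpNEA-L", "NEA", C=1.0, ro=0.01),
    "ExpAUR-C": _preset("ExpAUR-C", "AMH", C=3.0, ro=0.02),
    "ExpMIX-C": _preset("ExpMIX-C", "MIX", C=2.0, ro=0.02),
}


def load_preset(name: str) -> ExperimentPreset:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset '{name}'; available: {sorted(PRESETS)}")
    return PRESETS[name]


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------

@dataclass
class InitCenter:
    """Gaussian initial population centre (degrees; std converted to km)."""

    lon: float
    lat: float
    n0: int
    std_deg: float = 1.0


@dataclass
class PopulationConfig:
    demography: PopulationParams
    mobility: MobilityParams
    phi_ac: dict[str, np.ndarray]          # period label -> field
    init: list[InitCenter] = field(default_factory=list)


@dataclass
class ScenarioConfig:
    grid: GridSpec
    land_mask: np.ndarray
    populations: dict[str, PopulationConfig]
    timeline: list[tuple[float, str]]      # (start year, period label), ordered
    t_end: float
    dt: float = 1.0
    spinup_exclude: float = DEFAULT_SPINUP_EXCLUDE
    admixture: AdmixtureConfig | None = None
    smooth_density: bool = True
    snapshot_every: float | None = None
    step_order: str = "motion_first"     # or "demography_first"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.step_order not in ("motion_first", "demography_first"):
            raise ConfigError(f"unknown step_order '{self.step_order}'")
        if not self.timeline:
            raise ConfigError("timeline must contain at least one period")
        starts = [t for t, _ in self.timeline]
        if starts != sorted(starts):
            raise ConfigError("timeline must be ordered by start time")
        for name, pop in self.populations.items():
            for _, period in self.timeline:
                if period not in pop.phi_ac:
                    raise ConfigError(
                        f"population '{name}' lacks a Phi_Ac field for period "
                        f"'{period}'")
            if name not in POP_CODES:
                raise ConfigError(f"unknown population label '{name}'")

    def active_period(self, t: float) -> str:
        period = self.timeline[0][1]
        for start, label in self.timeline:
            if t >= start:
                period = label
        return period


# ---------------------------------------------------------------------------
# Initialization and measurement
# ---------------------------------------------------------------------------

def init_population(centers: list[InitCenter], grid: GridSpec,
                    land_mask: np.ndarray, sigma: float,
                    rng: np.random.Generator, agents: Agents | None = None,
                    pop: int = 0, t: float = 0.0) -> Agents:
    """Place N0 agents per centre, Gaussian in space (std in degrees
    converted to km), resampling draws that land on sea or outside the
    domain so the population size is preserved; initial velocities are
    random directions of magnitude sigma."""
    if agents is None:
        agents = Agents()
    for c in centers:
        cx, cy = grid.lonlat_to_xy(c.lon, c.lat)
        std_km = grid.deg_to_km(c.std_deg)
        # land coverage check around the centre
        probe = rng.normal([cx, cy], std_km * 3, size=(200, 2))
        inside = grid.in_bounds(probe[:, 0], probe[:, 1])
        iy, ix = grid.cell_of(probe[inside, 0], probe[inside, 1])
        frac_land = land_mask[iy, ix].mean() if inside.any() else 0.0
        if frac_land < 0.5:
            warnings.warn(f"centre ({c.lon}, {c.lat}): only {frac_land:.0%} land "
                          "within 3 std", stacklevel=2)
        xs = np.empty(c.n0)
        ys = np.empty(c.n0)
        need = np.arange(c.n0)
        for _ in range(1000):
            draw = rng.normal([cx, cy], std_km, size=(need.size, 2))
            ok = grid.in_bounds(draw[:, 0], draw[:, 1])
            iy, ix = grid.cell_of(draw[ok, 0], draw[ok, 1])
            ok[np.flatnonzero(ok)[~land_mask[iy, ix]]] = False
            xs[need[ok]] = draw[ok, 0]
            ys[need[ok]] = draw[ok, 1]
            need = need[~ok]
            if need.size == 0:
                break
        else:
            raise ParameterError(f"could not place agents near ({c.lon}, {c.lat}); "
                                 "no land within reach")
        theta = rng.uniform(0, 2 * np.pi, c.n0)
        agents.add(pop, xs, ys, sigma * np.cos(theta), sigma * np.sin(theta),
                   birth_time=t)
    return agents


def density_field(agents: Agents, grid: GridSpec, pop: int | None = None,
                  smooth: bool = False) -> np.ndarray:
    """Population density in PDU (humans per 100 km^2): cell count scaled by
    100/cell-area; for 20 km cells this is count/4."""
    idx = np.flatnonzero(agents.alive) if pop is None else agents.alive_of(pop)
    counts = np.zeros(grid.shape)
    iy, ix = grid.cell_of(agents.x[idx], agents.y[idx])
    np.add.at(counts, (iy, ix), 1.0)
    rho = counts * (100.0 / grid.cell_area_km2)
    return smooth_density(rho) if smooth else rho


# ---------------------------------------------------------------------------
# Single simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationOutput:
    times: np.ndarray
    pop_series: dict[str, np.ndarray]      # alive census per step
    snapshots: dict[str, list[tuple[float, np.ndarray]]]
    births: dict[str, int]
    deaths: dict[str, int]
    admixture_births: int
    n_trapped: int
    agents: Agents


def run_simulation(scenario: ScenarioConfig,
                   rng: np.random.Generator | None = None) -> SimulationOutput:
    """Run one member trajectory of a scenario."""
    rng = np.random.default_rng(scenario.seed if rng is None else rng)
    grid, land = scenario.grid, scenario.land_mask
    pops = scenario.populations
    agents = Agents()
    for name, cfg in pops.items():
        init_population(cfg.init, grid, land, cfg.mobility.sigma, rng,
                        agents=agents, pop=POP_CODES[name])

    nt = int(round(scenario.t_end / scenario.dt))
    times = np.arange(nt + 1) * scenario.dt
    series = {name: np.zeros(nt + 1, int) for name in pops}
    snapshots: dict[str, list] = {name: [] for name in pops}
    births = {name: 0 for name in pops}
    deaths = {name: 0 for name in pops}
    adm_births = 0
    n_trapped = 0

    def record(i, t):
        census = agents.census()
        for name in pops:
            series[name][i] = census[name]
        if scenario.snapshot_every is not None and (
                i == nt or t % scenario.snapshot_every < scenario.dt * 0.5):
            for name in pops:
                snapshots[name].append(
                    (t, density_field(agents, grid, POP_CODES[name])))

    record(0, 0.0)
    for i in range(1, nt + 1):
        t = times[i - 1]
        period = scenario.active_period(t)
        # (1)-(2) densities and demography fields per population
        fields = {}
        for name, cfg in pops.items():
            rho = density_field(agents, grid, POP_CODES[name],
                                smooth=scenario.smooth_density)
            rho_c = carrying_capacity(cfg.phi_ac[period], cfg.demography.C)
            f_pa = attractiveness(rho, rho_c, cfg.demography.eps_a,
                                  cfg.demography.eta_a)
            phi_av = available_hep(f_pa, rho_c)
            phi_av[~land] = 0.0
            fields[name] = (rho, rho_c, phi_av)
        # (3) motion, (4) births and deaths (order is a convention; the
        # dynamics at dt = 1 yr are insensitive to swapping, see tests)
        def do_motion():
            nonlocal n_trapped
            for name, cfg in pops.items():
                n_trapped += step_motion(agents, POP_CODES[name],
                                         fields[name][2], land, grid,
                                         cfg.mobility, cfg.demography.C,
                                         scenario.dt, rng)

        def do_demography():
            for name, cfg in pops.items():
                rho, rho_c, _ = fields[name]
                counts = step_births_deaths(agents, POP_CODES[name], rho,
                                            rho_c, cfg.demography, grid,
                                            scenario.dt, rng,
                                            sigma_newborn=cfg.mobility.sigma,
                                            t=t)
                births[name] += counts.births
                deaths[name] += counts.deaths

        if scenario.step_order == "motion_first":
            do_motion()
            do_demography()
        else:
            do_demography()
            do_motion()
        # (5) admixture
        if scenario.admixture is not None and "MIX" in pops:
            cooc = find_cooccupancy(agents, grid)
            adm_births += sample_admixture(
                agents, cooc, scenario.admixture, grid, scenario.dt, rng,
                sigma=pops["MIX"].mobility.sigma, t=t)
        # (6) record
        record(i, times[i])
        if i % 200 == 0:
            agents.compact()

    return SimulationOutput(times, series, snapshots, births, deaths,
                            adm_births, n_trapped, agents)


# ---------------------------------------------------------------------------
# Ensemble runs with parameter perturbation
# ---------------------------------------------------------------------------

#: scalar parameters subject to ensemble perturbation
PERTURBED_DEMOGRAPHY = ("C", "ro", "eta_g", "eps_g", "rho_d")
PERTURBED_MOBILITY = ("alpha", "sigma", "dt_response")


def perturb_scenario(scenario: ScenarioConfig, rng: np.random.Generator,
                     perturb: float = DEFAULT_PERTURBATION,
                     mode: str = "uniform") -> tuple[ScenarioConfig, dict]:
    """One member's parameter draw: every perturbable scalar is multiplied by
    an independent factor from [1-p, 1+p] (or Gaussian with std p). Draws
    violating a parameter invariant are clipped into range and logged."""
    def factor():
        if mode == "uniform":
            return rng.uniform(1.0 - perturb, 1.0 + perturb)
        if mode == "gaussian":
            return 1.0 + perturb * rng.standard_normal()
        raise ConfigError(f"unknown perturbation mode '{mode}'")

    log: dict = {"clipped": []}
    new_pops = {}
    for name, cfg in scenario.populations.items():
        dem_kw = {k: getattr(cfg.demography, k) * factor()
                  for k in PERTURBED_DEMOGRAPHY}
        dem = replace(cfg.demography, **dem_kw)
        mob_kw = {k: getattr(cfg.mobility, k) * factor()
                  for k in PERTURBED_MOBILITY}
        # the damped-velocity step needs gamma*dt <= 1, i.e. tau >= dt
        if mob_kw["dt_response"] < scenario.dt:
            log["clipped"].append((name, "dt_response", mob_kw["dt_response"]))
            mob_kw["dt_response"] = scenario.dt
        mob = replace(cfg.mobility, tau=None, **mob_kw)
        new_pops[name] = replace(cfg, demography=dem, mobility=mob)
        log[name] = {**dem_kw, **mob_kw}
    adm = scenario.admixture
    if adm is not None:
        p = min(adm.p_adm * factor(), 1.0)
        adm = replace(adm, p_adm=p)
        log["p_adm"] = p
    member = replace(scenario, populations=new_pops, admixture=adm)
    return member, log


@dataclass
class EnsembleSummary:
    times: np.ndarray
    member_series: dict[str, np.ndarray]       # (n_members, nt+1)
    mean_series: dict[str, np.ndarray]
    std_series: dict[str, np.ndarray]
    post_spinup_min: dict[str, np.ndarray]     # (n_members,)
    mean_snapshots: dict[str, list[tuple[float, np.ndarray]]]
    member_params: list[dict]
    spinup_exclude: float

    @property
    def n_members(self) -> int:
        return next(iter(self.member_series.values())).shape[0]


def run_ensemble(scenario: ScenarioConfig,
                 n_members: int = DEFAULT_ENSEMBLE_MEMBERS,
                 perturb: float = DEFAULT_PERTURBATION,
                 seed=None, mode: str = "uniform") -> EnsembleSummary:
    """Perturbed-parameter ensemble of scenario runs.

    Per member: draw parameter factors, rerun the scenario (fresh initial
    placement and dynamics under a member-specific seed), and collect the
    population time series and density snapshots; reduce to ensemble
    mean/std and post-spin-up minima.
    """
    if n_members < 1:
        raise ParameterError("n_members must be >= 1")
    ss = np.random.SeedSequence(seed)
    member_seeds = ss.spawn(n_members)
    names = list(scenario.populations)
    member_series = {n: None for n in names}
    snap_acc: dict[str, list] = {}
    member_params = []
    for m in range(n_members):
        rng = np.random.default_rng(member_seeds[m])
        member, log = perturb_scenario(scenario, rng, perturb, mode)
        out = run_simulation(member, rng=rng)
        member_params.append(log)
        for n in names:
            if member_series[n] is None:
                member_series[n] = np.zeros((n_members, len(out.times)))
            member_series[n][m] = out.pop_series[n]
            for k, (t, f) in enumerate(out.snapshots[n]):
                snap_acc.setdefault(n, {})
                snap_acc[n].setdefault(k, [t, np.zeros_like(f)])
                snap_acc[n][k][1] += f

    times = np.arange(member_series[names[0]].shape[1]) * scenario.dt
    post = times >= scenario.spinup_exclude
    mean_snapshots = {
        n: [(t, f / n_members) for t, f in
            (snap_acc[n][k] for k in sorted(snap_acc[n]))]
        for n in snap_acc
    }
    return EnsembleSummary(
        times=times,
        member_series=member_series,
        mean_series={n: member_series[n].mean(axis=0) for n in names},
        std_series={n: member_series[n].std(axis=0) for n in names},
        post_spinup_min={n: member_series[n][:, post].min(axis=1) for n in names},
        mean_snapshots=mean_snapshots,
        member_params=member_params,
        spinup_exclude=scenario.spinup_exclude,
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def rate_of_change(snapshots: list[tuple[float, np.ndarray]],
                   delta: float = 500.0):
    """Per-cell rate of change of ensemble-mean density, PDU/yr:
    (<rho(t+delta)> - <rho(t)>)/delta for every t with a snapshot at
    t+delta. Returns (times, fields)."""
    bytime = {round(t, 9): f for t, f in snapshots}
    times, fields = [], []
    for t, f in snapshots:
        key = round(t + delta, 9)
        if key in bytime:
            times.append(t)
            fields.append((bytime[key] - f) / delta)
    if not times:
        avail = sorted(bytime)
        raise ParameterError(
            f"no snapshot pair separated by {delta} yr; snapshot times: {avail}")
    return np.array(times), fields


def threshold_fractions(minima: np.ndarray, thresholds) -> np.ndarray:
    """Fraction of members whose (post-spin-up) population minimum reached 0
    or fell below each positive threshold."""
    minima = np.asarray(minima, float)
    if minima.size == 0:
        raise ParameterError("empty member window")
    out = []
    for thr in thresholds:
        if thr == 0:
            out.append(np.mean(minima <= 0))
        else:
            out.append(np.mean(minima < thr))
    return np.array(out)
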