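"""Density-dependent demography: carrying capacity, attractiveness,
available HEP, and the stochastic birth-death module.

The local carrying capacity is rho_c = C * Phi_Ac, with C the cultural
carrying capacity in PDU (humans per 100 km^2). Population pressure enters
through a Weibull-shaped attractiveness f_pa of the density-to-capacity
ratio, giving the available HEP Phi_Av = f_pa * rho_c that drives mobility.
Net growth follows the Verhulst equation d(rho)/dt = rho rB (1 - rho/rho_c)
with a density-dependent relative growth rate rB(rho) that turns negative
below a critical density (mating-network collapse, an Allee-type effect):

    rB = ro [ (1 - eta) / (1 + exp(-x)) + eta ],   x = eps * ln(rho / rho_d),

so rB -> eta*ro (< 0) as rho -> 0 and rB -> ro as rho -> infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.special import expit

from .agents import Agents
from .errors import ParameterError, StabilityError
from .landscape_io import GridSpec


@dataclass
class PopulationParams:
    """Demographic constants of one population.

    C        cultural carrying capacity, PDU
    ro       asymptotic relative growth rate, 1/yr
    eta_g    growth-rate floor (rB -> eta_g * ro as rho -> 0), small negative
    eps_g    steepness of the mating-network term, dimensionless
    rho_d    mating-network density scale, PDU
    eps_a    attractiveness (Weibull) scale
    eta_a    attractiveness (Weibull) shape, > 1
    """

    C: float
    ro: float
    eta_g: float = -0.1
    eps_g: float = 2.5
    rho_d: float = 0.05
    eps_a: float = 0.4
    eta_a: float = 1.6

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ParameterError(f"C must be > 0, got {self.C}")
        if self.ro <= 0:
            raise ParameterError(f"ro must be > 0, got {self.ro}")
        if self.eta_g >= 0:
            raise ParameterError(f"eta_g must be < 0, got {self.eta_g}")
        if self.rho_d <= 0:
            raise ParameterError(f"rho_d must be > 0, got {self.rho_d}")
        if self.eps_a <= 0:
            raise ParameterError(f"eps_a must be > 0, got {self.eps_a}")
        if self.eta_a <= 1:
            raise ParameterError(f"eta_a must be > 1, got {self.eta_a}")


def carrying_capacity(phi_ac: np.ndarray, C: float) -> np.ndarray:
    """Local carrying capacity rho_c = C * Phi_Ac, PDU."""
    if C <= 0:
        raise ParameterError(f"C must be > 0, got {C}")
    return C * np.asarray(phi_ac, float)


def attractiveness(rho, rho_c, eps_a: float = 0.4, eta_a: float = 1.6):
    """Weibull attractiveness f_pa = w / w_max in u = (rho/rho_c)/eps_a.

    w(u) = (eta/eps) u^(eta-1) exp(-u^eta); normalization uses the analytic
    maximum at the mode u* = ((eta-1)/eta)^(1/eta). Uninhabitable cells
    (rho_c = 0) get f_pa = 0, as does rho = 0 for eta > 1.
    """
    if eta_a <= 1:
        raise ParameterError(f"eta_a must be > 1, got {eta_a}")
    rho = np.asarray(rho, float)
    rho_c = np.asarray(rho_c, float)
    habitable = rho_c > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(habitable, rho / np.where(habitable, rho_c, 1.0), 0.0) / eps_a
        u_star = ((eta_a - 1.0) / eta_a) ** (1.0 / eta_a)
        # w/wmax = (u/u*)^(eta-1) exp(u*^eta - u^eta)
        ratio = np.where(u > 0, u / u_star, 0.0)
        f = ratio ** (eta_a - 1.0) * np.exp(u_star ** eta_a - np.where(u > 0, u, 0.0) ** eta_a)
    f = np.where(habitable, f, 0.0)
    out = np.clip(f, 0.0, 1.0)
    return out if out.ndim else float(out)


def available_hep(f_pa: np.ndarray, rho_c: np.ndarray) -> np.ndarray:
    """Available HEP Phi_Av = f_pa * rho_c; ranges over [0, C]."""
    return np.asarray(f_pa, float) * np.asarray(rho_c, float)


def growth_rate_rb(rho, ro: float, eta_g: float = -0.1, eps_g: float = 2.5,
                   rho_d: float = 0.05):
    """Density-dependent relative growth rate rB(rho), 1/yr.

    Monotone nondecreasing in rho; rB(0) = eta_g * ro by continuity.
    """
    rho = np.asarray(rho, float)
    with np.errstate(divide="ignore"):
        x = eps_g * np.log(np.where(rho > 0, rho, 1.0) / rho_d)
    sig = np.where(rho > 0, expit(x), 0.0)
    out = ro * ((1.0 - eta_g) * sig + eta_g)
    return out if out.ndim else float(out)


def smooth_density(rho: np.ndarray) -> np.ndarray:
    """One pass of a 3x3 uniform kernel (stabilizes gradients at 20 km)."""
    return uniform_filter(rho, size=3, mode="nearest")


@dataclass
class BirthDeathCounts:
    births: int
    deaths: int


def step_births_deaths(agents: Agents, pop: int, rho: np.ndarray,
                       rho_c: np.ndarray, params: PopulationParams,
                       grid: GridSpec, dt: float,
                       rng: np.random.Generator,
                       sigma_newborn: float = 15.0,
                       t: float = 0.0) -> BirthDeathCounts:
    """One birth-death step for one population.

    Per cell the net per-capita rate is g = rB(rho) (1 - rho/rho_c); each
    alive agent gives birth with probability g*dt when g >= 0 (newborn at the
    parent's position with a random velocity of magnitude sigma) or dies with
    probability -g*dt when g < 0, so the expected net change follows the
    Verhulst equation. Where rho_c = 0 but agents are present, the crowding
    factor is clamped at -1 (maximal per-capita death hazard rB*dt).
    """
    idx = agents.alive_of(pop)
    if idx.size == 0:
        return BirthDeathCounts(0, 0)
    rb = growth_rate_rb(rho, params.ro, params.eta_g, params.eps_g, params.rho_d)
    habitable = rho_c > 0
    crowding = np.where(habitable,
                        1.0 - rho / np.where(habitable, rho_c, 1.0), -1.0)
    crowding = np.maximum(crowding, -1.0)
    g = rb * crowding
    if np.max(np.abs(g)) * dt > 0.5:
        raise StabilityError(
            f"dt*|g| = {np.max(np.abs(g)) * dt:.3f} > 0.5; reduce dt")

    iy, ix = grid.cell_of(agents.x[idx], agents.y[idx])
    ga = g[iy, ix]
    draw = rng.random(idx.size)

    die = (ga < 0) & (draw < -ga * dt)
    agents.kill(idx[die])

    born = (ga >= 0) & (draw < ga * dt)
    n_born = int(born.sum())
    if n_born:
        parents = idx[born]
        theta = rng.uniform(0, 2 * np.pi, n_born)
        agents.add(pop, agents.x[parents], agents.y[parents],
                   sigma_newborn * np.cos(theta), sigma_newborn * np.sin(theta),
                   birth_time=t)
    return BirthDeathCounts(n_born, int(die.sum()))
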