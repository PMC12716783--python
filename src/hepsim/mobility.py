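"""Constrained random-walk mobility: gradient drift plus damped noise.

Each agent's velocity follows a Langevin (Ornstein-Uhlenbeck) equation
forced by the gradient of the available HEP,

    dU = ( (alpha/C) grad(Phi_Av) - gamma U ) dt + beta dW,
    dX = U dt,

integrated with Euler-Maruyama. The drift coefficient alpha = Us*Gd/Dt
links a scaling migration speed Us (km/yr), a drift distance scale Gd (km)
and a response time Dt (yr); dividing by the cultural carrying capacity C
makes the steady drift speed equal Us exactly when |grad Phi_Av| = C/Gd
(with tau = Dt). The damping gamma = 1/tau and noise amplitude
beta = sigma*sqrt(2*gamma) give a stationary per-axis velocity standard
deviation of exactly sigma. Coastlines and the domain boundary are
symmetric-reflective; the available HEP of sea cells is zero, so the drift
also pushes agents back inland.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .agents import Agents
from .errors import ParameterError, StabilityError
from .landscape_io import GridSpec


def drift_coefficient(us: float, gd: float, dt_response: float) -> float:
    """alpha = Us * Gd / Dt, km^2/yr^2."""
    if us <= 0 or gd <= 0 or dt_response <= 0:
        raise ParameterError(
            f"Us, Gd, Dt must all be > 0, got ({us}, {gd}, {dt_response})")
    return us * gd / dt_response


def ou_coefficients(sigma: float, tau: float,
                    convention: str = "stationary") -> tuple[float, float]:
    """Damping gamma = 1/tau and noise amplitude beta.

    The default 'stationary' convention sets beta = sigma*sqrt(2*gamma) so
    the stationary per-axis velocity variance of the damped process is
    exactly sigma^2. The 'literal' convention beta = sigma^2*gamma is kept
    switchable for comparison (it is not dimensionally consistent with a
    Wiener forcing and is not used by default).
    """
    if sigma <= 0 or tau <= 0:
        raise ParameterError("sigma and tau must be > 0")
    gamma = 1.0 / tau
    if convention == "stationary":
        beta = sigma * np.sqrt(2.0 * gamma)
    elif convention == "literal":
        beta = sigma ** 2 * gamma
    else:
        raise ParameterError(f"unknown beta convention '{convention}'")
    return gamma, beta


@dataclass
class MobilityParams:
    """Mobility constants of one population.

    With the defaults Us = 2.5 km/yr, Gd = 500 km, Dt = 1 yr the derived
    drift coefficient is alpha = 1250 km^2/yr^2; sigma = 15 km/yr; the
    Lagrangian time scale tau equals Dt unless set explicitly.
    """

    us: float = 2.5                 # scaling drift velocity, km/yr
    gd: float = 500.0               # drift distance scale, km
    dt_response: float = 1.0        # response time Dt, yr
    sigma: float = 15.0             # random-velocity std, km/yr
    alpha: float | None = None      # km^2/yr^2; derived from Us*Gd/Dt if None
    tau: float | None = None        # yr; = Dt if None
    dt: float = 1.0                 # integration step, yr
    beta_convention: str = "stationary"

    def __post_init__(self) -> None:
        if self.alpha is None:
            self.alpha = drift_coefficient(self.us, self.gd, self.dt_response)
        if self.tau is None:
            self.tau = self.dt_response
        if self.alpha <= 0 or self.sigma <= 0 or self.tau <= 0 or self.dt <= 0:
            raise ParameterError("alpha, sigma, tau, dt must all be > 0")
        if self.gamma * self.dt > 1.0 + 1e-12:
            raise StabilityError(
                f"gamma*dt = {self.gamma * self.dt:.3f} > 1: unstable; "
                "reduce dt or increase tau")

    @property
    def gamma(self) -> float:
        return 1.0 / self.tau

    @property
    def beta(self) -> float:
        return ou_coefficients(self.sigma, self.tau, self.beta_convention)[1]


# ---------------------------------------------------------------------------
# Gradient of the available HEP
# ---------------------------------------------------------------------------

def phi_av_gradient_fields(phi_av: np.ndarray, grid: GridSpec,
                           land_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centred (d/dx, d/dy) of Phi_Av with sea cells treated as 0.

    Central finite differences in the interior (one-sided at the domain
    edges); because sea carries Phi_Av = 0 the coastal gradient points
    inland toward higher Phi_Av.
    """
    phi = np.where(land_mask, phi_av, 0.0)
    if np.isnan(phi).any():
        bad = np.argwhere(np.isnan(phi))[0]
        raise ParameterError(f"NaN in Phi_Av at cell (iy={bad[0]}, ix={bad[1]})")
    gy, gx = np.gradient(phi, grid.cell_size)
    return gx, gy


def phi_av_gradient(phi_av: np.ndarray, grid: GridSpec, land_mask: np.ndarray,
                    x, y) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of Phi_Av bilinearly interpolated to agent positions."""
    inside = grid.in_bounds(x, y)
    if not np.all(inside):
        raise ParameterError("position off-grid in phi_av_gradient")
    gx, gy = phi_av_gradient_fields(phi_av, grid, land_mask)
    return (_interp(gx, grid, x, y), _interp(gy, grid, x, y))


def _interp(field: np.ndarray, grid: GridSpec, x, y) -> np.ndarray:
    rows = (np.asarray(y, float) - grid.origin_y) / grid.cell_size - 0.5
    cols = (np.asarray(x, float) - grid.origin_x) / grid.cell_size - 0.5
    return map_coordinates(field, [np.atleast_1d(rows), np.atleast_1d(cols)],
                           order=1, mode="nearest")


# ---------------------------------------------------------------------------
# Motion step and reflection
# ---------------------------------------------------------------------------

def step_motion(agents: Agents, pop: int, phi_av: np.ndarray,
                land_mask: np.ndarray, grid: GridSpec,
                params: MobilityParams, C: float, dt: float,
                rng: np.random.Generator) -> int:
    """One Euler-Maruyama velocity/position update plus boundary reflection
    for the alive agents of one population. Returns the number of agents
    that needed the trapped-agent fallback."""
    idx = agents.alive_of(pop)
    if idx.size == 0:
        return 0
    gx, gy = phi_av_gradient_fields(phi_av, grid, land_mask)
    ax = (params.alpha / C) * _interp(gx, grid, agents.x[idx], agents.y[idx])
    ay = (params.alpha / C) * _interp(gy, grid, agents.x[idx], agents.y[idx])
    gamma, beta = params.gamma, params.beta
    noise = rng.standard_normal((2, idx.size)) * beta * np.sqrt(dt)
    u = agents.u[idx] + (ax - gamma * agents.u[idx]) * dt + noise[0]
    v = agents.v[idx] + (ay - gamma * agents.v[idx]) * dt + noise[1]
    x_old, y_old = agents.x[idx].copy(), agents.y[idx].copy()
    x = x_old + u * dt
    y = y_old + v * dt
    x, y, u, v, n_trapped = reflect_positions(x, y, u, v, x_old, y_old,
                                              land_mask, grid)
    agents.x[idx], agents.y[idx] = x, y
    agents.u[idx], agents.v[idx] = u, v
    return n_trapped


def reflect_positions(x, y, u, v, x_old, y_old, land_mask: np.ndarray,
                      grid: GridSpec):
    """Mirror moves ending at sea or outside the domain back across the
    crossed edge, negating the normal velocity component.

    Domain edges fold like a billiard (repeatedly for large steps). A move
    into a sea cell is mirrored across the edge(s) of the departure cell
    that the move crossed; if the mirrored position is still invalid (e.g. a
    one-cell channel), the agent reverts to its pre-move position with fully
    reversed velocity. Returns (x, y, u, v, n_fallback).
    """
    x, y = np.array(x, float), np.array(y, float)
    u, v = np.array(u, float), np.array(v, float)
    x0, x1 = grid.origin_x, grid.x_max
    y0, y1 = grid.origin_y, grid.y_max

    # fold into the domain box
    for _ in range(100):
        out = (x < x0) | (x >= x1) | (y < y0) | (y >= y1)
        if not out.any():
            break
        lo = x < x0
        x[lo] = 2 * x0 - x[lo]
        u[lo] = -u[lo]
        hi = x >= x1
        x[hi] = 2 * x1 - x[hi]
        u[hi] = -u[hi]
        lo = y < y0
        y[lo] = 2 * y0 - y[lo]
        v[lo] = -v[lo]
        hi = y >= y1
        y[hi] = 2 * y1 - y[hi]
        v[hi] = -v[hi]
        # exact landing on the open upper edge after mirroring
        x[x >= x1] = np.nextafter(x1, -np.inf)
        y[y >= y1] = np.nextafter(y1, -np.inf)
    else:
        bad = (x < x0) | (x >= x1) | (y < y0) | (y >= y1)
        x[bad], y[bad] = x_old[bad], y_old[bad]
        u[bad], v[bad] = -u[bad], -v[bad]

    iy, ix = grid.cell_of(x, y)
    wet = ~land_mask[iy, ix]
    n_trapped = 0
    if wet.any():
        w = np.flatnonzero(wet)
        iy0, ix0 = grid.cell_of(x_old[w], y_old[w])
        xw, yw, uw, vw = x[w].copy(), y[w].copy(), u[w].copy(), v[w].copy()
        # mirror across the departure-cell edge crossed along each axis
        moved_col = ix[w] != ix0
        dx_dir = xw > x_old[w]
        edge_x = grid.origin_x + (ix0 + np.where(dx_dir, 1, 0)) * grid.cell_size
        xw = np.where(moved_col, 2 * edge_x - xw, xw)
        uw = np.where(moved_col, -uw, uw)
        moved_row = iy[w] != iy0
        dy_dir = yw > y_old[w]
        edge_y = grid.origin_y + (iy0 + np.where(dy_dir, 1, 0)) * grid.cell_size
        yw = np.where(moved_row, 2 * edge_y - yw, yw)
        vw = np.where(moved_row, -vw, vw)
        iyw, ixw = grid.cell_of(xw, yw)
        ok = (grid.in_bounds(xw, yw)
              & land_mask[np.clip(iyw, 0, grid.ny - 1), np.clip(ixw, 0, grid.nx - 1)])
        # fallback: revert and reverse
        xw = np.where(ok, xw, x_old[w])
        yw = np.where(ok, yw, y_old[w])
        uw = np.where(ok, uw, -u[w])
        vw = np.where(ok, vw, -v[w])
        n_trapped = int(np.sum(~ok))
        x[w], y[w], u[w], v[w] = xw, yw, uw, vw
    return x, y, u, v, n_trapped


def reflect_boundaries(agents: Agents, land_mask: np.ndarray, grid: GridSpec,
                       x_old: np.ndarray, y_old: np.ndarray) -> int:
    """In-place boundary reflection for all alive agents (see
    :func:`reflect_positions`); ``x_old``/``y_old`` are the pre-move
    positions of the alive agents in index order."""
    idx = np.flatnonzero(agents.alive)
    x, y, u, v, n = reflect_positions(
        agents.x[idx], agents.y[idx], agents.u[idx], agents.v[idx],
        x_old, y_old, land_mask, grid)
    agents.x[idx], agents.y[idx] = x, y
    agents.u[idx], agents.v[idx] = u, v
    return n
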