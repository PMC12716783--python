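"""Neanderthal-modern-human admixture under the weakly-interactive scenario.

When NEA and AMH agents co-occupy a grid cell, each cross pair may produce
an admixed (MIX) newborn with a small probability per year (default 1%).
MIX individuals thereafter grow and disperse with their own demographic
parameters but never themselves admix (single-generation crossing), and
their accessible HEP is the arithmetic mean of the parental Phi_Ac fields.
The event unit of the probability is configurable: per cross pair (default,
scales with both local densities), per AMH agent, or per co-occupied cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import AMH, MIX, NEA, Agents
from .errors import ConfigError, ParameterError
from .landscape_io import GridSpec


@dataclass
class AdmixtureConfig:
    """p_adm: probability per eligible event per year; single_generation:
    MIX offspring never admix further."""

    p_adm: float = 0.01
    event_unit: str = "pair"        # pair | per_amh | per_cell
    single_generation: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_adm <= 1.0:
            raise ParameterError(f"p_adm must be in [0, 1], got {self.p_adm}")
        if self.event_unit not in ("pair", "per_amh", "per_cell"):
            raise ParameterError(f"unknown event_unit '{self.event_unit}'")


@dataclass
class CooccupancyRecord:
    iy: np.ndarray
    ix: np.ndarray
    n_nea: np.ndarray
    n_amh: np.ndarray

    def __len__(self) -> int:
        return len(self.iy)


def find_cooccupancy(agents: Agents, grid: GridSpec) -> CooccupancyRecord:
    """Cells holding at least one alive NEA and one alive AMH agent."""
    counts = {}
    for pop in (NEA, AMH):
        idx = agents.alive_of(pop)
        c = np.zeros(grid.shape, int)
        iy, ix = grid.cell_of(agents.x[idx], agents.y[idx])
        np.add.at(c, (iy, ix), 1)
        counts[pop] = c
    both = (counts[NEA] > 0) & (counts[AMH] > 0)
    iy, ix = np.nonzero(both)
    return CooccupancyRecord(iy, ix, counts[NEA][iy, ix], counts[AMH][iy, ix])


def eligible_events(cooc: CooccupancyRecord, cfg: AdmixtureConfig) -> np.ndarray:
    """Number of eligible admixture events per co-occupied cell."""
    if cfg.event_unit == "pair":
        return cooc.n_nea * cooc.n_amh
    if cfg.event_unit == "per_amh":
        return cooc.n_amh.copy()
    return np.ones(len(cooc), int)


def sample_admixture(agents: Agents, cooc: CooccupancyRecord,
                     cfg: AdmixtureConfig, grid: GridSpec, dt: float,
                     rng: np.random.Generator, sigma: float = 15.0,
                     t: float = 0.0) -> int:
    """Draw MIX births from the co-occupancy record and append the newborns.

    Each eligible event independently yields one MIX newborn with
    probability p_adm * dt; newborns are placed at the cell centre with a
    random velocity of magnitude sigma. Returns the number of MIX births.
    """
    if cfg.p_adm * dt > 1.0:
        raise ConfigError(f"p_adm*dt = {cfg.p_adm * dt} > 1; reduce dt")
    if len(cooc) == 0 or cfg.p_adm == 0.0:
        return 0
    events = eligible_events(cooc, cfg)
    births = rng.binomial(events, cfg.p_adm * dt)
    total = int(births.sum())
    if total == 0:
        return 0
    cx = grid.origin_x + (np.repeat(cooc.ix, births) + 0.5) * grid.cell_size
    cy = grid.origin_y + (np.repeat(cooc.iy, births) + 0.5) * grid.cell_size
    theta = rng.uniform(0, 2 * np.pi, total)
    agents.add(MIX, cx, cy, sigma * np.cos(theta), sigma * np.sin(theta),
               birth_time=t)
    return total


def mix_accessible_hep(phi_ac_nea: np.ndarray, phi_ac_amh: np.ndarray) -> np.ndarray:
    """Accessible HEP of the MIX population: pointwise parental mean."""
    a = np.asarray(phi_ac_nea, float)
    b = np.asarray(phi_ac_amh, float)
    if a.shape != b.shape:
        raise ParameterError("parental Phi_Ac fields differ in shape")
    return 0.5 * (a + b)
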