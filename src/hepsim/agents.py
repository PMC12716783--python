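"""Struct-of-arrays agent container shared by the mobility, demography,
admixture and engine modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NEA, AMH, MIX = 0, 1, 2
POP_NAMES = {NEA: "NEA", AMH: "AMH", MIX: "MIX"}
POP_CODES = {v: k for k, v in POP_NAMES.items()}


@dataclass
class Agents:
    """Individual humans: position/velocity in km and km/yr, population label,
    birth time, and an alive flag. Dead agents remain in the arrays until
    :meth:`compact` is called; all per-step operations act on alive agents."""

    agent_id: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    population: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    x: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    y: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    u: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    v: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    birth_time: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    alive: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    _next_id: int = 0

    def __len__(self) -> int:
        return len(self.agent_id)

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def alive_of(self, pop: int) -> np.ndarray:
        """Indices of alive agents of one population."""
        return np.flatnonzero(self.alive & (self.population == pop))

    def census(self) -> dict[str, int]:
        return {name: int(np.sum(self.alive & (self.population == code)))
                for code, name in POP_NAMES.items()}

    def add(self, pop, x, y, u, v, birth_time=0.0) -> np.ndarray:
        """Append newborn agents; returns their indices."""
        n = len(np.atleast_1d(x))
        ids = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n
        self.agent_id = np.concatenate([self.agent_id, ids])
        self.population = np.concatenate(
            [self.population, np.full(n, pop, np.int8)])
        self.x = np.concatenate([self.x, np.atleast_1d(np.asarray(x, float))])
        self.y = np.concatenate([self.y, np.atleast_1d(np.asarray(y, float))])
        self.u = np.concatenate([self.u, np.atleast_1d(np.asarray(u, float))])
        self.v = np.concatenate([self.v, np.atleast_1d(np.asarray(v, float))])
        self.birth_time = np.concatenate(
            [self.birth_time, np.full(n, birth_time, float)])
        self.alive = np.concatenate([self.alive, np.ones(n, bool)])
        return np.arange(len(self.agent_id) - n, len(self.agent_id))

    def kill(self, idx: np.ndarray) -> None:
        self.alive[idx] = False

    def compact(self) -> None:
        """Drop dead agents from the arrays."""
        keep = self.alive
        for name in ("agent_id", "population", "x", "y", "u", "v",
                     "birth_time", "alive"):
            setattr(self, name, getattr(self, name)[keep])
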