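"""Stochastic spatially explicit lattice model of the BVOC emission game.

A periodic L×L square lattice whose sites are vacant, occupied by a BVOC
emitter, or occupied by a non-emitter. Each synchronous generation:

1. fitness is computed at every occupied site from the number of emitters
   within the Moore signaling radius ``r_bvoc`` (focal plant excluded);
2. every occupied site dies independently with probability ``d``, and a
   dead plant contributes no seeds this step;
3. every vacant site — pre-existing or newly vacated — is colonized by an
   emitter or a non-emitter with probabilities proportional to the summed
   fitness of each strategy within the Moore dispersal radius ``r_d``; a
   vacant site with no occupied neighbor in range stays vacant.

Neighborhood sums use periodic (torus) wrapping; the neighborhood metric is
the Chebyshev distance. Coordinates are 0-based, row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import fitness_emitter, fitness_nonemitter, gross_inter_effect_local
from .params import ModelParams, SimConfig

__all__ = [
    "VACANT", "EMITTER", "NONEMITTER",
    "LatticeState", "Trajectory",
    "moore_neighborhood", "count_emitters_in_range",
    "compute_fitness_field", "colonization_probabilities",
    "step", "init_lattice", "emitter_frequency", "run_simulation",
]

VACANT = 0
EMITTER = 1
NONEMITTER = 2

_STATE_CHARS = {VACANT: "0", EMITTER: "E", NONEMITTER: "N"}
_CHAR_STATES = {v: k for k, v in _STATE_CHARS.items()}


@dataclass
class LatticeState:
    """Periodic grid of three-valued sites plus a generation counter."""

    sites: np.ndarray  # int8 array, values in {VACANT, EMITTER, NONEMITTER}
    step_index: int = 0

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=np.int8)
        if self.sites.ndim != 2 or self.sites.shape[0] != self.sites.shape[1]:
            raise ValueError("sites must be a square 2-D array")
        if not np.isin(self.sites, (VACANT, EMITTER, NONEMITTER)).all():
            raise ValueError("sites contain values outside {vacant, emitter, non-emitter}")

    @property
    def L(self) -> int:
        return self.sites.shape[0]

    def counts(self) -> tuple[int, int, int]:
        """(n_emitter, n_nonemitter, n_vacant)."""
        e = int(np.count_nonzero(self.sites == EMITTER))
        n = int(np.count_nonzero(self.sites == NONEMITTER))
        return e, n, self.sites.size - e - n

    def to_text(self) -> str:
        """Plain-text grid of {E, N, 0}, one row per line."""
        lut = np.array([_STATE_CHARS[VACANT], _STATE_CHARS[EMITTER],
                        _STATE_CHARS[NONEMITTER]])
        return "\n".join("".join(row) for row in lut[self.sites])

    @classmethod
    def from_text(cls, text: str, step_index: int = 0) -> "LatticeState":
        rows = [[_CHAR_STATES[ch] for ch in line]
                for line in text.strip().splitlines()]
        return cls(np.array(rows, dtype=np.int8), step_index)


@dataclass
class Trajectory:
    """Per-step strategy counts of one simulation run.

    ``counts`` has one row per recorded state (initial state included) and
    columns (n_emitter, n_nonemitter, n_vacant) summing to L² everywhere.
    ``final_frequency`` is the emitter share among occupied sites of the
    final state — measured after colonization, before the next mortality
    event, so the lattice is near-fully occupied at measurement.
    """

    counts: np.ndarray  # shape (n_recorded, 3)
    steps_recorded: np.ndarray  # step index of each row
    final_state: LatticeState
    final_frequency: float  # nan if the population went extinct
    extinct: bool
    rng_seed: int
    config: Optional[SimConfig] = None

    @property
    def emitters_extinct(self) -> bool:
        return self.extinct or self.counts[-1, 0] == 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": self.steps_recorded,
            "n_emitter": self.counts[:, 0],
            "n_nonemitter": self.counts[:, 1],
            "n_vacant": self.counts[:, 2],
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _check_radius(r: int, L: int) -> None:
    if r < 1:
        raise ValueError(f"radius r={r!r} must be >= 1")
    if r >= L / 2:
        raise ValueError(
            f"radius r={r} >= L/2 = {L / 2}: periodic wraparound would "
            "double-count sites"
        )


def moore_neighborhood(i: int, j: int, r: int, L: int) -> set[tuple[int, int]]:
    """All sites within Chebyshev distance r of (i, j) on the L×L torus.

    Includes the focal site itself; cardinality (2r+1)². Callers decide
    whether to exclude the focal site.
    """
    _check_radius(r, L)
    if not (0 <= i < L and 0 <= j < L):
        raise ValueError(f"site ({i}, {j}) outside an {L}x{L} lattice")
    return {
        ((i + di) % L, (j + dj) % L)
        for di in range(-r, r + 1)
        for dj in range(-r, r + 1)
    }


def _neighborhood_sum(arr: np.ndarray, r: int) -> np.ndarray:
    """Sum of ``arr`` over the Moore-r neighborhood of every site (torus)."""
    kernel = np.ones((2 * r + 1, 2 * r + 1), dtype=arr.dtype)
    return ndimage.convolve(arr, kernel, mode="wrap")


def count_emitters_in_range(
    state: LatticeState, i: int, j: int, r_bvoc: int,
    include_self: bool = False,
) -> int:
    """Number of emitters within the Moore ``r_bvoc`` range of site (i, j).

    The focal site is excluded by default: its own signal is already
    accounted for by the intra-communication effect.
    """
    coords = moore_neighborhood(i, j, r_bvoc, state.L)
    if not include_self:
        coords = coords - {(i, j)}
    return int(sum(state.sites[ci, cj] == EMITTER for ci, cj in coords))


def compute_fitness_field(
    state: LatticeState, params: ModelParams, include_self: bool = False,
) -> np.ndarray:
    """Fitness of every site: f_E at emitter sites, f_N at non-emitter
    sites (same gross inter-communication effect alpha2**M), 0 at vacant
    sites."""
    _check_radius(params.r_bvoc, state.L)
    emit = state.sites == EMITTER
    non = state.sites == NONEMITTER
    m = _neighborhood_sum(emit.astype(np.int32), params.r_bvoc)
    if not include_self:
        m = m - emit  # focal emitter's own signal is the intra effect
    gross = gross_inter_effect_local(m, params.alpha2)
    f_e = fitness_emitter(params.alpha1, gross, params.p, params.c, params.fhat)
    f_n = fitness_nonemitter(gross, params.p, params.fhat)
    return np.where(emit, f_e, np.where(non, f_n, 0.0))


def colonization_probabilities(
    state: LatticeState, fitness: np.ndarray, i: int, j: int, r_d: int,
) -> tuple[float, float]:
    """(P(vacant -> emitter), P(vacant -> non-emitter)) for site (i, j).

    Each probability is the strategy's share of the total fitness (seed
    pool) within the Moore ``r_d`` dispersal range. They sum to 1 whenever
    any occupied site is in range; both are 0 when the pool is empty, in
    which case the site remains vacant.
    """
    if state.sites[i, j] != VACANT:
        raise ValueError(f"site ({i}, {j}) is not vacant")
    coords = moore_neighborhood(i, j, r_d, state.L)
    f_e = sum(fitness[ci, cj] for ci, cj in coords
              if state.sites[ci, cj] == EMITTER)
    f_n = sum(fitness[ci, cj] for ci, cj in coords
              if state.sites[ci, cj] == NONEMITTER)
    total = f_e + f_n
    if total <= 0.0:
        return 0.0, 0.0
    return f_e / total, f_n / total


def step(state: LatticeState, params: ModelParams,
         rng: np.random.Generator) -> LatticeState:
    """One synchronous generation: fitness, mortality, colonization.

    Fitness is evaluated on the pre-mortality state; plants that die this
    step contribute nothing to any dispersal pool; sites vacated this step
    are immediately eligible for colonization. All colonization draws read
    the same post-mortality state (synchronous update).
    """
    _check_radius(params.r_d, state.L)
    sites = state.sites
    fitness = compute_fitness_field(state, params)

    occupied = sites != VACANT
    deaths = occupied & (rng.random(sites.shape) < params.d)
    survivors = np.where(deaths, VACANT, sites).astype(np.int8)
    fitness = np.where(deaths, 0.0, fitness)

    pool_e = _neighborhood_sum(np.where(survivors == EMITTER, fitness, 0.0),
                               params.r_d)
    pool_n = _neighborhood_sum(np.where(survivors == NONEMITTER, fitness, 0.0),
                               params.r_d)
    total = pool_e + pool_n

    colonizable = (survivors == VACANT) & (total > 0.0)
    u = rng.random(sites.shape)
    new_sites = survivors.copy()
    # One categorical draw per vacant site: emitter with probability
    # pool_e / total, otherwise non-emitter (the two shares sum to 1).
    with np.errstate(invalid="ignore", divide="ignore"):
        p_e = np.where(total > 0.0, pool_e / np.where(total > 0.0, total, 1.0), 0.0)
    new_sites[colonizable & (u < p_e)] = EMITTER
    new_sites[colonizable & (u >= p_e)] = NONEMITTER
    return LatticeState(new_sites, state.step_index + 1)


def init_lattice(
    L: int,
    density_emitter: float,
    density_nonemitter: float,
    rng: np.random.Generator,
) -> LatticeState:
    """Seed each site independently: emitter w.p. ``density_emitter``,
    non-emitter w.p. ``density_nonemitter``, else vacant."""
    if density_emitter < 0 or density_nonemitter < 0:
        raise ValueError("initial densities must be nonnegative")
    if density_emitter + density_nonemitter > 1:
        raise ValueError("initial densities must sum to <= 1")
    u = rng.random((L, L))
    sites = np.full((L, L), VACANT, dtype=np.int8)
    sites[u < density_emitter] = EMITTER
    sites[(u >= density_emitter)
          & (u < density_emitter + density_nonemitter)] = NONEMITTER
    return LatticeState(sites, 0)


def emitter_frequency(state: LatticeState) -> float:
    """Emitter share among occupied sites."""
    e, n, _ = state.counts()
    if e + n == 0:
        raise ValueError("emitter frequency is undefined on an all-vacant lattice")
    return e / (e + n)


def run_simulation(config: SimConfig,
                   rng: Optional[np.random.Generator] = None) -> Trajectory:
    """Run one lattice simulation and record strategy counts over time.

    Fully reproducible from ``config.seed`` (or a caller-supplied
    generator, for replicate substreams). If the whole population goes
    extinct the run terminates early with the extinction flag set.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = init_lattice(config.L, config.density_emitter,
                         config.density_nonemitter, rng)
    counts = [state.counts()]
    recorded = [0]
    extinct = state.sites.max() == VACANT
    for t in range(1, config.steps + 1):
        if extinct:
            break
        state = step(state, config.params, rng)
        if t % config.record_every == 0 or t == config.steps:
            counts.append(state.counts())
            recorded.append(t)
        e, n, _ = state.counts()
        if e + n == 0:
            extinct = True
    final_freq = float("nan") if extinct else emitter_frequency(state)
    return Trajectory(
        counts=np.asarray(counts, dtype=np.int64),
        steps_recorded=np.asarray(recorded, dtype=np.int64),
        final_state=state,
        final_frequency=final_freq,
        extinct=extinct,
        rng_seed=config.seed,
        config=config,
    )
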