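"""Disturbance simulation: rarefaction of functional entities to collapse.

A community is disturbed in successive steps until no species remains.
After each step the fraction of the community disturbed (x) and the
fraction of functional entities still occupied (y) are recorded, giving a
rarefaction curve from (0, 1) to (1, 0).

Three disturbance regimes:

* ``abundance`` — each step removes a fixed budget of 5% (configurable) of
  the community's *initial* total abundance.  Two allocation rules are
  offered.  ``species`` (default) repeatedly draws an extant species
  uniformly at random and removes as much of its abundance as the
  remaining budget allows, so every step removes exactly the budget.
  ``individual`` removes the budget one individual at a time, each drawn
  uniformly from the surviving individuals (weight-proportional species
  selection); this is classical rarefaction of individuals, and its
  expected curve is invariant to how the budget is chunked into steps by
  construction.  Under the ``species`` rule the step size mildly shapes
  the expected curve for uneven communities, because a small budget only
  nibbles at whichever species it lands on.
* ``occurrence`` — each step drives a configurable number (default 1) of
  uniformly chosen extant species extinct.
* ``suitability`` — each step deterministically lowers every extant
  species' habitat suitability by a fixed decrement (default 0.05, i.e. 5%
  of the maximal suitability 1).

A species is extinct once its weight drops to ~0 (1e-12 absolute).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .communities import CommunityState
from .trait_space import FunvulError

logger = logging.getLogger("funvul")

EXTINCTION_EPS = 1e-12


@dataclass
class DisturbanceConfig:
    mode: str = "abundance"
    decrement_frac: float = 0.05  # fraction of initial total abundance per step
    suitability_decrement: float = 0.05  # absolute decrement per step
    species_per_step: int = 1  # occurrence mode
    replicates: int = 99
    seed: int = 0
    allocation: str = "species"  # abundance budget rule: species | individual

    def __post_init__(self) -> None:
        if self.allocation not in ("species", "individual"):
            raise FunvulError("allocation must be 'species' or 'individual'")
        if not (0 < self.decrement_frac <= 1):
            raise FunvulError("decrement fraction must be in (0, 1]")
        if not (0 < self.suitability_decrement <= 1):
            raise FunvulError("suitability decrement must be in (0, 1]")
        if self.species_per_step < 1:
            raise FunvulError("species_per_step must be >= 1")
        if self.replicates < 1:
            raise FunvulError("replicates must be >= 1")


@dataclass
class RarefactionCurve:
    """Normalized (fraction disturbed, fraction of entities surviving) trajectory."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise FunvulError("curve x/y must be 1-D and aligned")
        if self.x[0] != 0 or self.y[0] != 1:
            raise FunvulError("curve must start at (0, 1)")
        if np.any(np.diff(self.y) > 1e-12):
            raise FunvulError("curve y must be non-increasing")
        if np.any(np.diff(self.x) < -1e-12):
            raise FunvulError("curve x must be non-decreasing")
        if abs(self.x[-1] - 1.0) > 1e-9 or self.y[-1] != 0:
            raise FunvulError("curve must end at (1, 0)")

    def __len__(self) -> int:
        return len(self.x)


# ---------------------------------------------------------------------------
# Internal mutable simulation state (array-based, fast path)
# ---------------------------------------------------------------------------


class _SimState:
    """Weights + entity occupancy bookkeeping for one realization."""

    __slots__ = ("w", "entity_of", "entity_count", "n_occ", "alive", "n_alive")

    def __init__(self, state: CommunityState):
        self.w = state.weights.copy()
        cells = sorted(state.occupied_cells)
        cell_index = {c: i for i, c in enumerate(cells)}
        self.entity_of = np.array([cell_index[c] for c in state.cells])
        self.entity_count = np.bincount(self.entity_of, minlength=len(cells))
        self.n_occ = len(cells)
        self.alive = list(range(len(self.w)))
        self.n_alive = len(self.w)

    def kill(self, pos: int) -> None:
        """Remove alive[pos]; swap-pop keeps the draw O(1)."""
        i = self.alive[pos]
        self.alive[pos] = self.alive[-1]
        self.alive.pop()
        self.n_alive -= 1
        e = self.entity_of[i]
        self.entity_count[e] -= 1
        if self.entity_count[e] == 0:
            self.n_occ -= 1


def _step(sim: _SimState, cfg: DisturbanceConfig, rng: np.random.Generator,
          budget0: float) -> float:
    """One disturbance step; returns the weight removed."""
    if sim.n_alive == 0:
        raise FunvulError("disturbance step on an empty community")
    removed = 0.0
    if cfg.mode == "abundance":
        budget = budget0
        while budget > EXTINCTION_EPS and sim.n_alive > 0:
            pos = int(rng.integers(sim.n_alive))
            i = sim.alive[pos]
            take = min(sim.w[i], budget)
            sim.w[i] -= take
            budget -= take
            removed += take
            if sim.w[i] <= EXTINCTION_EPS:
                sim.w[i] = 0.0
                sim.kill(pos)
    elif cfg.mode == "occurrence":
        k = min(cfg.species_per_step, sim.n_alive)
        for _ in range(k):
            pos = int(rng.integers(sim.n_alive))
            i = sim.alive[pos]
            removed += sim.w[i]
            sim.w[i] = 0.0
            sim.kill(pos)
    elif cfg.mode == "suitability":
        dec = cfg.suitability_decrement
        for pos in range(sim.n_alive - 1, -1, -1):
            i = sim.alive[pos]
            take = min(sim.w[i], dec)
            sim.w[i] -= take
            removed += take
            if sim.w[i] <= EXTINCTION_EPS:
                sim.w[i] = 0.0
                sim.kill(pos)
    else:
        raise FunvulError(f"unknown mode {cfg.mode!r}")
    return removed


def _individuals(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split weights into unit-sized individuals (last one possibly partial)."""
    sizes, owners = [], []
    for i, w in enumerate(weights):
        k = max(int(np.ceil(w - 1e-12)), 1)
        sizes.extend([1.0] * (k - 1) + [w - (k - 1)])
        owners.extend([i] * k)
    return np.array(sizes), np.array(owners)


def _step_individuals(
    sim: _SimState, rng: np.random.Generator, budget: float
) -> float:
    """Consume the budget one uniformly drawn individual at a time."""
    sizes, owners = _individuals(sim.w)
    live = [j for j in range(len(sizes)) if sim.w[owners[j]] > EXTINCTION_EPS]
    removed = 0.0
    while budget > EXTINCTION_EPS and live:
        pos = int(rng.integers(len(live)))
        j = live[pos]
        take = min(sizes[j], budget)
        sizes[j] -= take
        i = owners[j]
        sim.w[i] -= take
        budget -= take
        removed += take
        if sizes[j] <= EXTINCTION_EPS:
            live[pos] = live[-1]
            live.pop()
        if sim.w[i] <= EXTINCTION_EPS:
            sim.w[i] = 0.0
            sim.kill(sim.alive.index(i))
    return removed


def disturb_step(
    state: CommunityState, cfg: DisturbanceConfig, rng: np.random.Generator
) -> CommunityState:
    """Apply one disturbance step, returning the surviving community.

    The input state is not mutated.  Raises on an already-empty community
    (a CommunityState cannot be empty, so this triggers only on internal
    misuse).
    """
    sim = _SimState(state)
    if cfg.mode == "abundance" and cfg.allocation == "individual":
        _step_individuals(sim, rng, cfg.decrement_frac * state.t)
    else:
        _step(sim, cfg, rng, cfg.decrement_frac * state.t)
    keep = [i for i in range(state.s) if sim.w[i] > 0]
    if not keep:
        raise FunvulError("disturbance drove the community extinct; no state to return")
    return CommunityState(
        species_ids=[state.species_ids[i] for i in keep],
        cells=[state.cells[i] for i in keep],
        weights=sim.w[keep],
        mode=state.mode,
        is_virtual=state.is_virtual,
    )


def simulate_series(
    state: CommunityState, cfg: DisturbanceConfig, rng: np.random.Generator
) -> RarefactionCurve:
    """Disturb until total extinction, recording the rarefaction curve.

    x is the cumulative disturbed fraction: removed weight / initial T for
    abundance and suitability, removed species / S for occurrence.  y is
    the fraction of initially occupied entities still occupied.
    """
    if state.mode == "abundance" and cfg.allocation == "individual":
        return _simulate_individual_series(state, cfg, rng)
    sim = _SimState(state)
    n0 = sim.n_occ
    t0 = float(sim.w.sum())
    s0 = sim.n_alive
    budget0 = cfg.decrement_frac * t0
    xs = [0.0]
    ys = [1.0]
    removed_total = 0.0
    removed_species = 0
    while sim.n_alive > 0:
        before = sim.n_alive
        removed_total += _step(sim, cfg, rng, budget0)
        removed_species += before - sim.n_alive
        if cfg.mode == "occurrence":
            x = removed_species / s0
        else:
            x = removed_total / t0
        xs.append(min(x, 1.0))
        ys.append(sim.n_occ / n0)
    assert abs(removed_total - t0) <= 1e-9 * max(
        t0, 1.0
    ), "total removed weight must equal the initial total"
    xs[-1] = 1.0
    return RarefactionCurve(np.array(xs), np.array(ys))


def _simulate_individual_series(
    state: CommunityState, cfg: DisturbanceConfig, rng: np.random.Generator
) -> RarefactionCurve:
    """Rarefaction of individuals, computed from one removal schedule.

    A realization is a uniform random permutation of all individuals; the
    curve samples the surviving-entity count at every budget boundary.
    Because the whole removal order is drawn up front, the recorded curve
    depends on the step size only through where it is sampled.
    """
    sizes, owners = _individuals(state.weights)
    sim = _SimState(state)
    entity_of = sim.entity_of
    perm = rng.permutation(len(sizes))
    cmass = np.cumsum(sizes[perm])
    t0 = float(cmass[-1])
    death_mass = np.zeros(state.s)
    np.maximum.at(death_mass, owners[perm], cmass)
    entity_death = np.zeros(sim.n_occ)
    np.maximum.at(entity_death, entity_of, death_mass)
    n_steps = int(np.ceil(1.0 / cfg.decrement_frac - 1e-12))
    bounds = np.minimum(np.arange(1, n_steps + 1) * cfg.decrement_frac * t0, t0)
    bounds[-1] = t0
    alive = entity_death[None, :] - bounds[:, None] > 1e-9
    ys = np.concatenate([[1.0], alive.sum(axis=1) / sim.n_occ])
    xs = np.concatenate([[0.0], bounds / t0])
    xs[-1] = 1.0
    return RarefactionCurve(xs, ys)


def replicate_series(
    state: CommunityState, cfg: DisturbanceConfig
) -> list[RarefactionCurve]:
    """Run independent replicate series with replicate-indexed substreams.

    Suitability-mode disturbance is deterministic, so a single series is
    run regardless of the replicate setting (noted in the log).
    """
    n_rep = cfg.replicates
    if cfg.mode == "suitability" and n_rep > 1:
        logger.info(
            "suitability disturbance is deterministic; running 1 series "
            "instead of %d replicates",
            n_rep,
        )
        n_rep = 1
    curves = []
    for rep in range(n_rep):
        rng = np.random.default_rng([cfg.seed, rep])
        curves.append(simulate_series(state, cfg, rng))
    return curves
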