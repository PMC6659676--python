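"""Asynchronous stochastic update engine and fixed-point analysis.

One time step is a sweep: the free (unclamped, non-input) species are
visited in a uniformly random order and each visited species fires
independently with probability ``p``. A firing species looks up its rule
target in the *current*, partially updated state and moves one level
toward it — never more, so trajectories are continuous on the ordinal
scale. A state in which every free species already sits at its target is
a fixed point; no realization of the stochastic update can leave it.

Two independent steady-state oracles are provided: brute-force
enumeration of all ``3**k`` free-species assignments, and single-pass
evaluation in topological order (valid whenever the constrained
dependency graph is acyclic, as it is for the bundled model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .model import Condition, ConstrainedModel, SystemState


@dataclass(frozen=True)
class SimulationSettings:
    """Knobs of the stochastic simulation.

    Parameters
    ----------
    p
        Per-species per-step update probability, in (0, 1].
    max_steps
        Hard cap on simulated steps before giving up on convergence.
    horizon
        Reporting length: trajectories are padded/truncated to steps
        0..horizon for ensemble alignment.
    n_runs
        Replicate trajectories per ensemble.
    seed
        Master seed; replicate streams are spawned from it.
    scheme
        ``"sweep"`` (random-permutation sweep per step, the default) or
        ``"single"`` (one randomly chosen species considered per step).
    """

    p: float = 0.5
    max_steps: int = 200
    horizon: int = 30
    n_runs: int = 100
    seed: int = 0
    scheme: str = "sweep"

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"update probability p must be in (0, 1], got {self.p}")
        if self.max_steps < 1:
            raise ValueError("max_steps must be positive")
        if not 1 <= self.horizon <= self.max_steps:
            raise ValueError("horizon must satisfy 1 <= horizon <= max_steps")
        if self.n_runs < 1:
            raise ValueError("n_runs must be positive")
        if self.scheme not in ("sweep", "single"):
            raise ValueError(f"unknown update scheme {self.scheme!r}")


def initial_state(cmodel: ConstrainedModel) -> SystemState:
    """Baseline state: clamps at their levels, every other species at 0."""
    return {
        sp: cmodel.clamps.get(sp, 0)
        for sp in cmodel.model.species
    }


def random_initial_state(
    cmodel: ConstrainedModel, rng: np.random.Generator
) -> SystemState:
    """Clamps at their levels, free species at uniform random levels."""
    state = initial_state(cmodel)
    for sp in cmodel.free:
        state[sp] = int(rng.integers(0, 3))
    return state


def _move_toward(current: int, target: int) -> int:
    if target > current:
        return current + 1
    if target < current:
        return current - 1
    return current


def step(
    cmodel: ConstrainedModel,
    state: SystemState,
    p: float,
    rng: np.random.Generator,
    scheme: str = "sweep",
) -> SystemState:
    """Advance one time step; returns a new state, leaving ``state`` intact."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"update probability p must be in (0, 1], got {p}")
    new = dict(state)
    free = cmodel.free
    if scheme == "sweep":
        for idx in rng.permutation(len(free)):
            sp = free[idx]
            if rng.random() < p:
                new[sp] = _move_toward(new[sp], cmodel.target_level(new, sp))
    elif scheme == "single":
        sp = free[int(rng.integers(len(free)))]
        if rng.random() < p:
            new[sp] = _move_toward(new[sp], cmodel.target_level(new, sp))
    else:
        raise ValueError(f"unknown update scheme {scheme!r}")
    return new


def is_fixed_point(cmodel: ConstrainedModel, state: SystemState) -> bool:
    """True iff every free species' rule target equals its current level."""
    return all(cmodel.target_level(state, sp) == state[sp] for sp in cmodel.free)


@dataclass(frozen=True)
class Trajectory:
    """One simulated run: recorded states, convergence step, provenance."""

    condition: Condition
    states: tuple[SystemState, ...]
    converged_at: int | None
    seed: int | None = None

    @property
    def final_state(self) -> SystemState:
        return self.states[-1]

    def levels(self, species: str) -> list[int]:
        return [s[species] for s in self.states]

    def to_frame(self, run: int = 0) -> pd.DataFrame:
        """Tidy table with columns (run, step, species, level)."""
        rows = [
            (run, t, sp, state[sp])
            for t, state in enumerate(self.states)
            for sp in state
        ]
        return pd.DataFrame(rows, columns=["run", "step", "species", "level"])


def simulate(
    cmodel: ConstrainedModel,
    settings: SimulationSettings,
    rng: np.random.Generator | None = None,
    initial: SystemState | None = None,
) -> Trajectory:
    """Run one trajectory from the baseline (or a supplied) initial state.

    Stops as soon as the deterministic fixed-point predicate holds (a
    state persisting by chance under ``p < 1`` is not mistaken for a
    steady state) or after ``max_steps``. Converged trajectories are
    padded with the fixed state out to ``horizon`` so ensembles align.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    state = dict(initial) if initial is not None else initial_state(cmodel)
    states = [dict(state)]
    converged_at = 0 if is_fixed_point(cmodel, state) else None
    t = 0
    while converged_at is None and t < settings.max_steps:
        state = step(cmodel, state, settings.p, rng, scheme=settings.scheme)
        t += 1
        states.append(dict(state))
        if is_fixed_point(cmodel, state):
            converged_at = t
    while len(states) - 1 < settings.horizon:
        states.append(dict(state))
    return Trajectory(
        condition=cmodel.condition,
        states=tuple(states),
        converged_at=converged_at,
        seed=settings.seed,
    )


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-step, per-species mean and standard deviation over replicates."""

    condition: Condition
    species: tuple[str, ...]
    mean: np.ndarray  # (horizon + 1, n_species)
    sd: np.ndarray  # (horizon + 1, n_species)
    n_runs: int
    converged_at: tuple[int | None, ...]
    final_levels: np.ndarray  # (n_runs, n_species), last reported step

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns (step, species, mean, sd)."""
        steps, n_sp = self.mean.shape
        rows = [
            (t, self.species[j], float(self.mean[t, j]), float(self.sd[t, j]))
            for t in range(steps)
            for j in range(n_sp)
        ]
        return pd.DataFrame(rows, columns=["step", "species", "mean", "sd"])

    def steady_levels(self) -> SystemState:
        """Modal level of each species at the final reported step."""
        out: SystemState = {}
        for j, sp in enumerate(self.species):
            counts = np.bincount(self.final_levels[:, j], minlength=3)
            out[sp] = int(np.argmax(counts))
        return out

    def convergence_fraction(self, t: int) -> float:
        done = sum(1 for c in self.converged_at if c is not None and c <= t)
        return done / self.n_runs


def run_ensemble(
    cmodel: ConstrainedModel, settings: SimulationSettings
) -> EnsembleSummary:
    """Simulate ``n_runs`` independent trajectories and summarize them.

    Replicate random streams are spawned deterministically from the
    master seed, so identical settings give bit-identical summaries.
    """
    species = cmodel.model.species
    n_steps = settings.horizon + 1
    levels = np.empty((settings.n_runs, n_steps, len(species)), dtype=np.int8)
    converged: list[int | None] = []
    children = np.random.SeedSequence(settings.seed).spawn(settings.n_runs)
    for r, child in enumerate(children):
        traj = simulate(cmodel, settings, rng=np.random.default_rng(child))
        for t in range(n_steps):
            state = traj.states[min(t, len(traj.states) - 1)]
            levels[r, t] = [state[sp] for sp in species]
        converged.append(traj.converged_at)
    return EnsembleSummary(
        condition=cmodel.condition,
        species=species,
        mean=levels.mean(axis=0),
        sd=levels.std(axis=0, ddof=0),
        n_runs=settings.n_runs,
        converged_at=tuple(converged),
        final_levels=levels[:, -1, :].copy(),
    )


def convergence_fraction(trajectories: Sequence[Trajectory], t: int) -> float:
    """Fraction of runs whose fixed point was reached by step ``t``."""
    if not trajectories:
        raise ValueError("convergence_fraction of an empty trajectory list")
    done = sum(
        1 for traj in trajectories
        if traj.converged_at is not None and traj.converged_at <= t
    )
    return done / len(trajectories)


# ---------------------------------------------------------------------------
# Steady-state oracles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedPointReport:
    """All steady states of a constrained model, with the method used."""

    condition: Condition
    fixed_points: tuple[SystemState, ...]
    method: str  # "exhaustive" or "analytic"


def enumerate_fixed_points(cmodel: ConstrainedModel) -> FixedPointReport:
    """Brute-force oracle: test every assignment of the free species.

    Examines all ``3**k`` states over the ``k`` free species (vectorized;
    k <= 12). This is the ground truth the simulation and the analytic
    oracle are checked against.
    """
    free = cmodel.free
    k = len(free)
    free_index = {sp: i for i, sp in enumerate(free)}
    # grid[i, n] = level of free species i in candidate state n
    grid = np.indices((3,) * k, dtype=np.int8).reshape(k, -1) if k else \
        np.empty((0, 1), dtype=np.int8)
    n_states = grid.shape[1]
    ok = np.ones(n_states, dtype=bool)
    for sp in free:
        rule = cmodel.model.rules[sp]
        flat = np.zeros(n_states, dtype=np.int64)
        for parent in rule.parents:
            if parent in free_index:
                col = grid[free_index[parent]].astype(np.int64)
            else:
                col = np.full(n_states, cmodel.clamps[parent], dtype=np.int64)
            flat = flat * 3 + col
        targets = rule.as_array().reshape(-1)[flat]
        ok &= targets == grid[free_index[sp]]
    points = []
    for n in np.flatnonzero(ok):
        state = {s: cmodel.clamps.get(s, 0) for s in cmodel.model.species}
        for i, sp in enumerate(free):
            state[sp] = int(grid[i, n])
        points.append(state)
    return FixedPointReport(
        condition=cmodel.condition, fixed_points=tuple(points), method="exhaustive"
    )


def analytic_fixed_point(cmodel: ConstrainedModel) -> SystemState:
    """Closed-form oracle for acyclic constrained models.

    Evaluates each free species' rule once, in topological order of the
    dependency graph restricted to free species; because no free species
    feeds back on itself the result is the unique fixed point.

    Raises
    ------
    ValueError
        If the free-species dependency graph contains a cycle.
    """
    free = set(cmodel.free)
    g = nx.DiGraph()
    g.add_nodes_from(free)
    for sp in free:
        for parent in cmodel.model.rules[sp].parents:
            if parent in free:
                g.add_edge(parent, sp)
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        raise ValueError(
            "constrained dependency graph is cyclic; use enumerate_fixed_points"
        ) from None
    state: SystemState = {
        sp: cmodel.clamps.get(sp, 0) for sp in cmodel.model.species
    }
    for sp in order:
        state[sp] = cmodel.model.rules[sp].evaluate(state)
    return state
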