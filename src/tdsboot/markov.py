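"""Phase-dependent Markov-chain simulation of TDS tasks.

Dominant sensations while eating evolve as a discrete-time Markov chain whose
states are the descriptors.  A task starts in a state drawn from an initial
distribution and makes ``n_steps`` transitions on the normalized grid
t' = k / n_steps.  The transition table is allowed to change along the
timeline: the task period is partitioned into *phases* (e.g. initial, middle,
last), each with its own row-stochastic matrix, reflecting that early-,
mid- and late-eating dynamics differ.  The transition leaving grid point k
uses the matrix of the phase containing the source time t' = k / n_steps.

Besides sampling trajectories, the module computes the exact marginal state
distribution at every grid point by propagating the initial distribution
through the step matrices — the analytic population curves that simulated
populations must converge to, used throughout the tests as an oracle.

Two built-in reference models, :func:`builtin_model`, provide a 4-descriptor
and a 6-descriptor scenario with three phases over 20 transitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    TaskRecord,
    TDSCurveSet,
    TDSValidationError,
    TimeGrid,
    task_states,
)

_PROB_TOL = 1e-9


@dataclass(frozen=True, eq=False)
class Phase:
    """A contiguous run of transition steps governed by one matrix."""

    first_step: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))


@dataclass(frozen=True, eq=False)
class MarkovTDSModel:
    """Markov model of a TDS task population.

    Parameters
    ----------
    descriptors : ordered labels (the chain's states).
    initial_distribution : length-p probability vector for the state at t' = 0.
    phases : ordered phases; the first must start at step 0 and first_steps
        must be strictly increasing, so steps 0 .. n_steps-1 are each covered
        by exactly one phase.
    n_steps : transitions per task; the native grid has n_steps + 1 points.
    """

    descriptors: tuple[str, ...]
    initial_distribution: np.ndarray
    phases: tuple[Phase, ...]
    n_steps: int = 20

    def __post_init__(self) -> None:
        object.__setattr__(self, "descriptors", tuple(self.descriptors))
        init = np.asarray(self.initial_distribution, dtype=float)
        object.__setattr__(self, "initial_distribution", init)
        object.__setattr__(self, "phases", tuple(self.phases))
        p = len(self.descriptors)
        if p < 1:
            raise TDSValidationError("model needs at least one descriptor")
        if init.shape != (p,):
            raise TDSValidationError(
                f"initial distribution has length {init.shape}, expected ({p},)"
            )
        if init.min() < 0 or abs(init.sum() - 1.0) > _PROB_TOL:
            raise TDSValidationError(
                f"initial distribution must be non-negative and sum to 1 (sum={init.sum()!r})"
            )
        if self.n_steps < 1:
            raise TDSValidationError("n_steps must be at least 1")
        if not self.phases:
            raise TDSValidationError("at least one phase is required")
        firsts = [ph.first_step for ph in self.phases]
        if firsts[0] != 0:
            raise TDSValidationError("the first phase must start at step 0")
        if any(b <= a for a, b in zip(firsts, firsts[1:])):
            raise TDSValidationError("phase first_steps must be strictly increasing")
        if firsts[-1] >= self.n_steps:
            raise TDSValidationError("a phase starts beyond the last transition step")
        for ph in self.phases:
            m = ph.matrix
            if m.shape != (p, p):
                raise TDSValidationError(
                    f"phase at step {ph.first_step}: matrix shape {m.shape}, expected ({p}, {p})"
                )
            if m.min() < 0:
                raise TDSValidationError(
                    f"phase at step {ph.first_step}: negative transition probability"
                )
            rowsums = m.sum(axis=1)
            bad = np.nonzero(np.abs(rowsums - 1.0) > _PROB_TOL)[0]
            if bad.size:
                detail = ", ".join(
                    f"row {self.descriptors[i]} sums to {rowsums[i]:g}" for i in bad
                )
                raise TDSValidationError(
                    f"phase at step {ph.first_step}: rows must sum to 1 ({detail})"
                )

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptors)

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid.simulation(self.n_steps)

    def matrix_for_step(self, step: int) -> np.ndarray:
        """Transition matrix governing the move from grid point ``step`` to ``step + 1``."""
        if not 0 <= step < self.n_steps:
            raise TDSValidationError(f"step {step} outside 0..{self.n_steps - 1}")
        chosen = self.phases[0]
        for ph in self.phases:
            if ph.first_step <= step:
                chosen = ph
        return chosen.matrix

    def step_matrices(self) -> list[np.ndarray]:
        return [self.matrix_for_step(k) for k in range(self.n_steps)]


@dataclass(frozen=True, eq=False)
class Trajectory:
    """State indices of one simulated task at each grid point t' = k / n_steps."""

    states: np.ndarray

    def __post_init__(self) -> None:
        st = np.asarray(self.states, dtype=np.int64)
        object.__setattr__(self, "states", st)
        if st.ndim != 1 or st.size < 2:
            raise TDSValidationError("a trajectory needs at least two states")
        if st.min() < 0:
            raise TDSValidationError("state indices must be non-negative")

    @property
    def n_steps(self) -> int:
        return int(self.states.size - 1)


# --- built-in reference models -------------------------------------------------

_CASE1_INITIAL = [0.5, 0.25, 0.25, 0.0]
_CASE1_TABLES = {
    0: [  # initial phase, transitions leaving steps 0-6
        [0.5, 0.3, 0.2, 0.0],
        [0.1, 0.5, 0.3, 0.1],
        [0.1, 0.2, 0.5, 0.2],
        [0.0, 0.0, 0.4, 0.6],
    ],
    7: [  # middle phase, steps 7-13
        [0.4, 0.3, 0.2, 0.1],
        [0.1, 0.4, 0.3, 0.2],
        [0.1, 0.1, 0.6, 0.2],
        [0.1, 0.1, 0.2, 0.6],
    ],
    14: [  # last phase, steps 14-19
        [0.2, 0.2, 0.3, 0.3],
        [0.1, 0.3, 0.3, 0.3],
        [0.1, 0.2, 0.3, 0.4],
        [0.1, 0.0, 0.2, 0.7],
    ],
}

_CASE2_INITIAL = [1 / 6, 1 / 3, 1 / 3, 1 / 6, 0.0, 0.0]
# Row D3 of the last phase is renormalized to unit sum (entries divided by 1.1).
_CASE2_TABLES = {
    0: [
        [0.4, 0.3, 0.2, 0.1, 0.0, 0.0],
        [0.1, 0.4, 0.2, 0.2, 0.1, 0.0],
        [0.1, 0.2, 0.4, 0.2, 0.0, 0.1],
        [0.0, 0.1, 0.4, 0.3, 0.1, 0.1],
        [0.0, 0.0, 0.3, 0.2, 0.3, 0.2],
        [0.0, 0.0, 0.2, 0.2, 0.3, 0.3],
    ],
    7: [
        [0.3, 0.3, 0.2, 0.1, 0.1, 0.0],
        [0.0, 0.3, 0.3, 0.2, 0.1, 0.1],
        [0.1, 0.1, 0.4, 0.3, 0.1, 0.0],
        [0.0, 0.1, 0.2, 0.4, 0.2, 0.1],
        [0.0, 0.0, 0.1, 0.2, 0.3, 0.4],
        [0.0, 0.0, 0.1, 0.2, 0.3, 0.4],
    ],
    14: [
        [0.1, 0.2, 0.3, 0.3, 0.1, 0.0],
        [0.1, 0.3, 0.3, 0.3, 0.0, 0.0],
        [v / 1.1 for v in (0.1, 0.2, 0.3, 0.4, 0.1, 0.0)],
        [0.1, 0.0, 0.2, 0.5, 0.2, 0.0],
        [0.0, 0.0, 0.0, 0.1, 0.6, 0.3],
        [0.0, 0.0, 0.1, 0.1, 0.3, 0.5],
    ],
}


def builtin_model(case: int) -> MarkovTDSModel:
    """The built-in reference scenarios.

    Case 1: four descriptors, initial distribution (0.5, 0.25, 0.25, 0).
    Case 2: six descriptors, initial distribution (1/6, 1/3, 1/3, 1/6, 0, 0).
    Both run 20 transitions with three phases (initial steps 0-6, middle 7-13,
    last 14-19).
    """
    if case == 1:
        initial, tables, p = _CASE1_INITIAL, _CASE1_TABLES, 4
    elif case == 2:
        initial, tables, p = _CASE2_INITIAL, _CASE2_TABLES, 6
    else:
        raise TDSValidationError(f"unknown built-in case {case!r}; choose 1 or 2")
    descriptors = tuple(f"D{i}" for i in range(1, p + 1))
    phases = tuple(Phase(first, np.asarray(m)) for first, m in sorted(tables.items()))
    return MarkovTDSModel(descriptors, np.asarray(initial), phases, n_steps=20)


# --- simulation ----------------------------------------------------------------


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_state_matrix(
    model: MarkovTDSModel, n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Sample n trajectories at once; returns an (n, n_steps + 1) index matrix.

    Draw order is fixed for reproducibility: all n initial states first, then
    the n transitions of step 0, step 1, ... in time order.
    """
    if n < 1:
        raise TDSValidationError("population size n must be at least 1")
    rng = _as_rng(rng)
    p = model.n_descriptors
    states = np.empty((n, model.n_steps + 1), dtype=np.int64)
    init_cum = np.cumsum(model.initial_distribution)
    states[:, 0] = np.searchsorted(init_cum, rng.random(n), side="right")
    np.clip(states[:, 0], 0, p - 1, out=states[:, 0])
    for k, mat in enumerate(model.step_matrices()):
        cum = np.cumsum(mat, axis=1)
        u = rng.random(n)
        nxt = (u[:, None] >= cum[states[:, k]]).sum(axis=1)
        states[:, k + 1] = np.minimum(nxt, p - 1)
    return states


def simulate_task(
    model: MarkovTDSModel, rng: np.random.Generator | int | None = None
) -> Trajectory:
    """Sample a single task trajectory."""
    return Trajectory(simulate_state_matrix(model, 1, rng)[0])


def trajectory_to_task(
    traj: Trajectory, descriptors: Sequence[str], task_id: str = "sim"
) -> TaskRecord:
    """Convert a trajectory to an event record on [0, 1].

    An event is emitted at t' = 0 for the initial state and at every state
    change thereafter; a change at the final grid point lands at t' = 1.
    """
    n_steps = traj.n_steps
    st = traj.states
    events = [(descriptors[st[0]], 0.0)]
    change = np.nonzero(np.diff(st))[0] + 1
    events.extend((descriptors[st[k]], k / n_steps) for k in change)
    return TaskRecord(task_id, 0.0, 1.0, tuple(events))


def task_to_trajectory(
    task: TaskRecord, descriptors: Sequence[str], n_steps: int
) -> Trajectory:
    """Read the trajectory back off a simulated task's step functions."""
    states = task_states(task, descriptors, TimeGrid.simulation(n_steps))
    if states.min() < 0:
        raise TDSValidationError(
            f"task {task.task_id!r} has no selection at t'=0; not a simulated trajectory"
        )
    return Trajectory(states)


def simulate_population(
    model: MarkovTDSModel, n: int, rng: np.random.Generator | int | None = None
) -> list[TaskRecord]:
    """Sample n independent tasks, deterministic for a given seed or generator."""
    states = simulate_state_matrix(model, n, rng)
    width = len(str(n))
    return [
        trajectory_to_task(Trajectory(row), model.descriptors, task_id=f"sim-{i:0{width}d}")
        for i, row in enumerate(states)
    ]


def exact_marginals(model: MarkovTDSModel) -> TDSCurveSet:
    """Exact population dominance proportions at every grid point.

    Propagates the initial distribution through the step matrices:
    d(t'_k) = d(0) @ M_0 @ ... @ M_{k-1}.  Column sums are identically 1,
    making this the convergence oracle for simulated populations.
    """
    p = model.n_descriptors
    values = np.empty((p, model.n_steps + 1))
    d = model.initial_distribution.copy()
    values[:, 0] = d
    for k, mat in enumerate(model.step_matrices()):
        d = d @ mat
        values[:, k + 1] = d
    return TDSCurveSet(model.descriptors, model.grid, values, n_tasks=0)
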