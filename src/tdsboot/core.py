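"""Core data structures for temporal dominance of sensations (TDS) data.

A TDS task records which sensory descriptor an assessor judged dominant at
each moment while experiencing a stimulus.  The assessor pushes a start
button, then sequentially selects descriptors; a selection stays in force
until the next one, and a stop button ends the task.  Each task therefore
induces, for every descriptor ``j``, a binary step function ``b_j(t)`` that
is 1 while ``j`` is the current selection and 0 otherwise, with at most one
descriptor dominant at any instant.

Aggregating the step functions of ``n`` independent tasks on a common
normalized time grid (task duration rescaled to ``[0, 1]``) and dividing by
``n`` yields the *dominance proportions* ``d_j(t')`` — the TDS curves that
are the method's primary output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: absolute tolerance used when checking normalized-time bookkeeping
TIME_TOL = 1e-12

#: default evaluation grid size for observed (non-simulated) tasks
DEFAULT_GRID_POINTS = 101


class TDSValidationError(ValueError):
    """Raised when a task, grid, curve set or model violates its contract."""


def _as_label(x: object) -> str:
    if not isinstance(x, str) or not x:
        raise TDSValidationError(f"descriptor labels must be non-empty strings, got {x!r}")
    return x


@dataclass(frozen=True)
class TaskRecord:
    """One TDS task: an ordered sequence of descriptor selections.

    Parameters
    ----------
    task_id : str
        Opaque identifier, echoed in every diagnostic about this task.
    start_time, stop_time : float
        Task boundaries in seconds (or any consistent unit); ``stop_time``
        must exceed ``start_time``.
    events : sequence of (descriptor, time)
        Selections in strictly increasing time order.  Times must lie in the
        closed interval ``[start_time, stop_time]``; a selection at exactly
        ``stop_time`` is dominant only at the final instant.  Before the
        first selection no descriptor is dominant.
    """

    task_id: str
    start_time: float
    stop_time: float
    events: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "events",
            tuple((_as_label(d), float(t)) for d, t in self.events),
        )
        object.__setattr__(self, "start_time", float(self.start_time))
        object.__setattr__(self, "stop_time", float(self.stop_time))
        if not self.stop_time > self.start_time:
            raise TDSValidationError(
                f"task {self.task_id!r}: degenerate record, "
                f"stop_time ({self.stop_time}) must exceed start_time ({self.start_time})"
            )
        times = self.event_times
        if np.any(np.diff(times) <= 0):
            raise TDSValidationError(
                f"task {self.task_id!r}: event times must be strictly increasing"
            )
        if times.size:
            if times[0] < self.start_time:
                raise TDSValidationError(
                    f"task {self.task_id!r}: event at t={times[0]} precedes start_time "
                    f"({self.start_time})"
                )
            if times[-1] > self.stop_time:
                raise TDSValidationError(
                    f"task {self.task_id!r}: event at t={times[-1]} is after stop_time "
                    f"({self.stop_time})"
                )

    @property
    def event_times(self) -> np.ndarray:
        return np.asarray([t for _, t in self.events], dtype=float)

    @property
    def event_labels(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.events)

    @property
    def duration(self) -> float:
        return self.stop_time - self.start_time

    @property
    def descriptors(self) -> tuple[str, ...]:
        """Distinct descriptor labels, in order of first selection."""
        seen: dict[str, None] = {}
        for d, _ in self.events:
            seen.setdefault(d)
        return tuple(seen)

    @property
    def is_normalized(self) -> bool:
        return abs(self.start_time) <= TIME_TOL and abs(self.stop_time - 1.0) <= TIME_TOL


def normalize_task(task: TaskRecord) -> TaskRecord:
    """Rescale a task affinely so that start = 0 and stop = 1.

    The elapsed time between the start and stop buttons maps to unit length;
    event ordering is preserved.  A zero-duration task cannot be normalized
    and raises :class:`TDSValidationError` (the constructor already rejects
    such records, so this can only trigger on hand-built inputs).
    """
    dur = task.stop_time - task.start_time
    if not dur > 0:
        raise TDSValidationError(
            f"task {task.task_id!r}: degenerate record with non-positive duration {dur}"
        )
    events = tuple(
        (d, min(max((t - task.start_time) / dur, 0.0), 1.0)) for d, t in task.events
    )
    return replace(task, start_time=0.0, stop_time=1.0, events=events)


@dataclass(frozen=True, eq=False)
class TimeGrid:
    """Strictly increasing normalized-time points spanning ``[0, 1]``."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size < 2:
            raise TDSValidationError("a time grid needs at least two points")
        if np.any(np.diff(pts) <= 0):
            raise TDSValidationError("grid points must be strictly increasing (hence unique)")
        if abs(pts[0]) > TIME_TOL or abs(pts[-1] - 1.0) > TIME_TOL:
            raise TDSValidationError("grid must start at 0 and end at 1")

    def __len__(self) -> int:
        return int(self.points.size)

    @classmethod
    def uniform(cls, n_points: int = DEFAULT_GRID_POINTS) -> "TimeGrid":
        """Evenly spaced grid; the 101-point default suits observed data."""
        return cls(np.linspace(0.0, 1.0, int(n_points)))

    @classmethod
    def simulation(cls, n_steps: int = 20) -> "TimeGrid":
        """The native grid of an ``n_steps``-transition simulated task."""
        return cls(np.linspace(0.0, 1.0, int(n_steps) + 1))


@dataclass(frozen=True, eq=False)
class TDSCurveSet:
    """Dominance-proportion curves: descriptors x grid matrix in ``[0, 1]``.

    ``n_tasks`` is the number of tasks aggregated; 0 marks an analytic
    (infinite-population) curve set such as exact Markov marginals.
    At any grid point the column sum is at most 1, and equals 1 wherever
    every contributing task had already made a selection.
    """

    descriptors: tuple[str, ...]
    grid: TimeGrid
    values: np.ndarray
    n_tasks: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "descriptors", tuple(map(_as_label, self.descriptors)))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        p, g = len(self.descriptors), len(self.grid)
        if vals.shape != (p, g):
            raise TDSValidationError(
                f"curve matrix shape {vals.shape} does not match {p} descriptors x {g} grid points"
            )
        tol = 1e-9
        if vals.min() < -tol or vals.max() > 1 + tol:
            raise TDSValidationError("curve values must lie in [0, 1]")
        if np.any(vals.sum(axis=0) > 1 + 1e-6):
            raise TDSValidationError("dominance proportions at a time point cannot exceed 1 in total")
        if self.n_tasks < 0:
            raise TDSValidationError("n_tasks must be non-negative")

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptors)

    def index_of(self, descriptor: str) -> int:
        try:
            return self.descriptors.index(descriptor)
        except ValueError:
            raise TDSValidationError(f"unknown descriptor {descriptor!r}") from None

    def curve(self, descriptor: str) -> np.ndarray:
        """The d_j(t') vector for one descriptor."""
        return self.values[self.index_of(descriptor)]

    def to_frame(self):
        """Wide-form table: t_prime plus one column per descriptor."""
        import pandas as pd

        data = {"t_prime": self.grid.points}
        for j, d in enumerate(self.descriptors):
            data[d] = self.values[j]
        return pd.DataFrame(data)


def indicator(
    task: TaskRecord,
    descriptor: str,
    t_prime: float,
    descriptors: Sequence[str] | None = None,
) -> int:
    """Binary dominance function b_j(t') of a normalized task.

    Returns 1 iff ``descriptor`` is the most recent selection at or before
    ``t_prime``.  Dominance intervals are right-open: at the instant of a new
    selection the new descriptor is dominant, and the last selection persists
    through t' = 1.  Before the first selection every indicator is 0.

    ``descriptors``, when given, is the universe of admissible labels;
    otherwise the task's own selections define it.
    """
    if not task.is_normalized:
        raise TDSValidationError(
            f"task {task.task_id!r}: indicator expects a normalized task (use normalize_task)"
        )
    if not (-TIME_TOL <= t_prime <= 1 + TIME_TOL):
        raise TDSValidationError(f"t_prime={t_prime} outside the normalized range [0, 1]")
    known = tuple(descriptors) if descriptors is not None else task.descriptors
    if descriptor not in known:
        raise TDSValidationError(f"unknown descriptor {descriptor!r} (known: {known})")
    times = task.event_times
    i = int(np.searchsorted(times, t_prime, side="right")) - 1
    if i < 0:
        return 0
    return int(task.events[i][0] == descriptor)


def task_states(
    task: TaskRecord, descriptors: Sequence[str], grid: TimeGrid
) -> np.ndarray:
    """Dominant-descriptor index at each grid point; -1 before any selection."""
    if not task.is_normalized:
        task = normalize_task(task)
    label_to_idx = {d: j for j, d in enumerate(descriptors)}
    try:
        ev_idx = np.asarray([label_to_idx[d] for d in task.event_labels], dtype=np.int64)
    except KeyError as exc:
        raise TDSValidationError(
            f"task {task.task_id!r}: selection of descriptor {exc.args[0]!r} "
            f"is not in the descriptor list {tuple(descriptors)}"
        ) from None
    pos = np.searchsorted(task.event_times, grid.points, side="right") - 1
    states = np.full(len(grid), -1, dtype=np.int64)
    sel = pos >= 0
    states[sel] = ev_idx[pos[sel]]
    return states


def state_matrix(
    tasks: Sequence[TaskRecord], descriptors: Sequence[str], grid: TimeGrid
) -> np.ndarray:
    """Stack ``task_states`` over tasks: an (n_tasks, n_grid) integer matrix."""
    if len(tasks) == 0:
        raise TDSValidationError("at least one task is required")
    return np.vstack([task_states(t, descriptors, grid) for t in tasks])


def curves_from_states(
    states: np.ndarray, descriptors: Sequence[str], grid: TimeGrid
) -> TDSCurveSet:
    """Dominance proportions from a precomputed state matrix."""
    n = states.shape[0]
    p = len(descriptors)
    values = np.empty((p, states.shape[1]))
    for j in range(p):
        values[j] = (states == j).mean(axis=0)
    return TDSCurveSet(tuple(descriptors), grid, values, n_tasks=n)


def compute_curves(
    tasks: Sequence[TaskRecord],
    descriptors: Sequence[str],
    grid: TimeGrid | None = None,
) -> TDSCurveSet:
    """TDS curves of a task set: d_j(t'_k) = (1/n) sum_i b_ij(t'_k).

    Proportions are taken over *all* n tasks; tasks that have not yet made a
    selection at t' contribute 0 to every descriptor, so column sums may fall
    short of 1 early in the timeline for observed data.
    """
    if grid is None:
        grid = TimeGrid.uniform()
    return curves_from_states(state_matrix(tasks, descriptors, grid), descriptors, grid)
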