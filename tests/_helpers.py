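"""Shared independent oracles and small builders for the test suite."""

from __future__ import annotations

import itertools

import numpy as np

from tdsboot import MarkovTDSModel, TaskRecord


def enumerate_marginals(model: MarkovTDSModel) -> np.ndarray:
    """Exhaustive path-sum oracle for the marginal state distributions.

    Sums initial x transition probabilities over all p**(n_steps+1) state
    paths; tractable only for tiny models, by design independent of the
    matrix-product implementation it checks.
    """
    p = model.n_descriptors
    mats = model.step_matrices()
    values = np.zeros((p, model.n_steps + 1))
    for path in itertools.product(range(p), repeat=model.n_steps + 1):
        prob = model.initial_distribution[path[0]]
        for k in range(model.n_steps):
            prob *= mats[k][path[k], path[k + 1]]
        for k, state in enumerate(path):
            values[state, k] += prob
    return values


def brute_force_indicator(task: TaskRecord, descriptor: str, t: float) -> int:
    """Linear scan over the event list: the last selection at or before t wins."""
    current = None
    for d, time in task.events:
        if time <= t:
            current = d
        else:
            break
    return int(current == descriptor)


def kth_smallest_by_counting(values, k: int) -> float:
    """Order-statistic oracle: smallest x with at least k values <= x."""
    vals = list(values)
    for x in sorted(set(vals)):
        if sum(v <= x for v in vals) >= k:
            return x
    raise AssertionError("k exceeds the number of values")


def random_tasks(n: int, rng: np.random.Generator, labels=("A", "B", "C")) -> list[TaskRecord]:
    """Random normalized tasks with 1-6 events, the first at t' = 0."""
    tasks = []
    for i in range(n):
        n_events = int(rng.integers(1, 7))
        times = np.sort(rng.random(n_events - 1)) if n_events > 1 else np.array([])
        times = np.concatenate([[0.0], np.unique(times)])
        events = tuple((labels[rng.integers(0, len(labels))], float(t)) for t in times)
        tasks.append(TaskRecord(f"rand-{i}", 0.0, 1.0, events))
    return tasks
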