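"""Bootstrap resampling of TDS tasks and uncertainty bands for TDS curves.

The sampling unit is the whole task, never a time point: from the observed
set of m tasks, m are drawn uniformly with replacement and the full curve set
is recomputed, q times over.  This respects the within-task serial dependence
of the step functions and is deliberately unlike block bootstraps for generic
time series.  Pointwise uncertainty bands then come from order statistics of
the q replicate values at each descriptor/time: the central 95% percentile
interval for a confidence band (for q = 1000, the 25th smallest to the 25th
largest value) and the central ~68.3% interval as a standard-error band (the
159th smallest to 159th largest).  For comparison, closed-form bands from the
normal approximation to a proportion, d +/- z * sqrt(d(1-d)/m), are provided
with z = 1.96 (95% CI) and z = 1 (SE).
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
    curves_from_states,
    state_matrix,
)

#: central-interval tail mass per band kind; ranks are round(alpha * q)
BAND_ALPHA = {"ci95": 0.025, "se": 0.1587}

#: z multiplier of the normal-approximation band per band kind
BAND_Z = {"ci95": 1.96, "se": 1.0}

#: a normal band is unreliable where m*d or m*(1-d) falls below this count
LOW_COUNT_THRESHOLD = 5.0


def _check_band(band: str) -> str:
    if band not in BAND_ALPHA:
        raise TDSValidationError(f"unknown band {band!r}; choose one of {sorted(BAND_ALPHA)}")
    return band


def percentile_rank(q: int, band: str) -> int:
    """Order-statistic rank k for a q-replicate ensemble: k = round(alpha * q).

    Reproduces ranks 25 (ci95) and 159 (se) at q = 1000.  A q too small for
    the requested band (rank < 1) is an error rather than a clamped band.
    """
    alpha = BAND_ALPHA[_check_band(band)]
    k = int(round(alpha * q))
    if k < 1:
        raise TDSValidationError(
            f"q={q} is too small for a {band!r} band (rank round({alpha}*q) < 1); "
            "increase the number of bootstrap replicates"
        )
    return k


@dataclass(frozen=True, eq=False)
class BootstrapEnsemble:
    """Base curves plus q bootstrap replicate curve sets.

    ``replicate_values`` has shape (q, p, n_grid); replicate r holds the
    curves of the r-th resample.  The replicate mean converges to the base
    curves as q grows.
    """

    base_curves: TDSCurveSet
    replicate_values: np.ndarray
    m: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.replicate_values, dtype=float)
        object.__setattr__(self, "replicate_values", vals)
        p = self.base_curves.n_descriptors
        g = len(self.base_curves.grid)
        if vals.ndim != 3 or vals.shape[1:] != (p, g):
            raise TDSValidationError(
                f"replicate array shape {vals.shape} incompatible with ({p}, {g}) curves"
            )
        if vals.min() < 0 or vals.max() > 1:
            raise TDSValidationError("replicate curve values must lie in [0, 1]")
        if self.m < 1:
            raise TDSValidationError("sample size m must be at least 1")

    @property
    def q(self) -> int:
        return int(self.replicate_values.shape[0])


@dataclass(frozen=True, eq=False)
class UncertaintyBands:
    """Pointwise lower/upper bounds for each descriptor at each grid point.

    ``method`` is "bootstrap" (order statistics of replicate values) or
    "normal" (proportion +/- z * binomial standard error, clipped to [0, 1]).
    ``low_count_mask`` flags points where the normal approximation is
    unreliable (m*d < 5 or m*(1-d) < 5); it is all-False for bootstrap bands.
    """

    descriptors: tuple[str, ...]
    grid: TimeGrid
    lower: np.ndarray
    upper: np.ndarray
    band: str
    method: str
    low_count_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        object.__setattr__(self, "descriptors", tuple(self.descriptors))
        shape = (len(self.descriptors), len(self.grid))
        if lo.shape != shape or hi.shape != shape:
            raise TDSValidationError(f"band matrices must have shape {shape}")
        if np.any(lo > hi + 1e-12):
            raise TDSValidationError("band lower bound exceeds upper bound")
        if lo.min() < -1e-12 or hi.max() > 1 + 1e-12:
            raise TDSValidationError("band bounds must lie in [0, 1]")
        _check_band(self.band)
        if self.method not in ("bootstrap", "normal"):
            raise TDSValidationError(f"unknown method {self.method!r}")
        if self.low_count_mask is None:
            object.__setattr__(self, "low_count_mask", np.zeros(shape, dtype=bool))

    @property
    def halfwidth(self) -> np.ndarray:
        return (self.upper - self.lower) / 2.0

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Elementwise inclusion of reference values, endpoints included."""
        v = np.asarray(values, dtype=float)
        return (self.lower <= v) & (v <= self.upper)


def resample_tasks(
    tasks: Sequence[TaskRecord], rng: np.random.Generator | int | None = None
) -> list[TaskRecord]:
    """Draw len(tasks) tasks uniformly with replacement (one bootstrap resample)."""
    m = len(tasks)
    if m < 1:
        raise TDSValidationError("cannot resample an empty task list")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    idx = rng.integers(0, m, size=m)
    return [tasks[i] for i in idx]


def _replicates_from_states(
    states: np.ndarray, n_descriptors: int, q: int, rng: np.random.Generator
) -> np.ndarray:
    """Counting-based bootstrap: index draws + count-weighted indicator averages.

    Per-replicate index draws of shape (m,) keep the random stream identical
    to resampling the task list itself with the same generator.
    """
    m, g = states.shape
    one_hot = np.empty((m, n_descriptors * g))
    for j in range(n_descriptors):
        one_hot[:, j * g : (j + 1) * g] = states == j
    counts = np.empty((q, m))
    for r in range(q):
        idx = rng.integers(0, m, size=m)
        counts[r] = np.bincount(idx, minlength=m)
    flat = counts @ one_hot / m
    return flat.reshape(q, n_descriptors, g)


def bootstrap_curves(
    tasks: Sequence[TaskRecord],
    descriptors: Sequence[str],
    grid: TimeGrid | None = None,
    q: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> BootstrapEnsemble:
    """Resample the task set q times and recompute the curve set each time.

    Replicate r equals ``compute_curves(resample_tasks(tasks, rng), ...)``
    for the same generator state; the computation is vectorized by resampling
    task indices against precomputed per-task indicator matrices rather than
    rebuilding task records.
    """
    if q < 1:
        raise TDSValidationError("q must be at least 1")
    if grid is None:
        grid = TimeGrid.uniform()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    states = state_matrix(tasks, descriptors, grid)
    base = curves_from_states(states, descriptors, grid)
    reps = _replicates_from_states(states, len(descriptors), q, rng)
    return BootstrapEnsemble(base, reps, m=len(tasks))


def ensemble_from_states(
    states: np.ndarray,
    descriptors: Sequence[str],
    grid: TimeGrid,
    q: int,
    rng: np.random.Generator,
) -> BootstrapEnsemble:
    """As :func:`bootstrap_curves`, but from a precomputed state matrix."""
    base = curves_from_states(states, descriptors, grid)
    reps = _replicates_from_states(states, len(descriptors), q, rng)
    return BootstrapEnsemble(base, reps, m=states.shape[0])


def band_from_order_statistics(
    ensemble: BootstrapEnsemble, band: str = "ci95"
) -> UncertaintyBands:
    """Percentile band from the sorted replicate values at each point.

    With rank k = round(alpha * q), the band runs from the k-th smallest to
    the k-th largest replicate value.  Ties are kept as-is on the sorted
    multiset; no interpolation between order statistics.
    """
    q = ensemble.q
    k = percentile_rank(q, band)
    srt = np.sort(ensemble.replicate_values, axis=0)
    lower = srt[k - 1]
    upper = srt[q - k]
    return UncertaintyBands(
        ensemble.base_curves.descriptors,
        ensemble.base_curves.grid,
        lower,
        upper,
        band=band,
        method="bootstrap",
    )


def normal_bands(curves: TDSCurveSet, m: int, band: str = "ci95") -> UncertaintyBands:
    """Normal-approximation band d +/- z * sqrt(d(1-d)/m), clipped to [0, 1].

    At d = 0 or d = 1 the band has zero width; such points, and any with
    fewer than 5 expected successes or failures, are flagged in
    ``low_count_mask`` since the approximation is unreliable there.
    """
    if m < 1:
        raise TDSValidationError("sample size m must be at least 1")
    z = BAND_Z[_check_band(band)]
    d = curves.values
    half = z * np.sqrt(d * (1.0 - d) / m)
    mask = (m * d < LOW_COUNT_THRESHOLD) | (m * (1.0 - d) < LOW_COUNT_THRESHOLD)
    return UncertaintyBands(
        curves.descriptors,
        curves.grid,
        np.clip(d - half, 0.0, 1.0),
        np.clip(d + half, 0.0, 1.0),
        band=band,
        method="normal",
        low_count_mask=mask,
    )
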