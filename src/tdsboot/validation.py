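"""Monte Carlo coverage study for TDS uncertainty bands.

The study asks: when a band (bootstrap percentile or normal approximation,
at the 95%-CI or SE level) is estimated from a sample of m tasks, how often
does it actually contain the population dominance proportion?  A large
simulated population of tasks serves as ground truth; repeatedly a sample of
m distinct tasks is drawn from it, bands are estimated from that sample, and
pointwise inclusion of the population curve values is recorded.  The
resulting inclusion probabilities — the empirical coverage, per descriptor
and time point — should approach the nominal 0.95 and 0.682 for large m and
are known to fall short for small samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bootstrap import (
    BAND_ALPHA,
    UncertaintyBands,
    band_from_order_statistics,
    ensemble_from_states,
    normal_bands,
    percentile_rank,
)
from .core import TDSCurveSet, TDSValidationError, curves_from_states
from .markov import MarkovTDSModel, exact_marginals, simulate_state_matrix

logger = logging.getLogger(__name__)

#: the m values of the full-scale study
DEFAULT_SAMPLE_SIZES = (15, 30, 50, 75, 100, 150, 200, 250, 300, 350, 400, 450, 500)


@dataclass(frozen=True)
class InclusionStudyConfig:
    """Conditions of a coverage study.

    Defaults are the full-scale conditions: a population of n = 10,000
    simulated tasks, thirteen sample sizes from 15 to 500, q = 1000 bootstrap
    replicates and 1000 Monte Carlo repetitions per sample size — several
    hours of computation.  Use :meth:`desk_scale` for a single-m run with 200
    repetitions that finishes in well under a minute.

    ``exact_reference`` replaces the finite simulated population's curves by
    the model's exact marginals as the inclusion reference (an
    infinite-population mode used by property tests; sampling is then with
    replacement, i.e. i.i.d. draws from the model).
    """

    model: MarkovTDSModel
    population_size: int = 10_000
    sample_sizes: tuple[int, ...] = DEFAULT_SAMPLE_SIZES
    q: int = 1000
    outer_reps: int = 1000
    methods: tuple[str, ...] = ("bootstrap", "normal")
    bands: tuple[str, ...] = ("ci95", "se")
    seed: int = 0
    exact_reference: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_sizes", tuple(int(m) for m in self.sample_sizes))
        object.__setattr__(self, "methods", tuple(self.methods))
        object.__setattr__(self, "bands", tuple(self.bands))
        if self.population_size < 1:
            raise TDSValidationError("population_size must be positive")
        if not self.sample_sizes:
            raise TDSValidationError("at least one sample size is required")
        bad = [m for m in self.sample_sizes if m < 1 or m > self.population_size]
        if bad:
            raise TDSValidationError(
                f"sample sizes {bad} outside 1..population_size ({self.population_size})"
            )
        if self.outer_reps < 1:
            raise TDSValidationError("outer_reps must be at least 1")
        for band in self.bands:
            percentile_rank(self.q, band)  # raises if q is too small for the rank
        unknown = set(self.methods) - {"bootstrap", "normal"}
        if unknown:
            raise TDSValidationError(f"unknown methods {sorted(unknown)}")

    @classmethod
    def desk_scale(
        cls,
        model: MarkovTDSModel,
        m: int = 500,
        outer_reps: int = 200,
        seed: int = 0,
        **kwargs,
    ) -> "InclusionStudyConfig":
        """Scaled-down conditions: one sample size, 200 Monte Carlo reps."""
        return cls(model, sample_sizes=(m,), outer_reps=outer_reps, seed=seed, **kwargs)


@dataclass(frozen=True, eq=False)
class InclusionStudyResult:
    """Per-point inclusion probabilities and mean band halfwidths.

    ``inclusion[(m, method, band)]`` is a (p, n_grid) matrix: the fraction of
    the ``outer_reps`` Monte Carlo repetitions in which the band estimated
    from an m-task sample contained the population value at that point.
    ``mean_halfwidth`` holds the corresponding average band halfwidths.
    """

    reference: TDSCurveSet
    inclusion: dict
    mean_halfwidth: dict
    outer_reps: int
    config: InclusionStudyConfig

    @property
    def descriptors(self) -> tuple[str, ...]:
        return self.reference.descriptors

    def eligible_mask(self, ref_range: tuple[float, float] = (0.1, 0.9)) -> np.ndarray:
        """Points whose population proportion lies within ``ref_range``.

        Near-zero (and near-one) proportions are conventionally excluded from
        headline coverage summaries: below the chance level they are treated
        as trivial, and bands there are degenerate.
        """
        lo, hi = ref_range
        v = self.reference.values
        return (v >= lo) & (v <= hi)

    def mean_inclusion(
        self,
        m: int,
        method: str = "bootstrap",
        band: str = "ci95",
        ref_range: tuple[float, float] = (0.1, 0.9),
    ) -> float:
        """Inclusion probability averaged over eligible descriptor/time points."""
        key = (m, method, band)
        if key not in self.inclusion:
            raise TDSValidationError(f"no study cell {key}; have {sorted(self.inclusion)}")
        mask = self.eligible_mask(ref_range)
        if not mask.any():
            raise TDSValidationError(f"no grid points with reference in {ref_range}")
        return float(self.inclusion[key][mask].mean())

    def mean_halfwidths(
        self,
        m: int,
        method: str = "bootstrap",
        band: str = "ci95",
    ) -> np.ndarray:
        return self.mean_halfwidth[(m, method, band)]

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per (m, method, band, descriptor, t')."""
        rows = []
        t = self.reference.grid.points
        for (m, method, band), incl in sorted(self.inclusion.items()):
            hw = self.mean_halfwidth[(m, method, band)]
            for j, d in enumerate(self.descriptors):
                rows.append(
                    pd.DataFrame(
                        {
                            "m": m,
                            "method": method,
                            "band": band,
                            "descriptor": d,
                            "t_prime": t,
                            "reference": self.reference.values[j],
                            "inclusion": incl[j],
                            "mean_halfwidth": hw[j],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def write_csvs(self, directory: str | Path) -> list[Path]:
        """One CSV per (m, method, band) cell, plus the combined long table."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        frame = self.to_frame()
        paths = []
        for (m, method, band), cell in frame.groupby(["m", "method", "band"], sort=True):
            path = directory / f"inclusion_m{m}_{method}_{band}.csv"
            cell.to_csv(path, index=False)
            paths.append(path)
        combined = directory / "inclusion_all.csv"
        frame.to_csv(combined, index=False)
        paths.append(combined)
        return paths


def population_reference(
    model: MarkovTDSModel,
    n: int,
    rng: np.random.Generator | int | None = None,
    exact: bool = False,
) -> TDSCurveSet:
    """Ground-truth curves: an n-task simulated population (or exact marginals)."""
    if exact:
        return exact_marginals(model)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    states = simulate_state_matrix(model, n, rng)
    return curves_from_states(states, model.descriptors, model.grid)


def run_inclusion_study(
    config: InclusionStudyConfig, output_dir: str | Path | None = None
) -> InclusionStudyResult:
    """Run the coverage experiment defined by ``config``.

    For every sample size m and every Monte Carlo repetition: draw m distinct
    tasks from the population (without replacement; with replacement only
    inside the bootstrap), build the requested bands from that sample, and
    record pointwise inclusion of the population value.  Sampling streams are
    keyed by (seed, m), so adding or removing sample sizes does not perturb
    the others.  If ``output_dir`` is given, per-cell CSVs are written there.
    """
    model = config.model
    grid = model.grid
    descriptors = model.descriptors
    p = len(descriptors)

    pop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    pop_states = simulate_state_matrix(model, config.population_size, pop_rng)
    if config.exact_reference:
        reference = exact_marginals(model)
    else:
        reference = curves_from_states(pop_states, descriptors, grid)
    ref = reference.values

    inclusion: dict = {}
    halfwidth: dict = {}
    for m in config.sample_sizes:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, m]))
        incl_sum = {
            (method, band): np.zeros((p, len(grid)))
            for method in config.methods
            for band in config.bands
        }
        hw_sum = {key: np.zeros((p, len(grid))) for key in incl_sum}
        for rep in range(config.outer_reps):
            if config.exact_reference:
                sample = pop_states[rng.integers(0, config.population_size, size=m)]
            else:
                sample = pop_states[rng.choice(config.population_size, size=m, replace=False)]
            need_boot = "bootstrap" in config.methods
            ensemble = (
                ensemble_from_states(sample, descriptors, grid, config.q, rng)
                if need_boot
                else None
            )
            base = (
                ensemble.base_curves
                if ensemble is not None
                else curves_from_states(sample, descriptors, grid)
            )
            for method in config.methods:
                for band in config.bands:
                    if method == "bootstrap":
                        bands_: UncertaintyBands = band_from_order_statistics(ensemble, band)
                    else:
                        bands_ = normal_bands(base, m, band)
                    incl_sum[(method, band)] += bands_.contains(ref)
                    hw_sum[(method, band)] += bands_.halfwidth
            if (rep + 1) % 50 == 0 or rep + 1 == config.outer_reps:
                logger.info(
                    "inclusion study m=%d: %d/%d repetitions", m, rep + 1, config.outer_reps
                )
        for key, total in incl_sum.items():
            method, band = key
            inclusion[(m, method, band)] = total / config.outer_reps
            halfwidth[(m, method, band)] = hw_sum[key] / config.outer_reps
        logger.info("inclusion study m=%d done (seed=%d, q=%d, n=%d)",
                    m, config.seed, config.q, config.population_size)

    result = InclusionStudyResult(
        reference=reference,
        inclusion=inclusion,
        mean_halfwidth=halfwidth,
        outer_reps=config.outer_reps,
        config=config,
    )
    if output_dir is not None:
        result.write_csvs(output_dir)
    return result
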