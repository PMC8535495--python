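# Methods

## TDS curves

A task record holds an ordered sequence of (descriptor, time) selections
between a start and a stop time.  Dominance intervals are **right-open**: at
the instant a button is pushed the new descriptor becomes dominant, and the
last selection persists through the end of the task.  A selection at exactly
the stop time is admitted and is dominant only at the final instant — this
keeps simulated trajectories (which may change state at the last grid point)
exactly representable as task records.  Before the first selection no
descriptor is dominant, so for observed panels the curves of all descriptors
may sum to less than 1 early in the timeline; proportions are always taken
over all *n* tasks, never only over the tasks that have responded.  Duplicate
selection of the already-dominant descriptor is legal and is a no-op.

Time is normalized affinely so that start = 0 and stop = 1 (tolerance
1e-12, double precision throughout).  Curves are evaluated on an explicit
grid: 101 evenly spaced points by default for observed data, and the native
(n_steps + 1)-point grid for simulated tasks, where the trajectory lives
exactly on the grid and no interpolation question arises.

## Markov task simulator

A population of TDS tasks is modelled as a discrete-time Markov chain on the
descriptors: an initial distribution at t′ = 0, then `n_steps` transitions
(default 20, so Δt′ = 1/20).  The transition table changes along the
timeline through a *phase schedule*; the built-in models use three phases
covering steps 0–6, 7–13 and 14–19, mirroring the distinct early/middle/late
dynamics of eating.  **Phase attribution at boundaries** is by the source
time of a transition: the move from grid point k to k + 1 uses the table of
the phase containing t′ = k/20.  The alternative (destination-time) reading
would shift curves by at most one grid step; the convention is fixed in one
place (`matrix_for_step`) and shared by the sampler and the analytic
marginals, which is what matters for correctness.

Two reference models ship with the package: Case 1 (4 descriptors, initial
distribution (0.5, 0.25, 0.25, 0)) and Case 2 (6 descriptors, initial
(1/6, 1/3, 1/3, 1/6, 0, 0), stored as double-precision quotients).  In the
Case 2 definition one last-phase row (from D3) is renormalized to unit sum;
all rows are validated to sum to 1 within 1e-9 on construction and on load
from a model spec file, with diagnostics naming the offending rows.

Sampling is vectorized with a fixed draw order — all initial states first,
then the transitions of step 0, step 1, … — so a population is
bit-reproducible given a seed.  Inverse-CDF draws against row cumulative
sums are clipped to the last state to guard against cumulative rounding.

`exact_marginals` propagates the initial distribution through the step
matrices, d(t′_k) = d(0)·M₀⋯M₍k₋₁₎, giving the exact population curves.  It
is the simulator's oracle: the test suite checks it against exhaustive
path enumeration on truncated models (where all p^(n_steps+1) paths can be
summed) and checks simulated populations against it at 4·√(0.25/n).

## Bootstrap bands

Resampling is of **whole tasks only**, uniformly with replacement, m out of
m — never of time points or blocks; the task is the independent sampling
unit and its internal time course is kept intact.  Replicate curve sets are
computed by a counting shortcut: per-task indicator matrices are built once,
and each replicate is a count-weighted average over resampled task indices.
The index stream is drawn per replicate, so each replicate is bit-identical
to literally resampling the task list with the same generator (tested).

Percentile bands use ranks on the sorted multiset of the q replicate values
at each point: lower bound the k-th smallest, upper the k-th largest, with
k = round(α·q), α = 0.025 for the 95% CI and α = 0.1587 (= 1 − Φ(1)) for
the SE band.  At the default q = 1000 this gives ranks 25 and 159.  The SE
"band" is thus a central ≈68.3% percentile interval, not a parametric ±σ
interval.  Ties share values and no interpolation is applied.  A q so small
that the rank would fall below 1 is an error rather than a clamped band.

Normal-approximation bands are d ± z·√(d(1−d)/m), z ∈ {1.96, 1}, clipped to
[0, 1]; points with m·d < 5 or m·(1−d) < 5 are flagged (`low_count_mask`)
because the approximation is unreliable there — at d ∈ {0, 1} the band
degenerates to zero width.

## Coverage (inclusion-probability) study

Ground truth is the curve set of a simulated population of n tasks (default
10,000).  For each Monte Carlo repetition, m distinct tasks are drawn from
the population **without replacement** — a sample of distinct panel results,
with replacement occurring only inside the bootstrap — then the requested
bands (bootstrap and/or normal, CI95 and/or SE) are estimated from the
sample and the pointwise inclusion of the population value (endpoints
inclusive) is recorded.  Per-point inclusion probabilities and mean band
halfwidths are retained for every (m, method, band) cell; headline summaries
average over the points whose population proportion lies in [0.1, 0.9],
since near-degenerate proportions (in particular those below the chance
level, conventionally treated as trivial) produce zero-width bands and
uninformative coverage.  Per-point values are always available alongside the
summary.  An `exact_reference` switch replaces the finite population by the
model's exact marginals (and the outer draw by i.i.d. sampling), which turns
the study into a textbook coverage experiment used by the property tests.

Random streams are keyed as (seed, 0) for the population and (seed, 1, m)
per sample size, so runs at different m share the population, and adding or
removing sample sizes does not perturb the others.

**Problem sizes.**  The full-scale study (thirteen sample sizes 15–500,
1000 repetitions, q = 1000) reproduces the complete coverage profile and
costs hours of CPU; it sits behind the `--full-scale` flag.  The package's
standard desk-scale run — one sample size, 200 repetitions, q = 1000 against
an n = 10,000 population — pins the mean coverage to a Monte Carlo standard
error of √(0.25/200) ≈ 0.035 per point (smaller after averaging across
points) in a few seconds, which is the scale used by the test suite and the
acceptance script.

## What the simulations do and do not show

The Markov populations exercise the full pipeline with known ground truth:
every task selects a descriptor at t′ = 0, states change on a fixed
21-point lattice, and transition dynamics are homogeneous within phases.
Real panel data differ in ways the generator does not emulate: a gap before
the first selection (handled by the curve code, but absent from the
simulated populations), event times off the lattice, assessor heterogeneity
and per-assessor correlation across products, and descriptor lists whose
dominance proportions hug 0 or 1 for long stretches.  Passing coverage tests
on the simulated populations therefore validates the estimator machinery,
not the adequacy of any particular panel's sample size; the small-m
undershoot observed in the study (bands too narrow below m ≈ 50) is, if
anything, expected to be worse under assessor heterogeneity.

## Numerical choices

* Probability vectors and matrix rows validated to 1e-9; exact marginals'
  column sums are exact to ≤ 1e-12 over 20 steps and are not renormalized.
* Curve values validated to [0, 1] within 1e-9; column sums ≤ 1 + 1e-6.
* Band inclusion counts endpoint hits as inclusions (order statistics are
  attained values, so the closed interval is the natural reading).
* Task CSV/JSON I/O round-trips event times exactly (`%.17g` on write,
  `round_trip` float parsing on read).
* Unknown-descriptor queries, empty task lists/files, zero-duration tasks,
  non-stochastic rows and uncovered phase steps all raise
  `TDSValidationError` with the offending task or row named.
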