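# tdsboot

Bootstrap uncertainty estimation for **temporal dominance of sensations
(TDS)** curves, with a Markov-chain simulator of TDS tasks and a Monte Carlo
coverage study to validate the estimated uncertainties.

## The problem

In a TDS task an assessor eats (or otherwise experiences) a sample and
sequentially selects, from a panel of *p* descriptors, the one sensation that
is dominant right now; a selection stays in force until the next one.  Task
*i* therefore yields binary step functions *b<sub>ij</sub>(t)* ∈ {0, 1}, with
at most one descriptor dominant at any instant.  After rescaling each task's
duration to the unit interval, the results of *n* independent tasks are
aggregated into **TDS curves** — the dominance proportions

> d<sub>j</sub>(t′) = (1/n) Σ<sub>i</sub> b<sub>ij</sub>(t′),  t′ ∈ [0, 1].

A single panel produces one curve set, which blocks any analysis that needs
the curves' sampling variability: hypothesis tests on curve values, peak
comparisons, or machine-learning methods that want many curve sets.
`tdsboot` addresses this by **bootstrap resampling of whole tasks**: from the
*m* observed tasks, draw *m* with replacement and recompute the curve set,
*q* times over (the sampling unit is the task, never a time point, so the
within-task serial structure is untouched).  At each descriptor and time
point the *q* replicate values give

* a **95% confidence band**: the central 95% percentile interval — for
  *q* = 1000, the range between the 25th smallest and 25th largest replicate
  value;
* a **standard-error band**: the central ≈68.3% interval — for *q* = 1000,
  the 159th smallest to 159th largest value;

and, for comparison, the normal-approximation bands for a proportion,
d ± z·√(d(1−d)/m) with z = 1.96 (95% CI) or z = 1 (SE).

To check that these bands mean what they claim, the package simulates TDS
task populations with a **phase-dependent Markov chain** (descriptors as
states, 20 transitions per task, separate transition tables for the initial,
middle and last thirds of the timeline; two built-in reference models with 4
and 6 descriptors) and runs a **coverage study**: repeatedly draw *m* tasks
from a 10,000-task simulated population, build the bands, and measure how
often they contain the population proportions.  For large *m* the observed
inclusion probabilities sit near the nominal 0.95 and 0.682; for small *m*
(≲ 50) the bands are systematically too narrow.

## Worked example

```python
import numpy as np
from tdsboot import (builtin_model, simulate_population, bootstrap_curves,
                     band_from_order_statistics, normal_bands)

model = builtin_model(1)                     # 4 descriptors, 3 phases, 20 steps
tasks = simulate_population(model, 100, rng=np.random.default_rng(0))
ens = bootstrap_curves(tasks, model.descriptors, model.grid,
                       q=1000, rng=np.random.default_rng(1))
ci = band_from_order_statistics(ens, "ci95")
norm = normal_bands(ens.base_curves, m=100, band="ci95")

k = 10  # grid index of t' = 0.5
d1 = model.descriptors.index("D1")
print(f"d_D1(0.5)        = {ens.base_curves.curve('D1')[k]:.3f}")
print(f"bootstrap 95% CI = [{ci.lower[d1, k]:.3f}, {ci.upper[d1, k]:.3f}]")
print(f"normal    95% CI = [{norm.lower[d1, k]:.3f}, {norm.upper[d1, k]:.3f}]")
```

prints

```
d_D1(0.5)        = 0.160
bootstrap 95% CI = [0.090, 0.240]
normal    95% CI = [0.088, 0.232]
```

Of these 100 simulated tasks, 16% have descriptor D1 dominant at the
mid-point of the normalized timeline; the percentile interval of the 1000
bootstrap curve sets brackets that proportion within about ±0.08, and the
closed-form normal band almost coincides with it — the expected behaviour at
a comfortable sample size.

The same pipeline is available from the shell:

```sh
tds simulate --case 1 -n 200 --seed 7 -o tasks.csv
tds curves tasks.csv -o curves.csv
tds bootstrap tasks.csv -q 1000 --band ci95,se --method bootstrap,normal -o bands/
tds validate --case 1 -m 200 --outer 200 -q 1000 --seed 7 -o study/
```

`tds validate --full-scale` runs all thirteen sample sizes
(15 … 500) with 1000 Monte Carlo repetitions each — hours of CPU; the
default desk-scale run takes seconds.

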