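# lifedisparity

Lifespan disparity asks not how long people live on average, but how unequally
length of life is distributed. The standard disparity measure is
**e†** (e-dagger), the average life expectancy lost due to death,

    e† = ∫₀^ω d(a) e(a) da,

where `d(a) = l(a)·μ(a)` is the life-table distribution of deaths, `e(a)` the
remaining life expectancy at age `a`, `l(a) = exp(−∫₀^a μ)` the survival
function, and `ω` the maximum age. e† alone can mislead: a mortality decline
*below* a threshold age **a†** compresses the age-at-death distribution and
lowers e†, while a decline *above* a† stretches it to older ages and raises
e†. Splitting e† at a† gives a compression component `ec†` and an expansion
component `ee†` (`e† = ec† + ee†`), and the headline summary implemented here
is the **ratio of expansion to compression**,

    REC = ee† / ec†,

with its additive counterpart `DEC = ee† − ec†`. The threshold age is located
through the sensitivity of e† to a relative mortality reduction at age `x`,

    g(x) = d(x) · [ e†(x) + e(x)(H(x) − 1) ],

with `H(x)` the cumulative hazard and `e†(x)` the conditional disparity above
`x`; a† is the unique zero crossing of the bracket (it exists whenever the
life-table entropy `e†/e0` is below one). The change of ln REC over time obeys
the exact identity `d ln REC/dt = d ln ee†/dt − d ln ec†/dt`, and the change
of e† decomposes as `ė† = ∫ ρ(x) g(x) dx` with `ρ = −μ̇/μ` the age-specific
rate of mortality decline.

The package is aimed at demographers and population-health researchers: it
builds fine-grid continuous life tables from any hazard schedule (including
HMD-style 1×1 text files), computes the full disparity decomposition, the
change decomposition between two schedules, and simulates long-run mortality
decline with a three-component Siler model under shifting /
faster-below-a† / faster-above-a† scenarios.

## Worked example

A Gompertz–Makeham population (`μ(x) = 1e-4·e^{0.1x} + 1e-3`):

```python
import numpy as np
import lifedisparity as ld

grid = ld.make_grid(omega=120, step=0.1)
mu = 1e-4 * np.exp(0.1 * grid.ages) + 1e-3
lt = ld.lifetable_from_hazard(ld.HazardSchedule(grid=grid, mu=mu))
print(ld.decompose(lt).summary())
```

```
e0 (life expectancy at birth)     61.3370 years
e-dagger (life disparity)         11.3215 years
a-dagger (threshold age)          59.5910 years
compression component ec           7.5639 years
expansion component ee             3.7576 years
REC = ee/ec                        0.4968
DEC = ee-ec                       -3.8062 years
entropy = e-dagger/e0              0.1846
```

People in this population lose 11.3 years of remaining life expectancy to
death on average. The threshold age (59.6) sits below life expectancy (61.3):
averting deaths before 59.6 narrows the death distribution, after it widens
it. Two thirds of the disparity (7.56 of 11.32 years) accrues below the
threshold, so compression dominates (REC ≈ 0.50).

Given two published component pairs five years apart — e.g. Russian men,
whose (ec†, ee†) moved from (9.64, 5.06) to (9.82, 6.04) during 1990–1995 —
the change decomposition shows *why* the REC rose:

```python
print(ld.component_rates_from_values(9.64, 5.06, 9.82, 6.04, dt=5.0).summary())
```

```
interval length dt                      5.00 years
d ln ee / dt (expansion growth)       +0.0354 /year
d ln ec / dt (compression growth)     +0.0037 /year
d ln REC / dt                         +0.0317 /year
```

Expansion grew at 3.5%/year against 0.4%/year for compression, so ln REC
rose at 3.2%/year — the growing dominance of old-age expansion, even though
both components increased.

The command-line interface exposes the same pipeline
(`lifedisparity compute|change|simulate|fixtures`); e.g.

```sh
lifedisparity simulate --scenario faster_above --horizon 150 --dt 1 --out traj.csv
```

writes the 151-year trajectory of (e0, e†, a†, ec†, ee†, REC) and reports the
REC peak year.

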