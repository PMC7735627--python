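# Methods

## Model

All quantities derive from a force of mortality μ(x) on a bounded age range
[0, ω]. The continuous life-table functions are

- survival l(x) = exp(−∫₀ˣ μ), cumulative hazard H(x) = −ln l(x),
- death density d(x) = l(x) μ(x),
- remaining life expectancy e(x) = ∫ₓ^ω l / l(x),

and lifespan disparity is e† = ∫₀^ω d(a) e(a) da, the mean remaining life
expectancy at death. The sensitivity of e† to a relative mortality reduction
concentrated at age x is g(x) = d(x)·φ(x) with the bracket
φ(x) = e†(x) + e(x)(H(x) − 1), where e†(x) = ∫ₓ^ω d e / l(x) is the
conditional disparity above x. Because d(x) ≥ 0, φ carries the sign
structure of g; for a life table with entropy e†/e0 < 1, φ is negative at 0
and crosses zero exactly once, at the threshold age a†. The compression and
expansion components are ec† = ∫₀^{a†} d e and ee† = ∫_{a†}^ω d e, with
REC = ee†/ec† and DEC = ee† − ec†.

Change over time uses two exact routes. Discrete: between two schedules dt
years apart, d ln REC/dt = (Δ ln ee†)/dt − (Δ ln ec†)/dt, an identity given
REC's definition; each endpoint uses its own threshold age. Continuous:
ė† = ∫ ρ g with ρ(x) = −μ̇/μ estimated as −Δ ln μ / dt, split at a† into
compression and expansion change rates. The sensitivity integral is
evaluated on a mid-interval schedule whose hazard is the geometric mean of
the endpoints — a midpoint evaluation that cancels the first-order bias of
either endpoint; for smooth proportional declines over dt ≤ 1 year it
matches the direct difference of e† within a few percent (tested at 5%).

## Numerics

Everything lives on a uniform age grid, by default ω = 120 with step
0.1 years. Cumulative hazards and survivorship integrals use the composite
trapezoid rule. Integrals *weighted by the death density* instead use exact
per-cell survival drops (l_i − l_{i+1}) times the trapezoid-averaged
integrand: a plain trapezoid on l·μ leaves an O(step²) defect (≈8e-6 for a
constant hazard of 0.1 at step 0.1) in the total death mass, whereas the
cell-mass form telescopes, making ∫d + l(ω) = 1 exact and the
compression/expansion split conservative to machine precision when the cell
containing a† is divided with l and e linearly interpolated.

Closure at ω: any surviving mass l(ω) is treated as deaths at exactly ω
with e(ω) = 0, so the death distribution always has total mass one and e†
stays bounded. Ages where survival has underflowed to zero report e = 0 and
are excluded from threshold scanning (survival below 1e-12).

Threshold location scans φ for sign changes between consecutive *nonzero*
grid values (exact zeros, e.g. the closed-out tail, carry no information)
and interpolates linearly inside the bracketing cell. Entropy ≥ 1 raises a
no-threshold error; several sign changes raise an ambiguity error listing
all crossings rather than silently picking one. A φ already non-negative at
age 0 (the constant-hazard limit) returns a† = 0 and an infinite REC with a
warning.

Grid adequacy: halving the step changes e0 by < 1e-4 years for the smooth
fixture families; the steep near-rectangular family converges at the same
second order but from a larger constant (3e-4 at step 0.1). Discrete 1-year
rates (HMD-style mx) are taken as a piecewise-constant hazard on [x, x+1)
(ax is ignored); the within-year curvature of a Gompertz hazard at b = 0.1
makes this discretization worth ≈0.06 years of e0.

## Siler scenario simulator

μ(x,t) = α₁e^{−ρ₁t−β₁x} + α₂e^{−ρ₂t} + α₃D₃(x,t)e^{β₃x}, defaults
α₁ = 1e-9, α₂ = 3e-4, α₃ = 1e-6, β₁ = 1e4, β₃ = 0.13, ρ₁ = ρ₂ = 0.01 /year
(approximating a contemporary low-mortality female population; initial
mortality μ(0,0) = 3.01001e-4). The senescent decline rate ρ₃(x) is 0.01
everywhere ("shifting"), 0.013 below a† ("faster progress below"), or 0.013
above a† ("faster progress above"). As printed, α₁ with β₁ = 1e4 makes the
infant component numerically negligible at every positive age; the values
are kept but configurable.

Because a† itself rises as mortality falls, ρ₃(x) must be re-anchored over
time. Two conventions are implemented:

- **repriced** (default): D₃(x,t) = exp(−ρ₃(x; a†)·t) with each age
  classified against the threshold of the previous step — the hazard
  formula read literally, with an age's whole decline history re-priced
  when the threshold passes it. This is the convention whose trajectories
  show the expected structure: under faster-progress-above the REC rises,
  peaks near simulated year 100 and then falls, and faster-progress-below
  yields the highest life expectancy at every year.
- **accumulated**: D₃ compounds step by step (D₃ ← D₃·e^{−ρ₃(x)dt}), never
  revising past decline. Kept for sensitivity analysis; it damps the
  scenario differences (the REC peak moves to ≈year 60 and the
  faster-above scenario overtakes faster-below in e0 after ≈year 80).

Both collapse to the closed form e^{−ρ₃t} when ρ₃ is age-constant (verified
to 1e-10). A `frozen_threshold` flag pins the classification at the
baseline a†. Default horizon 150 years, dt = 1. The simulator's default
grid extends to ω = 130: by year 150 life expectancy approaches 99 years
and with ω = 120 the truncated survival mass visibly distorts the late
expansion component (shifting the REC peak by ~6 years); ω = 130 and
ω = 140 give identical peak years. The ρ₃ discontinuity at a† is kept (no
smoothing); it produces ~1e-4-scale wiggles in the REC series as the
threshold crosses grid cells.

## Synthetic data and what the tests show

The fixture families (constant, Gompertz, Gompertz–Makeham,
near-rectangular) span life-table entropy from ≈1 (exponential, where the
threshold degenerates to 0 and REC diverges) to ≈0.04 (deaths piled near
one age). They exercise every code path with closed-form oracles but do not
emulate infant-mortality humps, accident bumps, cohort irregularities or
sampling noise of real national schedules — passing tests demonstrate the
correctness of the integral transforms and decompositions, not robustness
to rough empirical rate surfaces (no smoothing/graduation is provided). The
HMD reader supports real 1×1 files, but no registered data ships with the
package; published component pairs are used as numeric inputs where tables
are reproduced.

## Known limitations

- Single-decrement period/cohort tables only; no abridged (5-year) tables,
  no parametric fitting of the Siler model to data.
- ρ estimation between two time points is a finite difference; strongly
  non-proportional mortality change over long intervals degrades the
  sensitivity-integral route (the discrete component route is exact).
- The closure-at-ω convention slightly inflates d near ω for heavy
  old-age survival; choose ω so that l(ω) is negligible (the simulator's
  ω = 130 default does this for its scenarios).
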