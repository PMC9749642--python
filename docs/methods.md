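# Methods

## Model structure and assumptions

The simulator is a stock-flow system-dynamics model. Stocks accumulate;
flows are rates in stock units per year; auxiliaries are algebraic; the
four nonlinear couplings are piecewise-linear lookup tables ("rate
effects") evaluated with endpoint clamping. All equations live in a
closed expression language (arithmetic, comparisons, `IF_THEN_ELSE`,
`MAX`, `MIN`, lookup application) parsed into expression trees and
compiled to closures — configurations are data and can never execute
code.

Assumptions baked into the structure:

* **Population is exogenous** — constant fractional growth, no feedback
  from the health system.
* **Inflow-only stocks.** Beds, specialists and home-care capacity have
  no decommissioning/attrition outflows; each inflow closes as
  `stock × fractional rate` from its lookup, the standard fractional-
  growth pattern. This makes the loop polarities match the causal
  structure: scarce beds per patient accelerate construction (balancing),
  scarce specialists per bed attract specialists (reinforcing via the
  traveler stream), and high occupancy grows home care (balancing, via
  shortened stays).
* **Occupancy cap.** Effective occupancy cannot exceed the optimal rate
  (85%); demand beyond `0.85 × supply` is shortage, not occupancy. As a
  consequence `shortage > 0` exactly when the occupancy rate is pinned
  at 0.85.
* **Home-care substitution** enters only through the length of stay:
  `L = L0 · F4(H / (365·B))` with `F4(0) = 1`, so zero home care leaves
  stays unadjusted and more home care (relative to bed-days) shortens
  them monotonically.
* **Units.** Home-care capacity is interpreted as service-days per
  year, making the F4 driver dimensionless; its published initial value
  (76,650) never states units, and this reading is the one under which
  the share is a pure number.

## Parameters

| parameter | units | default | note |
|---|---|---|---|
| growth proportion | /yr | 0.014 | published |
| patient-to-population ratio | patients/person/yr | 0.129 | published |
| optimal occupancy | fraction | 0.85 | published |
| days per year | d | 365 | fixed |
| initial stocks (P, B, S, H) | — | 1,557,600 / 3560 / 690 / 76,650 | published |
| travelers-to-specialists ratio | patients/specialist/yr | 60 (synthetic) | no published value; required config |
| base length of stay | d | 4.45 (synthetic) | no published value; required config |
| lookup tables F1–F4 | mixed | synthetic archetypes | no published breakpoints |

The last three rows are **synthetic placeholders**, chosen so the
baseline configuration exhibits a mid-horizon shortage onset; they are
not estimates of the study city.

## Time conventions and numerics

* Explicit Euler, the conventional default for this model class:
  `stock(t+dt) = stock(t) + dt · net_flow(t)`. A one-stock linear model
  therefore reproduces its geometric closed form exactly, which the
  tests exploit as an oracle.
* Calendar-year time: the horizon is [2015, 2035], i.e. the 20 years
  2015–2034 integrated through the end of 2034; "end simulation" is the
  value at 2035.0. Default `dt = saveper = 1/12` year — shortage onset
  is meaningful at sub-annual resolution — with both exposed as
  configuration, never constants.
* Division guard: any division with an exactly-zero denominator yields
  0 and a warning naming the variable and time, keeping degenerate
  extreme-condition runs (zero beds, zero patients) finite.
* `saveper` must be an integer multiple of `dt` within relative
  tolerance 1e-9. Runs are pure float arithmetic: identical inputs give
  bit-identical trajectories, and each stock trajectory replays exactly
  from its saved flows when `saveper = dt`.

## Scenarios and policies

Scenarios are environmental assumption sets applied from the
intervention start (2020.0, the first year after the 2015–2019
observation window): an optional constant override of the growth
proportion and linear ramps on the patient ratio (+0.002/yr²), the base
stay (+0.05 d/yr) and the travelers ratio (−1.0/yr², clamped at zero).
S1 is the status quo; S2 adds the aging ramps; S3 combines reduced
growth (0.010) with aging; S4 adds declining patient travel. The preset
magnitudes are synthetic and trivially overridable in the config.

Policies are constant extra annual inflows (beds/yr, service-days/yr
per yr) from the intervention start — a smooth sustained build-out
rather than a one-time jump, which keeps each lever one-dimensional.
P1 adds nothing, P2 beds only, P3 home care only, P4 both.

### Minimal-intervention solver

For P2/P3 the single lever is bisected until the peak shortage over the
horizon is ≤ tol (default 1 bed-day/yr). Details that matter:

* A policy is judged from the first instant it can act: the Euler
  increment of the start step lands at `start + dt`, so the peak is
  taken over `t ≥ start + dt`. Shortage that predates the intervention
  is irreducible by construction and would otherwise make every solve
  infeasible.
* Bracketing starts at 10 × initial stock / horizon-years and doubles
  up to three times; a still-infeasible bound is reported as an error
  with the tried value (home care, for instance, genuinely cannot clear
  a shortage when F4 is flat).
* Monotone response is sampled (peaks at 0, mid, hi must be
  non-increasing within tol) before bisection; a violation aborts the
  solve rather than returning a wrong root.
* Bisection runs to a lever resolution of 1e-7 × the bracket, far below
  one bed per year.

For P4 the design space was genuinely open. A pure lexicographic rule
(minimize beds over a home-care grid reaching the P3 solution) is
degenerate: bed need decreases monotonically in home care, so the grid
top always yields zero beds and P4 collapses into P3. The package
instead imposes a home-care expansion capacity limit: the grid spans
[0, fraction × P3 solution] with fraction 0.5 by default, minimizing
the bed addition over 25 levels and tie-breaking toward less home care.
This keeps P4 a genuinely mixed policy — beds are the expensive
resource, home care the constrained one — and setting the fraction to
1.0 recovers the pure rule.

## Synthetic data

The generator stands in for unavailable administrative calibration
data. It emulates: monotone rate-effect tables of the loop-implied
shapes (three archetypes — `inert`, `baseline_shortage`,
`early_shortage`); full configurations around the published parameter
and initial-stock values; and annual 2015–2019 observations of beds,
specialists, occupancy, patients and home-care capacity produced by a
noiseless model run times multiplicative lognormal noise (sd 0.05 by
default — registry counts are positive with roughly proportional
errors). Supply-side tables F1–F3 get a ±2% seeded jitter (projected
back onto monotonicity); F4 is exempt because the shortage-onset year
responds strongly to a direct demand multiplier and the study
conditions should not drift materially with the seed. Everything is a
deterministic function of (settings, seed); the blessed fixture is
`baseline_shortage` with seed 20150.

What the generator does **not** emulate: structural drift (care
technology, epidemics — the pandemic period was deliberately out of
scope for the original data), serially correlated measurement error,
age structure, or bed-category heterogeneity. Passing tests therefore
demonstrate internal consistency of the method on data satisfying the
model's own assumptions, not predictive validity for any real city.

## Validation program

* **Historical fit**: simulated vs. observed annual values, MAPE and
  RMSE per variable; zero observations are excluded from MAPE with a
  warning. The CLI's gate of MAPE ≤ 10% per variable is an artifact
  convention, not an external standard.
* **Extreme conditions**: zero population (patients reduce to the
  traveler stream), zero demand (no shortage ever), 1000× beds
  (occupancy collapses, no shortage), zero stay (no bed-days required).
* **Equilibrium**: growth off, lookups inert ⇒ every stock holds its
  initial value to 1e-9 relative, at any dt.
* **Lookup recovery**: free y-values on a fixed x-grid are fitted by
  nested simulation, minimizing summed squared relative residuals with
  a Nelder-Mead simplex; monotonicity is enforced by reparameterizing
  y-values as cumulative signed squared increments (the objective is
  cheap but non-smooth at the occupancy cap, hence derivative-free).
  Before optimizing, a sensitivity screen flags the fit as
  under-determined if observations are fewer than free parameters or
  some free y-value has no influence on the residuals (its breakpoint
  region is never visited by the driver). Recovery fixtures place the
  generating grid just inside the driver range the run actually visits
  (a short fixed-point iteration) so every breakpoint is informative,
  and use brisk generating growth rates so the signal is well above
  2% observation noise.

## Problem sizes

Default experiments use the 2015–2035 horizon at monthly steps (241
saved points, ~25 variables). The randomized structural-invariant suite
runs 200 ten-year configurations; the solver oracle compares bisection
with 0.01-resolution grid scans on ten-year feedback-free
configurations; noisy recovery uses 20 replicate histories. The full
test suite runs in about two minutes on one core; the acceptance script
in under half a minute.

## Known limitations

* Inflow-only stocks cannot represent bed closures or specialist
  attrition; a sustained demand drop leaves capacity frozen, not
  shrinking.
* Explicit Euler at monthly steps is first-order accurate; the model's
  rates (a few percent per year) make the discretization error
  negligible relative to parameter uncertainty, but stiff user-supplied
  lookups would warrant a smaller dt.
* The P4 trade-off requires a home-care capacity fraction; there is no
  cost model (deliberately out of scope), so the 0.5 default encodes a
  feasibility judgment, not an optimum.
* Lookup recovery assumes the x-grid is known and the driver actually
  traverses it; sparse real histories (five annual points) identify at
  most one or two segments, and the under-determination diagnostic will
  say so.
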