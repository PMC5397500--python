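# Methods

## Fruit model

Each fruit is described by two coupled states on its own developmental
("biological age") clock: mass `M(t)` in grams and skin hue `H(t)` in
degrees. Mass follows the Gompertz law `dM/dt = km·M·ln(Mmax/M)` with initial
condition `M(0) = Mmax·exp(−C)`; its closed form
`M(t) = Mmax·exp(−C·e^(−km·t))` is kept throughout the package as an
independent oracle for the numeric integration. Hue decays exponentially
toward the ripe hue, `dH/dt = −(H − Hmin)·kh`, where the rate is modulated by
a mass-triggered switch `kh = kh_max / (1 + (Mmax − M)/Mmax)^s`. The switch
is empirical — it stands in for the climacteric (ethylene-driven) onset of
ripening without modelling it mechanistically — and its steepness `s` makes
`kh` negligible (`kh_max·2^(−s)`) until `M` is within a few percent of
`Mmax`.

Parameters and units: `C` (–, >0), `km` (1/d), `kh_max` (1/d), `H0` and
`Hmin` (degrees, `H0 > Hmin`), `s` (–), per-fruit `Mmax` (g) and `Δt` (d).
Bundled seasonal values: winter `C=4.87, km=0.0702, kh_max=26.02, H0=105.74,
Hmin=52.55, s=54.30`; summer `C=9.76, km=0.11, kh_max=14.83, H0=106.63,
Hmin=51.37, s=33.39`. Internal canonical units are grams and days; the
diameter→mass transform at the measurement boundary is SI
(`m = 4/3·π·(D/2)³·d`, default density 873 kg/m³) and the loader converts kg
to g. Hue from CIELAB `a*, b*` uses the two-argument arctangent mapped to
(0, 180], because the naive `arctan(b*/a*)` is ambiguous for green fruit
(`a* < 0`); pure red (`a*>0, b*=0`) maps to 0°.

## Numerics

`simulate_fruit` integrates the two-state system with an adaptive explicit
Runge–Kutta scheme (rtol 1e-8, atol 1e-10, max step 0.1 d — small enough to
resolve the fast hue transient, time constant ≈ 1/kh_max ≈ 0.04 d, without a
stiff solver). Everywhere performance matters (calibration, population
simulation) the package instead uses the exact solutions: the Gompertz
closed form for mass and the integrating-factor form
`H(t) = Hmin + (H0 − Hmin)·exp(−K(t))`, `K(t) = ∫₀ᵗ kh dτ`, with `K`
tabulated once by trapezoid quadrature on a 0.01–0.02 d grid. Because the
switch depends on mass only through `M/Mmax = exp(−C·e^(−km·t))`, which is
independent of `Mmax`, a single tabulated `K` serves every fruit of a season;
agreement with the ODE route is ~1e-4 degrees and is tested. Biological ages
before 0 extrapolate the same quadrature; `kh` is vanishingly small there, so
`H ≈ H0`.

## Calibration

All fruit of a season are fitted jointly: shared `(C, km, kh_max, H0, Hmin,
s)` plus per-fruit `(Mmax, Δt)`. Mass and hue observations are normalized by
their pooled standard deviations so both channels weigh equally in the
combined residual sum of squares. Estimation is nested/alternating least
squares exploiting separability:

* inner step — each fruit's 2-parameter `(Mmax, Δt)` subproblem is solved
  independently by bounded trust-region least squares (`Δt ∈ [−30, 30] d`);
* outer step — the free shared parameters are refitted with per-fruit values
  held fixed.

The model is exactly invariant under `C → C·exp(km·δ)`, `Δt → Δt − δ`, so
`C` is frozen — either at a caller-supplied value or at the estimate of an
initial pooled fit with all shifts pinned to zero — which makes the mean
`Δt` well defined. Even with the gauge fixed, `km` is strongly coupled to
the *population* of shifts and final masses; a plain alternating scheme
zig-zags very slowly along that valley (we observed it stall 6% away from
the optimum in `km`). The outer step therefore carries two auxiliary
population-level parameters — a common shift added to every `Δt` and a
common scale on every `Mmax` — which are folded back into the per-fruit
values after each outer fit. With them the alternation converges in a
handful of outer rounds (stopping rule: relative RSS improvement < 1e-8 or
50 rounds, with an honest `converged` flag).

Initial guesses: `Mmax_i = 1.05 × max observed mass`, `Δt_i = 0`, `H0`/`Hmin`
from the pooled hue extremes, `km` and `C` from the log-linearized Gompertz
relation `ln ln(Mmax_i/M) = ln C − km·t`, `kh_max = 10/d`, `s = 40`. Shared
bounds assume the green hue plateau lies above 60° and the ripe hue below —
true for tomato. Shared standard errors are approximate: they come from the
final outer Jacobian with per-fruit parameters held fixed (including the
auxiliary columns), scaled by RSS/(n − p). `R²` is `1 − RSS/TSS` on the
normalized combined response. Fruit with fewer than 4 observations are
excluded and listed. `kh_max` and `s` are only weakly identified by 2-day
ripening-phase sampling; recovery tests hold them to 25% relative rather
than to standard-error bounds.

## Synthetic cohorts

The generator emulates the study conditions: a seasonal cohort (342 winter /
370 summer fruit by default) with `Mmax` drawn from a zero-truncated normal
(winter mean 107.1 g, sd 36.9 g; summer 99.03 g, 28.39 g) and `Δt` normal
(7.01 ± 2.82 d; 5.39 ± 2.12 d), independent of each other; observations every
3 d while green and every 2 d once the hue has dropped 2° below `H0`,
continuing until hue < waste threshold + 2°; independent Gaussian measurement
noise, mass sd 2 g and hue sd 1° by default (the field campaign reports no
error model; these match caliper-derived mass and colorimeter hue precision).
Flowering-cohort labels are carried as metadata only: shifts are drawn
directly from the stated `Δt` distribution so the generated cohort has
exactly the stated statistical structure. Generators are pure functions of
(spec, seed). What passing recovery tests on these data show is that the
estimation machinery is correct under the model's own assumptions; they do
not probe model misspecification (non-Gompertz growth, fruit-specific final
hue, serially correlated measurement error), which real data would add.

The survey generator prices the bundled 13-mixture design per rater as the
mixture-model evaluation plus iid rater noise (sd 0.1 by default), then
min-max normalizes within each rater, mirroring how the panel data were
processed.

## Population, stages and price

The per-fruit parameter distribution is refitted from calibrated fruit by
moment matching (truncated-normal `Mmax` by default; a lognormal option
captures the right skew of fitted `Mmax` histograms), with dependence through
a Gaussian copula — independent by default, as the calibrated `Mmax` and `Δt`
show no correlation. Populations (default 10,000 fruit) are sampled
reproducibly from a seed and simulated with the shared-quadrature fast path.

Ripening stages are hue intervals, half-open with the lower edge included:
RS1 ≥ 95 > RS2 ≥ 85 > RS3 ≥ 75 > RS4 ≥ 65 > RS5 ≥ 58 > RS6 ≥ 54 > waste
(< 54°). Only the 54° waste edge is an established value; the intermediate
edges are configurable working defaults and should be replaced by a chart
calibrated for the cultivar at hand. Prices come from the no-intercept
mixture regression (ordinary least squares; the model is linear in its
coefficients). For a no-intercept model the headline `R²` is the uncentered
definition `1 − RSS/Σy²`; the centered value is also reported. Predictions
are not clipped to [0, 1]; out-of-range values are logged.

## Harvest accounting

On each harvest date, fruit are classified at their exact current state (no
look-ahead). Fruit in the targeted stages are removed at their current mass;
overripe fruit found on a harvest date are removed as waste (configurable to
leave them hanging), keeping the vine consistent with waste accounting over
a campaign. An event's batch composition spans all saleable stages (green
fruit enter at their ≈0 price rather than being pre-sorted), its value is
batch price × saleable kg, and a strategy's value is the undiscounted sum
over events. Mass conservation — saleable + waste + unharvested = every
fruit's mass at its removal date — holds to 1e-9 relative and is enforced by
tests. The single-harvest sweep evaluates a whole-crop harvest at each
candidate date in a 30 d window opening when the first fruit reaches RS6.
The default dynamic schedule (offsets 4, 9, 13, 16, 19, 22 d from the window
start) is a plausible hand-crafted plan, not an optimized one; dynamic
strategies are meant to be supplied explicitly via config.

## Known limitations

* The price model is only as good as the panel it is fitted to; the combined
  fit explains far less variance than per-rater fits, reflecting rater
  disagreement rather than model structure (a per-rater option is provided).
* Fitting the price model to the bundled *mean* prices reproduces the main
  effects well, but the interaction coefficients are numerically sensitive:
  a ±0.005 rounding of a mean price can move the RS2×RS6 coefficient by up
  to ±0.3, so only its sign and magnitude order are meaningful from the
  bundled table.
* Absolute dates in harvest outputs are tied to the cohort's labeling
  origin; comparisons across runs are only meaningful within a common
  population and window.
* Seasonality enters solely through the parameter sets; no weather or
  crop-load feedback is modelled, and variation enters only through
  `(Mmax, Δt)`.
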