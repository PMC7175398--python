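# Methods

## Physical model

The borehole is treated as a tube of radius *r* and wetted length *l*
through which moist air flows at volumetric rate *Q*, exchanging water
vapor with a liquid film on the walls that is connected to the xylem water
pool. The flow is laminar; radial transport between the moving core and
the walls is molecular diffusion, characterized by t_d = r²/(4D). Because
the parabolic velocity profile moves the core at twice the mean velocity,
advective terms use an effective carrier flow; two conventions are
exposed:

* `centerline_double` (q = 2Q) — the moving-core picture; the default for
  the turnover time t_u = V/q = πr²l/(2Q).
* `mean` (q = Q) — the bulk-throughflow picture; the default for the vapor
  relaxation time t_w = V/(q + 2πlD) and the isotopic time constants,
  where the relaxation of the whole borehole content is governed by the
  measured flow.

The split default is deliberate: the residence time of the fastest-moving
air (which sets how long the least-equilibrated parcels stay) is a
centerline quantity, while the relaxation of bulk vapor content is a
mean-flow quantity; both are reproduced in the characteristic-time tables
of monitored boreholes only under this pairing. Both functions accept an
explicit convention argument.

Wall exchange is parameterized as a conductance per segment
g = (A/r)·D = 2πl_seg·D (area A = 2πr·l_seg; the radius cancels, so
predicted equilibration is diameter-independent, as observed). The
vapor balance per segment at steady state gives the conductance-weighted
mean w_ss = (q·w_in + g·w_sat)/(q + g); the non-steady kernel is
exponential relaxation with t_w. Condensation (inflow above saturation at
stem temperature) is an error state, not modeled — matching field practice
of excluding condensed periods.

### Isotope closures

The isotope balance adds kinetic fractionation α_k on the wall-exchange
conductance (laminar advection does not fractionate). The surface-water
ratio R_s is closed three ways:

1. **Xylem equilibrium**: R_s = R_x/α⁺. The steady outflow ratio per
   segment is
   R_out = [q·w_in·R_in + (g/α_k)·w_sat·R_x/α⁺] /
           [q·w_in + g·(w_sat − (1 − 1/α_k)·w_out)].
2. **Craig–Gordon film**: the film composition adjusts so that the *net*
   evaporated flux carries the supply (xylem) composition, giving
   R_out = (q·w_in·R_in + g·(w_sat − w_out)·R_x) /
           (q·w_in + g·(w_sat − w_out)).
   At saturation the film has no net flux and the outflow ratio passes
   through unchanged.
3. **Mixed (fraction f)**: R_s = f·R_x/α⁺ + (1−f)·R_C/α⁺ with R_C the
   per-segment Craig–Gordon film. Substituting the closure into the
   isotope balance yields a closed-form linear fixed point per segment; at
   f ∈ {0, 1} the code dispatches to the pure closures so the endpoint
   identities hold bit-for-bit.

The chain of N segments (outflow of segment i−1 = inflow of segment i) is
evaluated at steady state throughout; the non-steady per-segment kernels
are provided separately for users driving a single volume with
time-varying inflow. A full 2D advection–diffusion treatment of the
borehole is out of scope.

### Numerical behavior

The segment chain is first-order accurate in 1/N. With the default
N = 500, halving the step changes the outlet δ¹⁸O by < 10⁻³ ‰ in all three
closures for the documented scenarios. The mixed closure converges most
slowly on the δ²H scale (whose natural per-mil scale is ~8× δ¹⁸O):
N = 400 vs 800 differ by ~0.01 ‰ there. Users needing δ²H agreement below
0.01 ‰ under the mixed closure should use N ≥ 1000.

With α_k > 1 the vapor passes through a transient isotopic minimum near
the inlet (the evaporative flux into dry air is depleted by 1/(α_k·α⁺))
before relaxing to R_x/α⁺; the outlet therefore approaches equilibrium
from below once saturation is reached. A consequence worth knowing: the
mixed-closure outlet δ as a function of f is strictly monotone only when
α_k = 1; with the default kinetic factors it can overshoot the f = 1 value
by a few hundredths of a permil around f ≈ 0.5. The minimum-mixing search
(`find_min_mixing_fraction`, bisection refined to 10⁻⁴ in f,
cross-checked against dense grid scans in the tests) is therefore valid
for tolerances above that overshoot; its default tolerance is 0.5 ‰,
chosen as a practical indistinguishability threshold on the δ¹⁸O scale
(instrument precision for calibrated vapor measurements is of that order),
and is always reported alongside the result.

## Parameters and defaults

| Parameter | Default | Why |
|---|---|---|
| D₀ | 2.12·10⁻⁵ m²/s | vapor-in-air diffusivity at T₀, p₀; scaled by (p₀/p)(T/T₀)^1.88 |
| α⁺(T) | Majoube (1971) polynomials | standard liquid–vapor equilibrium parameterization |
| e_sat(T) | Murray (1967) | standard liquid-water saturation formula, anchored at 610.78 Pa |
| α_k | 1.0285 (¹⁸O), 1.0251 (²H) | classical molecular-diffusivity ratios (Merlivat-type); configurable, since kinetic effects in a borehole are not independently constrained — α_k = 1 disables them |
| fitting penetration | 0.02 m | tube fittings screwed ~1 cm into each side of the stem block wall contact; wetted length = stem diameter − 2 cm (overridable) |
| N | 500 | grid-converged to < 10⁻³ ‰ (δ¹⁸O) at documented scenarios |
| QC thresholds | SD ≤ 0.5/1.5 ‰, RH ≥ 0.8, inclusive | the field protocol's exclusion rules; boundaries pass |
| calibration | per-species OLS line in vapor-δ space | with 2 standards this is exact interpolation; ≥ 2 required |

Ratios are stored normalized to VSMOW (δ = 0 ↔ R = 1); every model
equation is homogeneous in R, so absolute abundances never enter.

## Processing pipeline

Cycles are split on inter-sample gaps (> 60 s, the flush period) or an
explicit cycle column. Averaging uses the trailing window (default 3 min)
by wall clock, not sample count; cycles shorter than the window or with
< 3 samples are flagged SHORT_CYCLE. QC flags (SD_O18, SD_H2, LOW_RH,
CONDENSATION_SUSPECT at RH > 1.05) are retained on every record — nothing
is dropped silently, and run reports satisfy n_input = n_clean +
n_flagged. SD thresholds apply to the raw (pre-calibration) deltas over
the averaging window. Because the calibration is affine, it commutes with
averaging; it is applied after averaging.

Breakthrough timing estimates both plateaus as means over user-specified
windows, takes their midpoint, and reports the first crossing with linear
interpolation between bracketing samples; a warning is raised when the
plateau separation is within the combined plateau noise. Lag velocity is
the plain distance/lag quotient between two boreholes' crossing times.

## Synthetic campaigns

The generator emulates the structure the pipeline assumes: 15-min cycles
(5-min flush gaps) sampled every 3 h at 1 Hz; a plateau–transition–plateau
xylem signal (exponential relaxation after the switch by default,
logistic optional — the logistic crosses the plateau midpoint at the
switch time, the exponential τ·ln 2 later); sinusoidal diurnal stem
temperature (16.8 ± 1.3 °C default); near-saturated borehole air
(RH 0.98); i.i.d. Gaussian per-sample noise with SD defaults at the QC
thresholds (0.5/1.5 ‰); an affine instrument response; and Bernoulli
artifact cycles (RH dropped to 0.6, or noise inflated 3×). Identical seed
and configuration give byte-identical CSV/JSON output, and the truth file
carries everything needed to score the pipeline (per-cycle true liquid and
vapor deltas, artifact labels, implied calibration coefficients).

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real deployments: autocorrelated instrument
drift, inter-channel memory, condensation events and their Rayleigh
signatures in sample lines, spectral contamination by organics, wound
responses (pitch, cavitation) that shrink the exchanging area, and
vertical heterogeneity of stem temperature. Statistical recovery tests
(plateau within 2·SE, arrival within two sampling intervals in ≥ 95 % of
seeds, exclusion fraction tracking the artifact rate) are run as coverage
checks over seed ensembles, since each is itself a ~95 %-probability
event per realization. The artifact-rate check uses base noise of 0.2/0.6 ‰
— comfortably inside the QC limits, as is typical of stable instrument
periods — so that exclusions are artifact-driven; with base noise *at* the
limits, about half of all clean cycles would be flagged by sampling
variability alone.

## Problem sizes

Defaults were chosen so the full test suite and the reproduction script
run in seconds on a single core: N = 500 segments per simulation, sweeps
of ≤ a few dozen grid points, campaigns of 17–200 cycles with 60–180
samples per averaging window, and 100-seed Monte-Carlo for arrival-time
recovery. All reported numbers are computed at run time by the package;
none are stored constants.

## Known limitations

* Steady-state chain only; time-varying inflow requires composing the
  per-segment non-steady kernels manually.
* The Craig–Gordon film closure assumes the film is thin and always at its
  evaporative steady state; film dynamics are not modeled.
* Ice-phase fractionation, sub-233 K saturation, and boiling regimes are
  outside validity and rejected.
* The minimum-mixing fraction depends on the chosen tolerance; there is no
  tolerance-free definition of "indistinguishable from equilibrium".
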