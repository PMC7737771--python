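# Methods

## Models

**Equilibrium two-state.**  Unfolding N ⇌ U is assumed reversible and at
equilibrium at every point of the temperature ramp.  The free energy of
unfolding follows the Gibbs–Helmholtz equation

    ΔG_u(T) = ΔH_m·(1 − T/T_m) + ΔC_p·(T − T_m − T·ln(T/T_m)),

with R = 8.314 J/(mol K) and all temperatures in kelvin throughout the
package (°C exists only at the I/O boundary, converted by +273.15 under
an explicit flag, never guessed).  The observable is a baseline-weighted
mixture: Signal(T) = (k_N·T + b_N)(1 − f_unf) + (k_U·T + b_U)·f_unf with
f_unf = K_u/(1+K_u) and K_u = exp(−ΔG_u/RT) (exponent clamped to ±700 to
stay overflow-safe for very steep transitions).  ΔC_p is held fixed
during fitting — 0 by default, which is the screening convention: it
cancels in rankings as long as T_m differences are modest, and the
systematic error it causes is exactly
Error(T_ref, T_m) = ΔC_p·(T_ref − T_m − T_ref·ln(T_ref/T_m)), negative
whenever T_ref < T_m, so the zero-ΔC_p thermal ΔG_u°′ is an
overestimate (see the reconciliation workflow below).

**Irreversible kinetic.**  Unfolding N → U proceeds with Arrhenius rate
k_u(T) = exp(−E_a/R·(1/T − 1/T_f)); T_f is the temperature where
k_u = 1 per minute.  During a ramp at scan rate v (K/min) the native
fraction obeys the linear ODE dx_N/dT = −k_u(T)·x_N/v with x_N = 1 at
the scan start, whose closed form is
x_N(T) = exp(−(1/v)·∫ k_u dτ).  The integral is accumulated per grid
interval with 4-point Gauss–Legendre quadrature: on sub-kelvin grids a
cumulative trapezoid deviates from a reference ODE solve by up to ~4e-4
in x_N (the integrand grows exponentially), while Gauss–Legendre is
accurate to ~1e-8, verified in the test suite against a substepped
fixed-step Runge–Kutta oracle (the ODE is stiff where k_u/v ≫ 1 per
step, so the oracle subdivides steps to h·k_u/v ≤ 0.05).  The
observable mixes the same linear baselines weighted by x_N; the kinetic
literature leaves the observable largely implicit, and the baseline
mixture mirrors the equilibrium model deliberately so the two fits
share initialization.

**Empirical.**  The transition is summarized by its midpoint and onset.
T_onset is defined on the *fitted* equilibrium curve as the temperature
where f_unf equals 1% (configurable) — the raw "first detectable
deviation" depends on noise, whereas the fitted 1% point is
deterministic; it is found by bracketed bisection on [scan start, T_m]
to 1e-4 K, and flagged "onset extrapolated" when the onset lies below
the scan start.  T_eucl = √(T_m² + T_onset²) is the distance of
(T_m, T_onset) from the origin; it rewards both a high midpoint and a
late onset (a steep transition).

**Stability measures.**  ΔG_u°′ = ΔG_u(298.15 K) (apparent, per mole of
melting unit, at 100 kPa), pk_u°′ = −log₁₀ k_u(298.15 K) (decadic, by
analogy with pK conventions), and T_eucl.  ΔΔG is a signed difference
sample − reference.

## Fitting

Trust-region-reflective bounded least squares (`scipy.optimize.curve_fit`).
Six parameters per model: the core pair (ΔH_m, T_m) or (E_a, T_f) plus
four baseline parameters.  Initialization: baselines from least-squares
lines on the first and last 10 K of the scan; T_m/T_f from the extremum
of a Savitzky–Golay derivative (4th-order polynomial, 10 K window,
windows converted to odd point counts via the median temperature step;
maximum for rising "S" curves, minimum for falling "Z" curves, extremum
taken strictly between the end stretches, ties to the lower
temperature); ΔH_m always starts at 100,000 J/mol — robust across
proteins — and E_a likewise (the kinetic initialization is chosen
symmetric to the thermal one).  Bounds: T_m, T_f within the scan range;
ΔH_m ∈ [60, 4,000] kJ/mol; E_a ∈ [10, 4,000] kJ/mol; baselines
unbounded.  Fitting is deterministic — fixed initialization, no random
restarts — so identical inputs give identical tables.

Curve orientation (S vs Z) compares the two end-stretch lines evaluated
at their own stretch centers; evaluating them at the scan midpoint
misclassifies curves whose transition overlaps an end stretch, because
the stretch line then extrapolates wildly.

**No-transition gate.**  A curve is not fitted when a single straight
line already explains it down to the noise floor: the residual variance
about the best global line must exceed 2× the noise variance, with σ
estimated robustly as 1.4826·MAD(ΔS)/√2 from first differences (immune
to the transition's own shape).  Pure noise gives a variance ratio of
≈1 (±2/√n), so flat buffer wells are caught reliably while noisy but
genuine transitions (which inflate the ratio far past 2) still reach
the fitter and are then judged by the SD(T_m) rule.

**Quality metrics.**  S = √(RSS/(N − n)); parameter SDs are square
roots of the covariance diagonal from the fit Jacobian (a singular
covariance marks the fit failed rather than being pseudo-inverted);
BS-factor = 1 − 6·S/|k_U·T_m + b_U − k_N·T_m − b_N| with the absolute
value making S- and Z-curves score identically (zero separation returns
−∞ and flags "no transition").  Fits with SD(T_m) > 0.5 K are flagged
`unreliable_tm_sd` but kept in the table — callers filter, so screens
stay auditable.  Curves whose scan ends inside the transition (no
post-transition baseline) fall back to the derivative-peak T_m with
flag `no_post_baseline`; no free-energy, kinetic or empirical measure
is derived from such an estimate.  When several readouts of one sample
were fitted, the fluorescence ratio is preferred unless its BS-factor
is below 0.25 and the F330 fit beats it by ≥0.1 (both configurable).

**Fraction-unfolded display.**  The baseline-corrected experimental
fraction (Signal − native line)/(baseline separation) is deliberately
not clamped to [0, 1]; excursions expose noise and baseline problems,
and |f| > 1.5 anywhere is treated as a warning sign by the caller.

## Chemical denaturation and the ΔC_p bridge

Isothermal series are fitted to the six-parameter Santoro–Bolen
linear-extrapolation model (linear native and unfolded baselines in
concentration; ΔG_u(c) = ΔG°′ − m·c), initialized from three-point end
lines and the steepest-change midpoint with m ≈ 4RT·|df/dc| at the
midpoint.  ΔC_p is estimated independently as the ordinary
least-squares slope of ΔH_m versus T_m across denaturant concentrations
(Kirchhoff's (∂ΔH/∂T)_p = ΔC_p; at least 3 points spanning ≥2 K).  The
reconciliation report then compares the thermal ΔG_u°′ as fitted
(ΔC_p = 0), the same value with the ΔC_p-neglect error restored, and
the chemical ΔG°′; on synthetic data with known ΔC_p the correction
removes most of the ~20 kJ/mol systematic overshoot (the residual few
kJ/mol comes from the slope estimate absorbing apparent-enthalpy bias —
fits of a ΔC_p-curved transition with a van't Hoff model recover the
local effective enthalpy, not exactly the Kirchhoff line).

## Synthetic data

The simulator emulates nanoDSF-style ratio scans: 20–95 °C at 1 K/min
sampled every 0.5 K (151 points), ratio-like baselines (pre ≈ 0.8,
post ≈ 0.95 with small positive slopes), homoscedastic Gaussian noise
expressed as a fraction of the transition height (1% is the default
"good instrument" level).  Two panel generators:

* `panel_random` draws parameters independently from stated ranges —
  a collection of unrelated proteins.
* `panel_screen` emulates a condition screen of ONE protein: T_m
  uniform over 300–360 K, ΔH_m following the protein's Kirchhoff line
  ΔH_m(T_m) = 100 kJ/mol + 15 kJ/mol/K·(T_m − 300 K) — spanning 100 to
  1,000 kJ/mol across the T_m range — with 5% multiplicative scatter,
  the typical replicate-level uncertainty of enthalpy estimates.

The distinction matters scientifically: concordance of the three
stability measures is a property of condition screens, where enthalpy
and midpoint move together through ΔC_p.  If ΔH_m is drawn independently
of T_m, ΔG_u°′ is dominated by enthalpy scatter that T_eucl barely
senses and the Pearson correlation between them collapses to ~0.74;
measure concordance should therefore never be expected across unrelated
proteins.  Even on the single-protein panel the ΔG_u°′–T_eucl Pearson
correlation is bounded near ~0.97 over a 60 K T_m span, because ΔG_u°′
grows convexly with T_m while T_eucl grows almost linearly; rank
(Kendall) concordance is unaffected (τ ≈ 0.95–0.99).  Narrower, more
realistic screen windows (10–20 K of T_m spread) push the linear
correlation higher.

What the simulator does **not** reproduce by default: heteroscedastic
noise (a linearly ramping SD is available via ``noise_sd_end`` but off
by default), photobleaching and evaporation drifts, aggregation scattering,
multi-transition unfolding, and inter-capillary calibration offsets.
Passing tests on synthetic panels therefore validate the estimator
machinery (initialization, bounded fitting, covariance-based SDs,
flagging rules), not robustness to every instrument artifact.

## Numerical choices and degenerate inputs

* Savitzky–Golay windows below polyorder+2 points, median windows below
  3 points, bins narrower than 2× the median step, and binned curves
  with <20 bins are rejected with explicit errors.
* Curves need ≥20 finite points; unreadable columns are skipped with a
  per-sample warning rather than failing the file; missing interior
  points are dropped (never interpolated) and counted in the curve
  history, which records every preprocessing step in order.
* Nonmonotonic temperature or duplicate sample IDs reject a file.
* Baseline lines intersecting inside the scan make the fraction-unfolded
  transform undefined and raise.
* Derivative-extremum ties break toward lower temperature;
  deterministic throughout.

## Problem sizes

Test-suite simulations use the scan geometry above with panels of 40
curves (concordance), 50 noiseless + 200 noisy replicates (parameter
recovery), 20 random parameter draws on 0.1 K grids (ODE oracle), and a
6-concentration denaturant ladder (ΔC_p loop); these sizes give stable
statistics while keeping each suite fast.

## Known limitations

* Single-transition models only; oligomer dissociation coupled to
  unfolding is fitted "apparently" (per melting unit).
* ΔC_p is never a free fit parameter; it enters fixed or via the
  ΔH_m(T_m) slope.
* The kinetic model assumes first-order irreversible unfolding with a
  temperature-independent E_a.
* Vendor spreadsheet dialects are not parsed; the canonical input is
  the documented wide CSV/XLSX (temperature + one column per sample).
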