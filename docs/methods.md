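# Methods

## Data model

The unit of analysis is the group-level retention series: whole-body
activity expressed as percent of the activity at a reference day, with the
mean and SEM taken across animals at each measurement day. SEM is the
sample standard deviation (n−1 denominator) divided by √n. The reference
day is a parameter of `normalize_retention`, not a constant: immediate
intervention arms normalize at the contamination day (t = 0), while the
delayed-course analysis renormalizes at its first sampling day (day 13),
because the fast drop produced by treatment is best expressed relative to
the retention just before/at treatment onset.

AURC is the trapezoidal integral of the observed mean curve over a
window, deliberately model-free (no fitted curve is integrated), with
linear interpolation at window edges that fall between sampling days.
Dose–response lines are ordinary least squares of AURC or day-2 retention
against the chelator dose (mg per 0.25 mL per 100 g body weight; control
encoded as dose 0), computed on group means — per-animal regression would
also be defensible, but group means match how such summary figures are
usually produced, and the choice is configurable by passing per-animal
metrics to `dose_response` directly.

## Compartmental kinetics

The two-compartment model (blood ↔ deep tissue, first-order elimination
from blood) is carried in amounts; amounts and concentrations differ only
by the distribution volume, so no volume parameter exists. The exponents
α ≥ β (day⁻¹) are the roots of λ² − (k_bd+k_db+k_e)λ + k_db·k_e = 0,
computed with the cancellation-free quadratic formula (the small root
from the product). By Vieta, α+β equals the rate sum and αβ = k_db·k_e.
The micro→macro map gives the biexponential coefficients
A = C₀(k_db−α)/(β−α), B = C₀(k_db−β)/(α−β) (A+B = C₀); the inverse map is
k_db = (Aβ+Bα)/(A+B), k_e = αβ/k_db, k_bd = α+β−k_db−k_e. For positive
A, B and α > β the inverse always yields non-negative rates
(k_bd = α+β−k_db−αβ/k_db ≥ α+β−2√(αβ) ≥ 0), so the "inconsistent macro
set" error branch is defensive only.

A numerically repeated eigenvalue — relative discriminant below 1e−12 —
switches the closed forms to the confluent limit
C_b = C₀(1−(k_bd+k_e−λ)t)e^{−λt}, C_d = C₀k_bd·t·e^{−λt}; the macro
conversion refuses such sets and points at the confluent form.

The independent oracle for the closed forms is direct numeric
integration (`integrate_ode`, LSODA, rtol 1e−11, atol 1e−12·C₀) with the
eliminated amount accumulated as k_e∫C_b, so the conservation identity
blood + deep + eliminated = C₀ can be asserted along every trajectory.

Two observable modes exist for fitting: `total` (C_b + C_d, what a
whole-body counter physically measures — the default) and `blood` (the
biexponential C_b alone). Both are exposed because whole-body retention
curves in chelation studies are routinely fitted with the biexponential
blood solution, and because under the treated rate set used by the
generator only the blood form reproduces the reported day-2 retention
level of the high-dose arm (≈31–33%); the whole-body form of the same
rates stays near 83% at day 2, which contradicts the observed treatment
effect. The synthetic treated arms therefore carry the blood observable,
the control arms the total observable, and every fit states which mode it
used in its metadata.

## Diffusion model

The late phase is modelled as Fick diffusion across cell membranes from a
tissue reservoir at constant concentration C_d0 into a semi-infinite
medium. The implementation uses the standard erfc similarity solution
C(x,t) = C_d0·erfc(x/(2√(Dt))), whose boundary flux C_d0√(D/(πt))
integrates exactly to the cumulative-transfer law Q(t) = 2AC_d0√(Dt/π).
On retention data the law is fitted in the empirical form
%R = a − b√t. The intercept a is not constrained to 100 because the law
describes the window after the first-day drop. No clipping at 0% is
applied; the zero-crossing time t* = (a/b)² is reported as a diagnostic
for the end of the law's validity window. Only the lumped slope
2AC_d0√(D/π) is identifiable from retention data — the mechanistic triple
(D, C_d0, A) is not, and the package never pretends otherwise: the
`diffusion` registry model fits (r0, lumped slope).

The PDE oracle solves the same initial-boundary problem on a truncated
domain (L ≥ 6√(D·t_max) recommended; a violation is recorded as a warning
on the result) with Crank–Nicolson on a uniform spatial grid,
square-root-graded time steps (fine near the t = 0 boundary-layer
singularity) and four backward-Euler start-up steps to damp the
oscillation Crank–Nicolson develops on discontinuous initial data. The
boundary flux uses the second-order one-sided three-point derivative, and
numeric Q(t) is its trapezoidal time integral. With nx = 400 and 800 time
steps the oracle matches the erfc profile within 0.4% (where
C > 0.01·C_d0) and Q within 0.1%.

## Fitting

All models live in one registry (`monoexp`, `biexp_macro`,
`bicompartment`, `sqrtlaw`, `diffusion`), each exposing predictions, box
bounds (rates ≥ 0) and a data-driven initial guess. Fits minimize
Σ wᵢ(obsᵢ−predᵢ)² by bounded trust-region least squares
(`scipy.optimize.least_squares`, trf, xtol/ftol/gtol 1e−12). Default
weights are uniform (fits on group means); `inverse-sem` weighting uses
wᵢ = 1/semᵢ² with zero SEMs floored at the smallest positive SEM.
Standard errors come from the Gauss–Newton covariance
s²(JᵀJ)⁻¹ (pseudo-inverse when near-singular).

Multi-exponential fits are initialized by curve stripping: a log-linear
fit of the last 3–4 points gives (B, β); the early residuals
y − Be^{−βt} — restricted to points where they exceed 1% of the terminal
prediction, since smaller residuals are dominated by tail-estimate error
— give (A, α). If stripping cannot separate phases (non-positive or too
few usable residuals, or α ≤ β) the heuristic α = 5β, A = y₀ − B is used
and flagged. Five seed-controlled multi-starts (log-normal jitter,
σ = 0.3) guard against local minima; the best SSE wins.

Two-phase segmented regression fits two independent (unconstrained,
possibly discontinuous) OLS lines to ln(%R), searching breakpoints
exhaustively over the midpoints between consecutive sampling days with at
least two points per side — at daily sampling this is ≤ ~20 candidates,
so the search is exact. Ties in pooled SSE resolve to the earliest
breakpoint. Unconstrained segments were chosen over continuity at the
breakpoint because the two phases represent distinct processes and a
forced join biases both slopes.

Model comparison fits every requested model on the identical window and
weights and ranks by R² = 1 − SSE/SStot (computed about the observed
mean, also for nonlinear models; this convention is fixed here because
"R²" for nonlinear fits is otherwise ambiguous), with ties broken toward
fewer parameters. Information criteria are deliberately not the ranking
key; R² is what such retention analyses report.

## Synthetic data generator

The generator encodes the three experiment designs exactly (7 rats/arm,
0.037 MBq per rat, doses 3.32/5 mg per 0.25 mL per 100 g b.w.; a
"30 min before" administration is day −0.021): immediate arms measured
daily days 0–10, delayed course dosed days 12–16 and measured days
13–23. Defaults are fixed once and are the package's study conditions:

* **Treated rapid arms** carry the fitted treated rate set
  k_bd = 1.77, k_db = 1.21, k_e = 0.19 day⁻¹ (blood observable, see
  above). The low-dose arm interpolates each rate geometrically between
  control and treated with weight dose/5, since no low-dose rate set is
  reported anywhere; this yields a monotone dose–response.
* **Control arms** carry k_bd = 0.14, k_db = 0.09 day⁻¹ with k_e
  calibrated by root-finding so the noiseless whole-body curve crosses
  50% at t = 2.8 d (the reported early control half-life); this gives
  k_e ≈ 0.309 day⁻¹.
* **Delayed treated arm** starts from control kinetics; each of the five
  administrations multiplies (k_e, k_db) by (8, ≈13.4) for one day —
  contiguously days 12–17 — which reproduces the observed
  more-than-twofold retention drop over the first treatment day and a
  slope break at day 17 when the effect ends. The state (C_b, C_d) is
  propagated exactly with the matrix exponential of the
  piecewise-constant rate matrix and is continuous at every switch.
* **Noise** is multiplicative log-normal per measurement, σ_log = 0.02 by
  default — a stated assumption, as no per-animal variability magnitude
  is reported; counting plus biological variability is scale-
  proportional, which the log-normal captures while keeping activities
  positive. Per-rat streams derive from (seed, rat index), so a fixed
  seed reproduces CSV output byte-identically.
* **Square-root truths** for contest-style studies: the rapid-arm
  coefficients (a = 45.76, b = 8.86) are the √t-law projection of the
  treated blood curve over days 1–10 (the law applies after the
  first-day drop, so day 0 is excluded); the delayed coefficients
  (156, 19.4) and (176, 22.1) are the reported late-window lines.

What the generator does **not** emulate: radioactive decay of the tracer
(physical t½ ≈ 244 d; negligible over ≤ 23 days and largely cancelled by
the retention ratio), inter-animal kinetic heterogeneity (noise is
measurement-level only), organ-level distribution, and the detailed
pharmacology of repeated dosing (the repeat-dose arm shares the treated
rate set). Consequently, passing recovery tests demonstrate that the
estimation machinery is correct and adequately powered at realistic noise
— not that real retention data follow these models. One visible
divergence: with the treated rate set the synthetic biphasic inflection
of rapid arms falls near day 1.5 (set by α ≈ 3.1 day⁻¹), somewhat earlier
than the day 2–3 inflection seen in real treated curves.

## Analysis windows

Window conventions, all configurable: rapid arms — full 0–10 d
(mono-exponential and compartmental fits), late 2–10 d (mono-exponential
refit and √t-law); delayed arms — full 13–23 d, sub-windows 13–17 and
17–23 d around the breakpoint, √t-law on 16–23 d. The model contest runs
on the late windows, where the diffusional and exponential hypotheses
genuinely compete.

## Known limitations

* The two-compartment fit at daily sampling identifies the fast phase
  from essentially three points; k_bd/k_db standard errors are
  correspondingly wide at 2% noise (k_e is robust).
* The √t law and a slow exponential are nearly indistinguishable on
  short late windows (e.g. 16–23 d); discrimination power comes from
  wider windows with curvature (days 1–10).
* The PDE oracle is oracle-quality, not performance-tuned; very small
  diffusivities leave the boundary layer under-resolved on a uniform
  grid (use a shorter domain).
* `RetentionSeries` assumes a common measurement grid per group; animals
  measured on disjoint grids are pooled per-day with per-day n.
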