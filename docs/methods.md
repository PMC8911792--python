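# Methods

## Data model

An extraction experiment is a full factorial over temperature levels
(default 30/45/65 °C) and ethanol concentration levels (default
0/40/60/80/96 % v/v) with replicate means and standard deviations per
response. Validation enforces the factorial shape (|conditions| =
|t-levels| × |C-levels|), non-negative means and sds, and no duplicate
cells. The packaged grape-marc tables carry the printed means and sds
verbatim; the significance letters attached to the yield table are kept as
uninterpreted annotation strings only. In the antimicrobial table, "no
detected activity" is represented as an absent value, never as 0, so the
MBC ≥ MIC invariant stays well defined.

Fold-changes are rounded half-up (ties away from zero) at the requested
number of decimals: the reported ratios 1.47/1.59/1.63/1.45 follow from the
table means only under that rule.

CSV layout: one row per condition, columns `temperature_C,
concentration_pct, <resp>_mean, <resp>_sd[, <resp>_note]`, UTF-8,
comma-separated; units travel in a `<stem>.units.json` sidecar. A missing
sd column is accepted (sd = 0) with a warning.

## Parametric spline curve

The model is a **curve through the grid, not a response surface**. The n
factorial points are ordered, assigned strictly increasing parameter values
ξ₁ < … < ξₙ, and one interpolating spline per coordinate direction —
t(s), C(s), y(s) — is fitted. Each direction has n−1 polynomial pieces of
order k written in the local variable (s − ξᵢ):

    P_i(s) = Σ_{j=1}^{k+1} c_ji (s − ξ_i)^{k+1−j}

giving (n−1) × 3 × (k+1) coefficients in total (168 for n = 15, k = 3).

Choices where the procedure was underdetermined, fixed once and tested:

- **Point ordering.** Default temperature-major lexicographic
  (t ascending, C ascending within each block); a serpentine traversal
  (C direction alternating per block) is offered because either is a
  plausible way to thread a factorial grid. Interpolation fidelity is
  independent of the ordering and both are tested.
- **Parameterization.** Default knot index (ξᵢ = 0 … n−1): equally spaced,
  scale-free and reproducible. Cumulative chord length is available; it
  makes the parameterization depend on the units of the three axes, so it
  is not the default. Raw (unscaled) axis units are used throughout.
- **Boundary condition.** Default natural (zero second derivative at both
  ends); not-a-knot offered.
- **Order.** k = 3 (cubic, C² at interior knots) and k = 1 (piecewise
  linear) are supported; other orders are rejected rather than silently
  approximated.
- **Extrapolation** outside [ξ₁, ξₙ] raises unless explicitly requested;
  intervals are right-open with the last interval closed.

Cubic fits are computed with `scipy.interpolate.CubicSpline`; the
per-interval coefficient blocks, evaluation (interval lookup + Horner) and
exports are independent of scipy's evaluator, and the test suite checks the
fit against a separately assembled natural-spline tridiagonal system and
brute-force dense sampling per piece. Knot residuals are reported relative
to the point magnitude floored at 1 (so near-zero coordinates are compared
absolutely); the interpolation requirement is max residual ≤ 1e−9, in
practice ≈ 1e−16.

## Mutual-information analysis

Entropy and MI use the plug-in (maximum-likelihood) estimator with base-2
logarithms and **no bias correction**: the analysis runs on the 15
condition means (replicate-level data are not part of the data model), a
sample far too small for asymptotic corrections to be meaningful, and the
result is read as an *ordering* of dependencies, not as unbiased effect
sizes. Plug-in MI on 15 observations is biased upward for finer binnings —
another reason only the ordering is interpreted.

Discretization is explicit and recorded in every output. Defaults:
`distinct_levels` for the temperature factor (its three designed levels)
and 3-bin equal-width for responses, mirroring the factor's level count.
Bins are right-open with the last bin closed; a value within 1e−12 of an
interior bin edge is assigned to the bin below the edge (a deterministic
tie rule for float round-off at edges). A constant variable collapses to a
single bin (entropy 0) with a warning. Because the binning is a free
choice, `mi_sensitivity` recomputes the dependency graph over a range of
bin counts and reports whether the qualitative ordering (response–response
MI above every temperature–response MI) survives each binning; on the
packaged table it holds for 2–5 bins.

MI is clamped at 0 against float round-off; a value below −1e−12 raises,
since the identity H(X) + H(Y) − H(X,Y) cannot legitimately go negative.
A seeded permutation null (`permutation_null`) is provided for calibrating
"no dependence" at a given sample size.

## Optimization

The optimum is the argmax over *measured* conditions — the defensible
procedure for a 15-cell design — with ties broken toward lower temperature,
then lower concentration. The consensus optimum is the condition that is
argmax for the most responses (ties resolved by the higher TPC mean).
Fold-changes default to the (65 °C, 60 %) vs (30 °C, 60 %) contrast. The
optional spline refinement densely samples each response curve (1000 points
per interval by default) and reports the curve maximum; it is labelled
exploratory because an interpolating curve through a grid is not a response
surface — it can only confirm or locally exceed the grid optimum, never
validate between-grid behaviour.

## Chromatics

C\* = √(a\*² + b\*²); H\* = atan2(b\*, a\*) converted to degrees in
[0, 360), so negative b\* wraps to large angles rather than producing a
signed hue. Rounding is half-up at the requested decimals. Quadrants are
90° sectors with boundary angles opening the next quadrant (0° → Q1,
90° → Q2). The hue is undefined on the neutral axis (a\* = b\* = 0) and
raises there.

## Synthetic-data generator

The generator emulates the qualitative structure of hydroalcoholic
polyphenol extraction, not its physics. The mean surface is

    μ(t, C) = y₀ + β · t · exp(−(C − c₀)² / (2 w²))

— a Gaussian ridge in concentration (peak c₀ = 60 % v/v, width w = 25 %)
scaled linearly by temperature, the simplest form that rises to ~60 %,
falls toward 96 %, and grows monotonically with t. Default per-response
(y₀, β) are set so the four responses match the magnitudes of the
grape-marc yields (TPC peaking ≈ 11 mg/g DW at 65 °C/60 %, TAC ≈ 1).

Observations add noise through a shared latent factor:

    y_obs = μ + ρ·σ·Z(t,C) + √(1 − ρ²)·ε

with Z ~ N(0,1) drawn once per condition and shared across responses,
ε ~ N(0, σ²) independent per replicate, ρ ∈ [0,1] the coupling (default
0.9), 3 replicates, and everything reproducible from one seed. Replicate
means that would fall below zero are clamped to zero (yields are
non-negative); at the default noise scales this is rare. `with_noise_scale(f)`
sets each σ to f × the response's noise-free surface range; recovery
studies use f = 0.05.

**What the coupling check isolates.** With the sloped default surfaces,
response–response MI is dominated by the shared deterministic ridge — all
responses rise and fall together across conditions regardless of ρ.
Coupling recovery is therefore assessed on a *flat-surface* configuration
(β = 0), where the latent factor is the only cross-response dependence;
there, estimated MI is monotone in ρ over {0, 0.5, 0.95} on a 25 × 20
(500-condition) grid. What passing synthetic tests does **not** show: real
extracts have non-Gaussian peak shapes, heteroscedastic assay noise and
chemically mediated (not latent-Gaussian) response coupling.

`recovery_suite` scores, per configuration: whether the dataset argmax
recovers the designed optimum for every response, the max spline knot
residual, and whether the response–response MI exceeds every
temperature–response MI; rates are aggregated with Wilson 95% intervals
(statsmodels).

## Problem sizes and runtime

All fixture-based computations run on the 15-cell design in well under a
second. Synthetic studies use 5 noise-free + 20 noisy datasets for recovery
and a 500-condition grid for the coupling sweep — sizes at which every
reported quantity is stable across seeds while the full pipeline (tests plus
acceptance script) completes in seconds.

## Known limitations

- The spline curve depends on the chosen point ordering; only knot
  reproduction (not between-knot shape) is ordering-invariant.
- Printed MI bit values from any particular study are reproducible only if
  its discretization is known; this package fixes and reports its own
  scheme and treats cross-study comparison as qualitative.
- No response-surface methodology, smoothing splines, tensor-product
  surfaces, kinetic extraction models or continuous-MI estimators; the
  ±sd columns are stored but not modeled.
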