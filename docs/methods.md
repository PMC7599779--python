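# Methods

## Design construction and coding

A Box–Behnken design (BBD) for k three-level factors places runs at the
edge midpoints of the coded factor cube: each of the k(k−1)/2 factor pairs
contributes the four sign combinations (±1, ±1) with every other factor at
0, plus n_c replicated center runs, for 2k(k−1) + n_c runs in total. The
construction enumerates pairs in lexicographic order with center runs
last; run order is deterministic because the least-squares fit is
order-invariant and reproducible files are worth more than a randomized
sheet (a seeded shuffle is available for users who randomize execution
order in the lab).

Factors are stored with a natural-scale `center` and half-range `step`;
coding is the affine map `coded = (natural − center)/step`, exactly
invertible. Coded levels are authoritative for fitting — in coded space
the linear and interaction columns of a BBD are mutually orthogonal, which
is what makes single-pass term deletion coefficient-preserving (below).

The four shipped study factors are water content 30 ± 10 %, ultrasonic
power 200 ± 100 W, extraction temperature 50 ± 5 °C and extraction time
30 ± 10 min. The power coding follows the single-factor screening range
(100/200/300 W); a user needing a different mapping constructs their own
`FactorDef`.

`select_bbd_levels` encodes the level-selection rule used after
single-factor screening: the BBD center is the screened level with the
highest mean yield and the step is the screening spacing; an argmax on the
boundary of the screened range triggers a warning because the design would
then extrapolate.

## Fitting and ANOVA

The full second-order polynomial (1 + 2k + k(k−1)/2 terms) is fitted by
ordinary least squares in coded units. Rank deficiency is reported with
the names of the collinear columns rather than silently pseudo-inverted.

Per-term sums of squares are partial (drop-one-term extra SS against the
full model). For the orthogonal linear and interaction columns these
coincide with sequential SS and with the closed form
`coefficient² × Σcolumn²` (a test asserts this); for the quadratic
columns, which are not orthogonal to the intercept or to each other,
partial SS is the convention standard response-surface software uses.
Pure error is the within-replicate SS of the center runs; lack of fit is
the remainder of the residual, tested with F = MS_LOF / MS_PE. Per-term F
statistics use the residual mean square; p-values are upper-tail F
probabilities, uncorrected for multiplicity (single-pass screening of 14
terms, not hypothesis mining). R² = SS_model/SS_total,
R²_adj = 1 − (1−R²)(n−1)/(n−p−1), CV% = 100·√MS_res / mean(Y). With fewer
than two center replicates the lack-of-fit split is omitted with a
warning, never silently zeroed.

Model reduction removes linear and interaction terms with p ≥ α (strict
inequality retains a term sitting exactly at α) and keeps significant
quadratics; hierarchy is deliberately not enforced — a factor can act
purely through curvature or an interaction, and the study's reduced model
indeed keeps the power factor's quadratic and interaction while dropping
its linear term. After refitting, the surviving linear/interaction
coefficients are asserted equal to their full-model values to 1e−10; a
violation would mean the design columns were not orthogonal and the
single-pass reduction logic unsound, so it raises rather than warns.

Natural-unit coefficients are derivable (`natural_coefficients`) for
reporting, but all inference happens in coded space.

## Optimization

The fitted quadratic is maximized over the coded cube two ways.

**Genetic algorithm.** Real-coded, maximizing by internally minimizing the
negated objective: rank-based fitness scaling (weight ∝ 1/√rank),
stochastic-uniform selection, elite carry-over (default 2), scattered
crossover (each offspring gene drawn uniformly from either parent) on 80%
of non-elite slots, and Gaussian mutation on the rest with standard
deviation `scale × (upper−lower)/2`, the scale shrinking linearly from 1
to 0 over the generation budget. Offspring are clipped to the bounds.
Population 50, 200 generations. One seeded `numpy` generator owns all
randomness: identical seed and configuration give bit-identical results.

The optional stall criterion (stop after 50 generations without
improvement > 1e−8) is **off by default**: the late, small mutations at
the tail of the shrink schedule are what refine the optimum, and stopping
early when the coarse phase plateaus costs two to three orders of
magnitude of precision. With the full budget the GA lands within 1e−3 of
the analytic maximum on ≥95% of random concave quadratics (tested on 100
seeded instances).

**Analytic stationary point.** Writing the surface as Y = c + b·x + x'Ax,
the stationary point solves 2Ax = −b and is classified by the Hessian
eigenvalues. For a quadratic objective with an interior maximum this is
exact, so the pipeline reports it as the optimum and uses the GA as the
global cross-check; when the stationary point is a saddle or falls outside
the cube (it is then clamped, with a warning), the GA result is
authoritative. Degenerate (singular-Hessian) models raise.

`round_to_practice` snaps the natural-unit optimum to equipment grains
(default 1%, 10 W, 1 °C, 1 min) and reports the predicted yield at both
points; on the study surface the rounding costs < 0.001 mg/g.

## Assay formulas

The pH-differential yield takes the extraction volume V in **liters**, so
that ΔΔA·M·DF·1000/(ε·L) is a concentration in mg/L and ×V/m gives mg/g.
Method write-ups sometimes declare V in mL while also carrying the ×1000
factor, which double-counts; that literal reading is available behind
`volume_in_ml=True` rather than silently reinterpreted. A negative double
absorbance difference is physically impossible for a real sample and
triggers a data-quality warning, but the value is returned unclamped so
the caller can see the magnitude.

HPLC correction factors f_i default to 1 (equal detector response), the
usual assumption when no calibration is supplied. The UV-Vis
classification tolerance around the 280/520 nm anthocyanin bands is
±15 nm — "around" quantified; it is an argument, not a constant.

The solvent-system screen accepts a system only when every target
component's K lies in [0.5, 2]; rejection reasons name each offending
component and the direction of failure (washed out vs over-retained).
Widening the window never removes an accepted system (tested).

## Synthetic data

The generators are pure functions of (parameters, seed), and each inverts
one of the package's estimators, so round trips close exactly at zero
noise.

- `simulate_bbd_responses`: true polynomial + i.i.d. Gaussian noise.
  The default noise SD is √(1.212e−3) ≈ 0.0348 mg/g, the replicate
  scatter implied by the study's center-run pure-error mean square.
  Homoscedastic by design — the simplest model consistent with a pooled
  pure-error estimate; real assay noise may scale with the signal, so
  passing recovery tests here says nothing about variance-stabilizing
  transforms.
- `reference_surface`: the default truth vector is the study's reduced
  coefficient set (intercept 1.32, dominant negative curvature, two active
  interactions), so recovery tests exercise realistic effect sizes rather
  than convenient ones.
- `simulate_ph_diff` inverts the yield formula for the pH 1.0 A510 reading
  given plausible values of the other three absorbances; optional Gaussian
  absorbance noise is unbiased through the linear formula (Monte-Carlo
  tested).
- `simulate_peak_areas` inverts the purity formula; scaling total area
  leaves purities invariant.

What the synthetic data does not emulate: run-order drift, heteroscedastic
or correlated replicate noise, factor-setting error (the design assumes
levels are hit exactly), and any mechanistic extraction kinetics. Passing
recovery tests therefore validates the estimation chain, not the
adequacy of a quadratic for any particular extraction system — that is
what the lack-of-fit test is for on real data.

## Numerical choices

- OLS via `numpy.linalg.lstsq`; explicit rank check first, so coefficients
  are never silently regularized.
- ANOVA additivity (SS_model + SS_LOF + SS_PE = SS_total) holds to 1e−10
  relative and is asserted in tests rather than renormalized.
- Coefficient comparisons against printed 2-decimal values use half a unit
  in the last printed decimal (plus 1e−12 for binary representation at
  exact half-unit boundaries).
- The printed pure-error SS of the study differs by ~0.7% from the value
  recomputed from the 3-decimal printed center responses (the raw data
  evidently carried more digits); SS-level comparisons use 1% relative
  tolerance.
- The conventional CV% (100·√MS_res/ȳ ≈ 2.54 for the bundled table) is
  reported; the study's printed 0.7364 does not match this definition and
  is not asserted anywhere.
- Tie-break at p = α: term retained.
- GA bound handling by clipping; mutation isotropy and symmetric bounds
  are preserved by optimizing in coded space and decoding only at the end.

## Problem sizes

The shipped analyses fit 29-run/15-term models (instant), run the GA at
50×200 population×generations (~50 ms per run), and validate on 25–100
seeded synthetic replicates — sizes chosen so the whole analysis suite
re-runs in seconds while keeping Monte-Carlo assertions well away from
their thresholds.

## Known limitations

- Single-pass significance filtering only; no stepwise search, Box–Cox
  transform, or cross-validation.
- The GA is a single-objective box-bounded optimizer; no desirability
  functions or nonlinear constraints.
- The stationary-point oracle covers quadratics only (by construction).
- Purity and partition calculations start from integrated peak areas;
  peak detection from raw chromatograms is out of scope.
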