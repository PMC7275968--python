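# Methods

`quadspec` implements two complementary routes to quantifying four strongly
overlapped UV-Vis absorbers — atenolol (AT), paracetamol (PR),
hydrochlorothiazide (HZ), and levofloxacin (LV) — from a single absorbance
scan, together with the calibration design, validation statistics and
greenness scores that surround them in practice.  This note records the
models, the numerical choices, and what the synthetic data generator does
and does not emulate.

## Spectral model and data layout

Spectra live on uniform closed wavelength grids addressed by physical
nanometres (never raw indices).  The acquisition grid is 200–330 nm at
0.2 nm (651 points); the multivariate working grid is 220–290 nm at 0.4 nm
(176 points), reached by inclusive windowing plus exact decimation.  Below
220 nm real spectra are noise-dominated and above 290 nm AT has no
significant absorption, which is why the multivariate model discards those
regions.  Absorbance is dimensionless AU; concentrations are ug/mL
throughout.  No preprocessing (baseline, scatter, smoothing) is applied to
the data matrix.

## Extended derivative ratio (EDR)

Under Beer-law additivity, a four-component mixture spectrum divided by the
stored spectrum of a mixture of three of the components (the *divisor*)
yields a ratio spectrum in which those three components' joint contribution
is approximately a wavelength-independent constant; differentiation
annihilates the constant, leaving an amplitude proportional to the fourth
component's concentration.  The approximation is exact when the sample's
interferent concentrations are proportional to the divisor recipe, and the
residual cross-sensitivity otherwise is governed by how flat each
interferent-to-divisor ratio is around the analytical wavelength.

Per-analyte defaults (divisor composition in ug/mL; derivative order;
delta-lambda; scaling; analytical wavelength):

| target | divisor                  | order | Δλ (nm) | scale | λ (nm) |
|--------|--------------------------|-------|---------|-------|--------|
| AT     | PR 7, HZ 2, LV 4         | 2     | 4       | 10    | 281.6  |
| PR     | AT 15, HZ 3, LV 5        | 1     | 4       | 10    | 237.6  |
| HZ     | AT 15, PR 10, LV 5       | 1     | 2       | 10    | 279.2  |
| LV     | AT 15, PR 7, HZ 2        | 2     | 4       | 10    | 282.8  |

The derivative operator is a Savitzky–Golay smoothed derivative: window
length `round(Δλ/step) + 1` points (21 points for Δλ = 4 nm on the 0.2 nm
grid, 11 for Δλ = 2 nm), polynomial order = derivative order + 1, output in
per-nm units, multiplied by the scaling factor afterwards.  Commercial
instrument software does not document its Δλ kernel, so amplitudes here
match an instrument's only up to a kernel constant; calibration and
prediction share the kernel, which is all quantification needs.  Grid
points where |divisor| < 1e-3 AU, or whose smoothing window is incomplete
or touches such a point, are flagged unusable and refuse quantitative
reads.

Calibration is ordinary least squares of amplitude on concentration;
detection limits follow the ICH intercept-deviation convention
LOD = 3.3·S_a/|b|, LOQ = 10·S_a/|b|.

## MCR-ALS with correlation constraint

The bilinear model D = C·St + E is fitted by alternating least squares on
the working grid with five components: the four analytes plus one free
component that absorbs uncalibrated background (in the intended
application, the urine matrix).  Design choices:

* **Initialisation** — SIMPLISMA purest variables (Windig's
  determinant-weighted purity, 5% noise offset); initial spectral estimates
  are the non-negative least-squares solution using the purest-variable
  columns of D as provisional concentration profiles.  The procedure is
  deterministic: no randomness anywhere in the fit.
* **Constraints** — non-negativity on both modes (active-set NNLS per row /
  column); a correlation constraint per analyte: resolved concentrations
  are regressed onto the known calibration references each iteration and
  the calibration entries replaced by the regression-fitted values.  Two
  variants of this constraint circulate in the literature (reset to raw
  references vs regression mapping); the regression-mapping variant is
  implemented because it preserves the scale coupling between C and St.
  Inside the fit the regression is through the origin by default: a
  component's contribution must vanish at zero concentration, and a free
  intercept lets a weak analyte exchange a constant baseline with the
  unconstrained background component under noise (the affine form remains
  available both as a standalone operation and as a fit setting).  The
  stored per-analyte regression converts resolved values of unknown
  samples to ug/mL at prediction time.
* **No warm-up by default** — constraints engage from the first cycle.
  Unconstrained warm-up iterations tend to merge spectrally similar
  components, after which the analyte-component assignment fails; the
  `warmup_iter` setting exists for data where a gentler start helps.
* **Component assignment** — after the first constrained C update, analytes
  are matched one-to-one to components by maximal |correlation| with their
  reference columns (linear sum assignment).  Remaining components are
  labelled as interferents.
* **Free-component refresh** — after each constraint application the free
  components are re-solved against the residual
  D − C_constrained·St_constrained, which prevents the constrained columns
  from starving the background component.
* **Convergence and acceptance** — iterations stop when the relative change
  in lack of fit falls below 0.01% or after 100 constrained cycles.
  Constraint projections can transiently raise the residual, so the
  returned model is the best accepted iterate; the accepted lack-of-fit
  sequence is non-increasing by construction.
* **Component count** — five, chosen as the number of significant singular
  values of the augmented data in the intended four-drugs-plus-background
  setting.

Model quality: lack of fit lof% = 100·sqrt(Σe²/Σd²) and explained variance
R²% = 100·(Σd² − Σe²)/Σd², related identically by R²% = 100 − lof²/100.

Prediction re-solves C for new rows by NNLS with St fixed and maps the
constrained columns through the stored regressions; tiny negative mapped
values (possible near zero concentration) are clipped to zero.

## Calibration design

The five-level four-factor design places 25 runs so that every factor
visits each level exactly five times and factor columns are mutually
near-orthogonal.  Factor 1 follows a fixed cyclic generator — an Eulerian
circuit on the complete 5-node digraph (a generalized de Bruijn sequence of
order 2), so every ordered pair of levels occurs exactly once around the
cycle — and factor *j* is the same cycle advanced by *j − 1* runs.  The
ordered-pair property forces the lag-1 column correlation to exactly zero;
the shipped generator was additionally selected (once, among Eulerian
circuits) for exactly zero lag-2 and lag-3 autocorrelation and |lag-4| =
0.04, so up to five factors stay within |r| ≤ 0.05.  The published 25-run
concentration table is shipped verbatim as a fixture with its 18/7
calibration/validation split (validation runs 3, 4, 9, 15, 18, 20, 23);
its exact run order is not reproduced by this generator and is not
promised — the generator is validated by its balance and orthogonality
properties instead.  Level sets: AT {5, 10, 15, 20, 25}, PR and HZ
{1, 3.5, 5.5, 8, 10}, LV {1, 2.5, 4, 5.5, 7} ug/mL.

## Synthetic spectra generator

The generator stands in for instrument data that was never deposited.  It
emulates exactly the structure the two methods assume and nothing more:

* each component is a sum of Gaussian bands (per-concentration absorbance);
* mixtures are exact Beer-law sums, so the data are exactly bilinear at
  zero noise;
* noise is additive i.i.d. Gaussian per grid point, default sigma 0.002 AU,
  from a seeded generator (per-spectrum streams are spawned
  deterministically from the dataset seed and the row index, so any single
  spectrum is reproducible in isolation);
* a broad, featureless urine-background component can be added at random
  levels to emulate an uncalibrated interferent.

Band parameters are versioned constants.  Qualitatively they mimic the
real system — AT weakest with deep-UV and ~280 nm maxima, PR strong near
244 nm, HZ with deep-UV, ~273 nm and 317 nm features, LV strong near
289 nm, everything pairwise overlapped over 220–290 nm — but they were
calibrated once so that the four fixed analytical wavelengths fall in
informative regions of the corresponding ratio spectra: the shared
deep-UV band shape of AT/HZ/LV makes the interferent background locally
rank-one around PR's 237.6 nm read, and the remaining band positions and
widths were solved so the interferent cross-sensitivities at 279.2, 281.6
and 282.8 nm vanish for the default divisor recipes.  They are explicitly
not fitted to any published band shapes, and absorptivities are on the
high side of realistic so that quantification stays comfortably above the
default noise floor.

What the generator does **not** emulate: heteroscedastic or correlated
noise, baseline drift, stray light, Beer-law deviations at high
absorbance, wavelength-registration error, and any real urine matrix
variability beyond a single fixed background shape.  Passing tests
therefore demonstrate the correctness and internal consistency of the
algorithms under their stated assumptions, not instrument-grade accuracy
on real samples.

## Validation statistics

Figures of merit follow the standard prediction-error definitions
(RMSEP, bias, SEP with n−1 denominator, RE%), linked by the identity
RMSEP² = bias² + SEP²·(n−1)/n.  Sample (n−1) standard deviations are used
everywhere; report rounding (2 dp for concentrations and statistics, 1 dp
for percentages) is applied only at the reporting edge, never internally.
Method comparison from summary statistics uses the pooled-variance
unpaired t statistic and the variance ratio F ≥ 1 (larger variance in the
numerator); a paired t test requires raw paired values, which summary
tables do not carry.  Urinary excretion converts a measured urine
concentration (times an optional dilution factor) and voided volume to mg
excreted and percent of administered dose.

## Greenness

The NEMI profile is four boolean quadrants (PBT-free, non-hazardous,
non-corrosive 2 ≤ pH ≤ 12, waste ≤ 50 g) supplied by the caller — no
chemical-database lookups.  The Analytical Eco-Scale starts at 100 and
deducts penalty points; reagent penalties are amount points × hazard
points (GHS pictogram count × signal-word score), instrument-side
penalties are additive.  Under the literal multiplication rule a
non-hazardous reagent (hazard 0) contributes zero penalty even when its
amount bracket carries a point; the shipped worked-example sheet for this
method (water 1×0, ethanol 1×2, energy 0, vapour emission 0, waste 3)
totals 5 penalty points, score 95.  The rule tables ship as an editable
YAML data file so the arithmetic is auditable.

## Problem sizes and runtimes

The test and acceptance workloads use the 25-run design (18/7 split), 651-
or 176-point grids, 7-standard EDR calibrations, and five-component ALS
fits capped at 100 constrained iterations — each fit takes on the order of
a second, and the full suite runs in a few minutes on one core.

## Known limitations

* EDR accuracy on synthetic data depends on the band-library calibration
  described above; arbitrary band libraries (or real drugs on a different
  instrument) require re-selecting divisors and analytical wavelengths, as
  the original method development did.
* The correlation constraint assumes a straight-line relation between
  resolved and true concentrations; strong closure or intensity ambiguity
  is handled only through the non-negativity + correlation combination.
* t statistics computed from summary tables are pooled-unpaired; printed
  paired-test values from raw data are not reproducible from summaries.
* The Eco-Scale rule file covers only the reagents and brackets used by
  the shipped sheet; extend the YAML for other methods.
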