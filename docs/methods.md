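# Methods

This note records the statistical model behind `fruitspec`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing its
output.

## Calibration model

Each constituent is modelled separately (PLS1). After pretreatment, the
calibration block X (samples × wavelengths) and response y are centred
around their training means and decomposed by NIPALS sequential deflation:
per component, the weight vector is w ∝ Xᵀy (normalised), scores t = Xw,
loadings p = Xᵀt/tᵀt and q = yᵀt/tᵀt, followed by rank-one deflation of X
and y. The regression vector is composed as b = W(PᵀW)⁻¹q with the
intercept restoring the uncentred scale, so a fitted model predicts
directly from pretreated spectra. At full rank the fit coincides with
ordinary least squares (tested to 1e-6 relative); with one component it
solves an exactly rank-one problem (tested). Coefficients are invariant to
row order.

Centering happens *inside* `fit_pls`, not only in the MC pretreatment
step. This makes leave-one-out folds re-learn the centering from their own
I−1 rows automatically, which is the leak-free reading of mean centering
under cross-validation; because the other pretreatment operators (SM, Log,
derivatives) are strictly per-spectrum, pretreating once and cross-
validating afterwards introduces no information flow between folds.

### Latent-variable choice

`select_lv` implements the PRESS-ratio rule: with k* the PRESS minimiser,
r(k) = PRESS(k)/PRESS(k*) is treated as a variance ratio on (I, I) degrees
of freedom and the *smallest* k ≤ k* with r(k) < F⁻¹(0.75; I, I) is
chosen. The probability threshold (default 0.75) and a raw-ratio variant
are exposed. Ties (flat PRESS) resolve to the most parsimonious model.
The rule's quoted description in the literature is ambiguous about the
direction of the probability; we follow the conventional reading — fewest
components whose PRESS is *not significantly worse* than the minimum —
which reproduces the intended behaviour on monotone-then-flat PRESS
curves. Degrees of freedom (I, I) follow the original recipe.

### Error metrics

RMSE is √(mean squared residual) in all three contexts (calibration,
cross-validation with PRESS/I, external prediction). R² is 1 − SSres/SStot
about the mean of the reference values by default; the squared-correlation
convention is available (`r2_correlation`) because toolboxes differ and
cross-validated R² can legitimately exceed calibration R² under either
convention. Zero-variance references yield a missing R², never a crash.

## Wavelength selection (modified interval-PLS)

The retained grid is partitioned into `n_intervals` near-equal contiguous
blocks (earlier blocks absorb the remainder). Each round evaluates, for
every retained interval, the LOO RMSECV of the model *without* it —
re-selecting the component count per candidate, since optimal complexity
shrinks with the variable count — and permanently discards the single
interval with the largest improvement; the loop stops when no removal
improves RMSECV or one interval remains. Consequences: the audit trace is
deterministic, retained RMSECV is non-increasing across rounds, and the
final model is never worse in RMSECV than the full spectrum. Ties break
toward the interval starting at the lower wavelength. Removals must beat
the incumbent by 1e-9·sd(y); on data fit exactly to machine precision the
candidate RMSECVs are pure float jitter (~1e-16) and would otherwise
trigger arbitrary removals. Default `n_intervals` = 20 per region (6–8
variables per interval on the 121/161-point grids): fine enough to carve
multi-segment effective ranges, coarse enough that each interval still
supports a stable model. Greedy one-per-round backward elimination is used
rather than exhaustive subset search, which is intractable at 2²⁰ subsets.

## Outlier screening

For sample i, F_y(i) = (I−1)(ŷ_pred,i − y_nom,i)² / Σ_{j≠i}(ŷ_pred,j −
y_nom,j)², computed from left-out predictions at the chosen component
count, referred to F(1, I−1). Under independent homoscedastic residuals
the statistic is exactly F-distributed, so the expected flag rate on clean
data equals the chosen alpha (default 0.01; verified by null simulation).
Removal is iterative — drop the most significant flagged sample, refit,
re-score — with two guards: a round cap (default 10) and a floor on the
remaining sample count (default 80 % of the input), preventing runaway
deletion when the model is simply wrong for the data.

## Study design

The calibration/prediction split is a seeded stratified random partition
by maturity stage, with the per-stratum calibration count rounded up
(never leaving a stratum without prediction samples). Per-constituent
sample masks come from missing values in the concentration table, so
constituents with different assay coverage keep different counts. In the
model grid, refinement (interval elimination + outlier removal) applies by
default to the best full-spectrum chain per constituent, mirroring how
such studies first scan pretreatments and then refine the winner;
`refine="all"` overrides. Best-model selection is lowest RMSEP, then
highest R²pred, fewest components, fewest variables, stable input order.

Pixel-wise maps pass every masked pixel through the *fitted* chain (stored
calibration means) and the model. For fully linear chains the mean of
pixel predictions over an object equals the prediction of the object's
mean spectrum; with a Log step that identity does not hold and is not
asserted.

## Synthetic data generator

The generator is the package's test bed and default data source.

* **Concentrations.** Eight constituents with fixed population min/max/
  mean/sd (the defaults reproduce published compositional statistics for
  fresh goji berry; units: g kg⁻¹ for the vitamin C family, %, mg cm⁻²,
  etc.). Values are drawn from truncated normals on [min, max]. Vitamin C,
  SSC and TA ripen: their means shift up linearly across the four maturity
  stages by one within-stage sd per stage. The within-stage scale and a
  global offset are solved numerically (truncated-mixture moment matching)
  so the *population* mean and sd still hit the configured targets — a
  naive 1-sd-per-stage shift on top of the full population sd would
  inflate the spread by ~50 % and truncation would bias both moments.
* **Spectra.** Noiseless absorbance A = CSᵀ + water + baseline, where S
  holds Gaussian bands at literature positions (vitamin C family near 850,
  930, 1000, 1210, 1360, 1580, 1650 nm; sugars near 905/1435 nm; phenolics
  and anthocyanin in the visible at 450/760 and 532/653 nm), the water
  background is two broad fixed bands at 970 and 1450 nm (amplitude 0.4
  absorbance), and the baseline is a per-sample random quadratic (default
  amplitude 0.02 absorbance). Reflectance is 10^(−A) plus additive
  Gaussian noise (default sd 0.005 reflectance units), clipped into
  (0, 1]. Band strengths scale to ≈0.25 absorbance per band at mean
  concentration, placing signal-to-noise in the range where pretreatment
  choices visibly matter.
* **Cubes.** One sample renders as an ellipse (axes ratio ≈1.37, matching
  the fruit's major/minor dimensions) on a dark noisy background; inside,
  all constituent concentrations are modulated by a smooth radial field
  whose spatial mean equals the nominal value exactly.
* **Noise-equivalent error.** For recovery checks, the generator exposes
  the best-case concentration error implied by its own noise: reflectance
  noise propagated to absorbance at the mean spectrum, then inverted
  through the true mixing matrix (plus baseline nuisance columns) in the
  generalised least-squares sense. Pipeline RMSEP is compared against
  twice this floor.

**What the generator does not emulate** — scattering and particle-size
effects, instrument response curves, wavelength-dependent noise,
constituent correlations beyond the shared stage effect, and chemically
silent constituents (in real fruit, antioxidant activity and anthocyanin
are poorly predictable from reflectance; here every constituent gets a
genuine band so the machinery is testable). Passing recovery tests
therefore demonstrates correctness of the algorithms under the stated
forward model, not field performance on real fruit.

## Numerical conventions and degenerate inputs

* Wavelength grids are strictly increasing, uniform-step, endpoint-
  inclusive; the two sensor grids have 121 and 161 variables.
* Savitzky–Golay defaults: window 7, polynomial order 2 (conventional for
  a 5 nm step), polynomial edge handling so the variable count never
  changes; derivatives are produced by the filter itself (one pass) in
  per-nm units. Smoothing is exact on polynomials up to the filter order;
  the second derivative of a quadratic is recovered to 1e-9.
* "Log" means decadic absorbance (−log₁₀ R), the standard chemometric
  reading for reflectance; natural log is available. Log rejects
  non-positive input, so it must precede derivatives in a chain. Chains
  allow at most one derivative step and require MC to be last.
* NIPALS stops (strictly: errors; in cross-validation folds: carries the
  last feasible prediction forward) when X is numerically exhausted, which
  happens on noiseless low-rank data.
* Candidate component counts default to min(20, I−2, variables).
* Reports serialise deterministically: equal config and seed give
  byte-identical CSVs. All randomness flows from named integer seeds via
  seed sequences.

## Problem sizes

Default test and acceptance runs use n = 100 samples per region for
end-to-end recovery (matching the order of a realistic campaign of ~90–100
composite samples), 200 replicates for the null flag-rate simulation, and
10 small random datasets for the brute-force cross-validation oracle.
These sizes give stable statistics while keeping a full run in the
low minutes on a single CPU.

## Known limitations

* Backward greedy interval elimination can keep a locally optimal subset;
  no synergy/forward variants are provided.
* PLS2 (multi-response), scatter corrections (SNV/MSC) and reference-panel
  flat-fielding are out of scope; cubes are assumed already in reflectance.
* The F(1, I−1) outlier calibration assumes roughly homoscedastic
  residuals; heavy heteroscedasticity will misstate the flag rate.
* Printed variable counts use endpoint-inclusive nm ranges; other
  endpoint conventions will count differently.
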