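# Methods

## Scope and shape

The package models a two-fiber diffuse-reflectance needle probe and the
classification task "fascicular nerve vs everything around it". It has
four layers: forward optics (`optics`, `chromophores`), an inverse fit
(`fitmodel`), feature extraction + classification (`features`,
`classifiers`), and grouped validation + reporting (`evaluation`,
`pipeline`, `cli`). The inverse fit follows the Model/Results idiom of
statistical-modelling packages because it genuinely is a model fitted
to data; the surrounding stages are deliberately plain functions over
explicit containers, since a cross-validation loop is a procedure, not
a fitted model.

## Forward model

Reduced scattering is the Mie/Rayleigh power-law mixture
`μs′(λ) = S800[Fmie(λ/800)^(−b) + (1−Fmie)(λ/800)^(−4)]` in cm⁻¹.
Absorption is linear in six chromophore concentrations; the blood term
is `blood_fraction · C_pack(λ) · [StO2·μa_HbO2 + (1−StO2)·μa_Hb]`, where
`C_pack = (1 − e^(−2 μa,bl R))/(2 μa,bl R)` is the classical
pigment-packaging correction for blood confined to vessels of radius
`R`. Reflectance at the 0.85 mm source–detector separation uses the
steady-state diffusion approximation for a semi-infinite homogeneous
medium: an isotropic source buried at one transport mean free path and
its image across an extrapolated boundary at `2AD`, with the
internal-reflection parameter `A` from the Groenhuis polynomial at a
fixed tissue refractive index of 1.4. The formula is written out in
`optics.farrell_reflectance`'s docstring; an independently coded scalar
evaluation of the same closed form lives in the test suite and must
agree to 1e-10 relative on a 10×10 (μa, μs′) grid.

The diffusion approximation assumes μs′ ≫ μa and homogeneity; at strong
visible-band blood absorption and at layered tissue interfaces it is a
controlled simplification, which is exactly why the fitted parameters
are treated as features for classification rather than as gospel
physiology.

### Chromophore library

The six absorption tables are synthetic band models: sums of Gaussians
at each chromophore's canonical band positions (Soret/Q hemoglobin
bands; 760 nm Hb; 970/1190/1450 nm water; 930/1210/1725 nm lipid;
460 nm carotenoids; broad NIR collagen features) with magnitudes on the
scale of published compilations, sampled at 2 nm and interpolated once
to the grid. Files are named `*_synthetic.csv` and the manifest records
provenance and units. Forward and inverse share one library, so round
trips, recovery statistics and classification behaviour do not depend
on the tables being literature-exact; only the absolute physiological
scale of fits to *real instrument* data would.

## Inverse fit

12 free parameters: 9 physiological/scattering plus vessel diameter,
multiplicative amplitude (bounded ±10 %) and additive offset (bounded
±1e-3) so calibration drift cannot masquerade as composition. Solver:
`scipy.optimize.least_squares` (trust-region reflective), per-parameter
characteristic scales, ftol = xtol = gtol = 1e-12, up to 500 iterations
— a noiseless mid-range spectrum fits in ~10–15 function evaluations
and returns every non-nuisance parameter to ~1e-10 relative. Residuals
are unweighted in reflectance units by default; relative
(divide-by-model) weighting is a config flag. Start point is a fixed
mid-range composition; an optional deterministic multi-start (uniform
draws within bounds) guards against local minima but has not been
needed on synthetic data. Non-convergence is a flag on the results
object, never an exception; an all-zero spectrum is rejected outright.
Derived fractions use NaN as an explicit "undefined" when a denominator
is zero (no blood → StO2 undefined; no fat and no water → F/(W+F)
undefined), never a clamped 0 or 1.

## Synthetic cohort

The generator emulates the study design: 19 specimens; cervical area in
all of them, forearm in ten; per-area class counts 702/223/164/185 and
107/76/46/60 (nerve/muscle/sliding/subcutaneous); ~10 replicates per
location averaged to one spectrum. Class priors are truncated normals
whose means encode the qualitative contrasts that make the problem
solvable — adipose classes high in fat and β-carotene, muscle highest
in blood and lowest in StO2, nerve and muscle highest in collagen, Mie
slope distinct per class. The numeric means are the package's own
physiologically plausible choices, not values fitted to any
measurement, and everything generated is labelled synthetic. A
log-normal per-specimen multiplier (sd 10 %) on every parameter mean
correlates spectra within a specimen, which is what makes
leave-one-specimen-out genuinely harder than a random split. Noise is
per-wavelength multiplicative Gaussian (sd 2 %) plus an additive floor
(sd 1e-4) per replicate; a per-location calibration amplitude
(log-normal, ~3 %) plays the role of the real system's
intensity-calibration drift.

What the generator does **not** emulate: layered tissue geometry at
class boundaries, livor-mortis blood redistribution, probe-contact
artifacts, wavelength-dependent detector noise, and any overlap beyond
what the priors produce. Consequently the synthetic classes separate
more cleanly than cadaver tissue (LOSO MCC near 1 for SVM/PLS-DA vs
~0.7–0.8 in the published benchmark); passing the end-to-end tests
demonstrates the pipeline's mechanics, leakage-freedom and orderings,
not field performance.

**Problem sizes.** The `desk` profile keeps all 19 specimens (so LOSO
always has 19 folds) at 15 % of the per-class location counts (~234
locations); the `full` profile uses the complete counts. Tests and the
acceptance script use the desk profile.

## Features and classifiers

Segment features implement the literal recipe: normalise each spectrum
to unit mean (removing intensity fluctuations), z-score each wavelength
against the training set, and sum z-scores within contiguous 20 nm
segments — 65 segments, the last absorbing the 11 leftover grid points.
PCA is standard, on raw calibrated spectra, mean-centred on training.
All training statistics (PCA axes, z-score means/sds, feature scaling)
come strictly from the training partition; a dedicated test perturbs
held-out spectra and asserts bit-identical training statistics in every
fold. The open question of whether the original analysis z-scored over
all spectra or training only is resolved leakage-safe (training only)
as this package's own choice.

SVM: RBF kernel, C = 1, gamma = 1/n_features on standardised features —
the conventional "standard parameters". PLS-DA: regression of the
0/1-coded class on the raw spectra, 10 latent variables, then a
discriminant threshold at the prior-weighted equal-posterior point of
two Gaussians fitted to the class-conditional training scores, with a
midpoint fallback for degenerate variances. CART: Gini impurity,
minimum leaf 5, cost-complexity pruning picked by stratified 5-fold CV
inside the training partition (the original stopping rule is unstated).
All trainers are deterministic given inputs and seeds.

## Evaluation conventions

Fascicular nerve is the positive class everywhere. LOSO sums per-fold
confusion matrices before computing metrics. Undefined ratios are
reported as a distinct missing marker, except MCC's zero-denominator
case which reports 0 by the widespread convention (logged). Report
rounding matches the published tables: MCC/ACC/PPV/NPV to 3 decimals,
SENS/SPEC to 1 decimal percent. The bundled benchmark counts reproduce
every printed ratio metric exactly; three non-SVM MCC cells print 0.001
above what their own counts give (LOSO PLS-DA and CART, transfer CART)
and are asserted as exactly that delta rather than absorbed. The
published LOSO PLS-DA row's anomalous positive total (534 rather than
702) is carried verbatim and not emulated by the pipeline.

## Known limitations

- Single homogeneous semi-infinite layer; no angled-tip geometry
  correction, no Monte Carlo transport.
- Synthetic chromophore tables (above): fits to real spectrometer data
  would need digitised literature coefficients dropped into
  `data/` with the same CSV schema.
- No uncertainty quantification on fitted parameters; the benchmark
  study reports none and the classifiers consume point estimates.
- Priors are order-constrained, not value-matched, so absolute
  synthetic performance should not be read as a field estimate.
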