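# nervespec

Spectral tissue sensing for regional anesthesia: can an optical needle
tell **fascicular nerve tissue** apart from the muscle, sliding fat and
subcutaneous fat that surround it, from a single diffuse reflectance
spectrum measured at its tip?

`nervespec` is a tested, end-to-end implementation of that analysis for
researchers in biomedical optics and needle-guidance: a physics forward
model for two-fiber diffuse reflectance spectroscopy (DRS), an inverse
fit that unmixes each spectrum into physiological parameters, three
spectral feature families, three classifiers, and specimen-grouped
cross-validation with confusion-matrix reporting. Because no measured
cadaver data are public, the package ships a first-class synthetic
cohort generator that emulates the study design (19 specimens, two
anatomical areas, four tissue classes, ~10 replicates per location) so
every stage is reproducible from a seed.

## The model

Spectra live on a fixed grid of 1311 points, 400–1710 nm at 1 nm.
Reduced scattering follows a Mie/Rayleigh mixture

```
μs′(λ) = S800 · [ Fmie (λ/λ0)^(−b) + (1 − Fmie)(λ/λ0)^(−4) ],   λ0 = 800 nm
```

with amplitude `S800` (cm⁻¹), Mie slope `b` and Mie fraction `Fmie`.
Absorption is a linear mixture of six chromophores — Hb, HbO₂ (with
blood fraction scaled so 100 % blood ≡ 150 g hemoglobin/L, plus a
pigment-packaging vessel correction), β-carotene, fat, water and
collagen. The diffuse reflectance at the probe's 0.85 mm fiber
separation comes from the steady-state Farrell–Patterson–Wilson
diffusion approximation for a semi-infinite medium with an extrapolated
boundary (n = 1.4). The inverse problem — 12 parameters, of which 3 are
calibration/packaging nuisance terms — is solved by bounded
trust-region least squares (`DiffuseReflectanceModel(...).fit()`
returns a results object with estimates, diagnostics and `summary()`).

Derived quantities: blood oxygen saturation `StO2 = HbO2/(Hb + HbO2)`
and the fat-to-water fraction `F/(W + F)`.

Classification (positive class = fascicular nerve) uses the 12 fit
parameters, 30 principal-component scores, 65 wavelength-segment
features (per-wavelength z-scores summed over 20 nm bands) or all three
combined, fed to an RBF SVM, PLS-DA on the raw spectra (10 latent
variables), or a Gini CART on the fit parameters. Validation is
leave-one-specimen-out (LOSO: all spectra of one specimen held out per
fold, confusion matrices summed) and cervical→forearm transfer; the
scalar summary is the Matthews correlation coefficient

```
MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
```

## Worked example

```python
from nervespec import (CohortConfig, generate_cohort, fit_spectrum,
                       load_default_library, ProbeGeometry)

lib, geom = load_default_library(), ProbeGeometry()
dataset, truth = generate_cohort(CohortConfig.desk_profile(rng_seed=1))
spec = next(s for s in dataset if s.tissue_class == "subcutaneous_fat")
print(fit_spectrum(spec, lib=lib, geom=geom).summary())
```

```
Diffuse reflectance fit
============================================
location:       L00164
converged:      True
residual norm:  5.1013e-01
fn evals:       13
--------------------------------------------
blood_fraction         0.00336933
sto2                     0.810799
beta_carotene            0.934193
fat_fraction             0.638992
water_fraction           0.327459
collagen_fraction       0.0816494
s800                      8.78357
mie_slope                0.357012
f_mie                    0.563185
vessel_diameter_mm       0.100971 (nuisance)
amplitude                0.986894 (nuisance)
offset                0.000158005 (nuisance)
--------------------------------------------
StO2 (derived)           0.810799
F/(W+F)                  0.661174
```

The fitted composition is what a subcutaneous-fat spectrum should give:
fat fraction ≈ 0.64 (the generator's ground truth for this location is
0.638), little blood or collagen, and a shallow Mie slope. The same
pipeline end to end, from one JSON config:

```sh
nervespec evaluate --seed 1 --out-dir run1 --mode both
```

writes `spectra.csv`, `truth.csv`, `fits.csv` and a `results.csv` table
of MCC/ACC/SENS/SPEC/PPV/NPV + TP/FN/FP/TN per classifier × feature
selection, each row stamped with the config hash.

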