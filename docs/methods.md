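# Methods

## The synthetic study

The generator emulates a two-group (control C, HMB-supplemented), three-zone
(SZ/MZ/DZ), five-animals-per-group cartilage imaging experiment. Each
(animal, zone) cell is one hyperspectral cube: a 64 × 64 pixel map
(1.1 µm pitch) of absorbance spectra on a descending wavenumber grid from
1800 to 900 cm⁻¹ at 3.93 cm⁻¹ sampling (230 points; the grid is wider than
the analysed fingerprint region so that the 1800–1600 cm⁻¹ quality-control
window and the band-free 1800–1745 cm⁻¹ stretch exist).

### Band model

A pixel spectrum is a sum of Gaussian bands at the positions resolved by
second-derivative spectroscopy of cartilage: amide I components at 1695,
1660 and 1635 cm⁻¹; amide II at 1550; CH₂/CH₃ side-chain bands at 1457 and
1340; GAG-related mid bands at 1403 and 1378; amide III at 1238 and 1204;
and carbohydrate-ring stretches at 1161, 1122, 1070, 1050 and 1033 cm⁻¹.
Band widths (σ 7–14 cm⁻¹) are chosen so adjacent bands resolve as separate
minima in the nine-point Savitzky–Golay second derivative. Gaussians were
preferred over Lorentzian/Voigt shapes because their integrals are closed
form, which lets every recovery test compare against an analytic truth.

Each band belongs to one of six families (amide I, amide II, CH, GAG-mid,
amide III, carbohydrate). Zone character comes from family-level base
amplitudes (collagen-related families strongest in SZ, carbohydrate/GAG
strongest in DZ, consistent with the depth profile of cartilage), and group
effects are family multipliers per (zone, group) cell:

| zone | amide I (=amide II) | CH | GAG-mid / carbohydrate |
|------|--------------------|----|------------------------|
| SZ   | 1.232 | 1.232 × 1.55 | 1.20 |
| MZ   | 1.17  | 1.17         | 1.62 |
| DZ   | 1.00  | 1.00         | 1.52 |

Control cells carry all-ones multipliers. The amide II multiplier tracks
amide I so that the collagen-integrity index (a CH/amide II area ratio)
changes only through the CH family. The SZ proteoglycan effect has no
reported magnitude, only significance; its default (+20 %) sits between the
null and the MZ effect and is configurable (`pg_sz_ratio`).

### Noise model

Three pixel-level terms: (i) multiplicative log-normal jitter with unit mean
and 10 % log-sd, drawn per pixel *per family* — this produces realistic map
texture without moving expected band-area ratios; (ii) a random per-pixel
quadratic baseline with coefficient sd 0.02 a.u.; (iii) iid Gaussian channel
noise with sd 0.008 a.u., giving a quality-test SNR of roughly 60–80
(plausible for 64-scan focal-plane-array imaging). Animal-level biology is a
log-normal per-family composition jitter (1 % CV) plus a global intensity
scale (1 % CV, the thickness variation remaining after quality control and
ROI averaging). These CVs are deliberately modest: they represent a
well-controlled inbred study in which five animals per group suffice to
detect 17–62 % composition effects, and they put the end-to-end recovery of
the calibrated effect sizes within about one percentage point (Monte Carlo
over study seeds: per-cell sd 0.7–1.9 points), comfortably inside the
±5-point recovery tolerance the tests enforce.

What the generator does **not** emulate: trans-reflectance optics, water
vapor and CO₂ lines, Mie scattering, detector physics, and chondrocyte /
pericellular-matrix morphology. Passing tests therefore demonstrate that the
*analysis* recovers known ground truth under realistic noise — not that it
is robust to every artifact of real tissue spectra.

### Force curves

Indentation curves follow the pyramidal contact law
F = 2 tan(α) E / (π (1 − ν²)) · δ² with α = 17.5°, ν = 0.5, depths sampled
on [0, 500 nm] (100 points), optional contact offset and Gaussian force
noise (0.02 nN default). Ground-truth moduli per (group, zone) are the
study's reported values: C-SZ 33.88, HMB-SZ 88.82, C-MZ 29.16, HMB-MZ
80.02 kPa; the deep zone is an equal-weight two-component mixture (C-DZ
40.02 / 77.58, HMB-DZ 42.72 / 81.38 kPa — proteoglycan and collagen
phases). Within-zone spread is Gaussian with sd 4 kPa around each component,
wide enough that the two deep-zone modes overlap realistically yet remain
separable by a two-Gaussian histogram fit. Each (group, zone) cell gets
625 curves, matching a 25 × 25 indentation map.

## Preprocessing

Per pixel: nine-point Savitzky–Golay smoothing (order 2) → second-order
polynomial baseline correction → optional min–max normalization → crop to
the 1730–900 cm⁻¹ fingerprint. Quality control (run on the raw spectra)
requires the 1800–1600 cm⁻¹ maximum absorbance in [0.1, 2.0] a.u. and an
SNR ≥ 10, where SNR is that maximum divided by the sd of the linearly
detrended absorbance in the band-free 1800–1750 cm⁻¹ stretch; thresholds are
common FTIR QC heuristics and configurable.

Baseline support is the one place where two estimators coexist. The default
fits the polynomial by ordinary least squares to fixed band-free anchor
windows (1800–1745, 1310–1268 and 945–900 cm⁻¹ — above amide I, between the
CH₂ side-chain and amide III bands, and below the carbohydrate region), a
standard practice in cartilage FTIR mapping; when cropping removes anchor
windows the polynomial order is capped at (windows − 1) so the fit stays
well-posed. An iterative restricted-least-squares estimator (fit, keep
points below the fit + 2 noise sd, refit, ten rounds, with the noise level
taken from negative residuals only) is provided for spectra whose band-free
regions are unknown. The anchor variant is the pipeline default because the
iterative support retains band flanks in proportion to band amplitude, which
distorts between-group area *ratios* by a few percent on band-crowded
spectra; with anchors all calibrated ratios are recovered to <0.5 %.

Chemical maps are computed on baseline-corrected but *unnormalized*
absorbance (min–max scaling would flatten exactly the content differences
the maps quantify; CI, being a ratio, is unaffected either way). Spectra
entering the multivariate matrix are globally min–max normalized, which
removes per-pixel intensity scale and leaves shape.

ROIs are five disjoint 10 × 10-pixel rectangles placed uniformly at random
(seeded, rejection sampling) per cube; index statistics use ROI means, with
animals as the experimental units (ROI means → per-animal means → group
comparison), matching the n = 5 design.

## Statistics

Group comparison cascade per zone and parameter: Shapiro–Wilk on each group
(α = 0.05); if both pass, Levene (mean-centered) chooses Student's t (equal
variances) or Welch's t; any non-normal group falls back to the two-sided
Mann–Whitney U. Percent difference is 100 (mean_HMB − mean_C)/mean_C on the
per-animal means. No multiplicity adjustment is applied across the nine
zone × parameter cells. A two-level random-intercept model (REML, via
statsmodels MixedLM) with animal as the grouping factor is available for the
treatment effect; it requires at least two animals per group.

## Indentation analysis

With the contact point at zero depth, the least-squares modulus over depths
≤ 500 nm has the closed form E = (Σ F δ²/Σ δ⁴) · π(1 − ν²)/(2 tan α); the
depth cap excludes substrate-affected points. Contact-point estimation (a
1-nm grid search minimizing the residual sum of squares on shifted depths)
is off by default because the synthetic curves have a known contact point.
Histograms use counts with Freedman–Diaconis bin widths by default
(configurable); peak positions come from multi-start nonlinear least squares
of one or two Gaussians, with deterministic first starts at the histogram
modes and seeded random restarts. A two-component fit raises an error when
the components collapse (centers closer than half the width sum, or one
component's area below 10 % of the other), advising a one-component refit.

## Multivariate analysis

The data matrix stacks 15 randomly selected ROI-pixel spectra per (sample,
zone) — 450 rows × 196 wavenumbers on the 1730–960 cm⁻¹ grid. Columns are
z-scored (ddof 1) so PCA is an eigendecomposition of the correlation matrix;
loadings carry a deterministic sign convention (largest-magnitude element
positive), scores are X·V, and components are selected by Kaiser–Guttmann
(eigenvalue > 1) or a scree elbow formalized as the maximum second
difference of the sorted eigenvalues — a reproducible surrogate for the
visual criterion. On the default synthetic study the class-mean scatter is
more than 90 % two-dimensional (a collagen axis and a proteoglycan axis),
while PC1+PC2 carry about half of the total correlation-mode variance; the
rest is pixel-level heterogeneity and channel noise spread across the
unit-variance columns. Channel noise cannot be made arbitrarily small here:
below ≈0.006 a.u. the min–max-normalized amide I peak channel becomes
exactly constant and correlation-mode standardization is undefined (the
standardizer reports the offending column index).

## Neural networks

**Split.** 75:15:15 is normalized to 5:1:1 fractions. Global partition sizes
floor all but the validation set, which absorbs the residual (450 →
321/64/65). Stratification allocates per-class cells by capped
largest-remainder rounding under both row (class) and column (partition)
totals, preferring on ties the class with the largest remaining deficit;
every class stays within one case of its proportional share.

**MLP.** 196-18-6, logistic hidden layer, softmax output, summed categorical
cross-entropy E = −Σ dᵢ ln yᵢ. The trainer is BFGS with an Armijo
backtracking line search and the inverse-Hessian rank-2 update written as
outer products, so the ≈3,700-parameter network trains in seconds per 100
epochs; gradients are analytic backprop, verified against central finite
differences to 1e-6. An alternative gradient-descent trainer with learning
rate 0.01 and momentum 0.80 is provided. Decisions use acceptance /
rejection thresholds 0.95 / 0.05: a case is classified only when the top
softmax output is ≥ 0.95 and all others are ≤ 0.05, otherwise it is
undecided; the recognition rate counts thresholded hits, with undecided
treated as incorrect. Gain charts rank cases by a class's predicted
probability and report the cumulative fraction of that class captured.

**Sensitivity.** Each wavenumber's importance is the ratio of the training
loss with that column replaced by its mean (permutation replacement is
available) to the full-model loss; ratio ≥ 1 marks the variable important,
and contiguous important wavenumbers are reported as ranges. On the default
study these ranges cover the amide I/II, CH, GAG and carbohydrate regions —
the same regions that carry the PCA loadings.

**SOM.** 5 × 5 map, 1000 epochs. Inputs are presented in seeded random
order; all units update by w ← w + α(t)·h(t)·(x − w) with a Gaussian
neighborhood on the 2-D grid, α decaying linearly 0.9 → 0.01 and the radius
5 → 0 (floored at 1e-3, where the update reduces to winner-takes-all).
Weights initialize uniformly over each variable's data range (seeded). The
quantization error is the mean Euclidean distance of inputs to their
best-matching units; neurons are labeled by the majority class of the inputs
they win, so per-class neuron clusters are disjoint by construction and the
cluster count is the number of classes owning at least one neuron.

## Numerical conventions and degenerate inputs

Wavenumber grids are stored descending; constructors accept either order and
canonicalize. Grid construction counts floor((hi − lo)/step) + 1 points with
a 1e-9 relative guard against floating-point shortfall. Band integration is
trapezoidal on the native grid with windows clipped to the available range
and no local edge-baseline subtraction (the global baseline is already
removed, and the calibration tests fix this convention). Swapped crop or
window bounds auto-normalize. CI is set to NaN wherever the amide II
integral is non-positive and NaN-aware statistics are used downstream.
Constant spectra cannot be min–max normalized (error); zero-variance matrix
columns cannot be standardized (error naming the column); a stratified split
requires every class to have at least as many rows as partitions. All
randomness flows through explicit integer seeds; stage seeds derive from the
global seed via SHA-256 of "stage-name:seed" (kept below 2³¹), so each
pipeline stage is independently re-runnable with identical output.

## Problem sizes

The default test and reproduction runs use the full study design (30 cubes
of 64 × 64 pixels, 450 × 196 matrix, 100 BFGS epochs, 1000 SOM epochs,
625 curves per zone); property-level tests use smaller cubes and toy
networks sized to make their analytic oracles exact.

## Known limitations

The generator's zones differ only in band amplitudes — no spatial gradients
within a cube, no cells, no band-position shifts between groups (the real
second-derivative observation of a ~4 cm⁻¹ CH₂ shift is not modeled).
Between-animal variability is small by design (see above), so the
statistical cascade is exercised mostly in its Student-t branch; the
Mann–Whitney and Welch branches are covered by dedicated unit tests instead.
The mixed model treats animals as exchangeable random intercepts and is not
fitted per ROI. SOM cluster geometry (which corners classes occupy) is
seed-dependent; only the partition structure is asserted.
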