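# cartspec

Analysis pipeline for FTIR hyperspectral imaging and AFM nanoindentation of
articular cartilage, built around a calibrated synthetic-study generator.

Articular cartilage is zonally organized — superficial (SZ), middle (MZ) and
deep (DZ) zones differ in collagen and proteoglycan content — and prenatal
dietary supplementation with β-hydroxy-β-methylbutyrate (HMB) shifts that
composition. FTIR microspectroscopic imaging measures it non-destructively:
per-pixel absorbance spectra are reduced to band-integration indices

* **CC** (collagen content) = ∫ amide I, 1750–1590 cm⁻¹,
* **PG** (proteoglycan content) = ∫ sugar-ring region, 1140–965 cm⁻¹,
* **CI** (collagen integrity) = ∫ CH₂ side chain 1360–1325 cm⁻¹ / ∫ amide II 1590–1490 cm⁻¹,

while AFM force–indentation curves yield the tissue's Young's modulus *E*
through the pyramidal-indenter contact law

```
F = 2·tan(α)·E / (π·(1 − ν²)) · δ²          (α = 17.5°, ν = 0.5)
```

The package implements the full chain for a two-group (control vs HMB),
five-animals-per-group, three-zone study: synthetic hyperspectral cubes and
force curves with known ground truth; spectral quality control, Savitzky–Golay
smoothing and second derivatives, polynomial baseline correction, min–max
normalization and ROI extraction; chemical maps with a
Shapiro–Wilk → Levene → Student/Welch/Mann–Whitney statistics cascade and a
pig-level random-intercept model; Hertz fitting and Gaussian-peak analysis of
modulus histograms (the deep zone is bimodal); a 450 × 196 spectral data
matrix with correlation-mode PCA (Kaiser–Guttmann / scree selection); a
196-18-6 MLP classifier (logistic hidden layer, softmax output, cross-entropy,
BFGS) with 0.95/0.05 decision thresholds, gain charts and mean-replacement
sensitivity analysis; and a 5 × 5 Kohonen self-organizing map trained by the
winner-takes-most rule with quantization-error reporting.

Because no raw tissue data are deposited, the synthetic generator *is* the
study: its zone/group band-amplitude profiles are calibrated so the pipeline,
run end to end, reproduces the reported effect sizes (collagen content
+23.2 % SZ / +17 % MZ, collagen integrity +55 % SZ, proteoglycans +62 % MZ /
+52 % DZ) and the reported per-zone moduli (e.g. control SZ 33.88 kPa, HMB SZ
88.82 kPa, control DZ peaks 40.02 / 77.58 kPa).

## Worked example

```python
import cartspec as cs
from cartspec import indentation as ind

# a noiseless force curve at the control-SZ ground-truth modulus, refit
curve = cs.generate_force_curve(cs.ForceCurveConfig(E_true=33.88, seed=0))
fit = ind.fit_hertz(curve)
print(f"E = {fit.E:.2f} kPa")                 # E = 33.88 kPa

# deep-zone stiffness histogram: two Gaussian peaks
moduli = cs.sample_moduli(cs.ZONE_MODULI[("C", "DZ")], 2000, sd=4.0, seed=21)
peaks = ind.fit_gaussian_peaks(ind.build_histogram(moduli), n_components=2)
print(f"peaks at {peaks.centers[0]:.1f} and {peaks.centers[1]:.1f} kPa")
# peaks at 39.9 and 77.5 kPa  (ground truth 40.02 / 77.58)
```

The first fit recovers the generator's modulus exactly because the quadratic
contact law admits a closed-form least-squares estimator; the histogram peaks
land within the sampling error of the 2000-draw mixture.

The full study runs from the command line:

```sh
cartspec full --seed 1 --out run/
```

which writes the synthetic study (`run/study/`), preprocessed cubes and a QC
report, per-pixel CC/CI/PG maps with the 9-row zone × parameter group
comparison table (`run/maps/group_comparisons.csv`), per-zone moduli and peak
fits, PCA scores/loadings, and the MLP/SOM reports, plus a run manifest with
per-stage seeds. Individual stages (`simulate`, `preprocess`, `map`,
`indent`, `multivariate`, `nets`) are re-runnable in isolation.

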