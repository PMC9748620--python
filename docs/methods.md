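# Methods

## The measurement being emulated

A handheld XRF unit (21 kV tube voltage, 15 s dwell) pointed at the calyx
end of an apple returns photon counts per energy channel from 1.5 keV
upward; elements from Si up are visible through their characteristic Kα/Kβ
emission. In apple skin the dominant peaks are K (3.31/3.59 keV),
Ca (3.69/4.01 keV) and Cl (2.68/2.82 keV), with weaker Si, P and S lines
below 2.5 keV. Bitter-pit-affected fruit show systematically higher K and
lower Ca signal at the calyx; the K/Ca ratio is the classical univariate
risk proxy, and the full spectral signature supports multivariate
classification.

## Synthetic spectra generator

`GeneratorConfig` defines the study conditions; defaults are chosen once to
match the reported behaviour of real cohorts and are not tuning knobs.

| parameter | default | meaning |
|---|---|---|
| grid | 1.5–8 keV, 0.0115 keV/channel (565 ch) | instrument range; the 1.5–4.95 keV analysis window is exactly 300 channels |
| detector_sigma | 0.064 keV | Gaussian line width (≈0.15 keV FWHM, silicon-drift class resolution) |
| background_level | 50 counts | flat continuum |
| baseline amplitudes | K 20 000, Ca 4 000, Cl 3 000, S 800, P 600, Si 500 | non-BP Kα peak heights, reproducing the observed peak ordering |
| bp_effects | K ×1.30, Ca ×0.65, S ×1.15, Si ×1.10, Cl ×1.0, P ×1.0 | multiplicative class effects; every element except Cl and P differs by status |
| severity exponents | mild 0.4, moderate 1.0, severe 1.0 | log-effect attenuation; mild fruit sit closest to healthy and are hardest to classify |
| between_fruit_cv | 0.20 | per-element unit-mean lognormal across fruit |
| within_fruit_cv | 0.15 | per-measurement-point lognormal shared by all lines of a spectrum |
| points_per_fruit | 6 | replicate calyx points (balanced study); orchard cohorts use 1 |

Line shape is a pure Gaussian and the Kβ relative emission is 0.12
throughout. The Si/P/S line energies follow standard emission tables
(Si 1.74/1.83, P 2.02/2.14, S 2.31/2.46 keV) since published peak
assignments in this energy region are frequently ambiguous at handheld
resolution.

Rendering draws the per-point lognormal factor, scales the summed line
signal (not the background), and Poisson-realizes every channel. Applying
the heterogeneity factor before the Poisson draw keeps observed counts
integer Poisson variates; at these count levels the within-fruit CV of a
peak intensity is `sqrt(cv² + 1/N) ≈ cv` either way. The factor is needed
at all because pure Poisson noise at ~20 000 counts gives a CV below 1%,
far short of the 10–25% dispersion real calyx measurements show.

The orchard generator converts incidence to a BP count by round-half-up and
allocates severities by largest remainder, so cohort composition is exactly
reproducible; fruit order is a seeded shuffle.

**What the generator does not emulate:** bremsstrahlung curvature, escape
and pile-up peaks, matrix absorption, detector drift, and any correlation
structure between elements beyond the shared within-point factor. Passing
tests therefore demonstrate the correctness and calibration of the
*analysis chain*, not field performance on real fruit.

## K/Ca quantification

Deconvolution fits the 3.0–4.3 keV window with four Gaussians at fixed
centers (K Kα/Kβ, Ca Kα/Kβ), one shared width initialized at the detector
sigma, free non-negative amplitudes, and a constant background
(Levenberg–Marquardt via lmfit). The ratio uses Kα areas only; the Kβ
amplitudes are in the model purely to de-bias the K Kβ / Ca Kα overlap. On
noiseless spectra the fit inverts the generator to well within 0.1% in area.

The direct ratio divides background-subtracted apex heights, with the
background taken as the mean count over the line-free 4.4–4.9 keV region.
The apex is read within ±0.01 keV of the characteristic energy (the nearest
channel). A wide reading window must not be used for Ca: beyond K/Ca ≈ 5.6
the K Kβ shoulder at the edge of a ±0.06 keV window overtakes the Ca apex
and the direct ratio saturates. With apex reading, the two methods agree at
R² ≥ 0.98 over low-noise cohorts; the residual gap is the deterministic
concavity `direct ≈ r/(1 + 0.035 r)` caused by the K Kβ tail under Ca Kα.

Per-fruit ratios in the study-1 report are computed on the mean spectrum of
the replicate points. ANOVA treats status (2 levels) and measurement point
(6 levels) as fixed effects with interaction, type-II sums of squares
(statsmodels). Quantiles use the linear-interpolation (type-7) convention.

## PCA screening

PCA is computed by SVD of the scaled matrix — deterministic, no iteration;
each loading's largest-magnitude element is made positive so signs
reproduce across platforms. The component count is the smallest A whose
row-wise leave-group-out cross-validated explained variance reaches 90%
(capped, with a warning for structureless data).

Screening uses Q = squared reconstruction residual with the
Jackson–Mudholkar limit computed from the residual eigenvalue spectrum, and
Hotelling T² over the retained scores with the limit
`A(n−1)(n+1)/(n(n−A)) · F₀.₉₅(A, n−A)`. Defaults: autoscaling (matching the
classifier preprocessing), confidence 0.95, a single screening pass. At
0.95 the expected clean-data flag rate of the union rule is ≈5–8%; raising
confidence to 0.999 retains >99% of clean samples.

## PLS-DA and validation

Classes are coded non_BP → 0, BP → 1 in a single response column. The
orthogonal-scores NIPALS sequence (weight = X'y normalized, score = Xw,
deflate X by its score–loading outer product; no y-deflation needed for a
single response) yields coefficients `b = W(PᵀW)⁻¹q` for one-shot
prediction. With LVs equal to the rank of the autoscaled X this reproduces
ordinary least squares exactly — the test suite uses that identity, the
univariate closed form, and scikit-learn's PLSRegression as independent
oracles. The decision threshold is 0.5 with ties assigned to BP (flagging
the risky class).

Autoscaling is always re-estimated inside each training fold; held-out rows
are scaled with the stored parameters only, so no information leaks.
Venetian-blinds folding assigns fruit i (not spectrum i) to fold i mod k
after interleaving classes, keeping folds class-balanced and replicate
points of one fruit together. Monte-Carlo validation stratifies the random
20% holdout by class — at 2–4% orchard incidence an unstratified draw would
regularly produce single-class training sets. CV metrics are pooled over
held-out predictions; Monte-Carlo metrics are means over iterations (each
scheme's natural estimator; they differ slightly in finite samples).

The LV count is chosen to maximize venetian-blinds CV balanced accuracy,
ties toward fewer LVs, default search up to 10.

## Problem sizes and numerical choices

The acceptance script and the calibrated tests run the balanced cohort at
full scale (176 fruit per class × 6 points = 2 112 spectra × 300 channels);
ratio-agreement and screening checks use 200–352-fruit cohorts, chosen as
the smallest sizes at which the stochastic quantities are stable to well
under their acceptance margins. Grid construction adds a 1e-9 tolerance to
`floor((e_max − e_min)/step)` and region selection excludes a channel whose
center equals the upper edge up to float rounding, so exact divisions
match the hand-computed counts. The deconvolution bounds the shared width to
[0.02, 0.25] keV and amplitudes to ≥0; non-convergence is reported, never
silently patched.

## Known limitations

* With a 0.5 threshold, PLS-DA on strongly unbalanced orchard cohorts is
  conservative toward the majority class: sensitivity is high while
  specificity drops well below the balanced-cohort operating band.
  Class-specific thresholds are out of scope.
* The generator's single shared within-point factor makes the first
  principal component absorb most spectral variance (≥90%); real spectra
  spread variance over more components.
* Severity levels shift only the effect magnitude; no severity-specific
  spectral features exist, so multi-class severity models are out of scope.
* Absolute concentrations (mg/100 g FW) are not modelled; all quantities
  are relative signal intensities.
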