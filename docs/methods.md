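# Methods

`tanninspec` implements a complete near-infrared (NIR) calibration workflow
for kernel tannin content: synthetic spectra generation, spectral
transforms, continuous-wavelet feature extraction, Monte-Carlo outlier
screening, correlation-based characteristic-band selection, random-forest
calibration, and Shapley-value interpretation. This note records the models,
the numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## Synthetic spectra model

Real diffuse-reflectance spectra of ground walnut kernels over
4000–10000 cm⁻¹ are smooth, rise with wavenumber, run near-parallel across
orchard-management strata, and carry hydroxyl-related absorption features:
O–H combination bands at 4000–5000 cm⁻¹ and the first O–H stretching
overtone near 7000 cm⁻¹, both strengthened by polyphenols such as tannins.
The generator reproduces exactly this structure:

    R_i(ν) = b(ν) + δ_mode(i) + α_i + β_i·u(ν) − Σ_k d_k(i)·exp(−(ν−c_k)²/2σ_k²) + ε

* `b(ν) = c₀ + c₁u + c₂u²` with `u` the normalised wavenumber — a low-order
  rising baseline (defaults 0.35, 0.40, −0.10, i.e. reflectance ≈0.35→0.65).
* `δ_mode` — per-management-mode offset (±0.012 by default), ordered with the
  mode's tannin mean so reflectance increases with tannin across modes.
* `α_i ~ N(0, 0.015)`, `β_i ~ N(0, 0.008)` — per-sample intercept/slope
  scatter emulating packing-density and scatter variation. These nuisances
  are exactly annihilated by derivatives and by the gaus4 wavelet (which is
  orthogonal to cubics), which is what makes derivative/CWT features
  outperform raw reflectance here, as in real powders.
* Absorption bands `(c_k, σ_k)`: tannin-coupled at 4400/160, 4850/130 and
  7050/210 cm⁻¹ with depth `d_k = coupling_strength × tannin_i`
  (default 0.004 per mg/g); tannin-blind matrix bands at 5600/180 and
  8600/250 cm⁻¹ with fixed depths (0.025, 0.020) plus N(0, 0.005) jitter.
* `ε ~ N(0, scan_noise_sd)` i.i.d. per scan (default 0.004; an AR(1) option
  exists for wavelength-correlated noise). Three replicate scans per sample
  are averaged downstream, as in the acquisition protocol.
* Tannin is drawn per mode from N(mean, 2.4²) with mode means 10.5 / 13.2 /
  15.8 mg/g (pooled mean ≈13.17) and clipped to the observed range
  4.73–20.17 mg/g.

What the generator does **not** model: Beer–Lambert/Kubelka–Munk physics,
instrument line shape, water-vapour interference, wavelength-correlated
drift (unless the AR(1) flag is set), and band shapes beyond Gaussians.
Consequently, passing the benchmark shows the pipeline recovers a linear
absorption-depth signal under smooth multiplicative-style nuisance and white
scan noise — not that it calibrates any particular real instrument.

## Transform bank

Twelve spectral forms: R, 1/R, lgR, lg(1/R) (lg = log₁₀) and their first
and second derivatives. Derivatives are divided differences along the
wavenumber axis (robust to non-uniform grids), evaluated on midpoint axes;
each order shortens the axis by one band. Reflectance is clamped at 1e−9
before logs/reciprocals and clamp counts are logged. No pre-derivative
smoothing by default (a Savitzky–Golay flag exists). Because
lg(1/R) = −lgR holds exactly, derivative pairs {lg′R, lg′(1/R)} and
{lg″R, lg″(1/R)} are exact negations, which forces identical band counts and
mean |r| with mirrored extrema in the correlation summaries — a useful
internal consistency check.

## Continuous wavelet features

The CWT is the discrete Riemann sum of ∫ v(j)·a^(−1/2)·ψ((j−b)/a) dj over
band index j (Δj = 1), evaluated at every band index b (same-length
output), at dyadic scales 2¹–2¹⁰. The mother wavelet gaus4 is the fourth
derivative of exp(−t²/2), sign-fixed so ψ(0) > 0 and normalised to unit L2
norm: ψ(t) = (105√π/16)^(−1/2)(t⁴−6t²+3)e^(−t²/2). Boundaries use symmetric
reflection; the boundary-affected half-width (≈4a bands) is reported per
scale. Kernels are truncated at |t| = 8 (tails < 1e−13) and evaluated by FFT
convolution.

Numerical notes. With unit-L2 normalisation the per-coefficient variance of
white noise is scale-independent; noise suppression manifests as smoothing
(the fluctuation energy of noise coefficients falls monotonically with
scale), while the wavelet's four vanishing moments remove baseline nuisance
up to cubic polynomials. Large scales therefore stay informative on smooth
synthetic data, and the selected "optimal" scale can sit high in the dyadic
range; an interior optimum appears when the informative feature is narrow
relative to the spectrum (tested explicitly on a single-bump scenario).

## Monte-Carlo outlier screening

2000 random 60/40 splits by default; each fits a mean-centered PLS1 model
(NIPALS; for a univariate response each component's weight is the exact
one-step solution w = X'y/‖X'y‖) with 20 latent variables (capped at
min(n_train−1, p) with a warning) and accumulates absolute validation
errors per sample. A sample is flagged when its error mean or error SD
(the OR rule; AND available) exceeds the thresholds. The default thresholds
(mean > 10, SD > 2 mg/g) are on the original walnut study's error scale and
**must be re-based for other data**: on the synthetic benchmark, clean-sample
error means are ≲3 mg/g but an injected gross outlier inflates clean error
SDs above 2, so the desk-scale protocol uses (mean > 10, SD > 5). Errors are
absolute values, making the mean/SD scatter live in the positive quadrant.

## Band selection

Per feature, Pearson r against tannin and the two-sided p from
t = r√((n−2)/(1−r²)). Characteristic bands satisfy p < α (α = 0.01) and
|r| > r_crit, where r_crit is derived from α and n by inverting the t
relation (so the two gates coincide) unless overridden — the override exists
because published gates are sometimes computed at a different effective n
(0.123 corresponds to n ≈ 440 at α = 0.01, while 171 samples give 0.196).
No multiple-testing correction by default (Benjamini–Hochberg behind a
flag, never looser than the raw gate). Scale selection maximises mean |r|
over selected features, ties toward the smaller scale.

## Split and calibration

6:4 random split (floor on the training count: 171 → 102/69); no
stratification by default. The forest uses 200 trees and minimum leaf size
10 with a seeded sequential random search (50 evaluations, 5-fold
shuffled CV, objective = mean CV RMSE) over the per-split feature fraction
(optionally the leaf size); any sequential optimizer satisfying that budget
is equivalent for this purpose. Metrics: R² = 1 − SSE/SST, RMSE, and
RPD = SD(y; n−1)/RMSE computed on the evaluated set's own references;
RPD > 2.0 is the conventional robustness bar, 1.4–2.0 moderate. A zero-RMSE
fit reports RPD = +inf with a warning.

## Shapley attribution

Interventional value function: v(S) is the mean model output over a
(seeded, ≤100-row) background sample with features in S taken from the
explained instance. Exact enumeration up to 12 features; otherwise seeded
permutation sampling, batched so each permutation costs one model call.
Efficiency holds exactly for both (per-permutation telescoping); null
players get exactly zero; symmetry holds for models symmetric in the
features (a fitted tree breaks ties between duplicated columns arbitrarily,
which is a property of the model, not the attribution). Values may differ
numerically from path-dependent tree-specific algorithms. Rankings use mean
|φ|; beeswarm, bar and waterfall tables are exported as CSV (waterfall
samples drawn by seed).

When judging whether top-ranked features sit in tannin-informative regions,
a CWT feature at scale a and position w is counted inside a coupled window
(band center ± 2.5σ) if its receptive interval w ± a·Δν overlaps the
window: a scale-a coefficient integrates the spectrum over ~a bands either
side, so e.g. side-lobe responses of the 7050 cm⁻¹ band legitimately appear
near 6100–6350 cm⁻¹ at scale 256. At the largest scales the receptive
interval spans much of the axis and this check loses discrimination — a
known limitation.

## Pipeline and best-model rule

Stage order: generate/load → average replicates → MC outlier scan and
removal → 12-form transform bank with correlation summaries → CWT of
{R, R′, lg′R, lg′(1/R)} at dyadic scales → per-scale profiling and optimal
scale per source → 6:4 split → forests for the 8 input definitions × {full,
characteristic} bands → best model = highest validation RPD among models
whose train−val R² gap is below the overfit margin (0.15; fallback to the
overall best if none qualify) → Shapley attribution of that model. All
stage seeds derive from one global seed; reruns are byte-identical.

## Desk-scale protocol sizes

The acceptance protocol runs the full pipeline at the campaign design size
(180 samples × 3 scans, 1557 bands) in a high-coupling / low-noise regime
(coupling 0.006 per mg/g, scan noise 0.002) with iteration budgets sized
for a single CPU: 300 MC iterations, forests with 60 trees / 3 tuning
draws / 3-fold CV, and permutation Shapley with 8 permutations × 2 explained
validation samples over a 15-row background. Ten seeds are evaluated per
run. These budgets are the package's desk-scale defaults for simulation
studies; the module-level defaults remain the full protocol values.

## Known limitations

* The generator's linear depth–tannin coupling makes the problem nearly
  linear in a few latent variables; tree ensembles are not the strongest
  model class here and succeed mainly by feature quality — matching the
  workflow being exercised, not benchmarking regressors.
* Interventional Shapley with a small background and few permutations gives
  stable top-k rankings only because uninformative features receive (near-)
  zero attribution; increase the budgets for fine-grained per-feature values.
* The MC outlier thresholds are scale-bound; there is no automatic
  normalisation of prediction errors.
* JCAMP-DX and vendor binary spectra formats are not read; the wide CSV is
  the interchange format.
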