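# Methods

## The forward model

Absorbance of a single rovibrational transition follows the Beer–Lambert
law: `alpha(nu) = S(T) * phi(nu) * N_col`, with `S` the line strength at
the reference temperature 296 K (cm⁻¹ per molecule cm⁻²), `phi` an
area-normalised Voigt profile and `N_col` the molecular column — ideal-gas
number density `P/(k_B T)` times the mixing ratio times the path length in
cm. The Voigt profile combines the pressure-broadened Lorentz half-width
`gamma_air * P * (296/T)^n` with the thermal Doppler half-width
`(nu0/c) * sqrt(2 ln 2 k_B T / m)` and is evaluated with
`scipy.special.voigt_profile`; each line contributes only within
±25 cm⁻¹ of its (pressure-shifted) centre, the usual line-by-line wing
convention (configurable). Line intensities are used at their reference-
temperature values; a `partition_ratio` hook accepts an `S(T)/S(296)`
correction for other temperatures, but the default conditions of the
study (1 atm, 296 K, 580 m) make the reference path exact. Self-broadening
is ignored: every analyte is in the trace regime.

Smooth broadband absorbers enter through a composite cross-section table
(absorbance per ppm·m). Such tables are conventionally base-10; ingest
multiplies by `ln 10` (configurable via `xsec_log_base`) and by the path
length in metres. Negative table values — baseline artifacts of measured
composites — are clipped to zero with a log record.

Because absorbance is linear in concentration, a mixture spectrum is
`S_b = sum_i c_i * u_i + N`, where `u_i` is gas i's unit (1 ppm)
absorbance and `N` collects instrument noise. Unit spectra are computed
once and cached; blending is a matrix product.

The shared wavenumber axis spans 2950–3150 cm⁻¹ with 3321 points and
inclusive endpoints (spacing 200/3320 ≈ 0.0602 cm⁻¹). Where a nominal
resolution (0.06 or 0.062 cm⁻¹) and the point count disagree, the point
count wins; every artifact (dataset, checkpoint, attribution map) carries
this length and readers verify it.

## The labelled corpus

Seven mixture classes cover all non-empty subsets of {methane, acetone,
water}: MAW, MA, MW, AW, M, A, W. Each sample's label has six digits —
three binary component identifiers (CI) and three concentrations in ppm
(CR). Present trace gases draw uniformly from 0–50 ppm; the humid
background draws from 1000–2000 ppm (typical indoor humidity at this
window); absent gases are exactly zero. The full corpus is m = 17500
(2500 per class); the desk study uses m = 1750 (250 per class).

Four perturbation channels emulate instrument non-idealities, applied in
a fixed order (they do not commute):

1. **Source power fluctuation** — a multiplicative gain in transmittance,
   `alpha' = alpha − ln g(nu)`, with `g` a random sine envelope of at
   most 3 cycles across the window and relative excursion ≤ 2%.
2. **Unknown absorbers** — 0–3 additive Gaussian or Lorentzian bands per
   sample, centres uniform in the window, half-widths 1–20 cm⁻¹, depths
   up to 0.1 absorbance, truncated to zero beyond 5 widths.
3. **Detector noise** — additive white Gaussian, sigma = 0.01 absorbance.
4. **Baseline miscalibration** — a random polynomial of order ≤ 2 in the
   normalised coordinate, bounded by 0.05 absorbance.

All magnitudes are configuration fields; the defaults above describe a
well-behaved 580 m multi-pass cell whose humid-background peak SNR is
~150–200 at mid-range humidity.

## The synthetic gas fixture

The package runs its whole test surface without any database download.
Two archetypes emulate the window's absorber types: `dense-narrow` (many
random Voigt lines with log-uniform strengths — the character of CH₄ and
H₂O rovibrational manifolds at 1 atm) and `broad-band` (one dominant
~100 cm⁻¹ FWHM Gaussian band plus weaker shoulders — the character of
the unresolved acetone C–H stretch composite). The three-gas demo set
fixes per-ppm peak absorbances of ~0.15 (methane-like), ~0.03
(acetone-like) and ~0.0025 (water-like): the ordering matches the
emulated instrument's measured per-ppm detectability, and the
methane-like strength is capped so that a 50 ppm sample stays inside a
real detector's measurable dynamic range (absorbance ≲ 7) — the linear
forward model would otherwise happily produce absorbances no instrument
could record. The gas set is drawn once from a fixed `fixture_seed`
(default 7): the gases are constants of the study, like a downloaded line
list; run seeds vary only concentrations, perturbations, splits and
training.

What the fixture does **not** emulate: true rovibrational band structure
(P/Q/R branches, intensity correlations between neighbouring lines),
line-mixing, saturation of strong lines, instrument line-shape
convolution, or correlated (non-white) detector noise. Tests passing on
this fixture therefore demonstrate that the pipeline and the model
recover what they were trained on under the stated perturbations — not
that the trained weights transfer to real spectra.

## The spectral analysis model

A fully connected network 3321 → 196 → 74 → 211 → 6 with ReLU hidden
activations and dropout 0.2 between the last hidden layer and the output.
The first three outputs pass through a sigmoid (presence probabilities);
the last three are linear (scaled concentrations). Training minimises

    L_obj = L_iden + lambda * L_con,   lambda = 100,

with `L_iden` the mean binary cross-entropy over the m×3 presence flags
(probabilities clamped to [1e-7, 1−1e-7]) and `L_con` the mean squared
error over the m×3 scaled concentrations, using Adam with beta1 = 0.5,
beta2 = 0.999, minibatch 256. The full-study schedule is 500 epochs at a
constant step size of 0.01.

**CR target scaling.** Concentration targets are normalised by 4× the
per-gas maximum (200, 200, 8000 ppm), and predictions are rescaled to ppm
at inference. The factor matters: with lambda = 100, normalising by the
bare maxima makes the regression gradient ~20× the identification
gradient throughout training, which starves the CI head at small step
budgets; the 4× scale brings the two tasks' gradients to comparable size
while leaving retrieval accuracy unchanged (R² ≥ 0.997 desk-scale).
Unnormalised training is available by setting `cr_max` to ones.

**Gating.** A concentration is reported only when its presence
probability strictly exceeds 0.5; otherwise it is forced to zero, and
surviving values are clipped at zero. This separates "gas absent" from
"present at a low concentration" and is idempotent.

**Desk-scale schedule.** The desk preset (m = 1750, 100 epochs) keeps the
architecture, dropout, lambda, Adam constants and batch size, but runs
only 7 minibatches per epoch — 700 optimisation steps, where the
full-study constant 0.01 step oscillates and underfits. It therefore uses
a peak step size of 0.002 with a 5%-of-epochs linear warmup and cosine
decay to zero, and re-draws the four perturbation channels freshly every
epoch (online augmentation of the same 1750 physical samples). Both are
preset fields, not hard-coded behaviour.

**Numerics.** Weights initialise uniform in ±1/sqrt(fan_in) (biases
zero), seeded; a non-finite training loss raises a divergence error with
the epoch index; epochs = 0 returns an initialised, untrained model with
empty history. Training, shuffling and dropout draw from one seeded
generator, so a seed fully determines the fitted weights on a given
BLAS/platform.

## Evaluation

Identification: exact match ratio (fraction of samples whose 3-flag
pattern is fully correct) and Hamming accuracy (fraction of individual
flags correct); EMR ≤ HA always. The composition confusion matrix is
tabulated over the 7 classes plus a "none" bucket, since a model may
predict no gas at all; rows are normalised where observed. Retrieval: R²
per gas via `1 − Σ(c−ĉ)²/Σ(c−c̄)²`, MAE in ppm over all samples, and
relative errors only over samples where the gas is truly present
(relative error is undefined at c = 0; Table-style mean relative errors
here therefore mean present-only averages). Zero-variance truths make R²
undefined — reported as NaN with a warning, never silently.

## Gradient activation maps

Attribution targets are the output layer's pre-activation scores, which
are exactly linear in the last hidden activation `a(L)`. Three objects
are produced per spectrum: the activation map `M_x = Σ_{n∈targets}
W[n,x]·a(L)_x` over the 211 hidden units; the guided backpropagation
gradient `g_b` of the summed target scores with respect to the input
(at every ReLU both inactive units and negative upstream gradients are
zeroed; the subgradient at 0 is 0); and the fused map `g_a = g_b · M↑`,
where `M↑` is `M` linearly interpolated from hidden-unit index space
onto the 3321-point grid. The hidden layer has no native wavenumber
axis, so this uniform stretch is the key interpretive choice — it
preserves endpoints and ordering, nothing more. Maps are produced raw
and optionally rectified (positive part) for rendering; per-output
target selections (e.g. the methane CR neuron alone) are available for
diagnostics. The guided rule is defined for ReLU only; other activations
fall back to the exact gradient with an explicit error unless
`mode="plain"` is requested.

A caution on localisation: for narrow-line gases the trained network's
input gradient is *not* confined to the strong line cores. Rejecting the
broadband perturbation channels requires weight structure across the
whole window, and even an ideal matched filter places only ~60% of its
mass on grid points above 10% of the unit-absorbance maximum. Fused maps
for the broadband gas localise almost entirely on its band; maps for the
line gases highlight the strong lines but keep a substantial diffuse
component. The acceptance checks report this fraction per gas rather than
hiding it.

## Reproducibility plumbing

One global seed fans out to every stage through a stage-name-keyed SHA-256
derivation (below 2³¹), so `simulate`, `train` and `cv` can be re-run
independently yet reproducibly. Every CLI run writes a manifest (config
hash, package version, per-stage seeds, outputs, timestamps) before
computing and finalises it after. All containers embed a format version;
readers reject unknown major versions. The HDF5 corpus stores spectra as
float32 (storage) while computation is float64; checkpoints store weights
losslessly and round-trip bit-exactly.

## Problem sizes

The package's own regression tests and the acceptance script run the desk
study: three-gas synthetic fixture on the full 3321-point grid, m = 1750
(250 per class), 9:1 holdout, 100 epochs — about a minute per seeded run
on one CPU core. The full-study preset (m = 17500, 500 epochs, constant
step 0.01, no augmentation) is the configuration a user would run with
downloaded HITRAN line lists and a measured acetone cross-section; it is
exercised structurally (readers, config, shapes) but not trained in the
test suite.

## Known limitations

- The model is a dense MLP on a fixed grid: inputs must be resampled to
  the training grid, and nothing constrains the CR head to be linear in
  concentration outside the training ranges.
- Temperature generality is limited to the width scalings; line-strength
  temperature correction requires a user-supplied partition-function
  ratio.
- The perturbation model acts on the absorbance vector; interferogram-
  domain effects, comb-tooth structure and detector nonlinearity are out
  of scope.
- Mean relative errors are present-only averages; comparisons against
  conventions that include absent gases (where RE is undefined or zero)
  are not meaningful.
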