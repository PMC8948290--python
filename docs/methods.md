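# Methods

This note documents the models, defaults, and numerical choices behind the
package, and what the synthetic study can and cannot say about real scans.

## Forward model

Each pixel's waveform is synthesized in the frequency domain as
`E(f) · H(f)` and inverse-FFT'd, where `E(f)` is the spectrum of the
incident pulse and `H(f)` the transfer function of the window-backed
sample.

**Incident pulse.** A single-cycle derivative-of-Gaussian with unit peak
at the configured delay (default 50 ps) and width σ = 0.4 ps, giving an
amplitude spectrum peaking near 0.4 THz and covering roughly 0.1–1 THz
with zero DC content. Real emitters produce more structured few-cycle
pulses; a single clean cycle is the simplest shape with the right band.

**Tissue permittivity.** Double-Debye model
`ε(ω) = ε_∞ + (ε_s − ε_2)/(1 − iωτ₁) + (ε_2 − ε_∞)/(1 − iωτ₂)` with the
published healthy-human-skin set ε_s = 60.0, ε_2 = 3.6, ε_∞ = 3.0,
τ₁ = 10 ps, τ₂ = 0.18 ps as default. The function returns the loss
convention ε′ + iε″ (ε″ ≥ 0); the forward model conjugates it to match the
forward-FFT delay convention `e^{−i2πfτ}` (passivity there means
Im n ≤ 0). Edema scales the slow-relaxation amplitude:
Δ₁ → (1 + h)·Δ₁ with h the hydration delta, mapped linearly from the
dermal burn percentage (h = 0.35·d/100 by default). Any monotone map
satisfies the qualitative mechanism (more edema → higher index → stronger
window–tissue reflection); the linear map with a 35 % ceiling keeps the
in-band reflectivity change across grades at the few-percent level. The
quantitative link between scald exposure and dielectric change is unknown;
this map is deliberately generic.

**Window and echoes.** The imaging window is a flat-index slab
(n = 1.95, 3 mm — the material of the real window is not constrained
here), giving a round-trip delay of 2nd/c ≈ 39 ps. The sample response is

`H(f) = t_aw·t_wa · Σ_{m=0..M} r_wm(f)^{m+1} · r_int^m · e^{−i2πf·mT}`

(primary back-face reflection plus M = 2 Fabry–Pérot echoes; `r_int` is
the internal front-face window–air reflection; per-echo amplitudes decay
geometrically). Echoes delayed beyond the time record implied by the
frequency grid are dropped rather than aliased. Front-face (air–window)
reflection, beam optics, angular and polarization effects, and
depth-resolved skin layering are not modelled.

**Acquisition.** 27 × 27 pixels of 1 mm², time record 204.8 ps at
dt = 0.05 ps (4096 samples — power-of-two for the undecimated wavelet
transform; Nyquist 10 THz). White Gaussian noise of single-shot RMS 0.01
(≈ 3.5 % of the reference peak) scaled by 1/√20 for the 20-average
default. Tissue pixels get a multiplicative reflectivity jitter
(σ = 5 %, i.i.d. per pixel) standing in for Mie scattering by skin
appendages — the feature that motivates 16-pixel ROI averaging. Biopsy
pixels (4-mm disks) carry the window–air response: the punch leaves an air
gap behind the window.

**Default study.** Ten single-burn scans at d = 5, 15, 25, 35 (SPT),
45, 60, 75 (DPT), 85, 92, 98 (FT), echoing the ten-scald-burn design at
matched grade proportions. The burn disk (radius 20 mm) fills the FOV, as
the wounds do in the handheld-scanner geometry this emulates; one 4-mm
biopsy disk sits in the upper-right quadrant of each scan. The "tiny"
fixture is three 9 × 9 single-burn scans (d = 20, 60, 90), the first with
the biopsy disk.

## Denoising

Wavelet shrinkage on the shift-invariant (maximal-overlap / stationary)
transform, `sym4`, 6 levels. Per level, one hard threshold equal to the
largest coefficient magnitude whose (phase-compensated) time index falls
in either of two signal-free windows — pre-pulse (5–36 ps) and post-pulse
(64–75 ps, between the pulse and the first echo). This guarantees every
noise-window coefficient at a thresholded level is zeroed; a k·σ rule is
available behind a flag. The final-level scaling coefficients pass
untouched, so content below ≈ 0.16 THz is never shrunk.

Numerical choices worth knowing:

- Level alignment is calibrated per (wavelet, level, length) from a unit
  impulse; the transform itself is not phase compensated.
- `sym4` at 6 levels has ±≈11 ps coefficient support, which fits
  leakage-free between the pulse and the first echo. Longer filters
  (e.g. `sym8`) at 6 levels do not: their level-6 support (≈ 47 ps)
  exceeds the 39 ps pulse-to-echo gap, so thresholds would absorb pulse
  energy and the noiseless pass-through property would be lost.
- Window placement assumes signal-free intervals. This is exactly true
  only for non-dispersive reflections (the window–air reference): a skin
  pixel's reflection carries a τ₁ = 10 ps relaxation tail at the 1e-4
  level, so the noiseless-identity property (≤ 1e-6 relative error) is
  stated for the reference; dispersive pixels pass through at the few
  ×1e-5 level, far below the noise floor of any realistic acquisition.
- Record lengths must be divisible by 2^levels; no implicit padding is
  applied (the error message says what to do).

## Deconvolution

`R(f) = S·conj(S_ref)/(|S_ref|² + 1/SNR(f))` with SNR estimated from the
reference: Welch periodogram of the pre-pulse segment, interpolated to the
record's rfft grid and scaled to a full-record FFT magnitude-squared, with
the SNR clipped to [1e-12, 1e6] (the ceiling makes the noiseless limit
finite). A plain spectral ratio is retained as the unregularized
comparison mode; it diverges at reference nulls (DC, band edges) where the
Wiener estimate stays bounded.

## Biopsy masking

The mask is decided per pixel by the sign of the correlation between the
first-echo gate (±5 ps around the round-trip delay, measured from the
reference peak) and the reference's own echo template, after denoising.
Air-backed pixels replicate the reference echo (positive correlation);
for tissue, the echo term carries r_wm², whose complex phase lands in the
negative-real half-plane across the band for skin-like indices, flipping
the correlation sign. On default-noise phantoms the mask reproduces the
simulator truth pixel-for-pixel.

## Observations and classification

Per burn and iteration, k = 15 ROIs of 4 × 4 pixels are drawn uniformly
from top-left positions whose block avoids the biopsy mask (ROI–ROI
overlap permitted; a disjoint mode exists). Each ROI yields one row: the
16-pixel mean amplitude spectrum restricted to the inclusive in-band FFT
bins (82 bins for the default grid), plus the scalar band area
(trapezoidal) used for images and the ANOVA.

Six families run as three one-vs-all problems under stratified fivefold
CV. Hyperparameters are tuned per training split by an in-package Bayesian
optimizer: Gaussian-process surrogate (fixed Matérn-5/2 + white kernel on
the unit cube) maximizing expected improvement of the inner-CV
classification accuracy; 30 evaluations by default. Search spaces: SVM box
constraint log-uniform [1e-3, 1e3] and kernel scale σ log-uniform
[1e-2, 1e2] (γ = 1/σ²; polynomial kernel inhomogeneous, degree ∈ {2,3,4});
naive-Bayes variance smoothing log-uniform [1e-12, 1e-3]; LDA shrinkage
[0, 1]; AdaBoost 10–200 learners, learning rate [0.01, 1]. Because inner
objectives plateau on small samples, evaluations within 5e-3 of the best
are treated as tied and broken toward the max-margin (largest-C) then
smoothest-kernel setting: large-C SVM solutions have margin-calibrated
(±1) decision values, which keeps test scores commensurable when pooled
across folds before the ROC is built. Sensitivity, specificity, and
accuracy are read at the native score-0 operating point. AdaBoost's weak
learner is an in-package weighted LDA (weighted means and pooled
covariance, 5 % spherical shrinkage), since the stock LDA accepts no
sample weights.

**Fold modes and leakage.** By default, ROI rows from one burn may fall in
different folds (matching the protocol this emulates). On synthetic
phantoms this leaks: rows of a burn share that scan's frozen noise and
jitter pixels, so classifiers can identify the burn rather than the grade
and every family saturates near AUC 1.0 — which is also why the AUC
response to the hydration-separation scale only shows once folds are
grouped by burn (`group_by_burn=True`, with the inner search CV grouped
too). Both modes are first-class; the grouped mode is the leakage-safe
way to ask about generalization to unseen burns. Real wounds add
within-burn biological heterogeneity that the simulator does not model,
which is why the in vivo protocol reports sub-saturation AUCs while the
phantom study does not; passing suite-level tests here demonstrates the
machinery, not clinical performance.

The ANOVA stage is a standard one-way ANOVA on band areas across the three
grades with Tukey–Kramer pairwise comparisons at α = 0.05.

## Determinism

Every stage's randomness derives from one master seed through numpy
`SeedSequence` spawning; reruns with an unchanged config reproduce the
observation tables bit-for-bit, and each stage writes a manifest (config
hash + artifact checksums). Deterministic families reproduce exactly; the
GP search is deterministic given the seed chain.

## Problem sizes used in the shipped checks

Scaled to desk hardware: the forward-model and denoising checks use 2–3
pixel scans; mask checks one full 27 × 27 scan; the null calibration runs
the tiny three-scan study over 40 label permutations; the
separation-ordering check runs the ten-burn study at three hydration
scales with two SVM families, 3 iterations, 30 search evaluations; the
ANOVA calibration uses 1000 null simulations of three 10-value groups.

## Known limitations

- Single-layer tissue: no depth-resolved dermis/hypodermis structure, so
  "burn depth" enters only through the hydration map, not through
  time-of-flight signatures.
- The scatter jitter is white across pixels; real appendage scattering is
  spatially structured and frequency dependent.
- The simulated within-burn homogeneity overstates class separability and
  saturates row-level cross-validation (see fold modes above).
- The biopsy gap is modelled as a perfect air backing; partial contact or
  fluid pooling would weaken the echo-phase contrast the detector uses.
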