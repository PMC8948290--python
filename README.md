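# thzburn

Terahertz time-domain spectroscopic (THz-TDS) imaging for grading burn
injuries, as a tested, reproducible pipeline driven by a physics-based
synthetic scan generator.

## The problem

Partial-thickness burns are hard to triage by eye: whether a wound will
heal on its own or needs grafting depends on how deep into the dermis the
injury reaches, which visual inspection gets right barely more than half
the time in the first days. THz waves are exquisitely sensitive to tissue
water content. A burn triggers interstitial edema; the extra water raises
the skin's refractive index and therefore the reflection from the imaging
window–skin interface, so deeper burns reflect more strongly in the
0.1–0.5 THz band. A handheld reflection-mode scanner records a full
time-domain waveform for each 1 mm² pixel of a 27 × 27 mm² field of view
(20 averages per pixel), and supervised classifiers grade each wound as
superficial partial-thickness (SPT, dermal burn depth d < 40 %), deep
partial-thickness (DPT, 40–80 %), or full-thickness (FT, > 80 %), with
severity labels fixed by Day-4 histology.

The in vivo scans behind this protocol are not publicly deposited, so the
package ships a forward simulator that generates the study conditions with
known ground truth, and the full analysis chain that would run equally on
real scans stored in the same HDF5 container.

## What the pipeline does

1. **simulate** — per-pixel reflection waveforms from a double-Debye skin
   model behind a dielectric imaging window: primary window–tissue Fresnel
   reflection plus Fabry–Pérot window echoes, edema modelled as a
   hydration-dependent scaling of the slow Debye amplitude
   (ε(ω) = ε_∞ + Δ₁/(1 − iωτ₁) + Δ₂/(1 − iωτ₂)), shot noise scaled by
   1/√n_averages, 4-mm punch-biopsy air gaps, per-pixel scatter jitter.
2. **preprocess** — wavelet shrinkage on the shift-invariant (maximal
   overlap) wavelet transform with one hard threshold per level, estimated
   from two signal-free windows before and after the main pulse; then
   Wiener deconvolution of each pixel against the window–air reference,
   R(f) = S·conj(S_ref)/(|S_ref|² + 1/SNR(f)).
3. **features** — band-area images over 0.1–0.5 THz; biopsy pixels
   detected from the phase of the first Fabry–Pérot echo (an air gap flips
   the echo-template correlation sign); fifteen random 4 × 4-pixel ROIs
   per burn, each contributing one observation: the 16-pixel mean in-band
   amplitude spectrum.
4. **classify** — six families (linear/polynomial/Gaussian SVM, Gaussian
   naive Bayes, LDA, AdaBoosted LDA) on three one-vs-all problems under
   stratified fivefold cross-validation, hyperparameters tuned per
   training split by Bayesian (GP + expected-improvement) search, the whole
   protocol repeated over fresh ROI draws; one-way ANOVA with Tukey–Kramer
   pairwise comparisons on the scalar band areas.

## Worked example

The "tiny" study — three 9 × 9 scans, one per severity class, one
carrying the biopsy disk — runs the whole chain in well under a minute:

```python
from thzburn.pipeline import tiny_config, run_study
from thzburn.classify import anova_band_area

cfg = tiny_config()
cfg.classify.families = ("svm_gaussian", "lda")
report = run_study(cfg)
summary = report.summary()
print(summary[summary.metric == "auc"].to_string(index=False))
res = anova_band_area(report.observations[0])
print(f"ANOVA F = {res.f_statistic:.1f}, p = {res.p_value:.2e}")
```

prints

```
      family class metric     mean      std
         lda   DPT    auc 0.740741 0.231296
         lda    FT    auc 1.000000 0.000000
         lda   SPT    auc 1.000000 0.000000
svm_gaussian   DPT    auc 1.000000 0.000000
svm_gaussian    FT    auc 0.851852 0.128300
svm_gaussian   SPT    auc 0.981481 0.032075
ANOVA F = 58.1, p = 1.18e-04
```

Each row is the mean ± sd over three ROI-randomization iterations of the
area under the one-vs-all ROC curve: e.g. the Gaussian SVM separates DPT
burns from the other grades perfectly on this small, well-separated
phantom, while LDA struggles with the (not linearly separable) middle
class. The ANOVA confirms the in-band spectral areas of the three severity
groups differ far beyond chance.

The same stages run from the shell on any config:

```sh
thz-burnmap fixtures --size tiny          # write fixture scans + config
thz-burnmap all --config fixtures/tiny.yaml --seed 0
```

producing HDF5 scan/spectra containers, mask and band-area images
(CSV + PNG), the observation table (CSV), per-classifier metrics and ROC
samples (CSV), and a JSON summary — each stage with a manifest of config
hash and artifact checksums, all randomness derived from one master seed.

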