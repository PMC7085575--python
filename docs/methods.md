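# Methods

This note documents the models, conventions and design choices behind
`dwigrade`. Nothing here reports an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and ADC estimation

Diffusion-weighted MRI signal follows the mono-exponential decay

    S(b) = S0 · exp(−b · D)

with `b` the diffusion weighting (s/mm²), `S0` the unweighted signal and
`D` the apparent diffusion coefficient (ADC, mm²/s). Two per-pixel
estimators of `(S0, D)` are provided:

* **loglinear** (default): ordinary least squares of `log S` against `b`.
  Exact on noise-free data, closed form, vectorized over the image.
* **mle**: maximum likelihood under i.i.d. Gaussian noise on the signal
  intensities with a flat prior. For fixed `D` the optimal `S0` has a
  closed form, so the problem reduces to a bounded 1-D minimization per
  pixel (initialised from the loglinear fit and never allowed to be worse
  than it). The likelihood-product formulation collapses to least squares
  on the *linear* signals; the estimator is tested against a brute-force
  likelihood-grid oracle.

Numerical conventions: pixels with nonpositive intensity are floored at
`1e-6 × max(signal)` before the log transform and the clamp count is
recorded on the fit report; fitted `D < 0` is clipped to 0 (physical
constraint). Requesting a fit with fewer than two distinct b-values is a
configuration error.

**Computed high-b (CHB) synthesis** extrapolates the fitted decay from a
reference acquisition at `b_α`:

    Ŝ(b) = S_α · exp(−(b − b_α) · D̂)

The reference defaults to the lowest acquired b-value (highest SNR). At
`b = b_α` the synthesized image equals the reference exactly, and output is
strictly decreasing in the target b wherever `D̂ > 0`.

The acquisition protocol is configuration: the phantom default is
`b ∈ {0, 100, 400, 1000}` s/mm² with a CHB target of 1600 s/mm², a typical
low-b clinical protocol extrapolated past 1000 s/mm² where cancerous tissue
appears hyperintense.

ADC maps are exported in the conventional display unit of 10⁻⁶ mm²/s
(prostate tissue ≈ 700–2000) and clipped at the conventional ceiling 3949,
which is also the out-of-zone fill and the heuristic normalizer `M_ADC`.

## Synthetic cohort (phantom)

The generator emulates the *structure* of a zone-level prostate DWI study,
not prostate anatomy:

* per patient, 18–34 coronal slices (uniform draw), each carrying a 10-zone
  label map built from rings × sectors of a jittered ellipse (two
  equal-area rings of 5 sectors by default);
* zone-wise ADC truth: healthy zones `N(1.6×10⁻³, 1.5×10⁻⁴)` mm²/s,
  cancerous zones `N(0.8×10⁻³, 1.0×10⁻⁴)` mm²/s — the ~2:1 healthy:cancer
  ADC contrast typical of reported prostate values. These are generator
  defaults, not measured values;
* within-zone texture: a multiplicative smoothed-Gaussian-noise field
  (relative amplitude 0.08, correlation length 3 px) on both ADC and S0;
* signals simulated through the forward model with Rician noise (magnitude
  MRI; σ = 15 on S0 ≈ 800, i.e. ≈ 2 % of the unweighted signal). Gaussian
  and noise-free modes exist for estimator unit tests;
* labels: patients are designated positive with probability 0.41 (41/101
  patients in the emulated study) and, within positive patients, each
  (slice, zone) is positive with probability 0.026, giving an overall
  positive-zone prevalence near 1.1 % (135/12 466 in the emulated study).

A **texture-only** cancer mode keeps the cancerous mean ADC equal to
healthy tissue but shortens the texture correlation length (1 px vs 3 px):
the marginal intensity distribution is nearly unchanged while second-order
statistics differ. This deliberately constructs a cohort where min/max
intensity heuristics carry little information but texture features do —
the qualitative regime in which radiomic graders are claimed to help. The
mode was designed from that reasoning (scale contrast rather than amplitude
contrast, because a zone minimum responds directly to amplitude).

What the phantom does **not** emulate: anatomy, partial-volume and
registration effects, scanner bias fields, b-value-dependent noise floors,
inter-zone ADC correlation within a patient, PI-RADS reader behaviour.
Passing phantom tests therefore demonstrates pipeline correctness and the
qualitative heuristic-vs-radiomics ordering, not clinical performance.

## Zone patches

Per (slice, zone): tight axis-aligned bounding box (no margin), out-of-zone
pixels filled with the modality constant (ADC 3949 = maximally benign;
CHB 0 = minimally suspicious), then bilinear resize to 32×32 with
half-pixel-centered coordinates (align-corners off, no antialiasing, so a
constant region stays exactly constant). Fill precedes resizing. The
binary in-zone mask is resized alongside and re-binarized at 0.5; zones
thinner than 2 pixels get a nearest-neighbour upsampling pre-pass (bilinear
is undefined there). The original (pre-resize) in-zone pixel values are
retained on each patch for the intensity heuristics.

## Radiomic sequence (96 features)

Concatenation of four blocks; all computed from in-mask pixels only, so
every feature is invariant to the fill value (verified by test). A config
flag (`include_fill`) restores whole-patch computation for sensitivity
analysis.

1. **First-order (4)** — mean, population SD, skewness, excess kurtosis.
   Constant patches return skewness = kurtosis = 0 by convention (guarded
   on the value range to absorb floating-point near-constancy).
2. **Haralick (18 × 4 = 72)** — statistics of the normalized symmetric
   gray-level co-occurrence matrix at unit distance for offsets 0°, 45°,
   90°, 135°; pixel pairs touching out-of-mask pixels are excluded.
   Quantization: min–max over in-mask pixels into 32 levels (configurable).
   The 18 statistics, in order: energy, contrast, correlation, sum of
   squares variance, homogeneity (inverse difference moment), sum average,
   sum variance, sum entropy, entropy, difference variance, difference
   entropy, IMC1, IMC2, autocorrelation, cluster shade, cluster prominence,
   dissimilarity, maximum probability. Entropies use the natural log;
   degenerate denominators (zero variance, zero marginal entropy) return 0.
   The implementation is validated against a pure pair-enumeration oracle
   to 1e-10.
3. **Kirsch (8)** — mean absolute response to the eight 3×3 compass
   kernels (5/−3 ring rotated in 45° steps), out-of-mask pixels replaced by
   the in-mask mean before filtering, replicate boundary. A 90° patch
   rotation permutes the features by two compass steps (tested).
4. **Gabor (12)** — mean complex-response magnitude for 4 orientations
   (0°, 45°, 90°, 135°) × 3 wavelengths (2, 4, 8 px, bandwidth 1 octave),
   kernels DC-corrected so a constant patch responds ≈ 0. Wavelengths span
   the texture scales representable in a 32×32 patch. Filtering is
   FFT-based with edge-replicated padding (identical to direct correlation
   to ~1e-15).

## Graders

* **Clinical heuristic** — zone score `1 − min(zone)/M_ADC` (ADC) or
  `max(zone)/M_CHB` (CHB), computed on pre-resize in-zone pixels; binary
  cutoffs at 1000 with strict inequalities (below for ADC, above for CHB;
  the boundary itself grades negative). `M_ADC` is fixed at 3949; `M_CHB`
  is the training-cohort maximum, recomputed per dataset.
* **Feature-based (lr / rf / svm)** — scikit-learn logistic regression,
  random forest (200 trees), and RBF SVM (Platt-calibrated decision values)
  on standardized radiomic sequences; standardization is fit on the
  training split only. All use class weights {negative 1, positive 150},
  matching the weighting used for the convolutional grader.
* **Convolutional sequencer (dr)** — a compact conv-net over normalized
  32×32 patches: 3×3 same-padded convolutions with ReLU, optional 2×2
  max-pools, terminal global-average pooling and a dense 2-way softmax
  head. The design is declarative (`SequencerDesign`); two defaults ship:
  ADC = conv8–pool–conv16–pool–conv32 (≈ 5.9 k parameters) and
  CHB = conv8–conv8–pool–conv16–conv16–pool–conv32 (≈ 8.9 k), keeping the
  ADC design strictly smaller than the CHB design. The exact discovered
  topologies of an architecture search are not reproducible from a design
  space alone; a coarse random search utility over the space is provided
  but is explicitly not a generative design-search method.

Training of the convolutional grader uses Adam with class-weighted
cross-entropy (weights {1, 150}): the mean over batch samples of
`−[y log p + (1−y) log(1−p)]`, each term scaled by its class weight, so an
identical error on a positive sample costs exactly 150× the negative-sample
error. Modality defaults: ADC batch 219, learning rate 2×10⁻⁴, patience 50;
CHB batch 163, learning rate 2×10⁻³, patience 16. Early stopping monitors
validation loss on a held-out 20 % patient-level split (seeded; the split
protocol is a package choice — patience implies validation monitoring but
no protocol is standard). The epoch cap defaults to 100, which on the
separable phantom regimes used here is past the point where held-out AUC
saturates; training restores the best-validation parameter state. Inputs
are scaled to [0, 1] by the modality maximum (3949 for ADC, training-cohort
maximum for CHB) — bounded inputs stabilize optimization. The network and
Adam are implemented in numpy (float32 arithmetic, float64 loss/optimizer
accumulators); gradients are verified against finite differences, and
training is reproducible run-to-run for a fixed seed on one platform.

## Evaluation protocol

* **ROC / AUC** — thresholds at every unique score, trapezoidal AUC (equal
  to the Mann–Whitney pairwise count with ties at ½; verified against a
  brute-force oracle).
* **Threshold selection** — `θ̂ = argmax 2[w(1−fpr) + (1−w)tpr]`, `w = 0.5`
  by default (plain Youden (1−fpr)+tpr); `w` exposes the
  sensitivity/specificity trade-off. Candidates are midpoints between
  consecutive unique scores plus the extremes, so separable scores yield
  the midpoint of the separating gap. Ties break toward higher specificity,
  then toward the higher threshold. A sample grades positive iff its score
  ≥ θ̂ (closed lower bound).
* **Cross-validation** — patient-level stratified k-fold (default 5):
  patients with and without verified positive zones are shuffled separately
  (seeded) and dealt round-robin, so all zones of a patient share a fold.
  A 101-patient roster yields groups {21, 20, 20, 20, 20}. Per fold,
  learned graders are fitted on the other k−1 folds, the held-out zones
  are scored, θ̂ is selected on the held-out ROC (a deliberately optimistic
  convention — selecting on the training ROC is available via the same
  API), and AUC/sensitivity/specificity at θ̂ are recorded; the report
  aggregates mean ± SD over folds.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen to
exercise every code path on one CPU: 20-patient cohorts (~5000 zones,
~50 positive) for the cross-validated heuristic-vs-radiomics comparisons,
an 8-patient cohort with elevated positive rates (~2000 zones, ~370
positive) for convolutional-grader training with a 2-patient hold-out, and
100-instance oracle sweeps. Clinical-scale AUC values from any real cohort
are data-dependent and are not reproduced by these synthetic experiments.

## Known limitations

* The mono-exponential model ignores IVIM/kurtosis effects; the loglinear
  estimator is biased under Rician noise at low SNR (the MLE assumes
  Gaussian noise, adequate at the phantom's SNR).
* Zone maps are schematic; no segmentation is performed (zone maps are
  inputs by design).
* The Platt calibration inside the SVM grader refits on internal folds;
  with very few positives per training split its probabilities are coarse
  (rankings, hence AUC, are unaffected).
* Threshold selection on the held-out ROC overstates sensitivity/
  specificity relative to a fully prospective protocol; AUC is unaffected.
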