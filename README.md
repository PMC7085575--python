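# dwigrade

Zone-level prostate cancer grading from diffusion-weighted MRI (DWI).

Prostate cancer screening increasingly relies on DWI: water diffusion is
restricted in tumour tissue, so cancer shows a low apparent diffusion
coefficient (ADC) and appears hyperintense on high-b-value images. Because
high-b acquisitions are noisy, high-b images can instead be *computed* by
extrapolating a mono-exponential fit of low-b acquisitions (CHB-DWI).
Radiologists grade suspicion per anatomical *zone* — one of ten regions of
the gland, assessed slice by slice — and the simplest clinical rule
thresholds the zone's extreme intensity (minimum ADC below 1000, or
maximum CHB above 1000, flags cancer).

`dwigrade` implements that full zone-level sensing pipeline for
researchers comparing grading strategies:

* **Signal model** — forward simulation `S = S0·e^(−bD)`, per-pixel
  (S0, D) estimation (log-linear least squares or Gaussian MLE), and CHB
  synthesis `Ŝ(b) = S_α·e^(−(b−b_α)D̂)`.
* **Zone patches** — per-(slice, zone) crops, masked with modality fills
  (ADC 3949, CHB 0) and bilinear-resized to 32×32.
* **Radiomic sequence** — a 96-dimensional hand-engineered feature vector
  per zone: 4 first-order moments, 18 Haralick co-occurrence statistics in
  4 directions, 8 Kirsch compass-edge responses, 12 Gabor responses
  (4 orientations × 3 scales).
* **Graders** — the clinical min/max heuristic
  (`p = 1 − min/M_ADC`, `p = max/M_CHB`); logistic regression, random
  forest and SVM on radiomic sequences; and a compact convolutional
  sequencer trained end-to-end on patches with Adam and class-weighted
  cross-entropy (weights 1:150 for the rare positive grade).
* **Evaluation** — ROC/AUC, Youden-style threshold selection
  `θ̂ = argmax (1 − fpr) + tpr`, sensitivity/specificity, and stratified
  patient-level 5-fold cross-validation (all zones of a patient stay in
  one fold).
* **Phantom** — a seeded synthetic cohort generator (10-zone slice maps,
  zone-dependent ADC truth, Rician noise, ~1 % positive zones clustered in
  a minority of patients) so the pipeline runs end-to-end without access
  to clinical data.

See `docs/methods.md` for model details, parameter defaults and
limitations.

## Worked example

Simulate two 10-patient cohorts — one where cancer lowers the mean ADC
(the regime the clinical heuristic is built for), one where cancer differs
only in texture — and cross-validate the heuristic against a radiomic
grader:

```bash
cat > phantom.yaml <<EOF
image_size: 64
slices_per_patient: [4, 6]
positive_patient_rate: 0.5
positive_zone_rate: 0.2
EOF

dwigrade simulate --patients 10 --seed 42 --config phantom.yaml --out cohort
# wrote 10 patients, 540 zones (26 positive) to cohort

dwigrade evaluate --cohort cohort --strategy heuristic --modality ADC --k 3 --seed 0 --out eval
# ADC heuristic  AUC 1.000±0.000  sens 1.000  spec 1.000
dwigrade evaluate --cohort cohort --strategy lr --modality ADC --k 3 --seed 0 --out eval
# ADC lr         AUC 1.000±0.001  sens 1.000  spec 0.998
```

With strong mean-ADC contrast both graders are essentially perfect — the
zone minimum is a sufficient statistic. Now the texture-only regime
(`texture_only: true` added to the config): cancerous zones keep the
healthy mean ADC but carry a finer texture grain.

```bash
dwigrade simulate --patients 10 --seed 42 --config texture.yaml --out tcohort
dwigrade evaluate --cohort tcohort --strategy heuristic --modality ADC --k 3 --seed 0 --out teval
# ADC heuristic  AUC 0.536±0.062  sens 0.756  spec 0.465
dwigrade evaluate --cohort tcohort --strategy lr --modality ADC --k 3 --seed 0 --out teval
# ADC lr         AUC 0.978±0.025  sens 0.939  spec 0.963
```

The min-intensity heuristic collapses to near-chance (AUC 0.54: zone
minima no longer separate the classes) while the radiomic-sequence grader
still discriminates (AUC 0.98), because second-order texture features —
co-occurrence contrast, Gabor energy at short wavelengths — capture the
grain difference. Reported values are mean ± SD over the 3 patient-level
folds; sensitivity and specificity are taken at the per-fold optimal
threshold.

Other subcommands: `compute-chb` (write ADC/CHB maps as NIfTI),
`extract-zones` (32×32 patch stacks + manifest), `featurize` (the
96-column feature table as CSV), `train` (fit and save a single grader).
The library API mirrors the CLI (`dwigrade.phantom`, `dwigrade.pipeline`,
`dwigrade.evaluation`, ...).

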