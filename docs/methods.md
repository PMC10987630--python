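# Methods

This note documents the models, algorithms and design choices behind
`cspws`, in the package's own terms. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The measurement model

Chromatin inside a nuclear packing domain follows a mass-fractal scaling
N_f ∝ r^D between the number of chain monomers and the radius they
occupy. The autocorrelation function B(r) of the mass density then obeys

    D − 3 = ∂ log B(r) / ∂ log r

inside the instrument's length-scale sensitivity window, here 23–334 nm.
Interference microscopy measures, per pixel, the standard deviation Σ
over wavelength (500–700 nm, 2 nm steps, 101 planes) of the
reference-normalized back-scattered spectrum. Σ² is proportional to the
density ACF integrated against a coherence kernel, which we model as

    Σ²(D) = A · φ(1−φ) · ∫_{r_min}^{r_max} (r/r_min)^{D−3} · S(r) · r dr

with S(r) a Gaussian of transverse scale 458 nm (the transverse
coherence extent; the ~3 µm depth of field contributes an axial factor
folded into the instrument constant A), and φ the chromatin volume
concentration entering through the φ(1−φ) variance prefactor of a binary
medium. Normalizing the power law at the lower window edge r_min makes
Σ strictly increasing in D — denser long-range packing produces a larger
interference signal — and the table Σ(D) is inverted by monotone
interpolation to give per-pixel D. Sigma values outside the calibrated
range clamp to the grid ends and are flagged, never extrapolated; maps
with >50 % clamped pixels carry a warning in their metadata.

**Self-consistency, prominently:** the Σ→D calibration is built from
this package's own forward integral and used for both synthesis and
inversion. Absolute D values are therefore internally defined; they are
not cross-calibrated to any external electromagnetic (FDTD) or
electron-microscopy ground truth. What the round-trip tests demonstrate
is the correctness of the plumbing and the inversion, not instrument
realism. Physics realism is tested separately and independently at the
density-field level, where the generator must reproduce the D − 3 ACF
slope that defines the observable.

## Synthetic data

**Density fields.** Stationary zero-mean Gaussian random fields realize
a target ACF: a power law (r/r_min)^{D−3} on [23, 334] nm, flat below
(unresolved), and a Gaussian roll-off of scale 2·r_max beyond (the form
outside the window is unobservable and is our choice). A windowed power
law is not exactly positive definite, so the grid power spectrum is
obtained by alternating projections — clip the spectrum at zero,
transform back, re-pin B(r) to its target inside r ≤ r_max, 30
iterations — which leaves ≲0.03 deterministic slope bias on a 1024²
grid at 20 nm pitch; single-realization slope fits add ≈0.04 sd. Fields
are 2-D, representing the projection through the depth of field.

**Spectral cubes.** Per-pixel spectra are 1 + fluctuation, where the
fluctuation is a band-limited (Gaussian-smoothed over wavelength,
σ = 3 samples) white process, projected onto the complement of the
degree-1 polynomial space and scaled so its standard deviation equals
the forward-model Σ at the pixel's local D; white measurement noise of
chosen sd is added on top. Because the synthesized fluctuation is
detrend-invariant, the noiseless round trip through `compute_sigma_map`
(default degree-1 detrend) is exact to float precision. This is a
calibrated statistical emulation, not an electromagnetic simulation.

**Sigma detrending and noise.** Σ is computed after removing a low-order
polynomial baseline per pixel (default degree 1, configurable),
suppressing reflectance slope. When the blank-region measurement noise
level is known, its variance — shrunk by (L−p−1)/L for the detrend
projection — is subtracted from Σ² before inversion (independent noise
adds in variance). Without this correction the inversion is biased
upward where the noise floor is comparable to the signal (≈ +0.11 in D
at D = 2.1 with noise sd 0.01); with it, recovery is within 0.05
everywhere in the calibrated range.

**Nuclei and segmentation.** Synthetic nuclei are ellipses on a
low-fluctuation background (2 % of the in-mask Σ). The automated
segmentation stand-in (Otsu threshold, hole filling, connected
components, area filter) replaces the interactive manual segmentation a
trained investigator would perform on real data; on generator ellipses
it reaches Dice ≥ 0.95.

**Cohorts.** Patients carry diagnostic group, age, sex,
smoking/drinking, and a colonoscopy-history category. Defaults encode
the study structure the analysis assumes: 256 patients
(135 control / 13 DA / 15 NDA / 74 AA / 9 HNPCC / 10 cancer), 31 cells
per patient (the >30-cell inclusion floor), group ages and
female/smoking/drinking rates from the demographics table
(ages ≈ N(group mean, 8) truncated to [40, 90]), and a per-cell D model

    D = group_mean[g] + history_offset[h] + patient offset
        + cell offset + (−0.008/yr) · (age − group mean age).

The paper prints no absolute D values, so the group ramp
2.50 → 2.66 is a placeholder; only ordering and separations carry
meaning. The between-patient sd 0.11 sets the AA-vs-control
standardized effect near 0.8 (the reported effect-size band), and the
history offsets (0 / +0.02 / +0.05) reproduce the risk-ladder ordering
(control < high-risk-history control < AA by history). The age trend is
centered per group, so the configured group means are the observed
means: cases are elevated despite being older, and age explains only
within-group variation. Within-patient (cell) sd is 0.15. Every
stochastic step derives its seed from the cohort seed.

**D-map textures for classification.** `synthesize_dmap` produces
recovered-looking nuclear D maps directly: an elliptical nucleus with
smooth intra-nuclear heterogeneity of sd 0.06 whose correlation length
doubles every 0.25 in D (denser packing forms larger coherent domain
clusters). This matters because the classifier's preprocessing min–max
normalizes every image, deliberately discarding the mean D level — the
deep pipeline can only exploit spatial structure, which is exactly its
intended complement to the univariate mean-D biomarker. The texture
model is the generator's encoding of that structure; its correlation
scale, like the group ramp, is a modeling choice, not a measured value.

What the generator does **not** emulate: 3-D nuclear morphology,
staining appearance, mucus/debris artifacts, cell-type mixtures, or any
instrument drift. Tests passing on this data show the analysis chain is
correct under the stated statistical model; they do not certify
performance on real brushings.

## Cohort statistics

Patients, not cells, are the unit of inference; a patient's score is
the mean of its per-cell nuclear-mean D. Two-group contrasts use
Welch's t (unequal n, unequal variance; Mann–Whitney available) with
Cohen's d on the pooled sd, positive when the case side is elevated;
complete separation with zero pooled spread is flagged degenerate. The
confounder screen is an OLS of patient mean D on case status (case =
NDA + AA + cancer, as in the demographics table), age, sex, smoking and
drinking. The univariate biomarker analysis stratifies a 50/50 split by
class, picks the optimal cutpoint on the training half, and reports
sensitivity/specificity and the rank AUC on the held-out half. Raw
p-values are reported; no multiplicity correction is applied.

## Five-year CRC risk model

    CRC risk = (1/(Na+Nc)) · [ AAr · Σ_{i=1..Na} AA→CRC_i + Nc · CRCm ]

where Na are patients without and Nc with a prior-cancer history; each
AA→CRC_i converts a sex- and age-stratified (boundary at 80 years)
annual progression rate to the 5-year horizon via
1 − exp(−annual · t). AAr multiplies the sum, exactly as the formula is
written. All rates are literature-derived config inputs; the shipped
defaults are placeholders of plausible magnitude: annual AA→CRC
0.030/0.020 (M/F under 80) and 0.050/0.035 (over 80); AAr 0.06/0.17/0.35
for no/low/high-risk history without a current lesion and 0.40/0.55/0.75
for populations presenting with an advanced adenoma (recurrence risk,
graded by history); metachronous-CRC probability 0.09. Any real use
must supply rates from current surveillance literature. The ladder
regression (risk vs. population mean D over control/AA × history
populations) is an ordinary least-squares fit reporting r².

## AI classifier

1. **Preprocess**: crop the D map to its mask bounding box, zero-fill
   outside, min–max scale in-mask values (constant maps go to 0.5),
   resize anisotropically to the backbone input (224² default, 64² in
   the test configuration) and replicate to 3 channels. After resizing,
   a final exact min–max restores the (0, 1) span.
2. **Features**: a pluggable backbone maps images to fixed-length
   vectors. The in-repo default is a fixed-seed random-weight CNN
   (3×3 stride-2 He-initialized convolutions, a 1×1 projection, global
   average pooling; 2048-d default, 128-d in the test configuration) —
   deterministic, dependency-free, and geometry-preserving in the
   random-projection sense. A pretrained ResNet50 can be plugged in
   where torch and its weights are available; an identity-downsample
   baseline exists for sanity checks.
3. **Compression**: a symmetric 5-layer-encoder/5-layer-decoder MLP
   autoencoder (geometric width taper, tanh hidden units, linear latent
   and output, inputs standardized) trained 50 epochs with Adam
   (lr 3·10⁻³, batch 64) to a 40-d latent code. Training is
   bit-deterministic for a fixed seed.
4. **Classification**: a random forest on the latent codes, tuned by
   grid search (default: depth ∈ {None, 6}, √p features, 100 trees)
   under inner 3-fold stratified CV on training data only.

Evaluation is repeated stratified fourfold cross-validation with five
repeats (20 folds), stratified **by patient**: all cells of a patient
stay on one side of every split, and each fold entry records its
train/test patient ids and cell indices so leakage is auditable. Cell
scores are averaged to a patient score before ROC (a per-cell mode
exists). Each fold reports the rank (Mann–Whitney) AUC — ties count
one half — and the sensitivity/specificity at the cut-point maximizing
the number of correct classifications within that fold; candidates are
midpoints of sorted unique scores plus one sentinel beyond each extreme,
with ties broken toward higher sensitivity, then lower threshold.

## Numerical and scaling choices

- Calibration grid: D ∈ [2, 3], 101 points, scipy quadrature per point;
  construction aborts if Σ(D) is not strictly increasing.
- Field-ACF tests use 1024² grids at 20 nm pitch (extent ≫ 2·r_max);
  the ACF-slope property is asserted on the 5-seed mean, whose sampling
  sd (≈0.02) is well inside the ±0.1 band.
- Classifier tests run 12 patients/arm × 8 cells at 64² input with the
  128-d backbone and the full 40-d/50-epoch autoencoder — the smallest
  configuration at which the 20-fold protocol, the leakage audit, and
  the strong-signal/permutation-null contrast are all meaningful.
- The end-to-end CLI demo uses 48² images and a handful of imaged cells
  per patient; the imaged subset is a per-patient cap (`images.cells`),
  while the statistical tables always carry all 31 cells.
- Reports are JSON with sorted keys and CSV with fixed float formatting,
  so identical configs and seeds reproduce byte-identical files.

## Known limitations

- Absolute D is defined by the package's own forward model; comparisons
  to externally calibrated instruments require re-calibration.
- The spectral synthesis is statistical; it cannot reveal failures of
  the underlying electromagnetic approximations.
- Risk-model rates are placeholders; outputs are only as good as the
  supplied surveillance parameters.
- The permutation-null AUC of the classifier has high per-permutation
  variance on 24-patient cohorts (chance overlap with the true labels
  leaks residual signal in either direction); only its average over
  permutations is a calibrated 0.5.
- The random-weight backbone is a deterministic stand-in; transfer
  learning from pretrained weights may behave differently on real data.
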