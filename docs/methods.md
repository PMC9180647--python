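# Methods

## Problem setting

The package models a laboratory study of pesticide-residue detection on
table-grape clusters with hyperspectral imaging. Clusters of 3–6 berries from
three varieties (Cabernet Sauvignon, Red grape, Munage) are sprayed with a
three-product fungicide mixture at four levels — level 0 is distilled water;
levels 1–3 are 15%, 30% and 50% of a standard mixture — air-dried, and imaged
by two push-broom instruments. After noisy band removal the working grids are
80 bands over 476–890 nm (Vis-NIR) and 230 bands over 970–1594 nm (NIR). The
task is 4-class classification of residue level from each cluster's mean
reflectance spectrum, plus attribution of which wavelengths carry the signal.

The original cluster spectra are not publicly deposited, so the package ships
a synthetic generator that reproduces the *statistical structure* the analysis
assumes, and every stage is validated against that generator's ground truth.

## Spray-design arithmetic

Each product's standard solution dissolves 1 g in `ratio` mL of water:
concentration = 1000/ratio g/L (Jiatu 1:4000 → 0.2500 g/L, Xishuangke 1:6000 →
0.1667 g/L, Huiyin 1:2400 → 0.4167 g/L). Level concentrations are the level
fraction times the exact standard, rounded to 4 decimals only for reporting.

## Synthetic generator

A berry spectrum for level *l*, variety *v* is

```
x(λ) = g · [ b_v(λ) − d_l · p(λ) ] + o + ε(λ)
```

* `b_v` — a smooth base reflectance in (0, 1): green bump near 550 nm, red
  edge near 700 nm, water dips near 970/1450 nm, plus a small smooth
  variety-specific offset (no level × variety interaction, consistent with
  the observation that accuracy does not depend on variety).
* `p` — sum of three Gaussian absorption peaks (σ = 14 nm) at designated
  *informative* wavelengths (530/670/810 nm on the Vis-NIR grid;
  1120/1300/1450 nm on NIR). Three localized peaks make saliency enrichment
  a testable planted signal.
* `d_l` — class-ordered peak depth, default 0.00/0.02/0.04/0.08 reflectance
  units. These depths are deliberately small relative to the scatter term so
  raw class means overlap heavily, as real residue spectra do. Equal depths
  across classes are permitted and constitute the null model (no signal).
* `g ~ N(1, 0.15)`, `o ~ N(0, 0.05)` — per-sample multiplicative scatter and
  additive baseline. This affine corruption is exactly the model SNV removes,
  which makes SNV provably beneficial and its removal property testable.
* `ε ~ N(0, 0.01)` per band — instrument noise.

Default per-variety, per-level cluster counts reproduce the study design
(totals 288/411/372 by variety, 254/261/271/285 by level, 1071 overall).

Scene mode renders one cluster per sub-image: an elliptical berry mask with
jittered center/radius whose expected area fraction equals `berry_fraction`
(default 0.25), a flat 0.05-reflectance background, and white/dark reference
frames with small *fixed* spatial gradients (5%/2% linear terms and a smooth
lamp profile over wavelength) so that flat-field correction is non-trivial.
Raw digital numbers are synthesized by the exact inverse of the correction,
`raw = R·(white − dark) + dark`, giving the correction stage an exact oracle.
One scatter gain and baseline offset are drawn per scene (a cluster is one
physical sample); pixel noise is independent. The generator emits one
spectrum per sample in dataset mode; it does not emulate the two-shot
front/back imaging protocol, whose merging rule is unspecified in the
original design.

What the generator does **not** emulate: berry curvature and specular
highlights, uneven pesticide deposition, instrument-specific noise spectra,
wavelength-dependent stray light. Passing tests therefore demonstrate
correctness of the pipeline's algorithms under the stated generative
assumptions, not field performance on real grapes.

## Reflectance correction and ROI extraction

`R = (raw − dark) / (white − dark)` elementwise in floating point; a
coincident white/dark value raises immediately with the offending index
rather than producing infinities. A `gray_reference` switch implements the
alternative reading of calibrating against a 50% gray panel (divide by
`0.5·(white+dark) − dark`, rescale by 0.5); it is algebraically identical for
ideal frames and off by default.

The berry ROI is segmented by thresholding one high-contrast band — nearest
grid band to 804 nm (Vis-NIR) or 1092 nm (NIR), since neither target is
guaranteed on-grid. The default threshold is Otsu's method on that band's
histogram; connected components under 20 px are removed as speckle. The
sample spectrum is the per-band arithmetic mean over ROI pixels
(permutation-invariant and linear by construction).

## Preprocessing

Order: trim → Savitzky–Golay → SNV; all three are per-sample transforms, so
no train/test leakage is possible. Trimming keeps the closed interval
[476, 890] or [970, 1594] nm. SG uses polynomial order 0 and window 3
(equivalent to a 3-point moving average) with nearest-value edge padding to
preserve band count. SNV centers each spectrum and divides by its population
standard deviation (1/n); the affine-invariance property holds for either sd
convention, and the choice is recorded in dataset provenance.

## PCA exploration

Mean-centered PCA on the preprocessed spectra (no per-band standardization —
standard chemometrics practice for SNV-treated data). Component signs are
fixed so each loading's largest-magnitude element is positive, making score
plots reproducible. The 0.95 confidence ellipse of a 2-D score cloud is the
fitted Gaussian's contour at the χ²(2) quantile: semi-axes are
`sqrt(χ²₀.₉₅(2) · eigenvalues)` of the sample covariance.

## Classifiers

**Classical.** Exhaustive grid search selected by validation-split accuracy;
the winner is refit on the training split only, and ties keep the first
point in deterministic lexicographic grid order. Search spaces: SVM kernels
{poly, rbf, sigmoid, linear} with C and γ log-spaced (7 points) over
[10⁻⁵, 50]; logistic regression solvers {newton-cg, lbfgs, liblinear, sag}
with C log-spaced over [10⁻⁵, 10⁵] and L2 penalty (liblinear is applied
one-vs-rest, its classic multiclass scheme); random forest with
n_estimators 100–1000 in steps of 50 and max_depth 4–8. Continuous axes are
discretized because only ranges, not grids, are part of the design.

**Deep.** Both networks consume a spectrum as a 1-channel 1-D signal and are
implemented on a NumPy layer stack written for this package (explicit
forward/backward passes, float32 parameters, gradients propagated to the
input for saliency):

* CNN: conv(1→128, k3, p1)+BN+ReLU → conv(128→64, k3, p1)+BN+ReLU →
  conv(64→32, k5, p1)+BN+ReLU → avgpool(k2, s2) → flatten →
  [linear→BN→ReLU→dropout 0.5] × (256, 128) → linear→4. Conv lengths follow
  L' = L + 2p − k + 1; at 80 bands the flattened width is 32 × 39 = 1248, at
  230 bands 32 × 114 = 3648.
* ResNet: stem conv(1→64, k3, p1)+BN+ReLU, then three basic residual blocks
  (two k3 convs + BN each, ReLU between and after the sum; 1×1 conv + BN on
  the skip when channels change) with channels 64→64→128→256, global average
  pooling over the band axis (so the pooled feature width is 256 for any
  band count), and a 256→4 linear head.

Training: Adam on softmax cross-entropy, Xavier-uniform initialization,
mini-batches of 32; initialization, shuffling and dropout all derive from a
single seed, so runs are bit-reproducible on one machine. Average pooling
uses stride = kernel (non-overlapping). No learning-rate schedule, weight
decay, or early stopping is used.

After the last epoch, batch-norm running statistics are recalibrated by one
sweep over the training split (cumulative-average momentum, dropout off).
Without this, running estimates lag the final weights — the small trailing
batch of a 644-sample training split is especially distorting — and
evaluation-mode accuracy understates the fitted model. Evaluation mode
(dropout off, BN frozen) is deterministic: repeated passes give identical
predictions.

Reference full-scale budgets are 500 epochs (lr 10⁻³) for the CNN and 1000
epochs (lr 5·10⁻³) for the ResNet. The package's default experiment runs
desk-scale surrogates — CNN 100 epochs at lr 10⁻³, ResNet 30 epochs at
lr 10⁻³ — chosen so a full experiment completes in minutes on one CPU core;
the ResNet step size is reduced along with its epoch count because large
steps without the long schedule leave this stack short of convergence. Both
reach ≥ 0.98 test accuracy on the default generator.

## Splitting and evaluation

Stratified 3:1:1 split (60/20/20%) by residue level (optionally
level × variety): each stratum is shuffled under the split seed, sized by
floor division, and leftover samples are assigned train-first, so per-stratum
sizes are within one sample of exact proportions. Accuracy is the fraction
of predictions agreeing with the true labels.

## Saliency

For every correctly classified test sample, the importance weight is
`w = |∂S_c/∂x|` — the absolute gradient of the *pre-softmax* score of the
true (= predicted) class with respect to the input spectrum, computed in
evaluation mode so it is deterministic and invariant to a constant shift of
all class scores. Per-band importance is the mean of `w` over those samples,
divided by its maximum so the most important wavelength scores exactly 1;
per-class profiles (the same statistic restricted to one class, on the
shared scale) are attached as a breakdown. For linear scorers (logistic
regression) the gradient is the class weight vector, giving an exact
analytic oracle; one-vs-one SVMs and forests have no single per-class linear
score and are excluded from the saliency path.

## Numerical choices and degenerate inputs

* Float32 parameters and activations during training (memory/speed on one
  core); float64 inputs propagate in float64, which is how the
  finite-difference gradient checks reach ≤ 10⁻³ relative error.
* SNV raises on constant spectra, naming the row; segmentation raises when
  thresholding yields no foreground (e.g. constant band image); correction
  raises on coincident references, naming the first pixel-band.
* Conv/pool length underflow raises an architecture error at build time.
* Otsu with min-area 20 px is the default segmentation; a fixed threshold is
  available for controlled tests.
* Grid-search ties resolve to the earliest lexicographic point; RF and SVM
  randomness is seeded.
* Initialization sanity is assessed on the untrained *predictor*
  (evaluation mode): with Xavier weights and no dropout inflation the
  logits are near zero and the cross-entropy on balanced data sits at
  ln 4. A training-mode forward at initialization reads higher
  (inverted dropout doubles the variance of the wide flatten→FC logits)
  and is a property of the training objective, not of the predictor.

## Known limitations

* Synthetic spectra are affine corruptions of smooth class means; real berry
  spectra have curvature/specular effects the generator omits, so absolute
  accuracies here do not transfer to real fruit.
* The original study's accuracy tables depend on its unreleased dataset and
  are out of scope; this package demonstrates the method's correctness and
  behavior on its own generator.
* The ResNet's desk-scale budget (30 epochs) is a surrogate for the
  full-scale schedule; rankings among models at this scale may differ from
  full-scale training.
* Random-forest overfitting in the high-dimensional small-n regime (perfect
  training accuracy with depressed validation accuracy) appears here only as
  a tendency; it is not asserted by the test suite.
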