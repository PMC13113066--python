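# Methods

`boarscan` is a tested pipeline for scanning-factor analysis of
image-based prediction of boar semen-production potential.  Because farm
records and testicular ultrasound images of this kind are proprietary, the
package pairs every analysis stage with a synthetic-data generator whose
defaults emulate a realistic stud, so the whole pipeline — labeling,
augmentation, subject-level cross-validation, decision aggregation and the
factorial GLM — can be exercised and validated end to end.

## Rule-based boar labeling

A collection is **good** when it meets all three industry criteria — total
sperm count ≥ 20×10⁹ (inclusive), motility > 70 % and morphology > 70 %
(both strict) — **bad** when it meets at most one, and **intermediate**
when it meets exactly two.  A technician **trash** flag overrides the
metrics.  A boar is **underperforming** when it has more than one
low-quality collection (bad or trash) *and* those make up at least 10 % of
its collections; the boundary fraction of exactly 0.10 triggers the label.
Intermediate collections count only in the denominator: the rule
classifies "only one or none" as bad and leaves two-of-three unnamed, so
those records are neither good nor low-quality here.  The rule is
verified against an exhaustive enumeration over all (n_low, n_total) pairs
with n_total ≤ 20.

## Synthetic data generator

The generator defines the conditions the rest of the package is tested
under.

**Population.**  107 boars by default with underperforming prevalence
25/107.  Collections per boar: round(N(30, 8)) clipped to [2, 49] (median
30); images per boar: round(N(12, 1.7)) clipped to [9, 17] (median 12),
split binomially between the two probe orientations with at least 3 per
orientation.  Collections start at 200 days of age with gaps uniform on
{5, …, 14} days.

**Semen metrics.**  The quality thresholds are industry standards; the
metric distributions are the generator's own declared choices: good
records draw from truncated
normals that satisfy all three criteria (count N(60×10⁹, 15×10⁹) truncated
at the threshold; motility and morphology N(85, 5) truncated above 70).
With per-record probability `bad_rate` (0.01 for high-quality boars, 0.30
for underperforming) a record instead fails two or three randomly chosen
criteria, drawn from truncated normals below the thresholds; `trash_rate`
(0.005 / 0.05) sets the trash flag independently.  Under these defaults
the labeling rule recovers the planted class for ≈ 98 % of boars; the
residual disagreement comes from underperforming boars that by chance
produce fewer than two low-quality collections.  The generator never emits
intermediate (exactly-two-criteria) records; the labeling code handles
them, but the planted-label checks do not exercise that path.

**Images.**  A deliberate B-mode caricature, not an acoustic simulation:
8-bit, default 96×96, background speckle from log-compressed exponential
intensity (`45·log1p(5·Exp(1))`, mean ≈ 67, SD ≈ 35).  The vertical
(longitudinal) view adds a bright band across rows 8–17 % of image height
with a half-sine envelope (simulated rete testis); the horizontal
(transverse) view adds a compact elongated Gaussian blob peaking at
(0.085 H, 0.15 W).  Both lie outside the central 50 % crop box.

**Planted class signal.**  The class signal is carried by brightness in
two places:

* the *parenchyma* (central 80 % box) mean intensity is offset per boar:
  high-quality boars +16 ± 1.5, underperforming 0 ± 1.5; and
* the bright structures carry a class gain (band +30, blob +26 on a base
  of 50).

A fixed fraction (15 %) of high-quality boars are "hidden" positives
whose parenchyma echogenicity is drawn from the underperforming
distribution; their quality is visible only in the bright structures.
This is what plants the region effect: a model restricted to cropped
images cannot distinguish hidden positives from underperforming boars
*in principle* (their cropped pixel distributions are identical), so the
class-weighted posterior at that cluster (≈ h/(1+h) ≈ 0.13 for hidden
fraction h = 0.15) falls below the 0.3 decision threshold and cropped
recall pins near 1 − h, while full images recover the hidden boars
through the band or blob.  The band is the stronger cue (the blob covers
a narrow row segment), which plants the vertical-angle recall advantage.
Because brightness carries the signal, brightness-randomizing
augmentation destroys it during training, pushing probabilities toward
the class prior; at the 0.3 threshold this converts to predict-positive
behavior — recall rises toward 1 while precision falls toward the
prevalence — reproducing the direction of the augmentation effect.

These magnitudes were chosen so that each mechanism is decisively inside
its intended regime (hidden positives rejected by cropped models across
fit realizations, recovered by full-image models) rather than on the
logistic decision boundary, where fold-to-fold fits flip erratically.
What passing tests show is that the *pipeline* recovers planted effects
of this kind; they say nothing about effect sizes in real ultrasound
data, whose texture, anatomy and noise are far richer than this
caricature.

## Augmentation

Morphological operators (perspective ≤ 0.2 corner displacement, rotation
±15°, horizontal/vertical flip, zoom-out ≤ 1.5×, random affine: scale
±10 %, shear ±8°, translate ±5 %) are kept strictly separable from
brightness operators (color jitter with brightness/contrast factors in
[0.6, 1.4], solarize at 128, autocontrast, posterize to 4 bits, classic
CDF histogram equalization, invert).  "Color jitter" on grayscale reduces
to brightness/contrast scaling.  In a pipeline each operator fires
independently with probability 0.5 (configurable); consecutive
interpolating geometric operators compose into one homography applied in
a single bilinear, edge-padded resampling pass, and flips compose into
the same homography exactly (they land on integer grid positions), so a
flip-only draw is a pure pixel permutation.  Augmentation applies at
training time only; evaluation images are never augmented.  Operator
magnitudes and probabilities are moderate defaults, all configurable.

## Classifier harness

Deep image classifiers are out of scope for a desk-scale package; in
their place sits a pluggable contract (train / per-image positive-class
probability) with a
two-tier logistic baseline: **small** uses the 11 histogram features
(mean, variance, nine deciles), **medium** uses all 14 features (adding
central-region mean, gradient energy on a 2× subsampled grid, and the
row-profile maximum that acts as a band detector) plus all 91 pairwise
products.  Features are standardized; the logistic fit uses L2 (C = 1),
class-weighted likelihood for the ≈ 77/23 imbalance, and Newton iterations
(deterministic, and insensitive to signal-free features where quasi-Newton
solvers crawl).  Deciles are estimated on a fixed 4× pixel subsample for
speed.  The capacity contrast (medium strictly wider than small) mirrors
the nano/medium tiers of production detector families.

Splits are **By-ID**: boars are shuffled once per run and chunked into
k = 5 folds; each fold's test chunk is held out, the next chunk serves as
validation, the remaining three train.  The validation chunk is unused by
the default fit and reserved for threshold/regularization exploration.  A
single-class training chunk (possible by chance in small populations)
widens into the validation chunk, and failing that the fold predicts the
training prevalence.

## Evaluation and the factor grid

Image probabilities are averaged per boar and compared against the fixed
threshold 0.3 (≥ decides high-quality; the boundary case is deliberate).
Precision, recall and F1 treat high-quality as the positive class, with
zero-denominator conventions set to 0.  Metrics are computed on the union
of the five test folds (each boar tested exactly once); per-fold averaging
is available as a config option.  The threshold is fixed globally rather
than tuned per run: a global constant keeps runs comparable across the
factor grid.

`run_grid` evaluates all 16 configurations across n runs with per-run
reseeded splits, augmentation and training.  Within one run, the two
capacity tiers of a (region, angle, augmentation) cell share splits and
the augmented batch, making the model factor a paired comparison on
identical data (and halving the augmentation cost).  The table is
resumable: rows already present in an `existing` frame are carried over.

## Factorial models and diagnostics

Responses are modeled as y = μ + R + A + B + M + ε (main effects) or with
all six pairwise interactions, under treatment coding with level 0 (full,
horizontal, morphological, medium) as reference, so the coefficient signs
read directly as the effect of switching to cropped / vertical /
comprehensive / small.  F-tests use marginal (Type II) sums of squares,
identical to the sequential decomposition on the balanced grid; balanced
fits are verified against a brute-force group-means SS oracle at 1e-8
relative tolerance.  All-equal responses are reported as F = 0 with zero
coefficients rather than 0/0.  Rank-deficient designs (empty cells) raise
an estimability error naming the missing cells.

Diagnostics: the Durbin–Watson statistic (first-order only; the
observations are not time-ordered) computed directly as
Σ(Δe)²/Σe², and two condition numbers — the unit-column-scaled
singular-value ratio of the design (exactly 1.0 for a balanced ±1-coded
main-effects design with intercept) and the statsmodels-convention value
of the fitted design (≈ 4.27 for the balanced 0/1 treatment-coded
main-effects grid), the latter comparable to published regression
summaries produced with that library.

## Problem sizes

The default test and acceptance problem size is 60 boars at 96×96 pixels
with 10 runs per configuration and up to 20 replicate grids — small enough
to run on a single CPU in minutes, large enough that every planted effect
is recovered with its sign and significance.  Larger populations only
tighten the statistics.

## Known limitations

* The image model is a textural caricature; no anatomy, attenuation,
  shadowing or probe physics.
* The baseline classifier is linear in hand-crafted features; it stands in
  for deep models only at the level of the train/predict
  contract and the capacity contrast.
* The generator plants monotone brightness effects; it cannot emulate
  interactions between anatomy and augmentation beyond the mechanisms
  described above, so two-way interaction F-tests on default data are
  dominated by the Region × Augmentation and Angle × Augmentation terms
  the mechanisms imply.
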