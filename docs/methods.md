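# Methods

## Measurement model

All three eyelid measurements are defined on the corneal light reflex and
the lid margins, read along the vertical (y) axis at the reflex x-column —
the photographic analogue of laying a ruler across the lid margin, reflex
and opposite margin:

* MRD1 = (reflex y − upper-margin y) · s, clamped at 0;
* MRD2 = (lower-margin y − reflex y) · s;
* LF = (down-gaze upper-margin y − up-gaze upper-margin y) · s,

with `s` the mm-per-pixel scale. `s` is calibrated from a 20×20-mm square
fiducial as 20 mm divided by the mean of its four side lengths in pixels.
Ground-truth and rater values are quantized to the clinical 0.25-mm grid
(round half away from zero — how a ruler is read); model predictions are
never quantized and never clamped, so a model remains free to learn negative
MRD1 for ptotic lids. In an eye whose reflex is occluded by a ptotic lid,
MRD1 is recorded as 0 by convention: the alternative (lifting the lid and
measuring a negative distance) is examiner-dependent and is excluded from
gold-standard use. Ptosis grades use half-open, lower-inclusive bins
(severe [0, 2), moderate [2, 3), mild [3, 4), none ≥ 4 mm); the clinical
ranges overlap at the integers, so a convention had to be fixed.

Where two raters measure the same eye, the gold standard is their arithmetic
mean, not re-quantized — quantizing the mean would discard the half-step
information that two independent 0.25-mm readings carry.

## Synthetic scene generator

`eyegen` renders the minimal periocular geometry the pipeline needs, with
analytically known landmarks:

* **Lid margins** are parabolic arcs through three control points: the apex
  at the reflex x-column and the two canthi, placed midway between the two
  apexes at ±14 mm. A parabola is the simplest smooth family with a
  well-defined apex where the measurement is taken.
* **The reflex** is a Gaussian bright blob (σ = 2 px) whose *analytic*
  center is stored in the annotation; the blob is masked by the palpebral
  fissure, so a lid at or below the center occludes it and the annotation
  carries no reflex (the ptotic case).
* **Gaze kinematics.** Relative to primary gaze, the globe (and reflex)
  shifts up by 0.15·LF in up-gaze and down by 0.70·LF in down-gaze; the
  upper lid sits at −(MRD1 + 0.30·LF) from the reflex in up-gaze and
  −(MRD1 + 0.15·LF) in down-gaze. The absolute lid travel between gazes is
  then exactly LF, while the two reflex-relative offsets visible inside
  reflex-centered crops differ by 0.15·LF — this is what makes LF learnable
  from the merged up/down patch, which discards absolute image coordinates.
  These fractions are a modeling choice (real excursion splits vary); any
  split that keeps the reflex visible in both gazes and leaves an
  LF-dependent within-crop signal would serve.
* **Population distributions** default to the clinical summary statistics:
  MRD1 ~ truncated normal 2.59 (SD 1.21) mm on [0, 6], MRD2 5.51 (0.83) on
  [1.5, 10], LF 12.1 (2.12) on [3.5, 18], with 3.4% of eyelids set ptotic
  (MRD1 = 0, no reflex). Ground truth goes into the manifest before any
  quantization.
* **Noise** is additive Gaussian pixel noise (σ = 4) plus a coarse random
  background texture; an optional dark "mascara" band under the upper lash
  line is available as a stress-test artifact.
* **Scale.** Default full-size renders are 512×512 at 0.2 mm/px, i.e. a
  ~102-mm orbital field. This was chosen so that the crop rule (square side
  = min(H, W)/4) yields a 25.6-mm patch whose half-side (12.8 mm) contains
  the entire supported MRD1/MRD2/LF-offset ranges; at finer scales the
  lower lid margin of a large-MRD2 eye would fall outside its own patch.
  Desk-scale experiments and tests use 256×256 at 0.4 mm/px — the same
  25.6-mm field at half resolution.

What the generator deliberately does **not** emulate: skin texture and
specular skin highlights, eyelashes and creases, brow position, flash
falloff, head pose, motion blur, and camera noise statistics. Tests passing
on these renders therefore demonstrate the pipeline's geometric and
statistical correctness, not clinical-photograph accuracy.

## Reflex localization

The **classical detector** thresholds the grayscale image at the 99.5th
intensity percentile (with an absolute floor of 235/255), labels connected
components, keeps those with area in [3, 0.2% of the image], picks the one
with the highest peak intensity and returns its intensity-weighted centroid;
confidence is the blob's isoperimetric compactness. On noise-free renders
with an unoccluded blob (lid clearance ≥ 3σ) its error is well under 1 px —
it sees the rendered Gaussian directly, so the weighted centroid is
essentially exact. When the margin sits within ~2σ of the reflex center the
blob is partially clipped and the centroid biases away from the lid; such
eyes are the ptotic/near-ptotic regime that the clinical protocol itself
scores as "no reflex".

The **trained localizer** is a small convolutional network (two conv+pool
stages, one refining conv, a 1×1 conv to a single response map) ending in a
spatial soft-argmax, trained with MSE on coordinates normalized by image
width/height. The soft-argmax head turns the network into a differentiable
matched filter and reaches ~2-px median error at 256-px resolution after ten
epochs on 600 images; a dense regression head needs several times the
training budget for worse accuracy.

## Normalization

The crop side "image size / 4" is read as `min(height, width) / 4` — the
only reading that produces a square on non-square smartphone frames (e.g.
4032×3024 → 756 px). Crops that would cross the border are shifted inward
rather than zero-padded, preserving real anatomy. The up/down merge is a
vertical stack (up above down); both crops are centered on their own reflex,
so the reflex x-columns align by construction. The merged 2:1 image is
squashed to 256×256 — one input size for every model, accepting the aspect
distortion. An eye missing a usable reflex in either gaze raises a
`MergeExclusion`, which the pipeline counts rather than silently drops.

## Regression training

One convolutional regressor per measurement, on grayscale patches
downsampled to `net_input_size` (default 64): conv channels (8, 16, 32)
with 2× max-pooling, dropout (default 0.3; valid range 0.25–0.5), a
64-unit dense layer and a linear output. Targets are standardized per fold.
Optimization is Adam on MSE, minibatch 32, with a one-cycle schedule whose
ramp-up and decay are both cosine. Augmentation: horizontal flip (p = 0.5)
and uniform rotation within ±15° with reflection padding — both transforms
approximately preserve the measured lengths, so labels are unchanged (a
15° rotation perturbs a vertical distance by at most 1 − cos 15° ≈ 3.4%,
which acts as mild label noise). Five-fold cross-validation produces five
models whose outputs are averaged; output averaging can only reduce MSE
relative to the average member (Jensen), which the tests assert.

Splitting defaults to the **subject** level so both eyes of one person stay
in a single partition (left/right eyes are strongly correlated and would
leak); `SplitPlan(unit="eye")` reproduces photograph-level randomization.
Partition sizes use floor arithmetic: 10% test, then 20% of the remainder
as validation — 822 units → 740/82, 685 → 617/68, 740 → 592/148.

All networks run on a small self-contained numpy engine (`lidmetrics.nn`):
im2col convolutions, max-pooling, dropout, Adam, the one-cycle schedule and
a seeded training loop. Everything is deterministic given the seed (weight
initialization, batch order, dropout masks, augmentation draws).

## Agreement statistics

ICC forms are two-way **single-measure**: absolute agreement
(MSR − MSE)/(MSR + MSE + (2/n)(MSC − MSE)) and consistency
(MSR − MSE)/(MSR + MSE), matching the standard R conventions (ICC(A,1) /
ICC(C,1)); the implementation is verified against a definitional
sums-of-squares oracle to 1e-10 and cross-checked against pingouin.
Bland-Altman reports bias, a **t-based** 95% CI (df = n − 1) and limits of
agreement at bias ± 1.96·SD. The t/1.96 pairing is not arbitrary: inverting
published bias CIs under t and applying 1.96 reproduces the corresponding
published limits of agreement to 2 dp for all three measurement models,
which a normal-quantile CI does not. (One published LF LoA appears in two
versions, −0.63 and −2.63 mm; the CI inversion confirms −2.63.)
`recover_sd_from_ci` packages that inversion. Undefined statistics
(zero-variance input) are guarded and reported as `None` rather than NaN.

## Problem sizes used in tests and the acceptance script

Synthetic experiments run at the desk scale described above: geometry
round-trip on 100 eyes; reflex benchmarks on 100 noise-free renders
(classical) and 600 train / 100 test renders (regressor, 10 epochs);
end-to-end MRD1 recovery on 350 subjects = 700 eyes (630 train/val, 70
test) with 12-epoch folds at 64-px network input. These sizes were chosen
as the smallest cohorts at which the recovery statistics are stable;
doubling them changes the reported MAE/r only in the third decimal.

## Known limitations

* The generator's clean geometry makes the regression task much easier than
  clinical photographs; reported synthetic MAEs (~0.1 mm) are an order of
  magnitude below what real data yields and should be read as a correctness
  ceiling, not expected performance.
* MRD2 is unmeasurable (and LF merge is impossible) when the reflex is
  occluded; the pipeline records exclusions instead of imputing.
* The backbone is a ~10^5-parameter CNN, not an architecture-searched
  SE-ResNet/EfficientNet ensemble; capacity is a config knob.
* Rotation augmentation slightly perturbs length labels (≤3.4% at ±15°).
* Bland-Altman here is the simple paired form; proportional-bias regression
  and repeated-measures limits of agreement are out of scope.
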