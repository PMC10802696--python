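# Methods

## The problem

Short-axis cine CMR yields dense frame-by-frame strain curves, but the
number of frames and the lengths of cardiac sub-phases differ between
patients, so individual strain values are not comparable across a cohort.
This package aligns strain temporally by five cardiac key frames — ED
(end-diastole), MS (mid-systole, peak contraction rate), ES (end-systole),
PF (peak early-diastolic filling) and MD (mid-diastole, diastasis onset) —
and derives two complementary measures on the 16-segment AHA model:

* **ED2K** (composed): Green-Lagrange strain of each key frame relative to
  end-diastole, the classical material description;
* **K2K** (sequential): strain of each key frame relative to its cyclic
  predecessor, which isolates sub-phase deformation (e.g. early-diastolic
  relaxation) from everything that came before.

Per patient this gives 2 components (Ecc, Err) x 2 schemes x 5 sub-phases
x 16 segments = 320 aligned strain values, which feed segment-wise group
statistics (Welch + Holm) and a patient-level fibrosis (LGE+/-)
classifier.

## Synthetic phantom

All quantitative guarantees are established on a synthetic phantom with
closed-form motion: a tapering annular myocardium (endo 13 mm, epi 22 mm
at the base, linear taper to 0.55 at the apex) around a bright blood pool,
with a crescent-shaped RV band attached to the epicardium that fixes the
AHA orientation. Grey levels are background 0, myocardium 80, RV 160,
blood 200 (arbitrary units) with soft one-voxel edges and optional
additive Gaussian noise (default SD 2). The default grid is 30 frames x 8
slices x 64 x 64 voxels at (8, 1.5, 1.5) mm, which keeps the full pipeline
within minutes on one CPU.

Motion is an in-plane radial scaling about the per-slice LV centre driven
by a one-cycle contraction profile `s(t)` (cosine descent to `1 - depth`
at 38% of the cycle, cosine recovery until 78%, then a diastolic plateau;
default depth 0.15, i.e. peak Ecc of `(0.85^2 - 1)/2 ~ -0.14`, a realistic
mid-wall magnitude), optionally plus a linear base-to-apex torsion.
Hypokinetic segments — the synthetic stand-in for fibrotic, LGE-positive
myocardium — attenuate the scale deviation: `s_h(t) = 1 + h (s(t) - 1)`
with `h` in (0, 1].

Two motion modes exist. In the default *affine* mode every material point
of a segment scales by `s_h(t)`, so the strain tensor is spatially
constant and `Err = Ecc = (s^2 - 1)/2` exactly — the oracle used by the
strain tests. The *thickening* mode scales the endocardium and deforms
the wall area-preservingly (`r_t = sqrt(r0^2 + (s^2-1) r_endo^2)`), which
produces the physiological sign pattern Ecc < 0, Err > 0 during systole.

What the phantom does **not** emulate: MR physics (k-space, banding,
breathing artifacts), papillary muscles, through-plane motion, arrhythmia,
or realistic myocardial texture. Passing tests therefore demonstrate the
correctness of the numerical chain (key-frame rules, warping, strain
algebra, AHA bookkeeping, statistics) under known motion, not performance
on clinical images. In particular the flat-intensity myocardium makes
registration easier radially (sharp edges) and harder circumferentially
(no texture) than real tissue.

Ground-truth key frames are obtained by applying the canonical detection
rules (below) to the analytic blood-pool volume curve of the contraction
profile, so truth and detector share one set of conventions and the
detection error isolates rendering/segmentation discretization. A
constant profile (static phantom) has no detectable cycle and receives
evenly spaced placeholder key frames.

## Key-frame detection

The driving signal is the cyclic frame-to-frame change of LV blood-pool
volume, normalized to peak magnitude 1; negative values indicate
contraction. Because a hard-label voxel count is quantized, the volume
trace is smoothed with a cyclic 3-frame moving average before
differencing (configurable). Rules, ties toward the lower index:

* MS = argmin (peak contraction rate), PF = argmax (peak filling rate);
* ES = first frame at/after MS where the curve becomes non-negative;
* ED = last non-negative frame before the contraction onset preceding MS;
* MD = first frame after PF with |curve| < 0.2 x peak (diastasis onset;
  the 0.2 threshold is configurable — the p-wave itself is not observable
  without ECG). The scan stops at ED so MD cannot overrun the cycle.

On a noise-free phantom grid (24/30 frames, depths 0.10–0.20, systole
fractions 0.32–0.40 at the default in-plane resolution) the mean cyclic
key-frame difference to ground truth is about 0.6 frames.

## Deformable registration

Nine dense in-plane displacement fields are estimated per subject: four
composed (each non-ED key frame registered to ED) and five sequential
(each key frame to its cyclic predecessor). Fields follow the pull
convention `warped(p) = moving(p + phi(p))`, so a field on the reference
grid is simultaneously the forward material displacement used by the
strain stage. The per-field objective is

    lambda_sim (1 - SSIM) + lambda_dice DiceLoss + lambda_reg mean ||grad phi||^2

with slice-wise SSIM (uniform 7x7 windows, stabilizers `(0.01 L)^2`,
`(0.03 L)^2`, `L` = dynamic range over both slices so the measure is
symmetric; the loss is `1 - SSIM`, bounded below by 0), a smoothed soft
Dice on the warped myocardium indicator (epsilon = 1), and a forward-
difference squared-gradient smoothness term. The standalone `smoothness`
function reports the raw sum over voxels; the trainer divides by the
number of field entries so `lambda_reg` is grid-size independent.

Minimization is coarse-to-fine (in-plane factors 4/2/1; 100/80/60
iterations) with Adam (step 0.25 voxels) directly on the field values;
gradients of all three terms are derived analytically, with image
gradients of the moving frame chained through the warp (validated against
finite differences in the test suite). The best-loss iterate per level is
kept, so the fitted fields never lose to their initialization. The
procedure is fully deterministic: there is no stochastic initialization
or minibatching.

Defaults: `lambda_k2ED = lambda_k2k = lambda_dice = 1`, `lambda_reg = 2`.
The strong smoothness weight reflects a real prior — the true cardiac
field varies slowly across the wall, and the homogeneous myocardium gives
the similarity terms no circumferential signal, so the regularizer is
what interpolates the radially well-constrained boundary motion across
the wall. At desk scale this yields myocardium Dice ~1.0 (vs ~0.80 for
the identity warp), a median composed-field endpoint error of ~0.2 voxels
against the analytic field, and a median full-cycle sequential
composition drift of ~0.9 voxels.

When masks exist at the key frames but no registration is wanted (or for
oracle experiments), `DisplacementFieldSet.from_analytic` supplies the
phantom's exact fields; the pipeline exposes this as `fields: analytic`.

## Strain computation

Strain is evaluated slice-wise in 2D — short-axis Err/Ecc are in-plane
quantities and slice spacing (8 mm) is coarse relative to in-plane
resolution — in the Lagrangian description at reference-frame voxels.
Displacements are converted to millimetres, differentiated with central
differences (one-sided at edges), and `E = 1/2 (F^T F - I)` is projected
onto radial/circumferential unit vectors: `Err = r^T E r`, `Ecc = c^T E c`.

The AHA map splits myocardium-bearing slices base-to-apex 35/35/30 into
basal/mid/apical regions (largest-remainder rounding, ties toward the
base), each with its own polar centre (the region's myocardial centroid).
The angular origin is the anterior RV insertion, estimated from the
boundary of the RV-myocardium adjacency span (fallback: the RV centroid
direction rotated by -60 degrees, which is exact for the phantom's
symmetric crescent). Basal/mid rings carry six 60-degree sectors
(numbering proceeding from the anterior segment toward the septum),
the apical ring four 90-degree sectors centred on the anterior direction;
segment 17 (apical cap) is excluded. Segment values are unweighted means
over myocardial voxels; an empty segment yields NaN and is imputed
downstream (imputer fitted on training folds only). ED2K uses the ED
AhaMap for all phases — its fifth entry is the full-cycle ED-ED composed
field (the sequential chain composed around the cycle); K2K rebuilds the
map at each phase's reference key frame.

Numerical properties verified: affine fields are recovered to machine
precision (the derivative of a linear field is exact); rigid rotation
produces zero strain; all Err/Ecc values are invariant under global
in-plane rotation of masks and fields (< 1e-3) and unchanged by torsion.

## Cohort statistics and classification

Group comparison: Welch's t-test (unpaired, unequal variances,
Satterthwaite degrees of freedom) per feature, Holm-Bonferroni adjusted
at alpha = 0.05, one family per component-scheme (all phase x segment
tests of e.g. Ecc/K2K). Degenerate tests report p = 1 with a flag.

Classification: stratified 4-fold cross-validated grid search over 2031
scikit-learn pipelines ({standardize, robust-scale, none} x {rbf/linear
SVM, logistic regression, ridge, k-NN, random forest, gradient boosting,
Gaussian NB, LDA} x hyperparameter lattices), selected by mean balanced
accuracy and refit on the full cohort; reported metrics are per-fold
mean +/- SD of balanced accuracy, F1, sensitivity and specificity.

The synthetic cohort used in tests mirrors the clinical setting at the
segmental-strain level (imaging and registration are validated separately
on the phantom, so cohort features are drawn from the closed-form strain
for speed): 60 patients, 55% LGE+, per-patient contraction depth
N(0.15, 0.02), hypokinesis h = 0.5 (SD 0.05) planted in the typical
inferolateral/anterolateral segments {5, 11, 12} (plus occasionally one
random extra segment), and additive measurement noise of 0.015 strain
units per feature — about the repeatability of segmental strain. Under
these conditions the planted segments are flagged by Welch-Holm in every
tested seed and the task-tailored 20-feature classifier reaches
validation balanced accuracy ~1.0; the planted effect (|dEcc| ~ 0.067 at
ES vs 0.015 noise) is deliberately strong, as the goal is end-to-end
correctness, not a power study.

## Design choices and limitations

* The registration "model" is an instance-wise variational fit rather
  than an amortized network: the estimator is authored here with analytic
  gradients, keeps the same loss, warp and output contract, and is exactly
  reproducible on one CPU. It does not learn across subjects.
* Summing the three loss equations counts the smoothness term twice per
  field (the anatomical term carries its own regularizer); `total_loss`
  implements that literal sum and reports a per-term breakdown.
* In-plane motion and strain only; longitudinal strain, strain rate and
  torsion quantification are out of scope.
* The phantom's hypokinetic sectors create displacement discontinuities at
  sector borders (adjacent segments scale differently); border voxels
  therefore carry interpolation error, which the segment means tolerate.
* Regional defects below the registration's resolving power are smoothed
  away on the phantom: a 60-degree sector with h = 0.5 differs from its
  neighbours by only ~0.7 voxels of edge displacement on a textureless
  wall, which the similarity terms barely constrain at any smoothness
  weight (weak regularization instead underestimates strain globally, as
  the uniform wall interior provides no signal). Real myocardium carries
  trabecular texture that intensity-based registration exploits; on the
  phantom, regional-defect experiments therefore use the analytic fields
  (`fields: analytic`), and the synthetic cohort is generated at the
  closed-form strain level.
* Slice order is assumed base-to-apex along the slice axis; real stacks
  with reversed order must be flipped on import.
* Visual image-quality grading of clinical series (breathing and motion
  artifacts) has no phantom counterpart; only Gaussian noise is modelled.
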