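# Methods

## Problem and model

The package classifies breast-lesion ROI patches from DCE-MRI into
luminal (hormone-receptor-positive) versus non-luminal (HER2-overexpressing
or triple-negative) molecular subtype. Radiologically, luminal masses tend
to be irregular with burr-like (spiculated) margins, while triple-negative
disease more often presents as a well-defined round mass with annular
enhancement; the classifier is designed to pick up exactly such
shape-and-enhancement cues from small (64×64) tumor patches in a setting
where lesion/background contrast is low.

CAMBNet is a compact multi-branch CNN (≈26k trainable parameters,
deliberately small for cohort sizes in the low hundreds):

* a 3×3 stem to 16 channels shared by three branches;
* **SFEpath**: 1×1 expansion to 128 → 3×3 depthwise → squeeze-and-excitation
  (SE) → 1×1 reduction to 16, plus a residual connection from the stem, to
  preserve shallow texture/shape information;
* **LTTpath1**: a 16→8→16 bottleneck with a 3×3 depthwise core;
* **LTTpath2**: 1×1 to 4 channels, then alternating 1×3 and 3×1
  convolutions through (4, 8, 8, 8, 16) — Inception-style asymmetric
  factorisation (864 kernel weights versus 2 592 for the same plan with
  3×3 kernels);
* **cross-attention** between the LTT branches: channel weights computed
  from LTTpath1 gate LTTpath2, spatial weights computed from LTTpath2 gate
  LTTpath1. Both sub-modules are single-path (average-pooled descriptors
  only, not the average+max dual path of CBAM). The opposite wiring and
  the dual-path descriptors exist behind config switches
  (`cross_wiring`, `attention_dual_path`) because the published
  description does not pin the wiring; the default is the simplest reading
  consistent with one attention type per direction.
* **fusion**: the gated LTT branches are added, then concatenated with the
  SFEpath output (LTT sum in channels 0–15, SFE in 16–31);
* **DFEM**: maxpool → 1×1 to 128 → stride-2 3×3 depthwise (no residual
  here) → SE → 1×1 to 64 → maxpool → global average pooling → dropout 0.5
  → linear 64→2.

Where the published per-stage table is ambiguous, the following readings
were adopted: the classifier input "8×8×64 / weight 64×2" is bridged by
global average pooling (the only shape-consistent reading); the 32→16
spatial reduction is realised by the stride-2 depthwise stage; both
maxpools are kernel 2, stride 2; the stem has stride 1. Batch
normalisation before ReLU follows every convolution (the source names
neither; this is the standard choice for the cited building blocks), so
convolutions carry no bias except the spatial-attention conv. SE blocks
use reduction ratio 16 with the bottleneck clamped to ≥ 4 units. Weights
are Kaiming-normal, biases zero, all seeded.

## Compute layer

The network, its training loop and Grad-CAM run on a small reverse-mode
automatic-differentiation engine over numpy arrays (`cambnet.nn`):
convolution (general and depthwise), max-pooling and batch normalisation
are fused primitives with hand-written backward passes (verified against
finite differences in the test suite); everything else is composed from
elementwise/reduction primitives. All arithmetic is float32. Gradients
are retained on every graph node, which is what Grad-CAM needs to read
the gradient of a logit with respect to an intermediate feature map.

## Preprocessing

From each physician-style contour mask: extreme positive pixels in the
four directions → axis-aligned minimum box → 10 px margin per side,
clipped at the image frame (clipping is the only well-defined choice
without a padding policy) → crop all channels → bilinear resize of the
rectangular crop directly to 64×64 (aspect ratio not preserved),
half-pixel-centre sampling with edge clamping — the convention is pinned
by a closed-form checkerboard test — → per-channel normalisation
(x − 0.5)/0.5 after scaling intensities to [0, 1]. The normalisation
constants are label-free and dataset-independent; they are configurable.
Box indices are 0-based and inclusive.

## Training recipe

RMSprop (α 0.99, ε 1e-8, no momentum), base learning rate 0.002 multiplied
by 0.95 every 10 epochs, batch size 8 for training and 1 for evaluation,
cross-entropy loss, L2 penalty 1e-4 (coefficient unspecified in the
source; a conventional value, in config), and a per-output-filter max-norm
clamp at 2.0 after every step (bound likewise unspecified; in config).
The documented default budget is 200 epochs; tests and the acceptance
script train 30 epochs on 200 phantom cases, which is where training has
long converged on this cohort.

Splitting is at patient level, class-stratified, with largest-remainder
rounding so the test set holds exactly round(0.2·n) patients. Because
checkpoint selection needs a validation set and selecting on the test set
would leak, 15% of the training patients are carved out for validation;
the best-on-validation weights are restored at the end. The training
entry point independently re-asserts train/val/test disjointness.
Five-fold cross-validation is provided as a patient-level, class-stratified
fold assignment (scikit-learn `StratifiedKFold` on one row per patient);
the published protocol is ambiguous about whether folds cover the full
cohort or only the held-out portion, so the assignment function takes
whatever id list the caller passes, and the fixed 80/20 split coexists
with it. Augmentation is the dihedral group: random 90° rotations and
main-diagonal transposition; class imbalance (84:76) is mild and is not
reweighted.

## Evaluation

Accuracy, precision, recall and F1 come from the standard confusion-count
formulas; zero denominators yield 0.0 with a warning. AUC is computed on
the positive-class (non-luminal = 1 by default) probability with the
midrank tie convention, so it equals the Mann–Whitney U statistic
normalised by n₁n₀ (the test suite checks this against a brute-force
pairwise oracle). Headline precision/recall/F1 are macro-averaged over
the two classes — the only convention under which recall can exceed
accuracy, as in the published headline numbers — with per-class values
retained in the report. For a binary problem the macro AUC equals the
positive-class AUC, so a single AUC is emitted. Metrics are stored as
fractions and rendered as percentages with two decimals.

Subgroup analyses stratify by age at menarche (≤14 vs >14 years) or tumor
size (≤20 vs >20 mm) and relabel the 4-way subtype under one of three
binary schemes (luminal vs non-luminal, TN vs rest, luminal A vs rest);
each stratum is then scored like any evaluation set. Empty strata are
reported as missing rows, never dropped.

## Synthetic phantom cohort

The generator stands in for a 160-case clinical cohort (84 luminal, 76
non-luminal) that cannot be redistributed. It emulates exactly the
structure the pipeline consumes, not MR physics:

* 256×256 canvas, three channels rendered as correlated views of one
  lesion with different contrast gains (0.9/0.7/1.2), standing for
  T1WI/T2WI/DCE phase 3;
* background: smoothed Gaussian noise around a 0.35 base level with scale
  0.06 — a tunable stand-in for low lesion/background contrast;
* luminal-like lesions: ellipse (eccentricity 0.12–0.3) perturbed by
  radial sinusoids (3 frequencies from 6–12, amplitude 0.35 of the local
  radius) — irregular, spiculated margins. With amplitude 0 the boundary
  is exactly a pure ellipse, which the tests exploit;
* non-luminal-like lesions: a smooth disc with a brighter annulus (outer
  30% of the radius, contrast 0.35) — annular enhancement;
* masks are the rendered lesion support, guaranteed 4-connected and fully
  inside the frame;
* tumor size = maximum mask diameter × 0.5 mm/px (the pixel spacing places
  the default radius range 12–30 px on both sides of the 20 mm threshold);
  age at menarche uniform on integers 11–17, populating both sides of the
  14-year threshold; 4-way sub-labels drawn with probabilities
  approximating the published cohort composition.

Cohort generation is a pure function of (spec, seed). A logistic
classifier on two hand-crafted mask features (isoperimetric roughness,
ring-intensity contrast) separates the default classes essentially
perfectly, so the phantom task is learnable by construction and training
tests are meaningful. Consequently, passing them shows the pipeline,
optimiser and architecture work end to end — it says nothing about
classification performance on clinical DCE-MRI, where class differences
are far subtler, 3-D, and confounded. The published clinical headline
numbers are therefore not targets of this package.

## Explainability

Grad-CAM defaults to the last DFEM convolution stage ("Conv4_5");
per-channel weights are the spatial means of the target-logit gradient,
the weighted activation sum is rectified, bilinearly upsampled to 64×64
and min-max normalised (an identically-zero map is returned as zeros
rather than dividing by zero). Feature grids show channel-mean (or
per-channel, configurable) images for the six stage groups: stem,
SFEpath, LTTpath1, LTTpath2, fused, DFEM. The localisation score — the
fraction of total saliency inside the contour mask carried through the
same crop/resize — has a closed-form uniform baseline (mask area
fraction), which the trained model must beat on average.

## Numerical and degenerate-input choices

* Bilinear resize: half-pixel centres, edge clamping; constants are
  preserved exactly and identity-size crops are returned bit-identical.
* Empty contour masks raise a named error (mirroring the exclusion of
  cases with no visible ROI); degenerate boxes are rejected.
* Checkpoint ties on validation accuracy keep the earliest best epoch.
* Max-norm clamping only rescales filters whose norm exceeds the bound.
* Batch-norm running variance uses the unbiased correction; eval mode is
  a pure affine transform, so inference is batch-size invariant.

## Problem sizes

Defaults in tests and the acceptance script: 200-case cohorts for
learnability/explainability (160/40 split before validation carving), 30
training epochs, 50 held-out phantoms for Grad-CAM, 1 000 random
confusion tables and 100 tied score vectors for metric oracles, 200
random cohort compositions for split integrity. These sizes are the
package's own choice of a convergent yet quick demonstration; the
full-scale defaults (160 cases, 200 epochs) remain available in config.

## Known limitations

* Phantoms are 2-D, star-shaped, single-lesion, and noise-correlated in a
  simplistic way; no pharmacokinetics, no acquisition artefacts, no
  inter-observer contour variability.
* The cross-attention wiring is one defensible reading of an ambiguous
  description; both wirings are implemented, only one can be default.
* The numpy compute layer is single-device and unbatched across workers;
  it is sized for this architecture, not a general deep-learning stack.
* Four-way subtype classification is plumbed (n_classes, label schemes)
  but the default task is binary, like the source protocol.
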