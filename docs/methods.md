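# Methods

## Pipeline model and assumptions

`dermtex` treats lesion classification as a bag-of-windows problem: the
class signal of a pigmented lesion is assumed to live in the local texture
and color statistics of small windows, not in global shape or border
morphology.  Windows ("keypoints") are 6×6 px and are drawn uniformly at
random inside a caller-supplied region of interest (full image by
default), with replacement; their feature content is therefore invariant
to where the lesion sits in the frame.  A patch inherits the label of its
source image — a weak-labeling assumption that is wrong for windows
falling on healthy skin, which is one reason patch-level accuracy
underestimates image-level accuracy (the package also reports an
image-level majority-vote matrix, with ties broken toward melanoma so a
coin flip never hides a positive).

"Keypoint" here means a randomly positioned window.  No saliency detector
is used: the sampling scheme is the simplest position-independent one, and
a detector could be slotted in by supplying an ROI.

## Features

First-order moments are computed on the *unquantized* grayscale in [0, 1]
(8-bit values divided by 255; RGB→gray with BT.601 luma weights 0.299,
0.587, 0.114, configurable).  Moments use the population (divide-by-n)
convention and kurtosis is excess kurtosis.  Degenerate policy: a
numerically constant sample (spread below 10⁻¹² relative) reports
variance 0 and skewness = kurtosis = 0, so flat windows flow through the
pipeline instead of erroring.

Co-occurrence matrices are built on the grayscale quantized to L = 8
levels via `level = min(⌊v·L⌋, L−1)`.  Eight levels on a 6×6 window is a
deliberate compromise: the window holds only 30 horizontal pairs, so a
256-level matrix would be almost surely diagonal-free and every descriptor
degenerate.  Displacements follow the pixel-lattice convention with y
down: 0°→(+d,0), 45°→(+d,−d), 90°→(0,−d), 135°→(−d,−d); diagonal
distances are d *lattice steps* (not rounded Euclidean displacements —
scikit-image differs here for d ≥ 2, and its angle sign convention is
mirrored; the test suite encodes the mapping).  Counting is symmetric by
default (each pair tallied in both orders), which equalizes the marginals
and keeps the correlation well-behaved.  Entropy is log₂ with 0·log 0 = 0.
Degenerate correlation (σxσy = 0, i.e. a constant window) is defined as
+1: the neighbor level is perfectly predictable.  Per-window descriptors
are the arithmetic mean over all (d,θ) combinations that admit at least
one pair — combinations that do not (possible on sub-window inputs) are
skipped and logged, and an input where every combination is empty raises.
Averaging (rather than concatenating 20×4 values) was chosen because the
feature set is described as one value per descriptor; per-combination
values remain available for inspection.

The 28-feature vector is: 6 grayscale first-order + 4 aggregated Haralick
+ 6 first-order per RGB channel.  Per-channel co-occurrence features exist
behind a flag but are off by default.

## Classifier zoo

Twelve scikit-learn estimators with library-default hyperparameters and
fixed derived seeds: SGD, Gaussian/Bernoulli/multinomial naive Bayes,
decision tree, extra trees, random forest, gradient boosting, k-NN, linear
SVC, RBF SVC, logistic regression.  Margin- and distance-based learners
(SGD, both SVMs, logistic regression, k-NN, Bernoulli NB) receive z-scored
features with the scaler fitted on the training side only; multinomial NB
requires nonnegative inputs and receives min-max [0,1] scaling instead;
tree ensembles and Gaussian NB see raw features.  Standardization is a
deviation from a bare description of the method — without it the margin
learners are crippled by the heterogeneous feature scales (variance
~10⁻³ next to contrast ~10¹).

Splitting is at image level, stratified by class: train-image counts are
allocated by largest remainder so the global train fraction is exact and
each class is within one image of its quota, with at least one image per
class on each side.  Ranking uses AUC from continuous scores (melanoma
class probability where available, oriented decision margin otherwise).

## Synthetic data: what it emulates, and what it does not

Each image is a correlated Gaussian random field: white noise smoothed by
a Gaussian kernel of scale `corr_length` (pixels), standardized, passed
through a monotone sinh-arcsinh transform calibrated (by Gauss–Hermite
quadrature and least squares, cached per target pair) to the class target
skewness and excess kurtosis, rescaled to the target mean/SD, clipped to
[0, 1] (clip fraction logged; clipping attenuates the attained tail
moments), then multiplied per channel by a color cast and quantized to
8 bits.  Casts are luma-normalized at generation time so only color
*balance* changes, never the grayscale moments.

Class defaults (grayscale mean/SD, skewness, kurtosis) follow the
class-conditional patch statistics reported for nevus vs melanoma tissue:
mean 0.4514 vs 0.4204, SD 0.1434 vs 0.1543, skewness 0.1935 vs 0.2479,
excess kurtosis 3.0953 vs 3.6476.  Marginal moments alone barely separate
the classes, so the discriminative signal is carried by two invented,
field-plausible differences: spatial correlation length 4 px (nevus,
smoother) vs 1 px (melanoma, rougher) and a mild opposing color cast
(nevus red-shifted 1.03/1.00/0.97, melanoma 0.97/1.00/1.03).

Between-image heterogeneity is essential.  With class-constant parameters
every image of a class is statistically identical; the two classes then
form two near-point clusters in feature space, all twelve models reach
AUC 1.0, and a permutation null is violently unstable because the chance
correlation between shuffled labels and the true class (≈ n_images^(−1/2))
is amplified by the enormous separation.  Each image therefore draws its
own effective parameters: mean intensity jittered N(0, 0.06), correlation
length jittered log-normally (σ = 0.6 in log space), casts jittered
N(0, 0.045) per channel.  These spreads were fixed once so that the
default study lands where such patch-texture studies realistically land —
top model AUC ≈ 0.95–0.98 with heavily overlapping marginals and a mean
intensity difference that is statistically detectable but useless on its
own.

The generator does **not** emulate lesion morphology (borders, asymmetry,
hair, vignetting), JPEG artifacts (PNG output is lossless so regeneration
is byte-exact; the image reader accepts JPEG for real data), within-image
nonstationarity (lesion vs surrounding skin), or any correlation between
color and texture beyond what the shared gray field induces.  A green
test suite therefore demonstrates that the pipeline is correct and
leak-free and that it recovers engineered statistical structure — not
that these 28 features reach any particular accuracy on real dermoscopy
archives.

## Randomness and determinism

Every stage derives sub-seeds from a single master seed via SHA-256 over
content keys (image id, stage name), truncated to 31 bits.  Keying by
content rather than position makes extraction invariant to manifest row
order and dataset relocation (image ids are file stems, not paths).  A
fixed config reproduces every artifact byte-for-byte.

## Audits

*Split disjointness*: train/test image-id sets are verified disjoint
across 100 split seeds.

*Permutation null*: image labels are permuted across the **whole**
dataset, the split/train/evaluate pipeline is rerun, and each model's AUC
is averaged over 4 permutation replicates (the same design as
scikit-learn's `permutation_test_score`).  Permuting only the training
side while scoring against the true test labels is not a usable null
here: the chance correlation between permuted train labels and the true
class is recovered by mean-difference learners and amplified by the very
separation the study is designed to have, pushing single-replicate null
AUCs far from 0.5 regardless of leakage.  Whole-dataset permutation
removes the feature–label association entirely; the audit requires every
model's null AUC within 0.5 ± 0.05.

## Problem sizes

The default study uses 200 images per class at 96×96 px with 10 patches
per image (4,000 patches; ~12 s end-to-end on one CPU).  Parameter
recovery uses 100 images per class (1,000 patches per class); the
permutation audit uses 250 per class (5,000 patches) with 4 replicates.
Oracle-equivalence checks run exhaustively over window shapes up to 8×8
at L ≤ 4 for co-occurrence counting, 1,000 random windows for first-order
moments, and 100 random score vectors for the AUC–rank-sum identity.

## Known limitations

- The evaluation's reference worked example uses a published 500-image
  confusion matrix as fixed input; the package reproduces its derived
  metrics, not the underlying image-level experiment, whose exact image
  selection is not identifiable.
- The specificity printed in some descriptions of this metric family as
  TN/(TP+FP) is dimensionally inconsistent with its own definition; the
  package implements the standard TN/(TN+FP).
- Metrics with zero denominators are reported as NaN ("undefined"), never
  silently as 0.
- Exact Mann–Whitney enumeration is used only for n₁·n₂ ≤ 200 without
  ties; otherwise the normal approximation with tie correction applies.
- `min(⌊v·L⌋, L−1)` assigns v = 1.0 to the top bin; quantization is
  monotone but not equal-mass.
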