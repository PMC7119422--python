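# Methods

This note documents the models, parameter choices and numerical
conventions behind `spheropol`, and what the synthetic benchmark does and
does not establish about real microscopy data.

## The classification problem

A spheroid is a monolayered, usually hollow ball of epithelial cells grown
in 3D culture, imaged in four fluorescence channels: a basolateral
membrane marker (gp58), an apical membrane marker (gp135/podocalyxin),
filamentous actin, and nuclei. The phenotype classes are

| group | phenotype | equatorial signature |
|---|---|---|
| 1 (regular) | single central lumen, apical side inward | apical + actin ring at the lumen boundary, basolateral ring outside, nuclei ring between |
| 2 (inverse) | apical side outward, matrix-filled interior | apical + actin ring on the periphery, basolateral signal filling the interior |
| 3a (aggregate) | no lumen, undefined polarity | incoherent markers, nuclei occupy the centre |
| 3b (multilumen) | several small lumina | several small apical/actin rings at interior positions |

The coarse 3-group labelling collapses 3a/3b; the CNN branch keeps them
separate during training because heterogeneous classes train poorly, and
collapses them only for scoring.

Polarity is radially symmetric at the spheroid's equator, so all feature
extraction happens on a 2D projection of the central z-slices. Per-cell 3D
segmentation is deliberately out of scope.

## Equatorial plane and segmentation

The central plane z\* maximises the spheroid cross-sectional area (summed
channels, global Otsu threshold); the projection is a per-channel maximum
intensity projection over `n_slices` planes centred on z\* (default 5,
≈1.2 µm at a 0.24 µm z-step — enough to bridge the slice-to-slice
speckle of membrane stains without flattening the 3D structure).

Segmentation conventions, fixed because counts and circularities depend on
them:

- background: per-channel subtraction of the 5th-percentile intensity,
  floored at 0 (robust, deterministic, needs no empty-field image);
- channels are normalised by their maximum before thresholding, making
  every downstream quantity invariant to per-channel gain;
- spheroid mask: Otsu threshold on the summed normalised channels, largest
  connected component, interior holes filled (the lumen is dark but
  belongs to the spheroid);
- centre of mass: intensity-weighted centroid of the summed image inside
  the mask, kept at sub-pixel precision;
- actin belt: actin pixels above the 90th intensity percentile inside the
  mask ("most intense actin signals"); particles are connected components
  of at least 10 px. A quantile rule is scale-invariant where a fixed
  threshold would not be;
- nuclei: Otsu threshold on the nuclear channel, binary opening, then a
  distance-transform watershed seeded at local maxima (minimum peak
  distance 5 px); objects under 20 px are discarded. The nuclei
  "circularity" descriptor is computed on the convex hull of the union, so
  a closed ring of nuclei scores high and a lopsided cluster low;
- circularity: 4πA/P² clipped to [0, 1], with the contour-walk perimeter
  estimator (`skimage.measure.perimeter`). The choice matters: Crofton-type
  estimators bias blocky shapes (an axis-aligned square scores ≈0.88
  instead of the analytic π/4 ≈ 0.785), while the contour-walk estimator
  stays within 0.03 of the analytic value for squares and within
  [0.93, 1.0] for rasterised discs.

## Radial features

The polar transformation assigns each pixel the integer radius bin
`round(√((x−X_CoM)² + (y−Y_CoM)²))`, rounding half away from zero — the
convention is stated because banker's rounding changes bin membership on
exact .5 distances. Bins with no pixels (possible at r = 0 for a
fractional centre) contribute mean 0. Per-radius means are normalised by
their total and accumulated; the cumulative curve is a CDF of
circumference-corrected signal over radius.

The 60% position is read off by linear interpolation between the two
bracketing radius bins rather than as a step readout: the position is used
as the approximate centre of the rising slope of the curve, which a step
function misrepresents. For a signal concentrated on a single ring the
interpolated readout is within one bin (1/r_max) of the ring radius. The
nuclear initial slope is the chord slope cumulative(0.3·r_max)/0.3, with
the cumulative value at the fractional cutoff radius interpolated
linearly; 0 means an empty lumen zone, 1 matches a radially uniform
nuclear distribution, and values well above 1 flag central nuclei.

The full vector is f1/f2 (marker deltas), f3–f6 (per-channel 60%
positions), f7/f8 (spheroid and nuclei circularity), f9 (nuclear initial
slope), f10–f12 (actin relative area, particle count, circularity), f13
(nuclei count), f14 (nuclei-to-spheroid centroid distance over r_max), f15
(maximum radius in µm). Only seven of the fifteen slots have canonical
names; the remainder are reconstructions from the named part-1/part-2
quantities, chosen so that the training subset "features 1, 2 and 6–15"
is well defined. They should not be presented as an authoritative
original list.

## Decision-tree branch

Trees are CART with Gini impurity, minimum leaf size 3 and no depth cap
(a "complex" tree); cross-validation is stratified 20-fold with a fixed
shuffle seed, and the reported `cv_accuracy` is the mean held-out accuracy
over folds. The default training subset drops f3–f5 (they are linear
ingredients of f1/f2). An optional grid over minimum leaf size {1, 3, 5}
selected by the same CV stands in for a hyperparameter-optimisation tool;
it is off by default.

Reclassification: a second tree trained only on group-1/group-3 samples
over the lumen/nuclei descriptors (f8, f9, f13, f14) re-examines every
record the primary tree called 1 or 3; group-2 records pass through
untouched. Whether the original procedure used a rule or a trained tree is
unspecified; a trained tree is implemented. The bagged ensemble trains
`n_trees` (default 30) trees on seeded bootstrap resamples, reports
out-of-bag accuracy, and votes by majority with ties broken toward the
lower group number (the conservative call under the dominant group-1
prior); the tie-break is configurable in principle by reordering labels.
Serialized models are self-describing JSON (node arrays, subset, seed);
prediction from a loaded model is an in-package traversal of those arrays,
tested against scikit-learn's own predictions.

## CNN branch

Transfer learning of large pretrained backbones (Inception-class networks
at 299×299 input) is out of desk scope; the branch instead trains a
compact three-stage convnet — 3×3 convolutions with 8/16/32 channels, each
followed by ReLU and 2×2 max-pooling, then a 64-unit dense layer and a
softmax head (~40k parameters at 32×32 input) — implemented in numpy with
im2col convolutions and full backpropagation. The default configuration
trains all layers from scratch; `fine_tune="head"` freezes the
convolutional stages and retrains only the dense head, the
transfer-learning mode for reusing a previously trained backbone. The
training schedule is fixed at SGDM (momentum 0.9), learning rate 3×10⁻³,
batch size 80 (auto-reduced for smaller datasets), 15 epochs, with a
seeded stratified 20% internal hold-out recorded per epoch. Everything is
plain seeded numpy, so training is bit-reproducible on any machine.

Augmentation balances each fine label to a target count (default 600) by
rotating (uniform 45–315°) and scaling (uniform 0.4–1.2) randomly chosen
originals about the image centre with bilinear resampling; originals are
always retained, and a class already at or above the target is subsampled
without replacement. Input images are min-max scaled per channel to 8-bit
at conversion time (the RGB mapping is basolateral → green, nuclei → blue,
apical marker or actin → red) and resized bilinearly to the network input;
the default input is 96×96, and scaled-down runs use 32×32, which is ample
for ring-versus-disc geometry.

## Agreement statistics

Percent agreement is the diagonal share of the cross-correlation table,
reported to one decimal (half-away-from-zero). Cohen's κ uses
p_e = Σᵢ p_i·p_·i; the standard error is the Fleiss–Cohen–Everitt
large-sample variance (the estimator behind standard statistical
packages), since the original source for the coefficient does not pin one
down; the test suite verifies κ against a brute-force recomputation from
expanded rating lists and κ/SE against statsmodels. The confidence
interval is the normal approximation κ ± z₁₋α/₂·SE clipped to [−1, 1]. κ
for a degenerate single-category table (p_e = 1) is an error, not a
number. Multi-rater workflows are supported as pairwise tables plus a
strict-majority consensus resolver that flags unresolved items for human
discussion; chance-corrected multi-rater coefficients (Fleiss κ,
Krippendorff α) are out of scope.

## Synthetic generator

The generator draws, per spheroid: radius uniform in 40–80 px (256 px
frame), group-1 lumen radius 0.3–0.5 of the radius, 12–24 nuclei (matching
spheroids of 12–24 cells), 2–4 lumina for group 3b, and a ±2 px centre
jitter. Markers are Gaussian annuli (membrane width 3 px, actin 2.5 px),
nuclei are Gaussian blobs (σ 3 px) on a ring (groups 1/2) or scattered
with a centre-heavy radial law (group 3a — uniform in radius rather than
area, so aggregates genuinely occupy the lumen zone). Group-3a markers are
low-contrast random blob mixtures, which concentrates the Δ features near
zero, mimicking undefined polarity. The axial profile is a spherical cap
(intensity modulation only; no 3D PSF, since analysis is equatorial);
degradation is an isotropic Gaussian PSF (σ 2 px), constant background
(10), Poisson shot noise (gain 1) and Gaussian read noise (σ 5) on a
signal amplitude of 150 — a standard fluorescence-camera model.

Scaled geometry for simulation studies (`SCALED_PARAMS`: 96 px frames,
5 z-planes, radii 16–30 px, widths scaled proportionally) keeps test and
benchmark runs to minutes on one CPU; the experiments in the test suite
and acceptance script use it, with single-plane stacks where only the
equatorial image matters.

What passing on synthetic data shows — and does not. The generator
reproduces the *geometric* content the classifiers rely on (marker
ordering along the radius, lumen occupancy, belt fragmentation) under a
realistic noise model, so it exercises every computational step end to
end and detects regressions in any of them. It does not model cell
texture, membrane curvature, anisotropic PSFs, out-of-focus haze,
touching spheroids or staining variability; accuracies on synthetic data
are therefore upper bounds and do not transfer to any particular
microscope dataset. Classifier reuse across imaging batches degrades with
batch effects, which is why fresh training and continuous validation
against manual ratings (the agreement module) are part of the intended
workflow.

## Numerical conventions and degenerate inputs

- Coordinates are 0-based pixel indices; centroids are (x, y) sub-pixel.
- All-zero channels yield degenerate flat profiles with a warning; their
  60% position is defined as 0 so feature vectors never contain NaN.
- An empty actin belt yields zero counts/areas with a warning; an empty
  spheroid or nuclei mask is an error ("no spheroid/nuclei detected").
- Gain invariance is exact in floating point for power-of-two factors
  (tests use those) and mathematical for all positive factors.
- Every stochastic step (generator, CV shuffles, bootstrap, augmentation,
  weight init, batch order) is driven by an explicit integer seed.

## Known limitations

- Feature slots 3–7, 12, 13, 15 are reconstructions (see above).
- The nuclei count under-resolves touching nuclei at small scales; it is
  treated as a noisy descriptor, not a cell count.
- The CNN branch does not ship pretrained weights; "transfer" mode is
  only useful with a backbone trained in-session or supplied by the user.
- Proprietary microscope formats (CZI/ND2) are not read; convert to TIFF.
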