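# Methods

## Scope and data model

The package operates on macular OCT cubes stored as ITK MetaImage. The
reference geometry is a 6 × 6 × 2 mm³ cube sampled as 128 b-scans of
885 (axial) × 512 (lateral) pixels, i.e. voxel spacings of 46.875 μm
(inter-slice), 2.2599 μm (axial) and 11.71875 μm (lateral). Index order
is fixed as (b, z, x) with z increasing from the inner retina downward;
indices are 0-based and a voxel's physical coordinate is its centre,
(index + 0.5) × spacing. Intensities are mapped to [0, 1] in memory by
dividing the stored integer by its type maximum; the bit depth and
calibration of exported scans are vendor-specific, so this normalisation
is a package convention chosen to make network input deterministic.
Label masks use 0 = background, 1 = hard exudate, 2 = small HRD.

## Segmentation network

The segmenter is a 2D encoder–decoder applied per b-scan. Because the
targets are only a few pixels across, the depth is three pooling steps
rather than the classic four: a fourth halving would reduce a 20–40 μm
lesion to sub-pixel scale at the bottleneck while adding parameters.
Each encoder stage is a multi-scale convolution module (MSCM): three
parallel 3×3 convolutions at dilation rates 1, 2 and 3 (each
conv + batch-norm + ReLU), concatenated and fused by a 1×1 convolution
back to the stage width. The parallel dilations give the stage receptive
fields of three sizes at once without extra depth. The two deepest
encoder stages append a channel attention module (CAM): global average
pooling to a per-channel descriptor, a fully connected bottleneck
(reduction 4) with ReLU, a second fully connected layer with sigmoid,
and multiplication of each channel by its gate in (0, 1). Attention is
placed only at the bottom two stages because channel semantics are
richest there. The decoder mirrors the encoder with nearest-neighbour
upsampling, a 3×3 convolution, skip concatenation and two further 3×3
convolutions per level; a 1×1 head emits two class scores per pixel.
Inputs must be divisible by 8; inference pads with edge replication and
crops the output back.

Choices the architecture description leaves open, fixed here: MSCM
fusion by concatenation + 1×1 convolution; CAM bottleneck ratio 4; base
width 16 channels (tiny preset 8 for CPU-scale work); batch
normalisation after every convolution. At equal base width the network
has strictly fewer parameters than a 4-level double-conv U-Net
(`BaselineUNet` exists to make that comparison concrete).

The loss is the sum of pixel-wise cross-entropy and soft Dice of the
foreground channel. Dice dominates gradient flow when foreground is a
few hundred pixels in a 65k-pixel b-scan; cross-entropy stabilises early
training. Optimisation is SGD with learning rate 0.01, momentum 0.9,
weight decay 1e-4, batch size 2, 60 epochs, no schedule. Online
augmentation draws 2–4 distinct operations per sample from {left-right
flip, up-down flip, rotation, additive Gaussian noise}; rotation is
uniform in ±15° with nearest-neighbour mask interpolation (labels stay
integral), noise σ is uniform in [0.01, 0.05] of the intensity range and
touches the image only. Cross-validation splits volume ids into four
near-equal folds after seeded shuffling; each fold is held out once and
the harness reports per-fold and mean ± SD foreground Dice.

Everything runs on a small reverse-mode autodiff engine written on
NumPy (`hrdquant.nn`): dilated convolution by shift-and-tensordot,
batch norm with the standard closed-form backward, 2×2 max pooling,
nearest upsampling, channel concatenation and gating, fused
softmax/cross-entropy. Float32 by default; the test suite switches the
engine to float64 and verifies every parameter gradient of the full
network against central finite differences. Training at desk scale
(8 patches of 128², tiny preset, 60 epochs) takes on the order of two
minutes on one CPU.

A deterministic reference segmenter (`threshold_segment`: intensity
above a threshold inside a fractional axial band) provides a
network-free path through the rest of the pipeline, which keeps the
classification and quantification stages testable in isolation.

## Shadow detection

Hard exudates scatter strongly enough to attenuate the signal beneath
them down to the RPE. The default detector is deterministic: estimate
the RPE depth per column (brightest axially smoothed pixel in the lower
image half, median-filtered laterally over 15 px; flat images fall back
to 0.85 of depth with a flag), then compare the mean intensity of the
band directly beneath the component — from the component bottom to the
lateral-median RPE depth — with the mean of two flanking bands at the
same depths, offset by twice the component width on each side. Pixels
belonging to other components are excluded from the bands. The
component is shadowed iff below/flank < τ. The lateral-median depth
limit (rather than the per-column estimate beneath the component) is
deliberate: directly beneath a bright lesion the column-wise estimator
locks onto the lesion, not the RPE.

τ defaults to 0.75, midway between the rendered-shadow ratio (~0.4) and
the speckle-only ratio (~1). It has no reference value from patient
data; the decision is monotone in τ by construction. Components closer
than 10 px to the RPE return "window-too-short" and shadow = False —
they cannot be tested. A learned per-pixel shadow-probability provider
can be plugged into `classify_all` in place of the ratio test.

## Classification and measurement

Connected domains are extracted per b-scan with 8-connectivity (the
conventional choice for bright blobs; an independent flood-fill oracle
in the tests pins the semantics). Components are never merged across
b-scans: the inter-slice gap (≈47 μm) exceeds the small-HRD scale and
annotation is per b-scan. Size is the physical Feret diameter: the
maximum pairwise distance between pixel centres after scaling axes by
their spacings, plus one in-plane pixel diagonal (≈11.9 μm at reference
spacing) so a single bright pixel has a physically meaningful size. The
rule set is: diameter < 20 μm → noise, excluded; diameter > 40 μm with
shadow → hard exudate; otherwise small HRD. Both thresholds are strict,
so exactly 20 or 40 μm lands in the small-HRD band, and a large
component without a shadow is a small HRD, not an exudate. Noise is
decided before shadow testing (the order cannot change the outcome, it
only saves work). Whether size should be lateral, axial or longest-axis
is not fixed by any operating definition; the Feret choice is recorded
here because the pixel-diagonal term shifts the effective noise cutoff
by about one lateral pixel.

## Quantification

Per volume, counts and areas are accumulated per class for three
regions: the full scan and the 3 mm and 1 mm diameter fovea-centred
circles. The fovea defaults to the geometric scan centre (scans are
acquired fovea-centred) with an explicit override for decentred scans.
A component belongs entirely to every region containing its en-face
centroid — (b + 0.5) × inter-slice spacing, mean lateral pixel centre ×
lateral spacing — with no splitting at circle boundaries, keeping count
and area semantics consistent. Area is the cross-sectional pixel count ×
axial × lateral pixel area (≈26.48 μm² at reference spacing) summed over
b-scans, reported in mm². By construction total = hard exudate + small
HRD exactly, and region values nest (1 mm ⊆ 3 mm ⊆ full).

## Agreement statistics

Dice is computed per volume and class as 2|A∩B|/(|A|+|B|); a doubly
empty comparison is defined as 1.0 (vacuous agreement on lesion-free
scans) and reported as mean (SD) across volumes. The ICC is the
two-way random-effects, absolute-agreement, single-measures form
ICC(2,1) = (MS_R − MS_E)/(MS_R + (k−1)MS_E + k(MS_C − MS_E)/n),
with an F-based 95% CI using Satterthwaite degrees of freedom; absolute
agreement is the appropriate form when two methods' raw values are
interchanged in practice, and the consistency form ICC(3,1) is available
by flag. Pearson r carries a two-sided t-test p with n−2 df. Bland–
Altman limits are mean ± 1.96 × SD of the paired differences (n−1
denominator, normal quantile rather than t, the conventional form). Zero
total variance makes ICC and r undefined; they are reported as NaN, not
coerced to 1. No multiple-testing correction is applied. All four
estimators are checked in the tests against independently coded
brute-force implementations (exact rational arithmetic for Dice,
from-scratch two-way ANOVA for ICC) and, for ICC, cross-checked against
pingouin.

## Synthetic phantoms

The generator emulates exactly the features the pipeline keys on: a
bright NFL-like band (reflectivity 0.55) near the top, a darker
mid-retina (0.22), a bright RPE-like band (0.85) near the bottom,
vitreous and choroid fill, multiplicative gamma speckle with mean 1
(variance 0.03 by default), and elliptical lesions on single b-scans.
Hard exudates render at RPE-like reflectivity with the column beneath
them multiplied by 0.4 down through the RPE band; small HRDs render at
NFL-like reflectivity with no shadow; sub-threshold noise dots render in
the intensity image only. Default requested-diameter ranges are
45–150 μm (hard exudates), 20–40 μm (small HRDs) and 8–18 μm (noise
dots), with 4/6/5 lesions per volume on a (4, 256, 256) desk-scale grid
by default.

Lesion size is controlled in the same convention the classifier
measures: the ellipse's axial pixel run is ceiled so that the rendered
component's Feret diameter (centre extent + one pixel diagonal) lands at
or just above the requested diameter. This keeps every rendered lesion
on the intended side of the 20/40 μm thresholds despite pixel
quantisation; each lesion record stores the *measured* diameter of its
rendered component, so ground-truth class is decidable from the record
alone and provably consistent with the rule classifier. Placement is
rejection-sampled with guard margins that keep lesions, their shadows
and their flank bands disjoint. Speckle is applied after the mask is
fixed, so masks are a pure function of the lesion plan and seed.

The simulated second rater perturbs the ground-truth mask per component:
drop with probability p, class flip (1↔2) with probability q, and 0–k
iterations of random dilation or erosion with a disk(1) footprint. A
zero-noise spec reproduces the input exactly; mean Dice is
non-increasing in the jitter magnitude.

What the phantoms do **not** model: intraretinal cysts and subretinal
fluid (the hallmark of real DME), retinal curvature and layer
deformation, vendor noise statistics, motion artefacts, lesion clusters
that merge across b-scans, and sub-RPE pathology. Passing tests
therefore demonstrate that the pipeline's geometry, rules and statistics
are implemented correctly and that the network has the capacity to learn
this lesion appearance — not that the trained network reaches any
particular accuracy on patient scans. The reference study's accuracy on
clinical data (Dice ≈ 0.7 against a human rater) cannot be reproduced
without its cohort and is deliberately out of scope.

## Numerical and degenerate-input choices

* Binarisation threshold on probability maps: 0.5, foreground at ≥ t.
* Dice on two empty masks: 1.0, flagged by convention above.
* RPE estimation on a featureless image: fixed 0.85-depth fallback with
  an explicit flag.
* Connected-component ids are per b-scan and ordering-stable; class
  counts are permutation-invariant.
* All randomness flows through `numpy.random.Generator` seeds carried in
  the spec/config dataclasses; per-volume seeds are spawned from a
  master seed via `SeedSequence`, so datasets are bit-reproducible.
* Desk-scale problem sizes used by the tests and the acceptance script
  (4-slice 256² phantoms, 128² training patches, tiny 8-channel preset)
  were chosen so the full chain, including network training, runs on one
  CPU in minutes; the full 128 × 885 × 512 geometry is supported
  throughout.

## Known limitations

* The shadow test assumes a detectable RPE band and roughly flat
  retina within a b-scan; strong curvature would need the per-column
  depth estimate rather than its lateral median.
* The learned shadow-segmentation variant is an interface slot, not a
  trained model.
* Centroid-based ROI assignment means a large lesion straddling a circle
  boundary is counted wholly in or wholly out.
* The NumPy engine is single-threaded BLAS-bound; it is meant for
  CPU-scale experiments, not full-resolution training runs.
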