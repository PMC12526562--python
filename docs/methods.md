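# Methods

`scaseg` implements an automated pipeline for parcellating the human
brainstem (medulla, pons, mesencephalon) in template-space T1-weighted MRI
and for quantifying the progressive brainstem atrophy seen in
spinocerebellar ataxia type 2 (SCA2), from preclinical mutation carriers to
manifest patients.  Because clinical MRI cohorts of this kind cannot be
redistributed, the package ships a synthetic phantom generator that plays
the role of the cohort: every stage — preprocessing, network training,
evaluation, volumetry, statistics — runs end to end on data the package
creates itself.

## Segmentation network

The model is a 3D U-Net variant with two modifications.

**Inception modules.**  Every convolutional stage is a two-branch
multi-scale block.  The main branch chains three convolutions with kernels
1×1×1, 3×3×3, 3×3×3; all three intermediate feature maps are retained.  A
side branch applies a shape-preserving 3×3×3 max pool followed by a 1×1×1
convolution.  The four maps are concatenated (default allocation: a quarter
of the output width each) and instance-normalized with learnable affine
terms.  Rectified-linear activations follow every convolution.

**Attention on the skip connections.**  Each of the four skip connections
passes through three consecutive, independently parameterized convolutional
block attention modules (CBAM).  Channel attention pools the feature map
globally by maximum and by average, passes both descriptors through a
shared two-layer perceptron with reduction ratio r = 16 (clamped to the
channel count at narrow levels), sums them and applies a logistic gate per
channel.  Spatial attention computes channel-wise maximum and mean maps and
feeds the 2-channel stack through three consecutive 3×3×3 convolutions
(channel plan 2→2→2→1) with a final logistic gate; three stacked 3³ kernels
reproduce the 7³ receptive field of the classical single-convolution design
with far fewer parameters.  Both gates lie strictly in (0, 1), so attention
can only down-weight features.

The encoder uses five levels of widths (32, 64, 128, 256, 512) with 2×2×2
stride-2 max pooling; the decoder upsamples with learned stride-2
transposed convolutions (kernel 2) to the skip's width, concatenates, and
applies one inception module per level.  The head is dropout (rate 0.2), a
1×1×1 convolution to 4 classes, and a per-voxel softmax.  Input spatial
dimensions must be divisible by 2⁴; the default input is the 80×80×96
region of interest.  With the frozen default configuration the network has
3,081,490 trainable parameters, a pure function of `ModelConfig`.

Design points that the architecture description leaves open were fixed
once and frozen in the default config: one inception module per resolution
level per path; convolution biases on; instance-norm affine terms on,
applied after branch concatenation only; independent weights across the
three stacked CBAMs; max pooling for downsampling and a kernel-2 transposed
convolution for upsampling; argmax ties broken toward the lower channel
index.

The layers are implemented directly in NumPy with analytic
backpropagation (`scaseg.nn`): 3³ convolutions are lowered to im2col plus
BLAS matrix products; the stride-1 max pool uses three separable 1D max
filters, with tied maxima sharing gradient equally (the usual subgradient
choice).  Gradients of every layer were verified against central finite
differences in double precision.

## Training protocol

The loss is one minus the soft Dice score averaged across output channels
(all four channels by default, background included — the literal protocol;
a foreground-only variant is configurable).  Dice smoothing constant
1e-5 in numerator and denominator.  Optimization uses Adam with default
moments, a constant learning rate of 1e-4, 250 epochs and batch size 1 in
the full protocol.  Augmentation generates a fixed expanded set ahead of
training: per copy, one rigid transform with per-axis rotations uniform in
±15°, integer translations uniform in ±15 voxels, and a left-right flip
with probability 0.5 (the brainstem is approximately sagittally symmetric,
so only this flip is anatomically safe); images are interpolated linearly,
labels by nearest neighbor, out-of-field voxels filled with background.
Forty copies per training image reproduce the protocol's bookkeeping
(17 originals → 697 training images, 3 originals → 123).  Stratified
splitting keeps every clinical group represented in every subset whenever
the requested counts allow.  Validation is evaluated on the original
(un-augmented) validation images; the weights of the epoch with the best
validation Dice are retained.

**Reduced smoke scale.**  The test suite trains at a reduced scale chosen
to exercise the full pipeline on one CPU: 32×32×48 phantoms, encoder widths
(8, 16, 32, 64, 128), 8 training and 2 validation phantoms, 30 epochs, no
augmented copies.  Because the epoch budget is scaled down about eightfold
from the full protocol, the constant learning rate is scaled up to 1e-2.
The smoke phantoms use enlarged structure fractions (~0.9–2.2 %TICV,
preserving the patient < preclinical < control ordering) so that the
structures span more than a few voxels on the small grid.  The attention
ablation compares the full model against a twin with the CBAM stack removed
under identical data, budget and seeds; the comparison statistic is the
mean validation Dice over the training trajectory, which captures the
convergence-speed advantage attention is reported to give while averaging
out single-epoch noise.

## Phantom generator

A phantom is a head-like ellipsoid (semi-axes 42% of the grid extent) whose
voxelized volume defines the total intracranial volume (TICV), containing
three stacked solids on a common axis: a narrow inferior cylinder (medulla,
height = 5 radii), a wide middle ellipsoid (pons, polar semi-axis = 0.75 of
the equatorial), and a medium superior cylinder (mesencephalon, height =
2.5 radii).  Solid dimensions are solved analytically so that each
structure's volume equals the group's target fraction of TICV times a
multiplicative noise factor drawn from Normal(1, 0.05) — the 5% relative
dispersion is a package choice, as no per-subject dispersion is published.
Default group targets are the cohort means (in %TICV): medulla
0.26/0.29/0.31, pons 0.47/0.76/0.82, mesencephalon 0.40/0.44/0.48 for
patients/preclinical/controls.  A sub-voxel jitter of the common axis
decorrelates discretization error across subjects; at zero volume noise the
recovered fractions match the analytic targets to about 0.001 %TICV.

Intensities follow per-tissue-class means (background 0.02, head tissue
0.45, medulla 0.70, pons 0.80, mesencephalon 0.60, arbitrary units) chosen
to give T1-like contrast between the substructures, modulated by a smooth
multiplicative bias field — a random degree-2 polynomial in normalized
coordinates min-max scaled to [1 − A, 1 + A] with A = 0.2, mimicking
pre-correction coil inhomogeneity — plus additive Gaussian noise
(sd 0.03).  Labels are exact and unaffected by the intensity model.

Clinical scores are drawn so the cohort exhibits the published direction of
association: smaller brainstem, worse ataxia.  A Gaussian copula couples
the SARA score to the whole-brainstem fraction — latent severity
`a·(−z) + sqrt(1−a²)·ε` with `a = 2 sin(π·coupling/6)`, which yields a
population Spearman correlation of −coupling; a strictly monotone logistic
map takes the latent score onto [0, 40] without ties.  Controls receive
SARA near 0 and normal-range CAG; carriers draw CAG uniformly from
{36..40}; disease duration (patients only) is uniform on [1, 31] years.

What the phantoms do *not* model: real cortical/cerebellar anatomy, skull
and CSF, partial-volume effects, registration error, scanner-specific noise
spectra.  Passing tests therefore demonstrate that the pipeline's
machinery — geometry bookkeeping, optimization, metrics, statistics — is
correct and self-consistent, not that the network reaches the published
accuracy on clinical MRI.

## Preprocessing

The pipeline consumes volumes already bias-corrected and registered to the
ICBM 2009c symmetric template (those external steps are out of scope).  A
fixed 80×80×96 region of interest (614,400 voxels) is cropped around the
brainstem; the crop offset is derived once from the training segmentations'
pooled bounding box with symmetric margins and stored in the run config
(the phantom generator's default grid centers the ROI at offset (8, 8, 8)).
Intensity normalization clips to the [0.5, 99.5] percentile window and maps
it affinely to [0, 1]; the percentile clip makes the mapping robust to
bias-field tails.  Predicted label maps are uncropped back to the full
template grid, with everything outside the ROI set to background.
Volumes are reported in template space: the inverse registration to native
space is an external-tool step and is deliberately not wrapped.

## Evaluation metrics

Overlap metrics come from the voxel confusion table (DSC, IoU, sensitivity,
specificity, precision).  A surface voxel is a foreground voxel with at
least one of its six axial neighbors background or outside the grid.
HD95, the average symmetric surface distance (ASD, in mm) and the
normalized surface Dice (NSD, tolerance 1 mm by default — the tolerance is
not published and is configurable) are computed on the pooled symmetric set
of nearest-surface distances between voxel centers, so all three are
symmetric under swapping prediction and truth, and HD95/ASD scale linearly
with voxel spacing.  Metrics undefined for empty masks propagate as missing
values, never as zeros.  All metrics are verified against exhaustive
brute-force oracles on small random masks.  Published ASD values of ~0.05
are ambiguous in units (sub-voxel if mm); this implementation always
reports mm.

## Volumetry and statistics

Structure volumes are voxel counts times the voxel volume, computed on
uncropped template-space label volumes, normalized as %TICV (TICV is an
input; phantoms supply it analytically).  Group comparisons use the
tie-corrected Kruskal-Wallis H with the chi-square approximation.  Clinical
associations use Spearman rank correlations — chosen because ranks are
robust at cohort sizes of 10–20 and consistent with the nonparametric group
test — across 4 structures × 3 scores = 12 tests: SARA and CAG over
patients + preclinical carriers, disease duration over patients only.
Bonferroni adjustment multiplies raw p-values by 12 (capped at 1); the
family-wise threshold 0.05/12 is reported as 0.0042.  Cohort sizes are
taken from the supplied manifest, never hard-coded.

## Numerical and degenerate-input choices

Constant images cannot be normalized (error).  Empty cohorts, infeasible
splits and out-of-bounds crops raise errors rather than degrading.
Non-finite training loss aborts with a diagnostic.  All randomness flows
through explicitly seeded NumPy generators (one per call; no global state),
making phantom generation, augmentation, splitting, initialization and
training bit-reproducible on a fixed BLAS.

## Known limitations

* The default architecture's parameter total (3,081,490) reflects this
  implementation's frozen reading of the under-specified block internals;
  other readings of the same prose yield different totals.
* Phantom geometry is schematic; segmentation difficulty is far below
  clinical MRI, so absolute Dice values on phantoms are not comparable to
  cohort values.
* Surface metrics are voxel-based, not mesh-based; at 0.8 mm spacing the
  discretization of ASD is of the same order as published sub-voxel values.
* Training runs single-threaded on CPU; the reduced smoke scale exists to
  keep the full pipeline testable, and its Dice plateau (~0.84) is set by
  tiny-structure discretization rather than by model capacity.
* On the schematic phantoms the attention stack confers no measurable
  advantage: the task is nearly separable by intensity alone, and the three
  stacked sigmoid gates (initialized near 0.5) attenuate skip features
  early in training.  The convergence advantage of attention reported on
  clinical MRI is therefore not reproduced at the reduced phantom scale —
  the test suite measures and reports exactly this.
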