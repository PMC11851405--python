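# Methods

## Model

Two network families share one 3D U-Net topology: a four-level encoder
(two 3×3×3 convolution blocks per level, each convolution followed by
instance normalization and ReLU; downsampling by stride-2 convolution) and
a symmetric decoder (trilinear upsampling ×2 followed by a 3×3×3
convolution, skip concatenation, two convolution blocks), closed by a
1×1×1 logit head at input resolution.  The multi-modality network (MMN)
ingests the stacked T1/T2/T1c/Flair channels with widths
(32, 64, 128, 256); each single-modality network (SMN) ingests one channel
with widths scaled by `smn_width_factor` (default 0.5), keeping the
single-modality branches light.  Spatial inputs must be divisible by 8
(three downsamplings).

Instance normalization was chosen over batch statistics because volumetric
patches are trained at batch sizes of 1–4, where batch moments are
high-variance; this is the standard choice for 3D segmentation U-Nets.
Downsampling by strided convolution and upsampling by trilinear
interpolation + convolution are likewise conventional defaults where the
architecture family leaves the operator open.

### Dual recalibration

At each of the four decoder scales (bottleneck included) a Dual
Recalibration Module fuses the MMN decoder feature with the same-scale SMN
decoder features:

1. SMN features are projected to the MMN width R by a learned 1×1×1
   convolution.
2. *Spatial recalibration:* each branch is compressed to a single map by
   its own 1×1×1 convolution; the maps are softmax-normalized across
   branches per voxel and each branch is multiplied by its weight map.
   The weights sum to one at every voxel by construction.
3. *Channel recalibration:* global average pooling gives an R-vector per
   branch; the concatenated vectors feed three **independent**
   fully-connected heads (one linear map kR→R per branch, no hidden
   layer) with a sigmoid, and each branch's channels are rescaled by its
   weight vector.  Independent heads are essential: a single shared head
   would force identical weights on all branches and defeat per-branch
   recalibration.
4. The recalibrated branches are summed; the fused block replaces the MMN
   decoder feature before the next upsampling stage.

Channel recalibration consumes the spatially recalibrated features
(sequential composition) by default, since the fused output sums the
CR-stage outputs and SR precedes CR in the module's definition; a
`drm_composition="parallel"` switch computes both weightings from the raw
inputs instead, for comparison.  The module supports one or two SMN
branches — the two-branch form is the method proper, the one-branch form
serves the "MMN + single SMN" ablations; no further generalization is
attempted.

### SMN supervision

Each SMN is supervised on an exhaustive grouping of the labels
{0, 1, 2, 4}.  The default assignment (`smn_targets="flair_merged"`) gives
the Flair network {background, ED, ET∪NCR/NET} — edema is what Flair shows
best, and the core is kept as one merged class — and the T1c network
{background∪ED, ET, NCR/NET}, exploiting T1c's rim/core contrast to
separate the core.  The converse reading, T1c with the merged core and
Flair separating it, is defensible on the same radiological grounds and is
available as `smn_targets="t1c_merged"`; the `all_labels` variant
supervises both SMNs on all four classes.  Neither assignment is claimed
to be canonically correct.

### Losses

Per network, L = L_Dice + L_CE with equal unit weights (the simplest
choice absent evidence that either term should dominate).
Soft Dice averages over the Np classes with ε = 1e-5 added to numerator
and denominator so empty classes contribute zero loss rather than 0/0.
Cross-entropy is normalized by Np·M (classes × voxels) — note this differs
from the more common 1/M convention and makes a uniform 4-class prediction
score ln(4)/4 ≈ 0.3466; probabilities are floored at 1e-12 inside the log.
The joint objective is L_T = λ·L_MMN + (1−λ)/2·(L_T1c + L_Flair) with
λ = 0.5 by default: it weights the MMN and the SMN pair equally, and is
exposed as `lam` in the run config for tuning.

## Data pipeline

**Phantoms.**  Three concentric axis-aligned ellipsoids define the nested
subregions: necrotic core inside `et_radii`, enhancing rim out to
`tc_radii`, edema out to `wt_radii`.  Each modality image is the
tissue-class mean plus Gaussian noise (sd 10 on class means of order 100,
i.e. a contrast-to-noise ratio of roughly 2–9 depending on the tissue
pair, comparable to a clean clinical acquisition).  The default intensity
table (background/ED/ET/NCR-NET): T1 100/70/60/50, T2 100/180/140/120,
T1c 100/110/190/70, Flair 100/190/150/130 — arbitrary units chosen to
satisfy the qualitative contrast orderings (edema bright on T2/Flair,
tumor dark on T1, rim bright against core on T1c); only the orderings are
contractual.  One generator seeded per phantom is consumed in a fixed
order (noise per modality in channel order), so a spec plus seed is
bit-reproducible.  The phantoms deliberately omit MRI physics — bias
fields, partial-volume effects, infiltrative boundaries, multi-focal
lesions — so passing tests demonstrate that the pipeline and optimization
behave correctly, not that the model reaches clinical accuracy on real
BraTS volumes.

**Preprocessing.**  Per-modality z-score over the nonzero support
(background in BraTS-convention volumes is exactly 0), background kept at
0; constant channels are rejected.  Training patches are uniform random
crops over valid corner positions, zero-padded symmetrically when the
volume is smaller than the patch.

**Augmentation.**  Rotation (uniform ±15° per axis), isotropic scaling
[0.9, 1.1], elastic deformation (control-point spacing 32 voxels, sd 4
voxels) and gamma correction [0.8, 1.2] on the min–max-normalized range,
each applied with probability 0.5.  Geometric transforms are applied with
one transform to image (linear interpolation) and labels
(nearest-neighbor); gamma touches the image only.  Angles that are
multiples of 90° take an exact `rot90` path so the rotation-group identity
holds exactly.  The random stream is consumed in a fixed order regardless
of which transforms fire, making a seed fully determine the output.

## Training and inference

Defaults follow the reference recipe: Adam, learning rate 1e-4, weight
decay 2e-5, batch 4, 100 epochs, 96×128×128 patches, 300 randomly sampled
patches per epoch.  A fraction of cases (default 10%) is held out for
per-epoch validation-loss logging.  Checkpoints (flat parameter dict,
`.npz`) are written each epoch; a NaN loss aborts with a diagnostic.

Inference is sliding-window with half-patch stride, averaging softmax
probabilities over overlaps and decoding the argmax back to labels
{0, 1, 2, 4}; volumes smaller than the patch are padded and the output
cropped back.  Sliding-window is the standard volumetric inference choice
and keeps memory flat regardless of volume size.

The desk-scale profile used throughout the tests and the acceptance script
overrides to 32³ patches, batch 1–2 and widths (8, 16, 32, 64) — small
enough that 200 training steps take a few minutes on one CPU while leaving
the architecture, losses and fusion path identical to the full profile.

## Ablation variants

`run_ablation` maps the eight variants to (smn_set, drm_mode): MMN only;
MMN + Flair SMN; MMN + T1c SMN; both SMNs with all-label supervision; no
DRM (projection + plain 1×1×1 convolutional fusion of the concatenated
branches); SR only; CR only; full.  Parameters a variant never touches
(e.g. the plain-fusion convolution under `drm_mode="full"`, the unused
stage's parameters under `sr_only`/`cr_only`) receive no gradient, which
the tests assert variant by variant.

## Numerical engine

`recalseg.nn` is a minimal reverse-mode autodiff on numpy arrays: float32
storage, topological backward sweep, broadcast-aware accumulation.  3D
convolution runs as im2col + GEMM forward, with the input gradient
scattered per kernel offset to avoid materializing the column gradient;
trilinear upsampling is a separable linear operator applied (and
transposed) per axis with half-pixel alignment and edge clamping.
Correctness rests on adjoint identities (convolution is linear, so
⟨∂L/∂x, dx⟩ must equal ⟨∂L/∂y, conv(dx)⟩ to rounding) and
finite-difference checks on composite graphs.

## Degenerate-input conventions

* Overlap metrics: both masks empty → dice/sensitivity/PPV = 1; exactly
  one empty → all three 0.
* HD95: both empty → 0 mm; one empty → the physical volume diagonal (a
  documented worst-case sentinel).  Surfaces are foreground voxels with a
  6-connected background neighbor (volume border counts as background);
  distances are between surface-voxel centers scaled by spacing;
  percentiles are linear-interpolation quantiles.  These conventions match
  common BraTS tooling; the distances use surface point sets rather than
  full masks.

## Known limitations

* Phantom realism is deliberately minimal (see above); reported scores on
  phantoms do not transfer to clinical data.
* The CPU engine is orders of magnitude slower than GPU frameworks; the
  default (non-desk) profile is defined for completeness but is only
  practical on substantial hardware budgets.
* DRM placement is decoder-side only (four sites); fusing on the encoder
  path as well (eight sites) is a plausible alternative not implemented
  here.
* No deep supervision, test-time augmentation, class-frequency weighting
  or boundary losses.
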