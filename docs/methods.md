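# Methods

`bladderseg` implements a fully automated pipeline that segments the bladder
wall and the bladder tumor in 3D T2-weighted MRI volumes using a family of
progressive-dilated 3D U-Nets. This note records the model, the data
conventions, the synthetic phantoms used for testing, and the numerical and
design choices that were genuinely open.

## Problem and data model

A case consists of a 3D T2 intensity volume and two aligned binary masks
(bladder wall, tumor) delineated by radiologists and exchanged as NRRD
files. All arrays are addressed as `(rows, cols, slices)`, 0-based, with the
slice axis the axial acquisition axis. On T2-weighted images urine is
hyperintense, so the lumen is the brightest structure, the tumor
intermediate, the muscular wall darker, and the background darkest.

### Preprocessing

1. **Fixed ROI crop.** The bladder of a distended patient lies in the
   upper-central part of the field of view; the pipeline crops the fixed
   in-plane window rows/cols `[100, 400)` (requiring an in-plane matrix of
   at least 400×400) and takes 32 slices, center-cropping deeper stacks and
   zero-padding shallower ones. The crop is deliberately *not* derived from
   the ground-truth masks, so it works identically at test time on
   unannotated scans.
2. **Resize** from 300×300×32 to 128×128×32 — trilinear for intensities,
   nearest-neighbour for masks so the label set is preserved exactly. The
   reduction keeps a whole volume (and its gradients) comfortably in memory.
3. **Normalize** each volume to mean 0, standard deviation 1 over all
   voxels (per-volume, not per-slice; a constant volume maps to zeros).
   Resizing happens before normalization.
4. **Label encoding.** The two binary masks merge into one label grid with
   background = 0, wall = 255, tumor = 125; where wall and tumor overlap the
   voxel is tumor. The one-hot form orders channels (background, wall,
   tumor). The third class is read as "everything that is neither wall nor
   tumor" (full background complement).

### Augmentation

Each original training volume contributes `na` extra volumes (scenarios
na=5 and na=10), built from three transform families applied with one shared
geometry to image and labels (trilinear vs nearest-neighbour resampling):

* in-plane rotations with angles drawn uniformly from [5°, 10°] (positive)
  and [−10°, −5°] (negative);
* horizontal flips (mirror along the column axis) of a fixed subset of the
  rotated copies;
* elastic warps from a smooth random displacement field.

Shipped compositions: na=10 → 3 positive + 3 negative rotations (three of
the six flipped) + 4 elastic (2 fields × {original, flipped}); na=5 → 2
positive + 1 negative rotation (one flipped) + 2 elastic. The composition is
configurable; the constraint is only that it sums to `na`. Each original
also contributes one independently drawn rotated copy to the validation set,
so `x` originals yield `x·(1+na)` training and `x` validation volumes.

The elastic field is Gaussian-filtered uniform noise, in-plane only,
rescaled so the peak displacement is `elastic_alpha` voxels with smoothness
`elastic_sigma` (defaults 2 and 32 voxels at the 128×128×32 working
resolution). The defaults are deliberately gentle: volume change of a blob
under a smooth warp scales like alpha/sigma, and these values keep per-class
voxel counts within 10% of the original even for the small tumor blob,
which is the regime in which a warped mask is still a plausible annotation
of a warped anatomy.

## Architecture

The family has 4-, 5- and 6-block members (U-Net-4/5/6). Every convolution
is 3×3×3 (the head's is 1×1×1) and, unless noted, is followed by batch
normalization and PReLU.

* **Encoder** — `num_blocks` levels of three convolutions whose dilation
  rate alternates 1 → 2 → 4 within the level, growing the receptive field
  without extra parameters. The first convolution of *every* level has
  stride 2 and halves the volume. The 5-block encoder therefore has 15
  convolutional layers.
* **Bridge** — two convolutions, then a residual block: two dilation-1
  convolutions with *no* normalization, PReLU only, added elementwise to
  the block input.
* **Decoder** — per level: parameter-free nearest-neighbour ×2 upsampling,
  channel concatenation with the dilation-4 (i.e. last) convolution output
  of the encoder level at the same resolution, then two convolutions.
  Because every encoder level downsamples, no full-resolution encoder
  feature exists: the final decoder level upsamples to full resolution
  without a skip. This keeps the decoder at exactly `2·num_blocks`
  convolutions.
* **Head** — a 3-filter 1×1×1 convolution (one filter per class), batch
  normalization, PReLU, softmax over channels.

Filter widths are not dictated by the reference description; the default is
16 at the first level, doubling per level and capped at 256, with the
bridge/residual one growth step above the deepest encoder level. "Merge" is
channel concatenation by default (elementwise addition behind a flag).

**Stride policy.** Strides are (2,2,2) per level while every axis can still
halve exactly; an axis whose size is odd or 1 gets stride 1 for the
remaining levels. For the 128×128×32 input this gives full (2,2,2) striding
through 5 blocks (depth 32 → 1) and clamps the depth axis to stride 1 at
block 6. A user-supplied policy that cannot be inverted by ×2 upsampling is
rejected with the offending level and axis.

### Numerical core

No deep-learning framework is used: the layers (dilated/strided 3D
convolution, batch normalization, PReLU, nearest-neighbour upsampling,
softmax) are implemented directly over numpy with hand-written backward
passes, verified against finite differences in the test suite. Convolutions
use "same" padding (output `ceil(n/stride)` per axis, extra zero on the
high side when the total padding is odd) and are evaluated tap-by-tap as 27
GEMMs, which profiled faster than im2col at these channel widths on one
CPU; the input gradient of a stride-1 convolution is computed as the
dilated correlation with the flipped, channel-transposed kernel (a gather
with contiguous accumulation rather than strided scatter-adds). The
surrounding elementwise and reduction work (PReLU, batch-norm statistics
and normalization, Adam updates, the sum-pooling adjoint of upsampling) is
bandwidth-bound and runs as fused numba kernels. Weights use He-normal
initialization; PReLU slopes start at 0.25; batch-norm uses eps 1e-5 and
running-stat momentum 0.1.

## Training

Adam (lr 5e-4, β₁ 0.9, β₂ 0.999) minimizes voxel-wise categorical
cross-entropy, `−Σᵢ yᵢ log ŷᵢ` per voxel over the three classes, reduced by
the mean over voxels (the reduction is a free choice; Adam is invariant to
the global gradient scale). Probabilities are clipped at 1e-7 before the
log. Batch size defaults to 1 full volume, matching the memory profile of
volumetric training. After every epoch the validation loss and validation
Dice (argmax, no post-processing) are computed; a checkpoint is saved
whenever the overall validation Dice improves on the running best, and
training stops at `max_epochs` (default 200) or after `patience` (default
15) epochs without improvement. A non-finite loss aborts with the epoch
number. All shuffling and initialization is driven by explicit seeds; a
repeated run reproduces the loss trajectory bit-for-bit.

## Post-processing and evaluation

Test-time probability maps are smoothed slice-wise per class channel with
an edge-preserving bilateral filter and renormalized, then binarized by
per-voxel argmax (ties to the lower class index) into the {0, 255, 125}
convention. Default sigmas are 1.5 voxels (spatial) and 0.3 (intensity, on
the probability scale), and both are load-bearing. The intensity sigma
must be large enough that isolated single-voxel responses are averaged
away (a tiny sigma would preserve exactly the spurious spikes the step is
meant to remove) yet small enough that the probability edge around a
confident tumor region still blocks smoothing. The spatial sigma must sit
below the cross-section of the smallest anatomically real structure — the
tumor spans only a few voxels per slice at working resolutions — while
still covering single-voxel noise; intensity alone cannot separate a unit
spike from a moderately confident blob, size must. At (1.5, 0.3), unit
spikes are attenuated to ≈0.33 while tumor blobs backed by ≥0.75 class
probability survive binarization essentially intact; (3, 0.5) was measured
to erase the tumor entirely at the 64³ test resolution.

Agreement is measured with the Dice similarity coefficient
`2|A∩B|/(|A|+|B|)`; two empty masks score 1.0 (absence correctly
predicted). A report row carries wall, tumor and background Dice plus
"overall" = their unweighted mean. (A literal set-union denominator would
make Dice(A,A)=2; the implemented form is the standard one, and the
mean-of-three "overall" is the only reading under which overall can exceed
both foreground scores, since the large easy background class pulls the
mean up.) `run_experiment` drives the architecture × scenario × train-size
grid with a fixed seed, records the train/test split, and emits long-format
and pivoted CSV tables.

## Synthetic phantoms

The clinical cohort behind the original study is private, so the package
ships a phantom generator used by all tests. A phantom is an ellipsoidal
bladder: bright lumen, closed darker wall shell of configurable thickness
(outer minus inner ellipsoid), and an intermediate-intensity spherical
tumor centered on the inner wall surface and clipped to the organ (wall and
tumor masks disjoint, tumor taking precedence), plus additive Gaussian
noise. Defaults: 512×512×32 grid, ellipsoid semi-axes (80, 100, 12) voxels
centered at (250, 250, 16) — inside the fixed ROI window — wall thickness
4 voxels, tumor radius 12, intensities 200/120/60/30 (lumen/tumor/wall/
background) with noise SD 10, spacing (1, 1, 3) mm. Cohort generation
jitters radii and tumor size uniformly within ±20%, the in-plane center
within ±10 voxels, and re-draws the tumor's angular position per case; a
CSV manifest records the drawn parameters. A configuration whose tumor
cannot touch the wall shell is rejected (the pipeline's premise is a
wall-attached lesion).

What the phantoms do *not* emulate: MRI physics (bias fields, partial
volume, Rician noise), irregular tumor shape, bladder-wall thickness
variation, neighbouring organs, or multi-tumor cases. Passing tests on
phantoms therefore demonstrates that the pipeline's machinery — I/O,
geometry, optimization, metrics — is correct and that the models can fit
wall-and-tumor geometry; it says nothing quantitative about Dice scores on
clinical data.

## Desk-scale test conditions

The heavier checks run at reduced size so the whole suite completes on one
CPU: the memorization check trains the 4-block model with 8 base filters on
two noiseless phantoms preprocessed to 64×64×16, expanded by the na=10
augmentation exactly as the pipeline always trains (2 originals → 22
training volumes per epoch), for at most 200 epochs with an early stop
once the training loss falls below 0.02 — the small tumor class (about
0.1% of voxels) is the last thing memorized, and stopping earlier can
catch training mid-way through that phase. The probe evaluates the
end-of-training weights (`restore_best=False`): restoring the
best-validation checkpoint is a generalization device, and with a single
rotated validation volume the overall-Dice monitor is too noisy to rank
epochs by tumor memorization. Training on the 2 raw volumes
alone would give only 400 optimizer steps — far too few for Adam at
lr 5·10⁻⁴, whose update magnitude is bounded near the learning rate, to
drive the normalized head to confident predictions; the augmented
expansion is both the realistic condition and what makes memorization
reachable. The experiment-grid and pipeline smoke tests use 2-filter
models at 32×32×8 for a few epochs. These sizes are the package's own
test-design choice; the library defaults remain the full 128×128×32
contract.

## Known limitations

* Batch size > 1 requires equal-shaped volumes (always true after prep).
* The bilateral filter is 2D slice-wise; a 3D kernel would couple slices
  but has no conventional sigma scaling for strongly anisotropic voxels.
* Training is CPU-bound numpy; it is adequate for the desk-scale phantom
  experiments the package targets, not for clinical-scale training runs.
* The fixed ROI crop assumes the scanner's field of view matches the
  convention above; scans framed differently need upstream resampling.
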