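# Methods

## Problem and model

The package segments up to ten knee-joint tissues from 2D sagittal MR-like
slices by image-to-image translation: a U-Net generator G paints a 3-channel
colour-coded label map from a grayscale slice, optionally trained
adversarially against a conditional PatchGAN discriminator D that scores
(source, label) pairs patch-wise.  The generator objective is the
non-saturating binary-cross-entropy GAN term plus a λ-weighted pixel loss

    min_G  −E[log D(x, G(x))] + λ · L_pix(y, G(x)),

while D minimises −E[log D(x, y)] − E[log(1 − D(x, G(x)))].  The value
function is symmetric under the usual saddle-point reading; we use the
standard formulation in which D is trained to score real pairs high, with the
non-saturating generator term, since that is the convention of the pix2pix
family of models this implementation follows.  With the adversarial term
disabled the same generator trains as a plain U-Net regressor, which is the
quantitative comparison baseline throughout.

## Label codec

Each tissue owns one RGB channel and one 8-bit code (bones: blue 50/100/150,
ACL blue 200; cartilages: green 50/100/150, PCL green 200; muscles: red
100/200).  Decoding keeps pixels within ±20 colour-scale units of the code,
with inclusive bounds (|v − code| ≤ 20): "outside ±20" removal naturally
complements to an inclusive band.  Values falling between code bands (e.g.
blue 71–79) decode to background for every tissue — no nearest-code snapping
is invented.  Channels are written independently, so cross-channel overlap
(bone + cartilage at a boundary pixel) is legal; overlap of two tissues
within one channel is rejected as inconsistent ground truth.  The scheme
validator enforces that codes within a channel differ by more than twice the
tolerance, which guarantees decoded within-channel masks are pairwise
disjoint.  Noise-only slices are exactly all-zero label maps (8-bit PNG is
lossless, so exact equality is safe) and are excluded from training and, by
default, evaluation.

## Architectures

The generator encoder applies `n_down` stride-2 4×4 convolutions (so an
input of size 2^n_down reaches a 1×1 bottleneck at full depth: nine stages
for 512 px); the decoder mirrors it with stride-2 4×4 transposed convolutions
and skip concatenations between stages of equal spatial size.  Channel widths
start at `min_channels`, double per stage, and cap at 8 × min_channels
(16/32/64/128 → 128/256/512/1024).  Batch norm is applied everywhere except
the first encoder layer (raw image statistics) and the bottleneck (batch
statistics over a 1×1 map are degenerate); activations are leaky ReLU (0.2)
down, ReLU up, tanh on the output over labels rescaled to [−1, 1].  Dropout
in the innermost decoder stages is available behind a flag and off by
default.  Weights initialise from N(0, 0.02).  Transposed-convolution
upsampling is retained deliberately; its checkerboard artefacts are a known
property of this family and are not suppressed.

The four discriminator variants are layer stacks constrained to reproduce
the studied receptive fields: pixel_1 (two 1×1 convolutions + 1×1 output,
r = 1), patch_34 (two stride-2 4×4 + one stride-1 4×4 + output, r = 34),
patch_70 (three stride-2, r = 70, the default), patch_286 (five stride-2,
r = 286).  Widths start at 64, double per strided layer, cap at 512; the
first and output layers omit normalisation.  `receptive_field` iterates
r ← r·s + (k − s) backwards from r = 1; `empirical_receptive_field`
independently measures the nonzero input-gradient footprint of one central
output unit on a positively-weighted single-channel instantiation of the
same stack, and the two must agree exactly.  4×4 convolutions use 1 px zero
padding (exact halving); the footprint definition ignores padding.

## Numerical backend

No GPU framework is used: `kneeseg.nn` is a small numpy layer library with
hand-written backward passes — im2col convolutions, transposed convolutions
as the convolution adjoint, batch norm with running statistics, leaky
ReLU/ReLU/tanh/sigmoid, inverted dropout, and Adam.  All gradients are
verified against central finite differences in the unit tests.  Tensors are
NCHW float64; at the 64 px problem sizes used here a full training iteration
costs tens of milliseconds on one CPU core.

## Training protocol

Adam with learning rate 2e-4 and momenta β₁ = 0.5, β₂ = 0.999 is the
default, with batch size 1 (making batch norm act as instance norm — the
same per-image statistics are therefore used at inference).  Each iteration
performs one discriminator update (real pair ascent, fake pair descent) and
one generator update.  Jitter augmentation resizes the pair up (bicubic for
the source, nearest-neighbour for the label so codes are never interpolated
into the dead zones between bands) and crops back at one shared uniform
offset; the default ratio mirrors the full-scale 542→512 recipe (68→64 at
phantom scale).  Scores are clamped at 1e-7 before logarithms.  No
learning-rate decay is applied.

The pixel-loss kind may switch once at a fixed epoch (e.g. L2 → L1 at epoch
50 of 100) with weights and optimiser state persisting; checkpoints carry
parameters, Adam moments, batch-norm running statistics and the loss
history, and resuming from a checkpoint is bit-compatible because every
random draw is keyed as SeedSequence([seed, stream, epoch, iter]).  Transfer
learning pretrains on one dataset for `pretrain_epochs` (default 20) and
continues — same weights, fresh data stream — on the target dataset for the
remaining epochs (default 80), both phases tagged in the loss log.
SmoothL1 applies the Huber branch condition element-wise with δ = 1.

## Metrics

DSC = 2|X∩Y|/(|X|+|Y|); VOE = 1 − |X∩Y|/|X∪Y| (identically
1 − DSC/(2 − DSC), asserted as an invariant); ASD is the symmetric average
surface distance in mm.  Surfaces are mask voxels with a face-adjacent
outside neighbour (raster borders count as outside); distances are measured
voxel-centre to voxel-centre via Euclidean distance transforms sampled at
the voxel spacing, and equal a brute-force all-pairs oracle exactly on small
volumes.  Conventions for degenerate inputs: DSC(∅,∅) = 1, VOE(∅,∅) = 0,
DSC(∅, nonempty) = 0, ASD undefined (reported absent) when either mask is
empty — a total segmentation failure therefore scores 0.000.  Per-subject
metrics are computed on full stacked 3D volumes, and aggregation across
subjects uses the unweighted mean and the population (divide-by-n) standard
deviation.

## Phantom generator

The phantom emulates the structure of a per-subject sagittal stack: femur
and tibia as large ellipses whose radii taper toward the stack ends, a
patella disc and two thin oblique cruciate bands on central slices only,
1–3 px cartilage shells on the articular bone edges, and two posterior
muscle blobs.  Source intensities are tissue-dependent Gaussians (bones
0.85, cartilage 0.55, muscle 0.40, ligament 0.25, background 0.08; σ
0.02–0.03), multiplied by a smooth bias field of 2–4 random low-frequency
cosine modes with amplitude 0.15, qualitatively mimicking RF coil
non-uniformity.  20 % of slices, at the stack periphery, are pure noise with
all-zero labels.  One global seed fans out to per-subject seeds through
SeedSequence spawning, so each subject is independently reproducible.  A
default cohort is 10 subjects × 10 slices with a subject-level 80/20 split
(8 train / 2 test).  `perturb_domain` shifts all intensity means and
rescales the geometry to create a related-but-different second domain for
transfer experiments.

What the phantom does *not* model: MR physics, partial-volume effects,
pathology (osteophytes, cartilage loss), anatomical shape variation beyond
ellipse jitter, or inter-scanner contrast differences.  Passing the phantom
tests therefore demonstrates that the machinery — codec, objectives,
optimisation, metrics — is correct and that the networks can learn a
multi-tissue colour-coding task, not that real-MRI accuracy figures are
reproduced.

## Desk-scale training choices

Tests and examples run at 64 px (n_down = 5, min_channels = 16), where a
training epoch over 64 usable slices takes ~2.5 s on one CPU.  These runs
use learning rate 2e-3 rather than the 2e-4 default: the default is
appropriate to the ~10⁵-iteration full-scale regime, while a 640-iteration
demonstration needs a proportionally larger step to converge; all other
optimiser settings are unchanged.  At this scale the two large bones reach
held-out DSC ≈ 0.87–0.91 within 10 epochs, while the patella (a ~3.5 px
disc on central slices), cartilage shells and ligaments remain poorly
segmented — the same structure-size ordering reported on real knee MRI,
where the patella scores lowest of the bones and ligaments lowest overall.
The desk-scale cGAN check uses the patch_70 layer layout on 64 px inputs,
where its 70 px receptive field makes each output unit effectively
image-level; layout, not patch-to-image ratio, is what the check exercises.

## Known limitations

- 2D slices only; no 3D convolutions, so no spatial continuity along the
  stack beyond independent per-slice predictions.
- No multi-class cross-entropy / soft-Dice objectives; pixel losses operate
  on the colour-coded regression target by design.
- A pixel within tolerance of codes in two different channels decodes to
  multiple tissues; tissues are decoded independently and no arbitration is
  attempted.
- Batch size 1 and one D step per G step are fixed conventions of the
  implementation, not tuned values.
- The numpy backend is single-threaded apart from BLAS matmuls and is not
  intended for 512 px training; full-scale runs would need hours per epoch.
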