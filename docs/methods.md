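# Methods

`lobeseg` implements a lightweight, fully 2D training recipe for pulmonary
lobe segmentation in chest CT: an attention-gated U-Net trained with a
multi-class soft Dice objective, optionally pre-trained with a jigsaw-puzzle
self-supervised pretext, and regularized with an expert-guided augmentation
policy split into patient-related (geometric) and scanner-related
(photometric) transforms. Because clinical CT with expert lobe annotations
cannot ship with the package, every stage is exercisable end-to-end on
procedurally generated lung phantoms; real volumes enter through NIfTI or
DICOM series.

## The segmentation model

The network is a five-stage 2D U-Net over 256x256 slices. Each stage is two
Conv(3x3, pad 1)-BatchNorm-ReLU units; 2x2 max pooling halves resolution
four times, giving a bottleneck of shape (512, 16, 16) at the default
encoder widths (64, 128, 256, 512, 512). The decoder mirrors the encoder
with bilinear 2x upsampling and skip-connection concatenation; decoder stage
widths are half the matching encoder width with a floor of 8 channels — the
floor matters because the last decoder stage feeds a 1x1 convolution onto 6
logits (background + 5 lobes), and narrower features cannot span six class
scores (at 2 channels, two of the five lobes are never predicted in
practice). Softmax is applied by the loss and at inference, not inside the
model.

Attention gates sit on every skip connection: the immediately deeper decoder
feature is upsampled to the skip resolution, both inputs are projected to an
internal width (half the skip width) by 1x1 convolutions, summed, passed
through ReLU, projected to one channel, and squashed by a sigmoid into
coefficients in [0, 1] that multiply the skip features. The gates add under
3% parameters at default widths and let the decoder suppress the body shell
and background without a separate lung-localization step.

Where the published layer table is internally inconsistent (encoder rows
that conflate convolution and downsampling; a decoder path that contradicts
the latent shape the pretext head expects), the implementation honors the
three unambiguous constraints — input (1, 256, 256), output (6, 256, 256),
a (512, 16, 16) encoder stage for the pretext head — with the standard
U-Net reading of everything else. Max pooling and bilinear upsampling are
the conventional choices where the operator is unstated.

## Loss and metric

Training minimizes one minus the mean over all six classes of the
squared-denominator soft Dice

    D_k = 2 * sum_i p_ik g_ik / (sum_i p_ik^2 + sum_i g_ik^2),

computed on softmax probabilities pooled over the mini-batch, with
epsilon = 1e-6 added to numerator and denominator so a class absent from
both prediction and truth contributes D_k ~ 1 (correctly predicted absence)
instead of 0/0. Evaluation uses the hard overlap DSC = 2TP / (2TP + FP + FN)
per lobe; reports average the five lobe classes and exclude background. For
exactly one-hot probabilities the two forms coincide (then sum p^2 = sum p).
The absent-class convention for the metric is also 1.0.

The published recipe is kept verbatim as the defaults of `TrainConfig`:
Xavier-uniform initialization, Adam with initial learning rate 1e-4 and L2
weight decay 1e-5, learning rate multiplied by 0.96 every 2 epochs, 50
epochs, batch 16, best-on-validation checkpointing (validation metric: mean
foreground hard Dice). Scaled-down runs in the tests and the acceptance
script shrink widths, epochs and batch sizes and may raise the learning
rate (overfit experiments use 3e-3 with no decay); these are experiment
settings, not changed defaults.

## Jigsaw self-supervised pretraining

The pretext cuts a 256x256 slice into a 4x4 grid of 64x64 patches, permutes
them uniformly at random, and asks the network to classify, for each patch
of the shuffled image in board order, the position it originally came from
(the inverse permutation) — 16 independent 16-way classifications trained
with mean per-patch cross-entropy. Per-input-patch position prediction is
the standard jigsaw formulation: each visible patch is classified by where
it belongs. The source-indexed alternative ("where did source patch s go?")
asks the network to reason about content it cannot see and, in controlled
experiments here, never left chance level within desk-scale budgets, while
being information-equivalent (one target is the inverse of the other).

The classification head reads the encoder bottleneck. At full width it is
the published design: five Conv-BatchNorm-ReLU pairs reducing 512 channels
through 256, 128, 64, 32, 16 at 16x16 resolution, then a global MLP of
widths 512 and 128 (dropout 0.25 after each) onto a final 256-way output
reshaped to (16, 16) logits. For narrower encoders (`for_unet` scaling) the
conv widths shrink proportionally (floor 16) and the global MLP is replaced
by a weight-shared per-patch MLP over each board cell's latent block.
Measurements motivating this: with the global MLP, pretext accuracy stays
at chance for 800+ optimizer steps at every width and learning rate tried
(the MLP must discover 16 separate readout programs from one flattened
vector — a routing symmetry it cannot break quickly), whereas the shared
readout is position-equivariant by construction and exceeds 0.9 accuracy
within ~250 steps on phantom slices. A linear probe on raw patch content
solves position classification perfectly, confirming the task itself is
well-posed on phantoms.

After pretraining, `transfer_encoder` copies every encoder tensor (weights
and batch-norm statistics) into the segmentation model by name; decoder,
gates and head keep their fresh initialization, and the jigsaw head is
discarded. Nothing is frozen.

## Augmentation policy

Five transforms, applied in a fixed order, each gated by an independent
Bernoulli draw per sample:

| transform | p | parameters |
|---|---|---|
| elastic_transform | 0.6 | alpha 1, sigma 25, alpha_affine 25, border 0/value 0 |
| grid_distortion | 0.8 | num_steps 5, distort_limit 0.3, reflect border |
| motion_blur | 0.3 | kernel length 15 |
| gaussian_noise | 0.5 | variance U(0, 5e-4), mean offset 1e-3 |
| brightness_contrast | 1.0 | brightness U(-0.2, 0.2), contrast U(-0.2, 0.2) |

The patient class is the two geometric transforms (anatomy and pathology
deformations); the scanner class the three photometric ones (acquisition
and reconstruction variability); combined is all five. Geometric transforms
apply one displacement field to image (bilinear) and mask (nearest
neighbor), so the label set can shrink (border fill) but never grow;
photometric transforms never receive the mask. Parameter names follow the
widely used Albumentations conventions, but each transform is implemented
here on scipy/numpy so the semantics are pinned by this package's tests
rather than a library version. Photometric outputs are
clipped to [0, 1] since inputs are normalized. Parameters are configuration,
not constants — appropriate limits depend on the preprocessing applied.

## Preprocessing

Volumes are resampled along z only, to 2 mm by default, with cubic B-spline
interpolation (SimpleITK); the new slice count is floor(physical extent /
target) + 1. In-plane geometry is handled by the per-slice resize to
256x256 (bilinear for images, nearest for masks), reflecting the 2D
pipeline. Intensities are min-max normalized to [0, 1] per volume after
resampling; an optional HU clipping window precedes normalization and is
off by default (whether windowing should precede normalization is a
protocol choice; per-volume min-max without windowing is the default
reading). A constant volume raises an error rather than returning zeros.
Label maps always travel through nearest-neighbor paths, so preprocessing
can never invent labels.

## The phantom generator

Phantoms emulate the data properties the pipeline depends on, not anatomy
in detail: Hounsfield-like intensities (air -1000, parenchyma about -860
with a mild vertical gradient, soft-tissue shell about +40), anisotropic
spacing with z in the 1-5 mm range, two elliptical lung fields inside a
tapering torso, and exactly five lobes — the left lung split by one fissure
surface, the right by two. Fissure surfaces are tilted planes plus
low-frequency sinusoids over (y, x), expressed as a height fraction of the
lung's z extent. The oblique fissures (separating the lower lobes) tilt
steeply (mean slope 0.45 of the lung height across the anteroposterior
axis) while the right horizontal fissure stays nearly axial — matching real
fissure geometry and, importantly, making lobe boundaries visible inside
axial slices. Fissures image as thin dense sheets (+220 HU Gaussian profile
around the surface), as they do on CT; without that cue, distinguishing the
right-lung lobes from a single 2D slice is nearly impossible and
desk-scale training collapses onto the large classes. Optional lesions are
Gaussian intensity blobs inside a lung (300-800 HU, probability
`lesion_rate` per lung) that never alter labels, emulating consolidations.
Noise is a mixture of smooth (sigma 2) and white Gaussian components with
standard deviation `noise_sd` (default 25 HU).

Labels are deterministic given (spec, seed); lesion and noise streams are
split off the master seed so pathology never perturbs ground truth. A
cleanup pass reattaches stray voxels (discretization at the fissure/rim
junction) to the nearest kept component, so each lobe is always one
connected component; left and right lungs never touch by construction.

What phantoms do not emulate: airways, vessels, incomplete fissures,
pleural effusions, scanner-specific reconstruction kernels, or realistic
inter-patient shape statistics. Tests passing on phantoms therefore verify
the machinery (losses, gradients, geometry handling, policy integrity,
learnability of structured signal) — they do not certify clinical accuracy.

## Numerical and engineering choices

The neural-network machinery is a compact reverse-mode autodiff engine on
NumPy arrays (float32), with convolution as im2col + BLAS matmul and
explicit adjoints for every operator; gradients are verified against finite
differences in the test suite. Adam uses classic L2 weight decay folded
into the gradient. Batch normalization keeps running statistics with
momentum 0.1 and eps 1e-5. Checkpoints are `.npz` weight archives with a
JSON sidecar recording the architecture configuration and training
provenance; loading validates shape compatibility tensor by tensor.

Determinism: every stochastic component (phantom geometry, lesions, noise,
data order, augmentation gating and parameters, permutation sampling,
dropout, initialization) draws from generators fanned out of one master
seed; identical seeds reproduce runs bit-for-bit on the same platform.

Problem sizes in the tests and acceptance script are deliberately small —
phantoms of 16-32 slices at 64-96 px in-plane, encoder widths
(2, 4, 8, 16, 16), a few epochs — chosen so the whole suite runs on a
single CPU core in minutes while still exercising every code path at the
full 256x256 slice resolution the architecture fixes.

## Known limitations

- The published Dice scores of the original study (92.8% combined model on
  a curated clinical dataset) require non-public training data and
  GPU-scale budgets; nothing here reproduces them, and the acceptance
  quantities are properties of the method on phantoms instead.
- The global-MLP jigsaw head is kept for fidelity at full width but is not
  learnable within small step budgets; scaled-down configurations use the
  per-patch readout (see above).
- DICOM support is read-only and assumes a single axial series with uniform
  slice spacing.
- The 2D slice-wise design cannot use through-plane context at inference;
  lobes are reassembled independently per slice.
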