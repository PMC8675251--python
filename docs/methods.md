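# Methods

## The detection problem and the model

The package detects tears in the six anatomical sub-regions of the knee
menisci — anterior horn, body and posterior horn of the medial (MM) and
lateral (LM) meniscus — from a whole 3D image volume, as six simultaneous
binary classifications. Three approaches are implemented and compared:

* **`full_scale`** — a 3D ResNet-50 encoder reads the entire volume; a
  three-layer MLP head emits six tear logits, trained with class-weighted
  binary cross-entropy (BCE).
* **`bb_crop`** — the volume is first cropped to the region of interest
  (RoI) around both menisci (derived from segmentation masks) with a 5%
  margin and resampled to a fixed shape; a dilated residual network
  (DRN-C-26 in 3D) classifies the crop. Needs masks at inference time.
* **`bb_loss`** — the multi-task variant: the same ResNet-50 encoder as
  `full_scale` plus a second MLP head that regresses the 3D bounding boxes
  of both menisci. The auxiliary localisation loss pushes the encoder to
  attend to the meniscal region without any cropping at inference.

### Losses

With targets `y ∈ {0,1}^{N×6}` and logits `ŷ`, the classification loss is

    L_BCE = −(1/N) Σ_c Σ_i w_c [ y_ic log σ(ŷ_ic) + (1−y_ic) log(1−σ(ŷ_ic)) ]

computed with a numerically stabilised log-sigmoid. The leading minus makes
the quantity a proper minimisation objective (nonnegative, zero for perfect
confident predictions). The class weight is the balanced inverse prevalence
`w_c = N/(2·N_pos,c)`, one natural reading of "inverse label frequency";
it multiplies the whole per-class bracket. The trainer substitutes `w_c = 1`
for a class that a very small training split leaves single-valued.

A box is six floats: the relative center and relative size per axis
(voxel indices divided by the axis length). The box head emits 12
sigmoid-activated values (MM box then LM box). Its loss has two terms:

    L_L1   = (1/N) Σ_n Σ_{i=1..12} | b_ni − b̂_ni |
    L_GIoU = 1 − IoU(B, B̂) + |C \ (B ∪ B̂)| / |C|

where `C` is the axis-aligned envelope of both boxes; the GIoU term is
computed per meniscus and averaged over structures then over the batch
(with equal counts the two averaging orders coincide). Zero-size boxes
(possible for single-voxel structures, see below) are clamped to an
epsilon extent of 1e-6 before the ratio. The multi-task objective is the
unit-weighted sum `L = L_BCE + L_L1 + L_GIoU`.

### Architectures

Both encoders are direct 3D translations of their 2D originals, with every
convolution followed by batch normalisation and ReLU and with global average
pooling (GAP) at the end:

* ResNet-50-3D: 7³ stem (stride 2), 3³ max-pool (stride 2), 16 bottleneck
  blocks (1³ reduce / 3³ / 1³ expand ×4) in groups of 3, 4, 6, 3 with group
  strides (1, 2, 2, 2) — total downsampling ×32 — pooled to 2048·width
  features. Group strides follow the original design (the first group after
  the max-pool keeps stride 1), which is what makes the overall factor 32.
* DRN-C-26-3D: 7³ stem (stride 1, 16·width channels); two residual basic
  blocks replacing the max-pool (strides 1 and 2); residual groups of two
  blocks at 64/128·width (stride 2 each); two groups at 256/512·width where
  stride is replaced by dilation 2 and 4; and two final *non-residual*
  de-gridding blocks with dilation 2 then 1. Total downsampling ×8, pooled
  to 512·width features. The level table is spelled out in
  `nets.DRN_C26_LEVELS`.

Heads are three-layer MLPs (in → hidden → hidden → out) with dropout on
both hidden activations; hidden width is 2048 at paper scale. Outputs are
raw logits/coordinates; the assembled model applies the sigmoids.

`width_multiplier` scales every channel count while preserving the block
structure, so reduced-width models remain architecturally faithful
miniatures. A per-axis stride guard drops a stage's stride to 1 on any axis
already collapsed to one voxel, which keeps strongly anisotropic (thin-slab)
volumes processable.

**Initialisation.** Convolution and linear weights are zero-mean normal
with sd `sqrt(2/fan_in)` (the ReLU-corrected scheme); batch-norm scale 1,
shift 0. The *output* layer of each head is additionally scaled by 1e-2 so
the sigmoids start near 0.5 (probabilities at chance, boxes at the grid
center) instead of saturated — without this the box head can receive
essentially no gradient at the start of training.

## Coordinate and preprocessing conventions

* Arrays are indexed `(slice, row, col)`: sagittal slices along axis 0
  (medial → lateral), the in-plane anterior→posterior direction along
  axis 2. Boxes use the same axis order.
* Intensities: per-volume min-max normalisation to [0, 1], then
  standardisation `(v − μ)/σ` with `μ, σ` pooled over all voxels of the
  *training* volumes only; σ is the population sd.
* `box_from_mask` takes the literal per-axis min/max voxel indices:
  center = (max−min)/2 + min, size = max − min, both divided by the axis
  length. The literal size undercounts the inclusive voxel span by one —
  kept because these six values are the regression target; *cropping* uses
  the inclusive span (max − min + 1) so no structure voxel is lost.
* The 5% crop margin is interpreted per axis as a fraction of the RoI
  extent itself (scale-free). Crop shapes for training are the per-axis
  maximum margined extent over the training set rounded to the nearest
  multiple of 16 (half rounds up, floor at 16).
* Trilinear resampling maps target index t to source coordinate
  t·(S−1)/(T−1) (corner-aligned); masks use nearest-neighbour with the same
  mapping.

## Synthetic phantoms

Real sagittal knee MRI with expert sub-region tear readings is access
restricted, so the package generates volumetric phantoms that preserve the
*geometry* of the task: two disjoint crescent structures (annulus sectors
extruded and tapered across slices) in fixed slice-halves of the grid —
medial in the lower half, lateral in the upper — with mildly jittered
centers and radii; sub-regions are thirds of equal extent along the
anterior–posterior axis of each structure's own bounding box. A planted
tear is a thin bright sheet (±1 row around the sub-region's median row)
lying entirely inside the flagged sub-region's support. Intensities are in
arbitrary units (background plateau 120 with smooth texture of amplitude
40, tissue 420, lesion +300 by default, white noise sd 20), so min-max
normalisation is exercised non-trivially; the default contrast makes an
"easy" high-SNR cohort on which near-perfect detection is an appropriate
expectation. Cohorts draw each sub-region's tear flag as an independent
Bernoulli(0.4), matching roughly the prevalence of abnormal menisci in the
knee-osteoarthritis population the method targets. Everything is driven by
one integer seed through `numpy.random.SeedSequence`, so identical seeds
give bit-identical cohorts.

What the phantoms deliberately do **not** emulate: MR physics (sequence
contrast, bias fields, partial volume), anatomical shape variation and
neighbouring structures, tear morphologies (radial/horizontal/vertical),
and reader ambiguity. Passing the end-to-end suite therefore shows the
pipeline is *correct and able to learn localised lesion patterns*, not that
it reaches any particular accuracy on clinical data. One consequence of the
benign background is that the whole-volume baseline suffers no "distracting
context" penalty, so the multi-task and whole-volume variants both
saturate on easy phantoms and their ranking is a near-tie decided by run
noise.

## Training

ADAM (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with separate learning rates for
encoder and heads (default 1e-3 each, within the interval the method was
tuned in), halved every 50 epochs; batch size 4; dropout 0.3 in the heads;
global-norm gradient clipping at 5 (guards the sigmoid-activated box head
from early saturation at aggressive learning rates). The cohort splits
50/15/35% into train/validation/test (counts `round(f·N)` for train and
validation, remainder test), and the returned checkpoint is the epoch with
the lowest validation loss.

Augmentation is applied on-the-fly, each transform independently with
probability 0.5: horizontal flips (mirroring the anterior–posterior axis —
anterior/posterior labels are swapped and boxes recomputed, so the targets
stay truthful); in-plane rotations uniform in ±5°; random crops (up to
20/20/10% per axis for the whole-volume approaches, constrained so no
structure voxel is lost; for `bb_crop`, a crop window sampled between the
tight RoI and a 20%-margined envelope); voxel-wise Gaussian noise
N(0.1, 0.5²); and intensity scaling uniform in [0.9, 1.1]. Intensity
augmentations act on the standardised scale (unit-variance data), where a
noise sd of 0.5 is a perturbation rather than an obliteration; geometric
transforms are applied identically to image and mask, and box targets are
recomputed from the transformed mask.

Fine-tuning continues optimisation from a checkpoint on a new cohort with
both encoder and head weights trainable; normalisation statistics are
refitted on the new cohort's training split. This emulates the transfer of
a model between acquisition protocols (thin-slice isotropic to thick-slice
anisotropic grids).

**Desk-scale configuration.** The reference experiment the tests and the
acceptance script run is: 64 phantoms on a 32×64×64 grid,
quarter-width encoders (width 0.25 → 512 ResNet features) with
proportionally slimmed 512-unit MLP hidden layers, batch 4, 80 epochs
(~6–8 minutes per model on one CPU core). Eighty epochs is where the
slowest sub-regions (the lateral classes, whose slice-position cue must be
encoded into channels before the slice axis is pooled away) reach ceiling
on held-out phantoms.

## Evaluation

Per-sub-region ROC curves and AUC use a threshold sweep over unique scores
with trapezoidal integration and simultaneous tie-steps, which equals the
pairwise Mann–Whitney estimator with half credit for ties. Per-meniscus
and whole-knee ("anywhere") scores are max-aggregations of sub-region
probabilities. In small held-out sets a class (or an aggregate) can be
single-valued; its AUC is reported as NaN rather than an arbitrary number.
Box quality pools the per-meniscus 3D IoU values over the test set and
reports mean, sd, a normal-approximation 95% CI of the mean, and the
fraction above IoU 0.5 ("successful localisation").

## Saliency

A saliency map is the gradient of one sub-region's *pre-sigmoid* logit with
respect to the input volume (the sigmoid's saturation would otherwise wash
maps out), reported as magnitude by default; signed maps via a flag.
SmoothGrad averages maps over 20 augmented copies (noise, intensity
scaling, ±5° rotations, flips; each with probability 0.5 per copy).
Geometric transforms are inverted before averaging so all maps live on the
original grid — and for flipped copies the targeted sub-region index is
mirrored, so every map explains the same anatomical region.

## Numerical notes

* The reverse-mode autodiff engine (`autodiff.py`, `nn.py`) runs in float32
  by default; `using_dtype(np.float64)` switches the working precision,
  which the test suite uses to verify backpropagated gradients against
  central differences below the single-precision noise floor.
* 3D convolution is evaluated as im2col + one BLAS matmul, with the gather
  and scatter inner loops JIT-compiled; the column buffer is cached on the
  tape for the weight gradient.
* The voxelized GIoU oracle rasterises both boxes on a lattice spanning
  their joint extent and counts voxel centers; its deviation from the
  analytic value shrinks as O(1/resolution).
* Ties in elementwise max/min route the gradient to the first argument;
  max-pool ties take the first flat index.
* Training is bit-reproducible for a fixed seed on one machine (numpy BLAS
  single-threaded); across BLAS builds reductions may reorder.

## Known limitations

* Phantom realism as described above; conclusions about clinical data
  require clinical data.
* The engine targets desk-scale models; paper-scale training (width 1.0,
  160×384×384 inputs, GPU cluster) is out of reach by design.
* `bb_crop` augmentation composes the jittered crop with the subsequent
  fixed-margin crop, so the realised context jitter is the intersection of
  the two windows.
* The confidence interval on mean IoU assumes approximate normality of the
  pooled IoU distribution.
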