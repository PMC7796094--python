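# Methods

This note records the scientific and numerical choices behind `lungseg`:
what each stage computes, the parameters that matter, what the phantom
generator does and does not emulate, and the places where the design was
genuinely open.

## Ground-truth extraction

Reference lung masks are produced by a fixed seven-step sequence on
HU-calibrated slices:

1. binarize: pixel = 1 iff HU < **−604** (strict inequality). The
   threshold sits between lung parenchyma (≈ −800 HU and below) and every
   soft-tissue class, and is exposed in `ExtractionParams`;
2. clear border: every foreground component containing a border pixel is
   removed (air surrounding the body also falls below the threshold);
3. label connected components (8-connectivity by default);
4. keep the two largest components — the lungs. Ties are broken toward the
   smaller label id so the step is deterministic;
5. erode with a disk of radius 2 (separates wall-attached structures from
   vessels);
6. close with a disk of radius 10 (re-attaches juxtapleural nodules that
   thresholding carved out of the lung field);
7. fill holes: background components not 4-connected to the border are
   flipped to foreground (recovers intra-lung vessels).

Structuring elements are discrete Euclidean disks
`{(dy,dx): dy²+dx² ≤ r²}`. Erosion and dilation treat out-of-frame pixels
as background. Closing is defined as `erode(dilate(mask))` computed on the
infinite-plane embedding — the mask is padded by one radius before the
composition and cropped after — because clipping the intermediate dilation
at the frame would violate extensivity and idempotence for foreground near
the border. Connectivity is 8 for labelling/border clearing and 4 for the
hole-filling background, the standard pairing that prevents diagonal
leaks from holes to the border; both are configurable.

An empty final mask is returned with a `needs_review` flag rather than
raised: threshold/morphology extraction is expected to fail on some real
slices (it does, by construction, on an all-air slice), and those slices
are candidates for manual mask editing, which is out of scope here beyond
the flag.

Erosion (step 5) feeds closing (step 6) in strict sequence. A consequence
worth stating: any foreground within the erosion radius (2 px) of the lung
wall is removed and cannot be recovered by the later closing, which
bridges at the eroded boundary. The recovered mask is therefore the lung
field minus a ~2 px boundary ring; on the default phantom geometry this
caps the achievable Dice against exact truth at about 0.96.

## The phantom generator

`PhantomSpec` renders axial-chest geometry as ellipses: a body-wall
ellipse (default +40 HU) on an air background (−1000 HU) containing two
lung ellipses (−800 HU), a configurable number of bright vessel disks
(0 HU) well inside the lungs, and optionally one nodule disk (+20 HU)
abutting the left lung wall. Gaussian HU noise (default sd 20 HU) is added
everywhere; 20 HU is small against the ≈ 200 HU gap between lung HU and
the −604 threshold, which keeps the thresholding regime realistic but
solvable. Ground truth is the union of the lung ellipses and the nodule
disk, vessels included, known exactly by construction.

Because the extraction pipeline erodes before it closes, a nodule that
crosses the lung boundary can never be recovered in full — its outer
sliver lies in the irrecoverable boundary ring. The generator therefore
places the nodule strictly inside the wall with a clearance of
`erosion radius + 2 = 4 px` (one pixel of margin for discrete-grid
rounding): the disk abuts the wall, its threshold bite stays an enclosed
hole, and hole-filling recovers it exactly. This is the package's
definition of "wall-attached", chosen so that full nodule recovery is a
guaranteed property of the working regime rather than a statistical one.

Cohorts jitter ellipse centres (±3 % of the frame per unit jitter), axes
(±10 %), nodule angle and radius, with per-sample seeds derived
deterministically from the cohort seed (sample 0 reuses the seed
unchanged, so a jitter-free cohort of one equals the single-phantom call).
The phantoms deliberately do **not** emulate: textured parenchyma, the
trachea and airways, partial-volume boundary blur, scanner artefacts, bed
and cable structures, or 3-D continuity between slices. Tests passing on
phantoms demonstrate the pipeline's correctness in its intended regime —
HU-separable anatomy with clean borders — not clinical-grade performance
on real CT.

## Channel engineering

Channel 0 is the HU image clipped to a lung display window (default
[−1000, 400] HU, a standard choice; the normalization window is not
otherwise constrained) and min-max scaled to [0, 1]. Channel 1 is a Canny
edge map of that normalized image: Gaussian smoothing (sigma 2), gradient
magnitude, non-maximum suppression, and hysteresis thresholds defaulting
to the 70th/90th percentiles of the gradient magnitude — the detector's
parameters are not fixed by the method, so all are exposed. Channel 2
dilates (disk radius 2, exposed) a binary image whose lung region is black
(0) and everything brighter white (1); the dilation removes small dark
specks around the lung and shrinks the dark field slightly. Note the
polarity of this binarization is intentionally inverted relative to the
ground-truth binarization of step 1 above; internally masks always use
lung = 1, and rasters store lung as 255. A `replicate_default_channels`
arm puts the normalized original in all three channels for the
channel-scheme ablation.

## Network

The encoder follows ResNet-34: 7×7 stride-2 stem convolution + BN + ReLU,
3×3 stride-2 max-pool, then residual stages of 3/4/6/3 two-conv basic
blocks at 64/128/256/512 channels — five spatial halvings, hence input
sides must be divisible by 32. Identity shortcuts are added to block
outputs; stage transitions use a 1×1 projected shortcut. Skip features are
tapped at the four stage outputs (64/128/256/512 channels) and at the stem.

The bottleneck takes the deepest feature through three conv-BN-ReLU
blocks; in dense mode each block's input is the concatenation of all
previous block outputs (two concatenation junctions — features combine by
concatenation, never summation), otherwise the blocks are plainly stacked.

Each decoder level performs: nearest-neighbour ×2 upsampling → 3×3
projection convolution to the level's channel count → batch normalization
→ BConvLSTM fusion with the same-resolution encoder feature → 3×3
conv-BN-ReLU. The deepest level fuses the bottleneck output with the
512-channel encoder feature at the same resolution (no upsampling), giving
one fusion per tapped stage. In the BConvLSTM the encoder and decoder maps
form a length-2 sequence processed by two independent convolutional LSTMs
(kernel 3×3, hidden channels equal to the level's channel count, zero
initial state), one reading (encoder, decoder) and one the reverse; the
two final hidden states are concatenated. With the fusion disabled the two
maps are simply concatenated — either way the following convolution sees
2× channels. The stem-level skip is always a plain concatenation, and a
final upsampling + 3×3 conv + 1×1 conv produce single-channel logits; the
sigmoid is applied at the interface, and losses are computed on logits for
numerical stability.

Training choices not fixed by the architecture: Adam (default learning
rate 1e−4) on binary cross-entropy, with soft-Dice and BCE+Dice
selectable; He initialization from a seeded generator; batch statistics in
training mode and running statistics (momentum 0.1) at inference;
prediction threshold 0.5. The default epoch budget is 50 with batch size
32; desk-scale experiments in the tests and the acceptance script use 40
training phantoms at 64×64, batch 8, learning rate 1e−3, BCE+Dice, and at
most 10 epochs with optional early stopping once held-out Dice reaches
0.90 — sizes chosen so a full run fits in minutes on one CPU while still
demonstrating learnability. Encoder weights can be loaded from an
explicitly supplied `.npz` file (nothing is downloaded); random seeded
initialization is the default so the package is self-contained. Training
is bitwise deterministic for a fixed seed on a given BLAS.

## Evaluation

Lung (mask value 1) is the positive class throughout — precision and
recall therefore describe the lung field, not background. Metrics with a
zero denominator return NaN ("undefined") instead of raising. Dice of two
empty masks is defined as 1 (perfect agreement on emptiness). Dataset
reports pool pixel counts into a single confusion matrix by default
(per-image averaging is available behind a flag); under pooling F1 and
Dice coincide identically. ROC/AUC pools all pixels across images, sweeps
every distinct score threshold, and integrates by the trapezoid rule; a
single-class pool yields NaN.

## Known limitations

- The phantom's geometric simplicity means extraction failures seen on
  real CT (trachea retention, closure bridging into the mediastinum) are
  exercised only indirectly; the inter-lung gap is kept wider than the
  closing diameter so the two lungs never merge.
- The autodiff engine implements exactly the ops this network needs; it is
  not a general-purpose framework, and large inputs (512×512) are
  supported for inference-scale use but impractical to train on CPU.
- Multi-frame DICOM and 3-D volumes are rejected by design; one slice per
  file.
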