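# lungseg

Automatic lung-parenchyma segmentation of axial chest CT slices, built as a
complete, testable pipeline:

1. **Semi-automatic ground-truth extraction.** Lung CT archives rarely ship
   with binary lung masks. On Hounsfield-unit (HU) calibrated slices the
   lungs are dark (≈ −800 HU) against the body wall (≈ +40 HU), so reference
   masks can be produced by thresholding and morphology: binarize at
   −604 HU (`Binary(i,j) = 1 if f(i,j) < T`), remove blobs touching the
   image border, label connected components, keep the two largest (the
   lungs), erode with a disk of radius 2, close with a disk of radius 10
   (to retain juxtapleural nodules), and fill enclosed holes (vessels).
   Slices where this fails are flagged for manual review.
2. **Engineered three-channel inputs.** Each slice is re-expressed as an
   H×W×3 stack — normalized original image, Canny edge map, and the
   dilation of a lung-black binary image — so the network trains on inputs
   that already emphasise lung boundaries and suppress background clutter.
3. **Res BCDU-Net.** A U-shaped network whose encoder is the ResNet-34
   layout (residual stages of 3/4/6/3 basic blocks, feature channels
   doubling 64 → 128 → 256 → 512), whose bottleneck is three convolutional
   blocks joined by dense *concatenation* (not summation), and whose
   decoder fuses each upsampled feature map with the same-resolution
   encoder feature through a **bidirectional convolutional LSTM**
   (BConvLSTM): the two maps form a length-2 sequence read once forward
   and once backward with independent parameters, and the two final hidden
   states are concatenated. A 1-channel sigmoid head yields per-pixel lung
   probabilities. Both the dense bottleneck and the BConvLSTM fusion can be
   switched off for ablation runs.
4. **Pixel-level evaluation.** Confusion counts with lung as the positive
   class, accuracy / precision / recall / F1, the Dice coefficient
   `DSC = 2|E∩Q| / (|E|+|Q|)`, and a pooled-pixel ROC curve with
   trapezoidal AUC.

Because the intended CT archives are external and training at clinical
resolution needs GPU-scale compute, the package ships a **synthetic phantom
generator**: HU-calibrated slices with two elliptical lung fields inside a
body-wall ellipse, bright intra-lung vessels, optional wall-abutting
nodules, and Gaussian HU noise — with ground truth known exactly by
construction. Every stage of the pipeline is exercised end to end on these
phantoms, on a CPU, in minutes.

The network itself runs on a compact reverse-mode autodiff engine written
in numpy (`lungseg.nn`): im2col convolutions through BLAS GEMM, batch
normalization, max-pooling, nearest-neighbour upsampling, convolutional
LSTMs, and Adam — fully deterministic under a seed.

## Worked example

```python
from lungseg import (PhantomSpec, generate_phantom, extract_lung_mask,
                     assemble_channels, confusion, metrics, dice)

spec = PhantomSpec(seed=11, attach_nodule=True, nodule_radius=6.0)
ct, truth = generate_phantom(spec)          # 256x256 HU slice + exact mask

result = extract_lung_mask(ct)              # the 7-step threshold/morphology GT
print(dice(result.mask, truth))             # 0.9639
print(result.n_components, result.needs_review)  # 2 False

print(metrics(confusion(result.mask, truth)))
# {'accuracy': 0.979, 'precision': 1.0, 'recall': 0.9304, 'f1': 0.9639}

img = assemble_channels(ct)                 # (256, 256, 3) network input
```

The extracted mask overlaps the exact phantom truth with Dice 0.964: the
precision of 1.0 means no background pixel leaks into the mask, and the
recall of 0.930 reflects the thin boundary ring removed by the erosion
step. Two connected components — the two lungs — survive labelling, and
the slice needs no manual review. Training the network on such engineered
inputs is a few more lines (see `lungseg.network.train`); on 40 phantom
pairs at 64×64 it reaches held-out Dice > 0.9 within ten epochs on one CPU.

A command-line interface mirrors the library:

```bash
lungseg simulate   --seed 3 --out sim -n 20       # phantom DICOMs + masks
lungseg make-masks --input sim --out masks        # 7-step GT extraction
lungseg preprocess --input sim --out pre          # three-channel stacks
lungseg train      --images pre --masks sim --out run --config config.json
lungseg predict    --checkpoint run/checkpoint.npz --images pre --out preds
lungseg evaluate   --pred preds --truth sim --out scores
```

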