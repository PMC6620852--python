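# myoseg

Whole-slide skeletal muscle fiber segmentation with a hierarchically
connected encoder / multi-decoder network.

## The problem

Quantifying muscle fiber morphology (cross-section area, shape, minimum
Feret diameter) from H&E-stained histology requires segmenting every
individual fiber. Muscle cross-sections are hard: fibers pack tightly
into fascicles, the connective-tissue bands separating them are thin and
frequently blurred or broken by staining artifacts, and slide-to-slide
color variation is large. Patch-classification methods are far too slow
for gigapixel whole-slide scans.

`myoseg` implements a fully convolutional approach that produces the
dense segmentation of an arbitrarily sized input in a single forward
pass:

* **Network** — a VGG-16-style encoder (13 convolutional layers in five
  blocks, fully connected layers dropped) with a decoder attached before
  each max-pooling layer. Decoder *i* taps the *i*-th block and restores
  full resolution through *i* − 1 steps of learnable stride-2 transposed
  convolution, each followed by a 3×3 convolution. The five one-channel
  decoder outputs are concatenated and merged by a 1×1 convolution;
  every head (5 decoders + fused) carries its own loss, minimized
  jointly (deep supervision).
* **Spatially weighted loss** — per-pixel cross-entropy weighted by
  `f(X_i) = C(Y_i)⁻¹ · exp(max(ε − Ω_i, 0)/η₁) · 1[|Y_i − P_i| < η₂]`,
  where `C(Y_i)` is the label frequency of pixel *i*'s class, `Ω_i` is
  the Euclidean distance to the nearest fiber contour (ε = 10 px,
  η₁ = 5 px), and the last factor is a dynamic switch (η₂ = 0.6) that
  excludes pixels whose label the network contradicts with high
  confidence — treating them as probable annotation errors.
* **Two-stage training** — stage 1 trains the network to detect fiber
  boundaries (an edge-detection pretext close to what pretrained
  low-level filters already support), stage 2 fine-tunes the same
  parameters on the fiber masks, preserving the boundary sensitivity
  that separates touching fibers. SGD with momentum 0.9, minibatch 2,
  learning rate 1e-6 (÷10 every 1e4 iterations) in stage 1 and 1e-7 in
  stage 2; augmentation is 30 random 300×300 crops per training image.
* **Evaluation** — per-fiber precision `|S∩G|/|S|`, recall `|S∩G|/|G|`
  and F1, averaged over the fibers of each image, reported at a fixed
  threshold (FT: one threshold maximizing mean F1 over the test set) and
  dynamic thresholds (DT: best threshold per image).
* **Whole-slide inference** — any input ≥ 32 px per side in one pass;
  large slides are processed as overlapping tiles with probability
  averaging in the overlaps (automatic above 2048 px per side).

Real annotated muscle datasets are rarely public, so the package ships a
seeded synthetic generator (`myoseg.fixturegen`) producing muscle-like
images — Lloyd-relaxed Voronoi fibers separated by thin bands, H&E-like
coloring with per-fiber jitter, rim nuclei, and a configurable fraction
of *broken* boundary pixels — with exact masks and boundary maps. The
entire pipeline is exercisable end-to-end on these fixtures.

The network and training loop run on a small numpy reverse-mode autodiff
engine included in the package (`myoseg.autodiff`); there is no GPU or
deep-learning-framework dependency, and a `width_multiplier` scales all
channel counts so that desk-scale variants train on a CPU in minutes.

## Worked example

```python
import numpy as np
from myoseg import (ModelConfig, build_model, make_dataset, make_crops,
                    run_two_stage, predict_image, ft_dt_summary, load_manifest)
from myoseg.training import desk_profile
from PIL import Image
from scipy import ndimage

manifest = make_dataset(50, size_range=(128, 128), out_dir="ds", seed=11,
                        split_ratio=0.8, mean_fiber_area=2000)
crops = make_crops(manifest, crops_per_image=4, crop_size=96, seed=12)
model = build_model(ModelConfig(width_multiplier=0.125), seed=13)
run_two_stage(model, crops, *desk_profile(300, 300), seed=14)

records = [r for r in load_manifest(manifest) if r.split == "test"]
probs = [predict_image(model, np.asarray(Image.open(f"ds/{r.path_image}"))) for r in records]
gts = [ndimage.label(np.asarray(Image.open(f"ds/{r.path_mask}").convert("L")) > 127,
                     structure=np.ones((3, 3)))[0] for r in records]
s = ft_dt_summary(probs, gts)
print(f"FT(t={s.ft_threshold:.2f}) F1 {s.ft['f1'][0]:.3f}  DT F1 {s.dt['f1'][0]:.3f}")
```

Output from this exact run (a 1/8-width model, 40 training images,
300 + 300 iterations, ~5 min on one CPU core):

```
FT(t=0.95) F1 0.953  DT F1 0.956
```

i.e. after boundary pretraining and mask fine-tuning, the held-out
fiber-averaged F1 reaches ~0.95 on the synthetic benchmark, with the
dynamic-threshold mode at least matching the fixed-threshold mode (it
does so by construction).

The same pipeline is available from a shell:

```bash
myoseg synth --n-images 50 --min-size 128 --max-size 128 --out-dir ds --seed 11
myoseg train --manifest ds/manifest.tsv --run-dir run --width-multiplier 0.125 \
             --crops-per-image 4 --crop-size 96 --iterations1 300 --iterations2 300 \
             --lr1 3e-7 --lr2 3e-7 --clip-grad-norm 1e5 --switch-warmup 100
myoseg evaluate --checkpoint run/model.npz --manifest ds/manifest.tsv --out-dir eval
myoseg predict  --checkpoint run/model.npz --image ds/img_0040.png --out-dir pred
```

See `examples/` for one short narrative script per capability and
`docs/methods.md` for the model, parameter and design details.

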