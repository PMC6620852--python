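# Methods

This note documents the model, its parameters, the synthetic data the
package is validated on, and the design decisions taken where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model

The network is a fully convolutional encoder/multi-decoder design. The
encoder is the 13-convolution trunk of VGG-16 (blocks of 64, 128, 256,
512, 512 channels; 3×3 kernels, ReLU, 2×2/stride-2 max-pooling between
blocks). A decoder taps the last convolution of each block, *before*
the following pool, so the five decoders see representations at scales
1, 1/2, 1/4, 1/8 and 1/16 of the input. Decoder *i* applies a 3×3
convolution to a fixed working width, then *i* − 1 refinement steps of
[stride-2 transposed convolution (kernel 4, padding 1 — exact ×2),
3×3 convolution, ReLU], a 3×3 convolution to one channel, and a crop to
the input size. The five one-channel maps are concatenated (a
5-channel map) and merged by a 1×1 convolution. A sigmoid on each
decoder map and on the merged map yields six probability maps; each
carries the same loss and all are minimized jointly, so gradients on
shared encoder features accumulate from every consuming head.

Inputs are RGB images normalized to [−0.5, 0.5], reflect-padded to
multiples of 32 and cropped back after the forward pass, so any input
with both sides ≥ 32 px produces input-sized maps.

### Free architectural parameters

The per-layer widths of the decoders are not externally constrained, so
the decoder working width is a declared parameter (`decoder_channels`,
default 64). Transposed convolutions are initialized to bilinear
interpolation; other layers use He-normal initialization (appropriate
for ReLU). `width_multiplier` (default 1.0) scales every channel count
to `max(1, round(c·m))`; 0.125 is the desk-scale variant used in the
tests (~260 k parameters instead of ~17 M). A VGG-16 encoder checkpoint
can be loaded into the width-1 model (`load_pretrained_encoder`);
loading is optional and no weights ship with the package.

## Loss

For one probability map `P` and binary target `Y` the loss is the
pixel sum

    J = − Σ_i f(X_i) [ 1(Y_i = 1) log P_i + 1(Y_i = 0) log(1 − P_i) ]
    f(X_i) = C(Y_i)⁻¹ · exp(max(ε − Ω_i, 0)/η₁) · 1[|Y_i − P_i| < η₂]

* `C(Y_i)` — frequency of pixel *i*'s class **within the crop**
  (floored at 1e-6 for an absent class). Computing it per crop rather
  than over the corpus matches the precomputed per-sample weight maps
  the training loop consumes, and adapts the balance to local fiber
  density.
* `Ω_i` — Euclidean distance (pixel centers, 0-based row-major
  coordinates) to the nearest fiber-contour pixel. A contour pixel is a
  fiber pixel with at least one in-image 4-neighbor of the opposite
  class; a crop without fibers gets the +∞ sentinel (all pixels beyond
  ε). The exponential term is `e^(ε/η₁)` on the contour and decays to
  exactly 1 at distance ε — errors near boundaries, where touching
  fibers merge, are amplified; everything else is weighted by class
  balance alone. Defaults ε = 10 px, η₁ = 5 px. η₁ controls the decay
  sharpness and is a free parameter of this implementation; the
  clamped-exponential form is the monotone parameterization consistent
  with "high weight near the contour, exactly 1 beyond ε".
* The **switch** `1[|Y_i − P_i| < η₂]`, η₂ = 0.6, models annotation
  noise: a pixel whose label the network contradicts with probability
  gap ≥ η₂ is removed from the loss value *and* gradient (the forward
  pass still computes P there). The switch is recomputed every
  iteration from the fused map only and applied identically to all six
  heads, keeping the heads' supervision consistent; nothing in the
  formulation requires per-head gates, and a single gate is the simpler
  choice.
* The first two factors depend only on ground truth and are precomputed
  per crop into a **static weight map** (stored as float32; exposed as
  TIFF by the `prepare` CLI command). The six per-head losses are
  summed with equal weight — no coefficients are introduced.

Two numerical forms are provided. The probability-space form
(`objective.weighted_bce`) clamps P to [1e-7, 1 − 1e-7] before the
logarithms and returns the analytic gradient ∂J/∂P. The training loop
instead evaluates the identical quantity in logit space
(`autodiff.weighted_bce_logits_sum`): the value via softplus, the
gradient exactly `f·(P − Y)` on the logits. The logit form matters: at
saturated sigmoid outputs the probability-space clamp flattens the
gradient to zero, which can permanently lock a diverged network into an
all-one-class prediction, while the logit-space gradient stays alive.
The two forms agree to float32 precision wherever both are defined
(tested).

### Switch warm-up

Applied literally from iteration 0, the switch has two failure modes
observed on the synthetic benchmark: (i) under strong class imbalance,
a network drifting toward the majority class crosses the η₂ gap on the
minority pixels, which then gate themselves off — the degenerate
"predict majority, discard minority" state is self-reinforcing; (ii) at
the stage-1 → stage-2 handoff the network still predicts boundary-task
outputs, so most mask-target pixels start beyond the gap and training
freezes. Both are cold-start artifacts: the switch's premise — that a
confidently contradicted label signals *annotation* error — only holds
once the network is broadly correct. Schedules therefore carry a
`switch_warmup` count (default 0, i.e. the literal formulation; the
desk profile uses 100) during which the gate is held open.

## Training

Stage 1 trains on boundary maps (fiber-contour bands), stage 2
fine-tunes the same parameters on fiber masks; stage 2 starts from the
exact stage-1 parameters and the architecture never changes. Stage-1
weight maps are built from the boundary target with the same machinery
(class balance over boundary/non-boundary, distances to the boundary
band's own contour): the weighting scheme is target-agnostic.
Optimization is SGD with classical momentum over shuffled minibatches.

Paper-scale defaults: 30 random 300×300 crops per training image,
learning rate 1e-6 (divided by 10 every 1e4 iterations), momentum 0.9,
minibatch 2, stage 2 at 1e-7 with the rest unchanged. Iteration budgets
are configurable (defaults 2e4 / 1e4; no stopping criterion beyond the
budget). Augmentation is random cropping only; flips/rotations are
deliberately not applied by default. A non-finite loss aborts with a
diagnostic snapshot rather than continuing.

**Desk-scale profile** (`training.desk_profile`): 300 + 300 iterations,
learning rate 3e-7 in both stages, global gradient-norm clipping at
1e5, switch warm-up 100. Clipping is needed because the loss is a pixel
*sum*: on a freshly initialized (non-pretrained) encoder its gradient
norm is ~1e6 and varies by orders of magnitude between batches, and no
fixed learning rate is simultaneously stable and fast without a bound.
The equal stage-2 rate (rather than the paper-scale ÷10) reflects that
desk-scale stage 2 must undo the boundary pretext in 300 iterations
rather than gently fine-tune a converged model. These values were
chosen from stage-wise loss curves on the generator's default
conditions and then frozen.

## Synthetic data

The generator emulates the structural challenges of H&E muscle
cross-sections, not their optics:

* **Geometry** — n uniformly sampled sites with a minimum-distance
  constraint, two Lloyd relaxation iterations, Voronoi assignment, and
  erosion of each cell by half the boundary width (border treated as
  foreign). This yields packed convex-ish fibers separated by a
  label-0 band of controlled width (default 3 px), the "tightly grouped"
  morphology that makes instance separation hard. Ground truth: mask =
  fiber interiors, boundary map = the band; mutually exclusive by
  construction. Impossible packings (a cell vanishing under erosion)
  raise instead of silently producing fewer fibers.
* **Appearance** — eosin-pink fiber interiors with per-fiber color
  jitter (±18 per channel), collagen-white band, hematoxylin-dark
  nuclei scattered along fiber rims (3 per fiber), global brightness
  wobble (±8 %) and per-pixel Gaussian noise (σ = 6). The default
  **boundary_break_rate = 0.15** recolors 15 % of band pixels as the
  adjacent fiber interior — the broken/unstained boundaries that cause
  merge errors.
* **Dataset** — image sides drawn from a size range (paper-like default
  500–1500 px; the desk benchmark uses 128 px), fiber count scaled to
  image area around a mean fiber cross-section of 6000 px² (2000 px² at
  desk scale), 80/20 train/test split, plain-text TSV manifest, PNG
  images and {0,255} PNG masks. Everything is a deterministic function
  of the arguments and seed.

What the fixtures do **not** model: real stain spectra and optics,
fiber-type heterogeneity, fascicle-scale organization, out-of-focus and
tissue-fold artifacts, annotation error. Consequently, passing the
desk-scale benchmark shows the pipeline learns and evaluates correctly
end-to-end on data with the right structure; it does not certify
accuracy on real slides. Notably, on these fixtures color alone almost
separates fiber from band, so the mask-only ablation can match or
exceed two-stage training — the pretext's advantage (exploiting
pretrained edge detectors, preserving weak boundaries) targets real
histology; the benchmark only requires two-stage training to be
non-inferior within a small margin.

## Evaluation protocol

Probability maps are thresholded (`P ≥ t`), 8-connected components
smaller than `min_area` (default 30 px) are discarded, and each ground
truth fiber G is matched to the predicted region S with the largest
pixel overlap (ties → lowest predicted label). Per fiber,
P = |S∩G|/|S| and R = |S∩G|/|G| (0 without overlap); image-level P and
R are fiber means and F1 = 2PR/(P+R) is computed from the image means
(averages first, then F1). FT reports metrics at the single grid
threshold (grid step 0.01 on [0, 1]) maximizing mean F1 across images;
DT lets each image use its best-F1 threshold. Reported as mean ± σ over
images. Images without ground-truth fibers are excluded with a warning.
The matching rule, tie-break and min-area filter are declared here for
reproducibility; they are not externally fixed.

## Inference

Single-pass for anything that fits in memory; above 2048 px per side
(or on request) the image is processed in overlapping tiles (default
1024 px, overlap 64 px, overlap < tile/2 enforced) and probabilities
are averaged where tiles overlap. Overlap-averaging was chosen over
center-crop stitching as the simplest scheme with bounded seam
artifacts; the tiled-vs-untiled mean absolute difference is measured by
the test suite and the acceptance script.

## Numerical choices and degenerate inputs

* float32 arithmetic throughout the network; loss values accumulated in
  float64; the probability-space loss API computes in float64.
* Probability clamp 1e-7; class-frequency floor 1e-6.
* Max-pooling ties resolve to the first maximum (scan order); its
  gradient goes to that pixel only.
* Empty mask → all-zero boundary map and +∞ distance sentinel (no
  error). Zero training iterations → model bit-identical. Images
  smaller than the crop are reflect-padded with a logged warning.
* Checkpoints are single-file `.npz` archives with a version tag and
  the embedded model configuration.

## Problem sizes used by the test suite and acceptance script

The desk-scale benchmark trains the 1/8-width model on 40 synthetic
128×128 images (4 crops of 96×96 each), 300 + 300 iterations, and
evaluates on 10 held-out images; the ablation uses 600 mask-only
iterations from the same initialization. The augmentation-arithmetic
check uses 400 images of 64 px and 30 crops each. Oracle checks run on
16×16–48×48 grids where exhaustive recomputation is exact. These sizes
are the package's declared desk-scale study conditions.

## Known limitations

* CPU-only; the full-width model at paper-scale iteration counts is not
  practical to train with this engine (the desk profile is the
  supported regime; the full architecture is still constructed,
  checked, and usable for inference).
* The switch term requires warm-up to avoid the cold-start pathologies
  described above; with `switch_warmup=0` the literal formulation is
  used and can collapse on strongly imbalanced targets.
* σ in the FT/DT summaries is over images (the per-image metric is
  already a fiber average).
* No pyramidal slide formats (SVS/NDPI); plain PNG/TIFF only.
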