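"""Two-stage training of a desk-scale model on synthetic images.

Stage 1 teaches the network to detect inter-fiber boundaries (an
edge-detection pretext close to what generic low-level filters support);
stage 2 fine-tunes the same parameters on fiber masks.  This shortened
demonstration uses ~2 minutes of CPU; raise the iteration counts for the
accuracy shown by the full desk-scale benchmark (scripts/acceptance.py).
"""

import numpy as np

from myoseg import ModelConfig, build_model, make_crops, make_dataset, run_two_stage
from myoseg.training import desk_profile

manifest = make_dataset(
    12, size_range=(128, 128), out_dir="scratch/example_train", seed=3, mean_fiber_area=2000
)
crops = make_crops(manifest, crops_per_image=4, crop_size=96, seed=4)
print(f"{len(crops)} training crops of 96x96 with precomputed weight maps")

model = build_model(ModelConfig(width_multiplier=0.125), seed=5)
print(f"model: 1/8-width variant, {model.n_parameters():,} parameters, "
      f"{len(model.decoders)} decoders")

schedule1, schedule2 = desk_profile(stage1_iterations=80, stage2_iterations=80)
history = run_two_stage(model, crops, schedule1, schedule2, seed=6)

for stage in ("stage1", "stage2"):
    h = history[stage]
    first = np.mean([e["total_mean"] for e in h[:10]])
    last = np.mean([e["total_mean"] for e in h[-10:]])
    print(f"{stage}: weighted loss per pixel {first:.2f} -> {last:.2f} "
          f"(gated-off fraction at the end: {h[-1]['excluded_fraction']:.3f})")
# the per-pixel loss is the minimized sum rescaled for readability; the
# drop within each stage shows the boundary pretext and the mask
# fine-tuning both making progress from their respective starting points
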