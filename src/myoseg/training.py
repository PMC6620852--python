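"""Crop augmentation and the two-stage training procedure.

Training follows a boundary-then-mask transfer strategy: stage 1 teaches
the network to detect the thin inter-fiber boundary bands — a task close
to the generic edge detection that pretrained low-level filters already
support — and stage 2 fine-tunes the same parameters on the fiber masks,
preserving the learned boundary sensitivity that separates touching
fibers.  Both stages minimize the spatially weighted cross-entropy of
:mod:`myoseg.objective` with SGD + momentum; the stage-1 weight maps are
built from the boundary target with the same machinery (class balance
over boundary/non-boundary pixels), since the weighting is
target-agnostic.

The paper-scale defaults are: 30 random 300x300 crops per training image,
stage 1 at learning rate 1e-6 (divided by 10 every 1e4 iterations),
momentum 0.9, minibatch 2; stage 2 identical but at 1e-7.  The
``desk_profile`` helper returns a configuration sized for CPU runs on
small synthetic images (reduced crops, iterations in the hundreds, and a
learning rate rescaled for the smaller pixel-sum gradients).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

from . import autodiff as ad
from .autodiff import Tensor
from .fixturegen import ManifestRecord, load_manifest
from .network import HCNet, normalize_image, pad_to_multiple, save_checkpoint
from .nn import SGD
from .objective import DEFAULT_ETA2, switch_mask
from .targets import DEFAULT_EPSILON, DEFAULT_ETA1, TargetKind, static_weight_map

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSchedule",
    "AnnotatedSample",
    "make_crops",
    "train_stage",
    "run_two_stage",
    "desk_profile",
]


@dataclass(frozen=True)
class TrainingSchedule:
    """Optimization hyperparameters for one training stage."""

    stage: int
    lr: float
    max_iterations: int
    lr_decay_every: int = 10_000
    lr_decay_factor: float = 10.0
    momentum: float = 0.9
    batch_size: int = 2
    #: iterations at the start of the stage during which the dynamic switch
    #: is held open (all pixels participate).  The switch models annotation
    #: noise as "confidently contradicted labels"; before the network is
    #: broadly correct — in particular right after the boundary->mask target
    #: handoff — that signal is spurious and gating on it can silence an
    #: entire class, freezing training.
    switch_warmup: int = 0
    #: optional global gradient-norm ceiling; the loss is a pixel sum, so
    #: raw gradient norms scale with crop area and class weights, and
    #: from-scratch desk runs need a bound to train at a useful rate
    clip_grad_norm: Optional[float] = None

    def __post_init__(self):
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def lr_at(self, iteration: int) -> float:
        """Learning rate used for ``iteration`` (0-based)."""
        return self.lr / self.lr_decay_factor ** (iteration // self.lr_decay_every)

    @classmethod
    def stage1(cls, max_iterations: int = 20_000, lr: float = 1e-6, **kw) -> "TrainingSchedule":
        return cls(stage=1, lr=lr, max_iterations=max_iterations, **kw)

    @classmethod
    def stage2(cls, max_iterations: int = 10_000, lr: float = 1e-7, **kw) -> "TrainingSchedule":
        return cls(stage=2, lr=lr, max_iterations=max_iterations, **kw)


def desk_profile(
    stage1_iterations: int = 300,
    stage2_iterations: int = 300,
    lr1: float = 3e-7,
    lr2: float = 3e-7,
    clip_grad_norm: float = 1e5,
    switch_warmup: int = 100,
) -> tuple[TrainingSchedule, TrainingSchedule]:
    """Schedules for CPU-scale from-scratch runs on small synthetic crops.

    Compared with the paper-scale schedules these shorten both stages to
    hundreds of iterations, clip the global gradient norm (the pixel-sum
    loss on a freshly initialized encoder produces norms ~1e6), and hold
    the dynamic switch open for the first iterations of each stage."""
    return (
        TrainingSchedule.stage1(max_iterations=stage1_iterations, lr=lr1,
                                clip_grad_norm=clip_grad_norm, switch_warmup=switch_warmup),
        TrainingSchedule.stage2(max_iterations=stage2_iterations, lr=lr2,
                                clip_grad_norm=clip_grad_norm, switch_warmup=switch_warmup),
    )


@dataclass
class AnnotatedSample:
    """One training crop: image, mask Y, boundary map B, static weight maps."""

    image: np.ndarray  # (h, w, 3) uint8
    mask: np.ndarray  # (h, w) uint8 in {0, 1}
    boundary: np.ndarray  # (h, w) uint8 in {0, 1}
    weight_mask: np.ndarray  # static weights for the mask target
    weight_boundary: np.ndarray  # static weights for the boundary target
    source: str = ""
    origin: tuple = (0, 0)  # top-left crop coordinate in the source image

    def target(self, kind: TargetKind) -> tuple[np.ndarray, np.ndarray]:
        if TargetKind(kind) is TargetKind.BOUNDARY:
            return self.boundary, self.weight_boundary
        return self.mask, self.weight_mask


def _load_binary(path: Path) -> np.ndarray:
    return (np.asarray(Image.open(path).convert("L")) > 127).astype(np.uint8)


def _reflect_to(arr: np.ndarray, size: int) -> np.ndarray:
    ph = max(0, size - arr.shape[0])
    pw = max(0, size - arr.shape[1])
    if not ph and not pw:
        return arr
    pad = ((0, ph), (0, pw)) + ((0, 0),) * (arr.ndim - 2)
    return np.pad(arr, pad, mode="reflect")


def make_crops(
    manifest: str | Path | list[ManifestRecord],
    crops_per_image: int = 30,
    crop_size: int = 300,
    seed: int = 0,
    split: str = "train",
    eta1: float = DEFAULT_ETA1,
    epsilon: float = DEFAULT_EPSILON,
) -> list[AnnotatedSample]:
    """Random crops with aligned targets and precomputed static weight maps.

    Draws ``crops_per_image`` random ``crop_size`` x ``crop_size`` crops
    from every image of the requested split; crop coordinates are
    deterministic given the seed.  Undersized images are reflect-padded
    first (with a logged warning).  Each crop carries static weight maps
    for both the mask and the boundary target.
    """
    if isinstance(manifest, (str, Path)):
        base = Path(manifest).parent
        records = load_manifest(manifest)
    else:
        base = Path(".")
        records = list(manifest)
    records = [r for r in records if r.split == split]
    rng = np.random.default_rng(seed)
    crops: list[AnnotatedSample] = []
    for rec in records:
        image = np.asarray(Image.open(base / rec.path_image).convert("RGB"))
        mask = _load_binary(base / rec.path_mask)
        boundary = _load_binary(base / rec.path_boundary)
        if min(image.shape[0], image.shape[1]) < crop_size:
            logger.warning(
                "image %s (%dx%d) smaller than crop size %d; reflect-padding",
                rec.path_image, image.shape[0], image.shape[1], crop_size,
            )
            image = _reflect_to(image, crop_size)
            mask = _reflect_to(mask, crop_size)
            boundary = _reflect_to(boundary, crop_size)
        h, w = mask.shape
        tops = rng.integers(0, h - crop_size + 1, size=crops_per_image)
        lefts = rng.integers(0, w - crop_size + 1, size=crops_per_image)
        for t, l in zip(tops, lefts):
            t, l = int(t), int(l)
            sl = (slice(t, t + crop_size), slice(l, l + crop_size))
            m = np.ascontiguousarray(mask[sl])
            b = np.ascontiguousarray(boundary[sl])
            crops.append(
                AnnotatedSample(
                    image=np.ascontiguousarray(image[sl]),
                    mask=m,
                    boundary=b,
                    weight_mask=static_weight_map(m, eta1, epsilon).weights,
                    weight_boundary=static_weight_map(b, eta1, epsilon).weights,
                    source=rec.path_image,
                    origin=(t, l),
                )
            )
    return crops


def _batch_arrays(
    samples: list[AnnotatedSample], kind: TargetKind
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a minibatch; pad images by reflection and targets/weights by
    zeros (zero weight = padded pixels carry no loss or gradient)."""
    xs, ys, ws = [], [], []
    for s in samples:
        x = normalize_image(s.image)[0]
        y, w = s.target(kind)
        xs.append(x)
        ys.append(y[None].astype(np.float32))
        ws.append(w[None].astype(np.float32))
    x = np.stack(xs)
    y = np.stack(ys)
    w = np.stack(ws)
    xp, h0, w0 = pad_to_multiple(x)
    if xp.shape[2:] != x.shape[2:]:
        ph, pw = xp.shape[2] - h0, xp.shape[3] - w0
        y = np.pad(y, ((0, 0), (0, 0), (0, ph), (0, pw)))
        w = np.pad(w, ((0, 0), (0, 0), (0, ph), (0, pw)))
    return xp, y, w


def train_stage(
    model: HCNet,
    crops: list[AnnotatedSample],
    schedule: TrainingSchedule,
    target_kind: TargetKind | str,
    seed: int = 0,
    eta2: float = DEFAULT_ETA2,
    log_every: int = 50,
    checkpoint_every: Optional[int] = None,
    checkpoint_dir: Optional[str] = None,
) -> list[dict]:
    """SGD over shuffled minibatches for one stage; returns the loss history.

    Each iteration recomputes the dynamic switch from the fused
    probability map and applies it to every head.  A non-finite loss
    aborts with a diagnostic snapshot.  ``max_iterations = 0`` leaves the
    model untouched.
    """
    kind = TargetKind(target_kind)
    expected = TargetKind.BOUNDARY if schedule.stage == 1 else TargetKind.MASK
    if kind is not expected:
        raise ValueError(f"schedule stage {schedule.stage} pairs with the {expected.value} target, got {kind.value}")
    if not crops:
        raise ValueError("no training crops supplied")
    optimizer = SGD(model.parameters(), lr=schedule.lr, momentum=schedule.momentum, clip_grad_norm=schedule.clip_grad_norm)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(crops))
    cursor = 0
    history: list[dict] = []
    n_heads = model.config.n_decoders + 1
    for iteration in range(schedule.max_iterations):
        batch_idx = []
        for _ in range(schedule.batch_size):
            if cursor == len(order):
                order = rng.permutation(len(crops))
                cursor = 0
            batch_idx.append(order[cursor])
            cursor += 1
        x, y, w = _batch_arrays([crops[i] for i in batch_idx], kind)
        logits, fused_logit = model.forward_tensor(Tensor(x))
        fused_prob = ad.sigmoid(fused_logit)
        if iteration < schedule.switch_warmup:
            gate = np.ones_like(y, dtype=np.uint8)
        else:
            gate = switch_mask(fused_prob.data, y, eta2)
        w_eff = (w * gate).astype(np.float32)
        head_losses = [ad.weighted_bce_logits_sum(lg, y, w_eff) for lg in logits]
        fused_loss = ad.weighted_bce_logits_sum(fused_logit, y, w_eff)
        total_loss_t = ad.add_n(head_losses + [fused_loss])
        total = float(total_loss_t.data)
        if not np.isfinite(total):
            snapshot = {
                "iteration": iteration,
                "per_head": [float(hl.data) for hl in head_losses] + [float(fused_loss.data)],
                "lr": schedule.lr_at(iteration),
                "batch": [crops[i].source for i in batch_idx],
            }
            raise RuntimeError(f"non-finite loss during stage {schedule.stage}: {snapshot}")
        optimizer.zero_grad()
        total_loss_t.backward()
        optimizer.step(lr=schedule.lr_at(iteration))
        n_px = y.size
        entry = {
            "iteration": iteration,
            "lr": schedule.lr_at(iteration),
            "per_head_mean": [float(hl.data) / n_px for hl in head_losses] + [float(fused_loss.data) / n_px],
            "total_mean": total / n_px,
            "total": total,
            "excluded_fraction": float(1.0 - gate.mean()),
        }
        history.append(entry)
        if log_every and iteration % log_every == 0:
            logger.info(
                "stage %d it %d lr %.2e loss/px %.4f excluded %.3f",
                schedule.stage, iteration, entry["lr"], entry["total_mean"], entry["excluded_fraction"],
            )
        if checkpoint_every and checkpoint_dir and (iteration + 1) % checkpoint_every == 0:
            Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
            save_checkpoint(model, str(Path(checkpoint_dir) / f"stage{schedule.stage}_it{iteration + 1:06d}.npz"))
    return history


def run_two_stage(
    model: HCNet,
    crops: list[AnnotatedSample],
    schedule1: TrainingSchedule,
    schedule2: TrainingSchedule,
    seed: int = 0,
    eta2: float = DEFAULT_ETA2,
    skip_stage1: bool = False,
    **stage_kwargs,
) -> dict:
    """Boundary pretext (stage 1) then mask fine-tuning (stage 2).

    Stage 2 starts from the exact parameters stage 1 produced.  Stage 1
    can be skipped for the mask-only ablation, which is logged.
    """
    histories: dict = {}
    if skip_stage1:
        logger.info("skipping stage 1 (mask-only ablation)")
        histories["stage1"] = []
    else:
        histories["stage1"] = train_stage(
            model, crops, schedule1, TargetKind.BOUNDARY, seed=seed, eta2=eta2, **stage_kwargs
        )
    histories["stage2"] = train_stage(
        model, crops, schedule2, TargetKind.MASK, seed=seed + 1, eta2=eta2, **stage_kwargs
    )
    return histories
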