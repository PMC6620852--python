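"""Hierarchically connected encoder / multi-decoder segmentation network.

The encoder is a VGG-16-style stack (13 convolutional layers in five
blocks, fully connected layers dropped) with 2x2 max-pooling between
blocks.  A decoder taps the last convolution of each block — *before* the
following pooling layer — so five decoders see the feature hierarchy at
scales 1, 1/2, 1/4, 1/8 and 1/16.  Decoder ``i`` projects its tap to a
small working width with a 3x3 convolution, then applies ``i - 1``
refinement steps of [learnable stride-2 transposed convolution, 3x3
convolution], a 3x3 convolution to one channel, and a center-crop to the
input size.  The five one-channel maps are concatenated into a 5-channel
map and merged by a 1x1 convolution; a sigmoid on each decoder map and on
the merged map yields six probability maps, all trained jointly.

``width_multiplier`` scales every channel count, producing desk-scale
variants that train in minutes on a CPU; the default multiplier of 1
reproduces the full architecture.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv2d, ConvTranspose2d

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "PredictionBundle",
    "HCNet",
    "build_model",
    "forward",
    "load_pretrained_encoder",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1

DEFAULT_ENCODER_WIDTHS = ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512))

#: inputs are padded (reflect) to multiples of this before the forward pass
PAD_MULTIPLE = 32
MIN_SIDE = 32


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    encoder_widths: per-block output channel counts (full-width values;
        ``width_multiplier`` is applied on top).
    decoder_channels: internal working width of every decoder.
    n_decoders: number of decoders; must equal the number of encoder blocks.
    width_multiplier: in (0, 1]; every channel count is scaled to
        ``max(1, round(c * width_multiplier))``.
    """

    encoder_widths: tuple = DEFAULT_ENCODER_WIDTHS
    decoder_channels: int = 64
    n_decoders: int = 5
    width_multiplier: float = 1.0

    def __post_init__(self):
        if self.n_decoders != len(self.encoder_widths):
            raise ValueError(
                f"n_decoders ({self.n_decoders}) must equal the number of encoder blocks ({len(self.encoder_widths)})"
            )
        if not (0.0 < self.width_multiplier <= 1.0):
            raise ValueError("width_multiplier must lie in (0, 1]")

    def scaled(self, channels: int) -> int:
        return max(1, int(round(channels * self.width_multiplier)))

    def to_dict(self) -> dict:
        return {
            "encoder_widths": [list(b) for b in self.encoder_widths],
            "decoder_channels": self.decoder_channels,
            "n_decoders": self.n_decoders,
            "width_multiplier": self.width_multiplier,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            encoder_widths=tuple(tuple(b) for b in d["encoder_widths"]),
            decoder_channels=int(d["decoder_channels"]),
            n_decoders=int(d["n_decoders"]),
            width_multiplier=float(d["width_multiplier"]),
        )


@dataclass
class PredictionBundle:
    """Per-decoder probability maps plus the fused map, all input-sized."""

    decoder_maps: list  # of (H, W) float32 arrays in (0, 1)
    fused_map: np.ndarray  # (H, W) float32 in (0, 1)


class _Decoder:
    """Decoder for encoder block ``index`` (1-based): i-1 upsampling steps."""

    def __init__(self, index: int, in_channels: int, channels: int, rng: np.random.Generator):
        self.index = index
        name = f"dec{index}"
        self.head = Conv2d(in_channels, channels, 3, rng, padding=1, name=f"{name}.head")
        self.deconvs: list[ConvTranspose2d] = []
        self.refines: list[Conv2d] = []
        for s in range(index - 1):
            self.deconvs.append(ConvTranspose2d(channels, channels, name=f"{name}.deconv{s + 1}"))
            self.refines.append(Conv2d(channels, channels, 3, rng, padding=1, name=f"{name}.refine{s + 1}"))
        self.out = Conv2d(channels, 1, 3, rng, padding=1, name=f"{name}.out")

    def __call__(self, x: Tensor, out_h: int, out_w: int) -> Tensor:
        h = ad.relu(self.head(x))
        for up, conv in zip(self.deconvs, self.refines):
            h = ad.relu(conv(up(h)))
        logit = self.out(h)
        return ad.crop2d(logit, out_h, out_w)

    def parameters(self) -> list[Tensor]:
        ps = self.head.parameters()
        for up, conv in zip(self.deconvs, self.refines):
            ps += up.parameters() + conv.parameters()
        return ps + self.out.parameters()


class HCNet:
    """The assembled network; holds parameters and builds the graph per call."""

    def __init__(self, config: ModelConfig, rng: Optional[np.random.Generator] = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        self.encoder_blocks: list[list[Conv2d]] = []
        in_ch = 3
        for b, widths in enumerate(config.encoder_widths, start=1):
            block = []
            for k, w in enumerate(widths, start=1):
                out_ch = config.scaled(w)
                block.append(Conv2d(in_ch, out_ch, 3, rng, padding=1, name=f"conv{b}_{k}"))
                in_ch = out_ch
            self.encoder_blocks.append(block)
        dch = config.scaled(config.decoder_channels)
        self.decoders = [
            _Decoder(i, config.scaled(widths[-1]), dch, rng)
            for i, widths in enumerate(config.encoder_widths, start=1)
        ]
        self.fuse = Conv2d(config.n_decoders, 1, 1, rng, name="fuse")

    # -- parameter bookkeeping ------------------------------------------------

    def encoder_convs(self) -> list[Conv2d]:
        return [c for block in self.encoder_blocks for c in block]

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for c in self.encoder_convs():
            ps += c.parameters()
        for d in self.decoders:
            ps += d.parameters()
        ps += self.fuse.parameters()
        return ps

    def named_parameters(self) -> dict:
        return {p.name: p for p in self.parameters()}

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- forward --------------------------------------------------------------

    def forward_tensor(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        """Run on a padded NCHW batch; returns (decoder logits, fused logit).

        Spatial dims must be multiples of ``2 ** (n_blocks - 1)`` so that
        every pooling halves exactly and every decoder upsamples back to
        the input size.
        """
        n, c, h, w = x.data.shape
        taps: list[Tensor] = []
        feat = x
        for b, block in enumerate(self.encoder_blocks):
            if b > 0:
                feat = ad.maxpool2d(feat)
            for conv in block:
                feat = ad.relu(conv(feat))
            taps.append(feat)
        logits = [dec(tap, h, w) for dec, tap in zip(self.decoders, taps)]
        fused_logit = self.fuse(ad.concat_channels(logits))
        return logits, fused_logit

    def forward_probabilities(self, batch: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Inference on a padded NCHW float batch, no gradient tracking."""
        with ad.no_grad():
            logits, fused = self.forward_tensor(Tensor(batch))
            dec = [ad.sigmoid(t).data for t in logits]
            return dec, ad.sigmoid(fused).data


def build_model(config: Optional[ModelConfig] = None, seed: int = 0) -> HCNet:
    """Instantiate the network with He-normal / bilinear initialization."""
    return HCNet(config if config is not None else ModelConfig(), np.random.default_rng(seed))


def normalize_image(image: np.ndarray) -> np.ndarray:
    """uint8 RGB (H, W, 3) -> float32 NCHW in [-0.5, 0.5]."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an RGB (H, W, 3) image, got shape {img.shape}")
    x = img.astype(np.float32) / 255.0 - 0.5
    return x.transpose(2, 0, 1)[None]


def pad_to_multiple(batch: np.ndarray, multiple: int = PAD_MULTIPLE) -> tuple[np.ndarray, int, int]:
    """Reflect-pad NCHW spatial dims up to the next multiple; returns (padded, H, W)."""
    h, w = batch.shape[2], batch.shape[3]
    hp = -(-h // multiple) * multiple
    wp = -(-w // multiple) * multiple
    if (hp, wp) != (h, w):
        batch = np.pad(batch, ((0, 0), (0, 0), (0, hp - h), (0, wp - w)), mode="reflect")
    return batch, h, w


def forward(model: HCNet, image: np.ndarray) -> PredictionBundle:
    """Segment one RGB image of arbitrary size >= 32 px per side.

    The image is reflect-padded to multiples of 32 internally and all six
    probability maps are cropped back, so every returned map matches the
    input size exactly.
    """
    img = np.asarray(image)
    if img.ndim != 3 or min(img.shape[0], img.shape[1]) < MIN_SIDE:
        raise ValueError(
            f"input must be an RGB image with both sides >= {MIN_SIDE} px, got shape {img.shape}"
        )
    batch = normalize_image(img)
    padded, h, w = pad_to_multiple(batch)
    dec_maps, fused = model.forward_probabilities(padded)
    return PredictionBundle(
        decoder_maps=[m[0, 0, :h, :w].copy() for m in dec_maps],
        fused_map=fused[0, 0, :h, :w].copy(),
    )


# -- pretrained encoder -------------------------------------------------------


def load_pretrained_encoder(model: HCNet, weights_source: Union[str, dict, None]) -> int:
    """Copy VGG-style encoder weights into the model; decoders untouched.

    ``weights_source`` is a mapping (or ``.npz`` path) with keys like
    ``conv1_1.weight`` / ``conv1_1.bias``.  Returns the number of tensors
    loaded.  A missing source logs a warning and leaves the model
    unchanged; any shape mismatch raises, naming the offending layer.
    """
    if weights_source is None:
        warnings.warn("no pretrained encoder weights given; encoder keeps its random initialization")
        logger.warning("no pretrained encoder weights given; model unchanged")
        return 0
    if isinstance(weights_source, (str,)):
        with np.load(weights_source) as npz:
            source = {k: npz[k] for k in npz.files}
    else:
        source = dict(weights_source)
    staged = []
    for conv in model.encoder_convs():
        for attr in ("weight", "bias"):
            key = f"{conv.name}.{attr}"
            if key not in source:
                raise KeyError(f"pretrained source is missing tensor {key!r}")
            arr = np.asarray(source[key], dtype=np.float32)
            target = getattr(conv, attr)
            if arr.shape != target.data.shape:
                raise ValueError(
                    f"shape mismatch for {key!r}: source {arr.shape} vs model {target.data.shape}"
                )
            staged.append((target, arr))
    for target, arr in staged:  # all-or-nothing: validate every layer first
        target.data = arr.copy()
    return len(staged)


# -- checkpoints --------------------------------------------------------------


def save_checkpoint(model: HCNet, path: str) -> None:
    """Single-file parameter archive with a version tag and the embedded config."""
    arrays = {p.name: p.data for p in model.parameters()}
    meta = json.dumps({"version": CHECKPOINT_VERSION, "config": model.config.to_dict()})
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_checkpoint(path: str) -> HCNet:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
        model = build_model(ModelConfig.from_dict(meta["config"]))
        for p in model.parameters():
            if p.name not in npz.files:
                raise KeyError(f"checkpoint is missing parameter {p.name!r}")
            arr = npz[p.name]
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch for {p.name!r}")
            p.data = arr.astype(np.float32)
    return model
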