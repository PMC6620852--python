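"""Arbitrary-size and whole-slide prediction.

The network itself accepts any input with both sides >= 32 px, so
moderate images go through in a single forward pass.  Whole-slide scans
exceed memory in one pass, so they are processed as overlapping tiles
whose probability maps are averaged in the overlap bands — a blending
scheme whose deviation from the single-pass result is bounded and
checked by a self-consistency test.  Tiling switches on automatically
above 2048 px per side.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

from .network import HCNet, MIN_SIDE, forward

__all__ = ["predict_image", "save_overlay", "AUTO_TILE_THRESHOLD", "DEFAULT_TILE", "DEFAULT_OVERLAP"]

AUTO_TILE_THRESHOLD = 2048
DEFAULT_TILE = 1024
DEFAULT_OVERLAP = 64


def _tile_starts(extent: int, tile: int, stride: int) -> list[int]:
    if extent <= tile:
        return [0]
    starts = list(range(0, extent - tile, stride))
    starts.append(extent - tile)
    return starts


def predict_image(
    model: HCNet,
    image: np.ndarray,
    tile_size: Optional[int] = None,
    overlap: int = DEFAULT_OVERLAP,
) -> np.ndarray:
    """Fused probability map for an RGB image of any size >= 32 px.

    ``tile_size=None`` runs a single forward pass unless a side exceeds
    2048 px, in which case the default 1024-px tiling activates.  With
    tiling, tiles overlap by ``overlap`` pixels and probabilities are
    averaged where tiles meet; the output always matches the input size.
    """
    img = np.asarray(image)
    h, w = img.shape[0], img.shape[1]
    if tile_size is None and max(h, w) > AUTO_TILE_THRESHOLD:
        tile_size = DEFAULT_TILE
    if tile_size is None:
        return forward(model, img).fused_map
    if tile_size < MIN_SIDE:
        raise ValueError(f"tile_size must be >= {MIN_SIDE}")
    if overlap < 0 or overlap >= tile_size / 2:
        raise ValueError("overlap must satisfy 0 <= overlap < tile_size / 2")
    stride = tile_size - overlap
    acc = np.zeros((h, w), dtype=np.float64)
    cover = np.zeros((h, w), dtype=np.float64)
    for top in _tile_starts(h, tile_size, stride):
        for left in _tile_starts(w, tile_size, stride):
            th = min(tile_size, h)
            tw = min(tile_size, w)
            patch = img[top : top + th, left : left + tw]
            prob = forward(model, patch).fused_map
            acc[top : top + th, left : left + tw] += prob
            cover[top : top + th, left : left + tw] += 1.0
    return (acc / cover).astype(np.float32)


def save_overlay(
    image: np.ndarray,
    labels: np.ndarray,
    out_path: str | Path,
    alpha: float = 0.45,
    seed: int = 0,
) -> Path:
    """Write the image with each labeled fiber alpha-blended in its own color.

    The palette is drawn deterministically from ``seed``; label 0
    (background/boundary) is left untouched, so a labeling without
    fibers reproduces the input image exactly.
    """
    img = np.asarray(image)
    lab = np.asarray(labels)
    if img.shape[:2] != lab.shape:
        raise ValueError(f"shape mismatch: image {img.shape[:2]} vs labels {lab.shape}")
    out = img.astype(np.float64).copy()
    n = int(lab.max())
    if n > 0:
        rng = np.random.default_rng(seed)
        # distinct hues, randomized order; saturated colors over histology pink
        hues = rng.permutation(np.linspace(0.0, 1.0, n, endpoint=False))
        palette = np.stack([_hsv_to_rgb(h, 0.85, 0.95) for h in hues])
        for k in range(1, n + 1):
            sel = lab == k
            out[sel] = (1 - alpha) * out[sel] + alpha * palette[k - 1] * 255.0
    out_path = Path(out_path)
    Image.fromarray(np.clip(out, 0, 255).astype(np.uint8)).save(out_path)
    return out_path


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb)
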