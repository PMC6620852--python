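"""Training targets and the static part of the pixel weight-assigning function.

The loss weights each pixel by the product of three terms: an inverse
class-frequency term C(Y_i)^-1, a boundary-proximity term that grows
exponentially as the pixel approaches a fiber contour, and a dynamic
switch (see :mod:`myoseg.objective`).  The first two depend only on the
ground truth, so they are precomputed per training crop into a static
weight map

    W_i = C(Y_i)^-1 * exp(max(eps - Omega_i, 0) / eta1)

where Omega_i is the Euclidean distance from pixel i to the nearest fiber
contour pixel, eps (default 10 px) is the distance beyond which the
boundary term is exactly 1, and eta1 (default 5 px) sets how sharply the
weight rises toward the contour (e^(eps/eta1) on the contour itself).

Conventions: a contour pixel is a fiber pixel (Y=1) with at least one
4-neighbor of the opposite class; coordinates are 0-based, row-major,
distances are between pixel centers; class frequencies are computed over
the given crop.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

__all__ = [
    "TargetKind",
    "TargetPair",
    "WeightMap",
    "fiber_contour",
    "derive_boundary_map",
    "distance_to_boundary",
    "class_balance",
    "static_weight_map",
]

DEFAULT_ETA1 = 5.0
DEFAULT_EPSILON = 10.0
FREQ_FLOOR = 1e-6

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


class TargetKind(str, Enum):
    BOUNDARY = "boundary"
    MASK = "mask"


@dataclass
class TargetPair:
    """Binary mask Y and boundary map B for one crop, values in {0, 1}."""

    mask: np.ndarray
    boundary: np.ndarray
    stage: TargetKind = TargetKind.MASK


@dataclass
class WeightMap:
    """Static per-pixel weights W (strictly positive) with their parameters."""

    weights: np.ndarray
    eta1: float
    epsilon: float


def _as_binary(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    out = (m != 0)
    return out


def fiber_contour(mask: np.ndarray) -> np.ndarray:
    """Fiber pixels with at least one in-image 4-neighbor of the opposite class.

    Pixels beyond the image border do not count as neighbors, so a fiber
    truncated by the crop edge has no contour along that edge.
    """
    m = _as_binary(mask)
    if not m.any():
        return np.zeros_like(m, dtype=bool)
    interior = ndimage.binary_erosion(m, structure=_CROSS, border_value=1)
    return m & ~interior


def derive_boundary_map(mask: np.ndarray, thickness: int = 1) -> np.ndarray:
    """Binary map of pixels within ``thickness`` of any fiber contour.

    The contour itself is at distance 0, so ``thickness=1`` marks the
    contour plus its immediate (Euclidean distance <= 1) neighbors;
    larger thickness gives a pixelwise superset.  An empty mask yields an
    all-zero map.
    """
    if thickness < 1:
        raise ValueError("thickness must be >= 1")
    contour = fiber_contour(mask)
    if not contour.any():
        return np.zeros(np.asarray(mask).shape, dtype=np.uint8)
    dist = ndimage.distance_transform_edt(~contour)
    return (dist < thickness).astype(np.uint8)


def distance_to_boundary(mask: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance Omega to the nearest fiber contour pixel.

    If the mask contains no fiber at all, every distance is the +inf
    sentinel (treated as "beyond epsilon" downstream).
    """
    contour = fiber_contour(mask)
    if not contour.any():
        return np.full(np.asarray(mask).shape, np.inf, dtype=np.float64)
    return ndimage.distance_transform_edt(~contour)


def class_balance(mask: np.ndarray) -> tuple[float, float]:
    """Inverse label frequencies (w0, w1) over the crop.

    w_c = 1 / max(freq(c), 1e-6); the floor only matters for a class
    absent from the crop, whose weight is then never used.
    """
    m = _as_binary(mask)
    n = m.size
    freq1 = m.sum() / n
    freq0 = 1.0 - freq1
    return 1.0 / max(freq0, FREQ_FLOOR), 1.0 / max(freq1, FREQ_FLOOR)


def static_weight_map(
    mask: np.ndarray, eta1: float = DEFAULT_ETA1, epsilon: float = DEFAULT_EPSILON
) -> WeightMap:
    """The precomputable part of the pixel weights for target ``mask``.

    W_i = C(Y_i)^-1 * exp(max(eps - Omega_i, 0) / eta1): the class term
    everywhere, multiplied by e^(eps/eta1) on the contour, decaying to
    exactly 1 at distance eps and beyond.
    """
    if eta1 <= 0:
        raise ValueError("eta1 must be > 0")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    m = _as_binary(mask)
    w0, w1 = class_balance(m)
    omega = distance_to_boundary(m)
    boundary_term = np.exp(np.maximum(epsilon - omega, 0.0) / eta1)
    weights = np.where(m, w1, w0) * boundary_term
    return WeightMap(weights=weights.astype(np.float32), eta1=float(eta1), epsilon=float(epsilon))
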