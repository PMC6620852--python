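"""Spatially weighted cross-entropy with a dynamic reliability switch.

The loss for one probability map P against binary target Y is

    J = -sum_i W_i * s_i * [ 1(Y_i=1) log P_i + 1(Y_i=0) log(1 - P_i) ]

where W is the static weight map (class balance x boundary proximity,
:mod:`myoseg.targets`) and s is the switch: s_i = 1 when |Y_i - P_i| <
eta2 and 0 otherwise.  The switch removes pixels whose label the network
contradicts with high confidence — treating them as probable annotation
errors — from both the loss value and its gradient, while the forward
pass still computes P everywhere.  The network's M decoder maps and the
fused map are scored with the identical formula and the total is their
unweighted sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import PredictionBundle
from .targets import WeightMap

__all__ = [
    "LossReport",
    "DEFAULT_ETA2",
    "switch_mask",
    "bce_value_and_grad",
    "weighted_bce",
    "total_loss",
]

DEFAULT_ETA2 = 0.6
P_CLAMP = 1e-7


@dataclass
class LossReport:
    """Per-head loss values for one sample or minibatch."""

    per_decoder: list  # M scalars
    fused: float
    total: float
    excluded_fraction: float  # pixels gated off by the switch


def switch_mask(prob: np.ndarray, target: np.ndarray, eta2: float = DEFAULT_ETA2) -> np.ndarray:
    """1 where |Y - P| < eta2 (pixel participates), else 0.

    eta2 must lie in (0, 1]; values above 0.5 mean a pixel is only
    silenced when the prediction sits confidently on the opposite side
    of its label.
    """
    if not (0.0 < eta2 <= 1.0):
        raise ValueError("eta2 must lie in (0, 1]")
    return (np.abs(np.asarray(target, dtype=np.float64) - prob) < eta2).astype(np.uint8)


def bce_value_and_grad(
    prob: np.ndarray, target: np.ndarray, weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted cross-entropy sum and its gradient with respect to P.

    Probabilities are clamped to [1e-7, 1 - 1e-7] before the logarithm;
    zero-weight pixels contribute exactly zero to both outputs.
    """
    p = np.clip(np.asarray(prob, dtype=np.float64), P_CLAMP, 1.0 - P_CLAMP)
    y = np.asarray(target, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    value = -float(np.sum(w * (y * np.log(p) + (1.0 - y) * np.log1p(-p))))
    grad = np.where(w != 0.0, w * (p - y) / (p * (1.0 - p)), 0.0)
    return value, grad


def weighted_bce(
    prob: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | WeightMap,
    switch: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Loss of one map: returns (scalar value, gradient dJ/dP).

    ``switch`` gates pixels out of both the value and the gradient; P is
    still expected to have been computed at gated pixels (they are
    excluded from backpropagation only).
    """
    w = weights.weights if isinstance(weights, WeightMap) else np.asarray(weights)
    if switch is not None:
        w = w * np.asarray(switch)
    if w.shape != np.asarray(prob).shape:
        raise ValueError(f"shape mismatch: weights {w.shape} vs prob {np.asarray(prob).shape}")
    return bce_value_and_grad(prob, target, w)


def total_loss(
    bundle: PredictionBundle,
    target: np.ndarray,
    weights: np.ndarray | WeightMap,
    eta2: float = DEFAULT_ETA2,
) -> LossReport:
    """Joint loss over the M decoder maps and the fused map.

    The switch is computed once from the fused map and applied to every
    head, so all heads agree on which pixels are treated as unreliable.
    """
    y = np.asarray(target)
    if bundle.fused_map.shape != y.shape:
        raise ValueError(f"shape mismatch: fused map {bundle.fused_map.shape} vs target {y.shape}")
    gate = switch_mask(bundle.fused_map, y, eta2)
    per_decoder = []
    for m in bundle.decoder_maps:
        if m.shape != y.shape:
            raise ValueError(f"shape mismatch: decoder map {m.shape} vs target {y.shape}")
        v, _ = weighted_bce(m, y, weights, gate)
        per_decoder.append(v)
    fused_v, _ = weighted_bce(bundle.fused_map, y, weights, gate)
    return LossReport(
        per_decoder=per_decoder,
        fused=fused_v,
        total=float(sum(per_decoder) + fused_v),
        excluded_fraction=float(1.0 - gate.mean()),
    )
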