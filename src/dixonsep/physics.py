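"""The two-point Dixon physical model.

At the in-phase echo the fat and water magnetizations add, at the
opposed-phase echo they subtract, so for magnitude data

    IP = W + F,        OP = |W - F|,

and in theory W = |IP + OP| / 2 and F = |IP - OP| / 2. Because only
magnitudes are observed, the analytic inversion cannot tell which of the
pair is water and which is fat: it always returns the larger component as
"water". Voxels where fat dominates therefore come back exchanged — the
intrinsic fat-water swap ambiguity that reconstruction must resolve with
spatial context.

This module provides the forward synthesis, the analytic (ambiguous)
inversion, the joint intensity normalization used before feeding volumes to
a network, and the physics-consistency residuals that underlie the Dixon
loss.
"""

from __future__ import annotations

import numpy as np

from .fields import DixonChannels, ScalarField3D, _require_same_shape

__all__ = [
    "forward_model",
    "analytic_separation",
    "normalize_channels",
    "normalize_arrays",
    "dixon_residuals",
]


def forward_model(
    water: ScalarField3D, fat: ScalarField3D
) -> tuple[ScalarField3D, ScalarField3D]:
    """Synthesize in-phase and opposed-phase volumes from water and fat.

    Returns ``(ip, op)`` with ``ip = water + fat`` and ``op = |water - fat|``
    voxel-wise. Both outputs are non-negative and ``op <= ip`` everywhere.
    """
    _require_same_shape("water", water.values, "fat", fat.values)
    if np.any(water.values < 0) or np.any(fat.values < 0):
        raise ValueError("water and fat must be non-negative")
    ip = water.values + fat.values
    op = np.abs(water.values - fat.values)
    return water.with_values(ip), water.with_values(op)


def analytic_separation(
    ip: ScalarField3D, op: ScalarField3D
) -> tuple[ScalarField3D, ScalarField3D]:
    """Magnitude-only analytic inversion: W = |IP+OP|/2, F = |IP-OP|/2.

    Composed with :func:`forward_model` this returns ``(max(W,F), min(W,F))``
    per voxel — the true pair is recovered only where water dominates, which
    is exactly the swap ambiguity of magnitude-only two-point Dixon.
    """
    _require_same_shape("ip", ip.values, "op", op.values)
    water = np.abs(ip.values + op.values) / 2.0
    fat = np.abs(ip.values - op.values) / 2.0
    return ip.with_values(water), ip.with_values(fat)


def normalize_arrays(
    arrays: list[np.ndarray], percentile: float = 99.0
) -> tuple[list[np.ndarray], float]:
    """Jointly normalize a set of channels by their pooled percentile.

    The scale is the ``percentile``-th percentile (linear interpolation
    between order statistics) of the voxel intensities pooled across all
    given channels of one subject. Every channel is divided by the scale and
    clipped to [0, 1], so the rare intensity spikes above the percentile
    cannot stretch the value range.
    """
    pooled = np.concatenate([np.asarray(a, dtype=np.float64).ravel() for a in arrays])
    scale = float(np.percentile(pooled, percentile))
    if scale <= 0:
        raise ValueError("degenerate intensity range: pooled percentile is not positive")
    return [np.clip(np.asarray(a, dtype=np.float64) / scale, 0.0, 1.0) for a in arrays], scale


def normalize_channels(
    channels: DixonChannels, percentile: float = 99.0
) -> tuple[DixonChannels, float]:
    """Joint 99th-percentile normalization of all four channels of a subject.

    Returns the normalized channels (values in [0, 1]) and the scalar scale,
    which can be kept to map predictions back to raw intensity units.
    """
    arrays = [channels.ip.values, channels.op.values, channels.fat.values, channels.water.values]
    normed, scale = normalize_arrays(arrays, percentile)
    spacing = channels.spacing
    ip, op, fat, water = (ScalarField3D(a, spacing) for a in normed)
    return DixonChannels(ip=ip, op=op, fat=fat, water=water), scale


def dixon_residuals(
    ip: ScalarField3D,
    op: ScalarField3D,
    fat_hat: ScalarField3D,
    water_hat: ScalarField3D,
) -> tuple[ScalarField3D, ScalarField3D]:
    """Voxel-wise physics-consistency residuals of a predicted (F, W) pair.

    ``r_ip = IP - (W_hat + F_hat)`` and ``r_op = OP - |W_hat - F_hat|``.
    Both are identically zero iff the prediction satisfies the two-point
    Dixon relations; note zero residuals are preserved under a global
    exchange of the predicted channels — the physics alone cannot
    disambiguate fat from water.
    """
    for name, f in (("op", op), ("fat_hat", fat_hat), ("water_hat", water_hat)):
        _require_same_shape("ip", ip.values, name, f.values)
    r_ip = ip.values - (water_hat.values + fat_hat.values)
    r_op = op.values - np.abs(water_hat.values - fat_hat.values)
    return ip.with_values(r_ip), ip.with_values(r_op)
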