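"""Whole-volume prediction by cubic-patch tiling and reassembly.

A trained generator accepts fixed-edge cubes, so a full neck-to-knee volume
is covered by patches whose start coordinates are multiples of the patch
edge, with the final start along each axis clamped to ``dim - edge`` (which
creates overlap at the far ends but keeps the patch count minimal: a
(224, 174, 370) volume with 128-cubes gives 2 x 2 x 3 = 12 patches). Where
patches overlap, each voxel takes the value of the *first* patch containing
it in lexicographic (left-right, anterior-posterior, superior-inferior)
start order — first-value precedence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .fields import ScalarField3D
from .nn import Tensor
from .physics import normalize_arrays

__all__ = ["PatchLayout", "compute_patch_layout", "assemble", "predict_volume"]


@dataclass(frozen=True)
class PatchLayout:
    """Ordered cubic patch cover of a volume.

    ``starts`` are 0-based corner coordinates; extents are half-open
    ``[s, s + patch_edge)``. Order is lexicographic in (x, y, z), which
    defines the first-value precedence used by :func:`assemble`.
    """

    patch_edge: int
    starts: tuple[tuple[int, int, int], ...]
    volume_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "starts", tuple(tuple(s) for s in self.starts))
        e = self.patch_edge
        for s in self.starts:
            if any(c < 0 or c + e > d for c, d in zip(s, self.volume_shape)):
                raise ValueError(f"patch at {s} leaves the volume {self.volume_shape}")

    def __len__(self) -> int:
        return len(self.starts)


def _axis_starts(dim: int, edge: int) -> list[int]:
    starts = list(range(0, dim - edge + 1, edge))
    if starts[-1] + edge < dim:
        starts.append(dim - edge)  # clamp the overshooting final start
    return starts


def compute_patch_layout(volume_shape, patch_edge: int) -> PatchLayout:
    """Clamped-multiples patch layout covering the whole volume.

    Per axis the starts are 0, E, 2E, ...; if the last multiple overshoots,
    the final start is clamped to ``dim - E``. Patch count is
    ``prod(ceil(dim / E))``. Raises if any dimension is smaller than the
    patch edge.
    """
    shape = tuple(int(d) for d in volume_shape)
    if any(d < patch_edge for d in shape):
        raise ValueError(
            f"volume shape {shape} has a dimension smaller than the patch edge {patch_edge}"
        )
    axes = [_axis_starts(d, patch_edge) for d in shape]
    starts = tuple(product(*axes))  # lexicographic in (x, y, z)
    return PatchLayout(patch_edge=patch_edge, starts=starts, volume_shape=shape)


def assemble(patch_predictions, layout: PatchLayout) -> np.ndarray:
    """Reassemble per-patch predictions with first-value precedence.

    Each voxel takes its value from the earliest patch (in layout order)
    containing it; later overlapping patches never overwrite.
    """
    preds = [np.asarray(p) for p in patch_predictions]
    if len(preds) != len(layout):
        raise ValueError(f"expected {len(layout)} patch predictions, got {len(preds)}")
    e = layout.patch_edge
    for p in preds:
        if p.shape != (e, e, e):
            raise ValueError(f"patch prediction has shape {p.shape}, expected {(e, e, e)}")
    out = np.zeros(layout.volume_shape, dtype=preds[0].dtype)
    written = np.zeros(layout.volume_shape, dtype=bool)
    for start, p in zip(layout.starts, preds):
        x, y, z = start
        sl = (slice(x, x + e), slice(y, y + e), slice(z, z + e))
        fresh = ~written[sl]
        out[sl][fresh] = p[fresh]
        written[sl] = True
    if not written.all():
        raise AssertionError("patch layout failed to cover the volume")
    return out


def predict_volume(
    generator,
    ip: ScalarField3D,
    op: ScalarField3D | None = None,
    normalize: bool = True,
    rescale: bool = False,
    patch_edge: int | None = None,
) -> tuple[ScalarField3D, ScalarField3D]:
    """Predict full fat-hat / water-hat volumes with a trained generator.

    The volume is tiled per :func:`compute_patch_layout`, each patch is
    pushed through the generator, and both output channels are reassembled
    with first-value precedence. ``patch_edge`` should normally equal the
    crop size the generator was trained on (the network is fully
    convolutional, but feature-normalization statistics match the training
    distribution at that size); it defaults to the largest compatible edge
    up to 128.

    ``op`` is required iff the generator is dual-input. With ``normalize``
    the inputs are jointly scaled to [0, 1] by their pooled 99th percentile;
    ``rescale`` maps the predictions back to raw intensity units using that
    same scale.
    """
    config = generator.config
    if config.in_channels == 2 and op is None:
        raise ValueError("dual-input generator requires the opposed-phase volume")
    if config.in_channels == 1 and op is not None:
        raise ValueError("single-input generator accepts no opposed-phase volume")
    arrays = [ip.values] if op is None else [ip.values, op.values]
    scale = 1.0
    if normalize:
        arrays, scale = normalize_arrays(arrays)
    if patch_edge is None:
        edge = _choose_patch_edge(ip.shape, config.divisor)
    else:
        if patch_edge % config.divisor:
            raise ValueError(
                f"patch_edge {patch_edge} not divisible by the generator's "
                f"stride^levels = {config.divisor}"
            )
        edge = patch_edge
    layout = compute_patch_layout(ip.shape, edge)
    fat_patches, water_patches = [], []
    for x, y, z in layout.starts:
        sl = (slice(x, x + edge), slice(y, y + edge), slice(z, z + edge))
        patch = np.stack([a[sl] for a in arrays])[None].astype(np.float32)
        pred = generator(Tensor(patch)).data[0]
        fat_patches.append(pred[0])
        water_patches.append(pred[1])
    fat = assemble(fat_patches, layout).astype(np.float64)
    water = assemble(water_patches, layout).astype(np.float64)
    if rescale:
        fat *= scale
        water *= scale
    return ip.with_values(fat), ip.with_values(water)


def _choose_patch_edge(shape: tuple[int, int, int], divisor: int, preferred: int = 128) -> int:
    """Largest multiple of ``divisor`` that is <= min(preferred, min(shape))."""
    cap = min(preferred, min(shape))
    edge = (cap // divisor) * divisor
    if edge < divisor:
        raise ValueError(
            f"volume shape {shape} too small for the generator "
            f"(needs an edge divisible by {divisor})"
        )
    return edge
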