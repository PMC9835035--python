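"""Reconstruction-quality metrics and the swap-assessment protocol.

PSNR and SSIM quantify voxel-wise fidelity of predicted fat/water volumes
against scanner references. Because a swapped reference invalidates such
metrics (the "ground truth" itself is wrong inside a swap), swap performance
is assessed separately: :func:`count_induced_swaps` finds connected regions
where a prediction pair is closer to the *exchanged* reference than to the
reference itself — the operational analogue of reading difference images.

The semantic interpretability score (SIS) judges reconstructions by how well
a segmentation model still finds organs in them: the Dice of segmentations
computed on reconstructed volumes against manual annotations, normalized by
the mean Dice the same segmenter achieves on ground-truth volumes. A
phantom-native stand-in segmenter (fat-fraction window + connected
components) plays the role of the external organ-segmentation models.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from .fields import ScalarField3D, _require_same_shape
from .phantom import LabelMap

__all__ = [
    "psnr",
    "ssim",
    "dice",
    "sis",
    "count_induced_swaps",
    "segment_structure",
    "MetricReport",
    "evaluate_prediction",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def psnr(reference: ScalarField3D, test: ScalarField3D) -> float:
    """Peak signal-to-noise ratio, 10 * log10(MPI^2 / MSE), in dB.

    MPI is the maximum intensity of the reference volume. Identical volumes
    (MSE = 0) return ``inf`` rather than a silent large number.
    """
    _require_same_shape("reference", reference.values, "test", test.values)
    mpi = float(reference.values.max())
    if mpi <= 0:
        raise ValueError("reference volume has no positive intensity (MPI = 0)")
    mse = float(np.mean((reference.values - test.values) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(mpi**2 / mse)


def ssim(
    reference: ScalarField3D,
    test: ScalarField3D,
    window_edge: int = 11,
    dynamic_range: float | None = None,
) -> float:
    """Structural similarity with a uniform cubic sliding window.

    Local means, variances and covariance are computed over an 11^3 uniform
    window (population normalization); ``C1 = (0.01 L)^2`` and
    ``C2 = (0.03 L)^2`` with ``L`` the dynamic range, defaulting to the
    reference's max - min. Only fully interior windows contribute to the
    mean. Returns a value in [-1, 1]; +1 only for identical volumes.
    """
    _require_same_shape("reference", reference.values, "test", test.values)
    x = reference.values.astype(np.float64)
    y = test.values.astype(np.float64)
    w = int(window_edge)
    if any(d < w for d in x.shape):
        raise ValueError(f"volume shape {x.shape} smaller than the {w}^3 window")
    if dynamic_range is None:
        dynamic_range = float(x.max() - x.min())
        if dynamic_range == 0:
            raise ValueError("reference volume is constant; pass dynamic_range explicitly")
    L = float(dynamic_range)
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2

    def win_mean(a: np.ndarray) -> np.ndarray:
        m = ndimage.uniform_filter(a, size=w, mode="constant")
        lo = w // 2
        return m[lo : a.shape[0] - (w - 1 - lo),
                 lo : a.shape[1] - (w - 1 - lo),
                 lo : a.shape[2] - (w - 1 - lo)]

    mu_x = win_mean(x)
    mu_y = win_mean(y)
    var_x = win_mean(x * x) - mu_x**2
    var_y = win_mean(y * y) - mu_y**2
    cov = win_mean(x * y) - mu_x * mu_y
    ssim_map = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    )
    return float(ssim_map.mean())


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a & b| / (|a| + |b|); two empty masks give 1.0."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    _require_same_shape("a", a, "b", b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def sis(dice_reconstruction: float, baseline_mean_dice: float) -> float:
    """Semantic interpretability score: Dice on the reconstruction divided by
    the segmenter's mean Dice on ground-truth volumes. May exceed 1."""
    if baseline_mean_dice <= 0:
        raise ValueError("baseline mean Dice must be positive")
    return float(dice_reconstruction) / float(baseline_mean_dice)


def count_induced_swaps(
    fat: ScalarField3D,
    fat_hat: ScalarField3D,
    water: ScalarField3D,
    water_hat: ScalarField3D,
    body_mask: np.ndarray,
    rel_threshold: float = 0.25,
    swap_ratio: float = 0.5,
    min_component_voxels: int = 27,
    voxel_volume_ml: float | None = None,
) -> tuple[int, int, float]:
    """Count connected swapped regions a prediction induces inside the body.

    A voxel is flagged as swapped when the prediction pair *matches* the
    exchanged reference decisively better than the reference itself,
    ``|F_hat - W| + |W_hat - F| < swap_ratio * (|F_hat - F| + |W_hat - W|)``,
    and the channel disagreement exceeds ``rel_threshold`` times the local
    total signal (suppressing noise-level flips). The ratio mirrors how a
    swap reads in a difference image — the region resembles the *other*
    channel — and keeps merely-inaccurate voxels (where both distances are
    comparable) out of the tally; a genuinely exchanged region has
    near-zero distance to the exchanged reference and is always flagged.
    Flagged voxels are grouped into 26-connected components; components
    with at least ``min_component_voxels`` voxels are counted. Returns
    ``(component count, voxel tally, millilitres)``.
    """
    for name, f in (("fat_hat", fat_hat), ("water", water), ("water_hat", water_hat)):
        _require_same_shape("fat", fat.values, name, f.values)
    body = np.asarray(body_mask, dtype=bool)
    _require_same_shape("fat", fat.values, "body_mask", body)
    if not body.any():
        raise ValueError("body mask is empty")
    if voxel_volume_ml is None:
        voxel_volume_ml = fat.voxel_volume_ml
    f, w = fat.values, water.values
    fh, wh = fat_hat.values, water_hat.values
    err_keep = np.abs(fh - f) + np.abs(wh - w)
    err_swap = np.abs(fh - w) + np.abs(wh - f)
    local_signal = f + w
    flagged = body & (err_swap < swap_ratio * err_keep) & (err_keep > rel_threshold * local_signal)
    labelled, n_comp = ndimage.label(flagged, structure=_CONN26)
    if n_comp == 0:
        return 0, 0, 0.0
    sizes = np.bincount(labelled.ravel())[1:]
    big = sizes >= min_component_voxels
    count = int(big.sum())
    voxels = int(sizes[big].sum())
    return count, voxels, voxels * float(voxel_volume_ml)


# ---------------------------------------------------------------------------
# stand-in segmenter for SIS on phantoms
# ---------------------------------------------------------------------------

def segment_structure(
    fat: ScalarField3D,
    water: ScalarField3D,
    annotation: np.ndarray,
    fat_fraction_window: tuple[float, float],
    min_signal: float = 0.05,
) -> np.ndarray:
    """Segment one structure from separated fat/water channels.

    Candidate voxels have total signal above ``min_signal`` (times the volume
    maximum) and a fat fraction F/(F+W) inside the structure's
    characteristic window; the returned mask is the 26-connected candidate
    component that best overlaps the manual ``annotation`` (the component a
    human reader would identify as that organ). Empty if no candidate
    component touches the annotation — e.g. when a fat-water swap moved the
    organ's fat fraction out of its physiological window.
    """
    _require_same_shape("fat", fat.values, "water", water.values)
    annotation = np.asarray(annotation, dtype=bool)
    _require_same_shape("fat", fat.values, "annotation", annotation)
    f, w = fat.values, water.values
    total = f + w
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(total > 0, f / np.maximum(total, 1e-12), 0.0)
    lo, hi = fat_fraction_window
    candidates = (total > min_signal * total.max()) & (ff >= lo) & (ff <= hi)
    labelled, n_comp = ndimage.label(candidates, structure=_CONN26)
    if n_comp == 0:
        return np.zeros_like(annotation)
    overlaps = ndimage.sum_labels(annotation, labelled, index=np.arange(1, n_comp + 1))
    best = int(np.argmax(overlaps)) + 1
    if overlaps[best - 1] == 0:
        return np.zeros_like(annotation)
    return labelled == best


# ---------------------------------------------------------------------------
# aggregate report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-channel fidelity, per-structure semantics, and swap tallies."""

    ssim_fat: float
    ssim_water: float
    psnr_fat: float
    psnr_water: float
    dice_per_structure: dict[int, float] = field(default_factory=dict)
    sis_per_structure: dict[int, float] = field(default_factory=dict)
    induced_swap_count: int = 0
    misclassified_voxels: int = 0
    misclassified_volume_ml: float = 0.0

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        d["dice_per_structure"] = {str(k): v for k, v in self.dice_per_structure.items()}
        d["sis_per_structure"] = {str(k): v for k, v in self.sis_per_structure.items()}
        return json.dumps(d, **kwargs)


def evaluate_prediction(
    fat_hat: ScalarField3D,
    water_hat: ScalarField3D,
    fat_ref: ScalarField3D,
    water_ref: ScalarField3D,
    labels: LabelMap | None = None,
    fat_fraction_windows: dict[int, tuple[float, float]] | None = None,
    body_mask: np.ndarray | None = None,
    baseline_dice: dict[int, float] | None = None,
    rel_threshold: float = 0.25,
    min_component_voxels: int = 27,
) -> MetricReport:
    """Full evaluation of a predicted (F, W) pair against reference channels.

    With ``labels`` and per-structure fat-fraction windows, the stand-in
    segmenter produces per-structure Dice on the prediction; ``baseline_dice``
    (the segmenter's Dice on reference volumes, averaged over a cohort)
    normalizes them into SIS values. Swap counting runs inside ``body_mask``
    (default: voxels with positive reference signal).
    """
    report = MetricReport(
        ssim_fat=ssim(fat_ref, fat_hat),
        ssim_water=ssim(water_ref, water_hat),
        psnr_fat=psnr(fat_ref, fat_hat),
        psnr_water=psnr(water_ref, water_hat),
    )
    if body_mask is None:
        body_mask = (fat_ref.values + water_ref.values) > 0
    count, voxels, ml = count_induced_swaps(
        fat_ref, fat_hat, water_ref, water_hat, body_mask,
        rel_threshold=rel_threshold, min_component_voxels=min_component_voxels,
    )
    report.induced_swap_count = count
    report.misclassified_voxels = voxels
    report.misclassified_volume_ml = ml
    if labels is not None and fat_fraction_windows:
        for label_id, window in fat_fraction_windows.items():
            annotation = labels.labels == label_id
            seg = segment_structure(fat_hat, water_hat, annotation, window)
            d = dice(seg, annotation)
            report.dice_per_structure[label_id] = d
            if baseline_dice and baseline_dice.get(label_id, 0) > 0:
                report.sis_per_structure[label_id] = sis(d, baseline_dice[label_id])
    return report
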