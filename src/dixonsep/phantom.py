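"""Synthetic Dixon phantoms with injectable fat-water swap artifacts.

Real training data for swap-free separation comes from curated scanner
reconstructions; this module replaces it with a parametric digital phantom:
geometric tissue regions (ellipsoids, boxes, cylinders) with per-region fat
fractions generate non-negative W/F maps, the Dixon forward model produces
IP/OP, and configurable swap injectors corrupt the "scanner" fat/water
channels the way failed reconstructions do — whole-slab swaps, isolated-organ
swaps, boundary swaps, and compact blobs.

All randomness flows from explicit seeds; identical specs give bit-identical
phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .fields import DixonChannels, ScalarField3D, _require_same_shape
from .physics import forward_model

__all__ = [
    "TissueRegion",
    "SwapSpec",
    "PhantomSpec",
    "LabelMap",
    "generate_phantom",
    "realize_swap_mask",
    "inject_swap",
    "make_dataset",
    "default_template",
]

SWAP_KINDS = ("full_volume", "slab", "region_label", "boundary_shell", "blob")


@dataclass(frozen=True)
class TissueRegion:
    """One geometric tissue region of the phantom.

    ``geometry`` is ``ellipsoid`` (center + semi-axes), ``box`` (center +
    half-extents) or ``cylinder`` (center + (radius_x, radius_y, half_len_z)),
    all in voxel units. ``fat_fraction`` is the fat share of the region's
    total signal ``intensity``; later regions overwrite earlier ones.
    """

    geometry: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    fat_fraction: float
    intensity: float
    fat_fraction_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.geometry not in ("ellipsoid", "box", "cylinder"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.fat_fraction_range is not None:
            lo, hi = self.fat_fraction_range
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"fat_fraction_range must be ordered within [0, 1], got {self.fat_fraction_range}")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError(f"fat_fraction must be in [0, 1], got {self.fat_fraction}")
        if self.intensity <= 0:
            raise ValueError(f"intensity must be positive, got {self.intensity}")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean support of the region on a voxel grid of the given shape."""
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
        if self.geometry == "ellipsoid":
            return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0
        if self.geometry == "box":
            return (
                (np.abs(x - cx) <= ax) & (np.abs(y - cy) <= ay) & (np.abs(z - cz) <= az)
            )
        # cylinder: circular cross-section in (x, y), extent along z
        return (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0) & (
            np.abs(z - cz) <= az
        )


@dataclass(frozen=True)
class SwapSpec:
    """Description of one fat-water swap artifact to inject.

    Kinds mirror the failure modes seen in scanner reconstructions:

    - ``full_volume`` — the whole volume swapped (a fully swapped series);
    - ``slab`` — all voxels with index in ``[lo, hi)`` along ``axis``
      (a swap covering one acquisition station);
    - ``region_label`` — the support of one labelled organ (isolated-organ
      swap, e.g. the top of the liver);
    - ``boundary_shell`` — a shell of ``thickness`` voxels at the volume
      faces (field-inhomogeneity swaps at the edge of the field of view);
    - ``blob`` — a ball of ``radius`` at ``center`` (localised partial swap).
    """

    kind: str
    axis: int = 2
    lo: int = 0
    hi: int = 0
    label: int = 0
    thickness: int = 2
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SWAP_KINDS:
            raise ValueError(f"unknown swap kind {self.kind!r}; expected one of {SWAP_KINDS}")


@dataclass(frozen=True)
class LabelMap:
    """Integer tissue labels; 0 is background, region i has label i + 1."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be rank-3, got shape {labels.shape}")
        if labels.dtype.kind not in "iu" or np.any(labels < 0):
            raise ValueError("labels must be non-negative integers")
        object.__setattr__(self, "labels", labels.astype(np.int32, copy=False))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def ids(self) -> list[int]:
        return [int(v) for v in np.unique(self.labels) if v != 0]


@dataclass(frozen=True)
class PhantomSpec:
    """Full parametric description of one synthetic subject.

    ``noise_sigma`` is the standard deviation of additive Gaussian noise
    applied to the W and F tissue maps (truncated at zero, magnitude data
    being non-negative) before IP/OP are synthesized. ``texture_amp``
    modulates the water and fat maps with two independent smooth random
    fields (correlation length ``texture_scale`` voxels) inside tissue:
    real tissue is spatially heterogeneous in both total signal and fat
    content, and that heterogeneity is what makes the opposed-phase channel
    informative voxel-by-voxel rather than merely region-by-region. ``swap_specs`` corrupt
    only the scanner-style fat/water channels; IP and OP are left untouched,
    as swaps arise downstream of the acquisition.
    """

    shape: tuple[int, int, int]
    regions: tuple[TissueRegion, ...]
    spacing: tuple[float, float, float] = (2.2, 2.2, 3.0)
    noise_sigma: float = 0.0
    texture_amp: float = 0.0
    texture_scale: float = 5.0
    swap_specs: tuple[SwapSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "swap_specs", tuple(self.swap_specs))
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if len(self.regions) == 0:
            raise ValueError("phantom needs at least one tissue region")


def generate_phantom(spec: PhantomSpec) -> tuple[DixonChannels, LabelMap]:
    """Render a phantom: clean DixonChannels with matching tissue labels.

    For each voxel of region ``r``: ``W = intensity * (1 - fat_fraction)``
    and ``F = intensity * fat_fraction`` before noise; IP/OP follow from the
    forward model applied to the noisy W/F, so the returned channels are
    exactly physics-consistent. Background voxels are zero.
    """
    shape = tuple(spec.shape)
    water = np.zeros(shape)
    fat = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    for i, region in enumerate(spec.regions):
        m = region.mask(shape)
        if not m.any():
            raise ValueError(
                f"region {i} (center {region.center}, semi-axes {region.semi_axes}) "
                f"lies outside the grid of shape {shape}"
            )
        water[m] = region.intensity * (1.0 - region.fat_fraction)
        fat[m] = region.intensity * region.fat_fraction
        labels[m] = i + 1
    rng = np.random.default_rng(spec.seed)
    if spec.texture_amp > 0:
        tissue = labels > 0
        for channel in (water, fat):
            t = ndimage.gaussian_filter(rng.normal(size=shape), spec.texture_scale)
            t /= max(float(t.std()), 1e-12)
            channel[tissue] *= np.clip(1.0 + spec.texture_amp * t[tissue], 0.0, None)
    if spec.noise_sigma > 0:
        water = np.maximum(water + rng.normal(0.0, spec.noise_sigma, shape), 0.0)
        fat = np.maximum(fat + rng.normal(0.0, spec.noise_sigma, shape), 0.0)
    water_f = ScalarField3D(water, spec.spacing)
    fat_f = ScalarField3D(fat, spec.spacing)
    ip, op = forward_model(water_f, fat_f)
    channels = DixonChannels(ip=ip, op=op, fat=fat_f, water=water_f)
    return channels, LabelMap(labels)


def realize_swap_mask(
    spec: SwapSpec, labels: LabelMap, rng_seed: int = 0
) -> np.ndarray:
    """Turn a SwapSpec into a boolean mask on the label grid."""
    shape = labels.shape
    if spec.kind == "full_volume":
        return np.ones(shape, dtype=bool)
    if spec.kind == "slab":
        if not 0 <= spec.axis <= 2:
            raise ValueError(f"slab axis must be 0, 1 or 2, got {spec.axis}")
        mask = np.zeros(shape, dtype=bool)
        idx = [slice(None)] * 3
        idx[spec.axis] = slice(spec.lo, spec.hi)
        mask[tuple(idx)] = True
        return mask
    if spec.kind == "region_label":
        if spec.label not in labels.ids():
            raise ValueError(f"label {spec.label} absent from label map (have {labels.ids()})")
        return labels.labels == spec.label
    if spec.kind == "boundary_shell":
        t = spec.thickness
        mask = np.ones(shape, dtype=bool)
        if all(d > 2 * t for d in shape):
            mask[t : shape[0] - t, t : shape[1] - t, t : shape[2] - t] = False
        return mask
    if spec.kind == "blob":
        cx, cy, cz = spec.center
        x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= spec.radius**2
    raise ValueError(f"unknown swap kind {spec.kind!r}")


def inject_swap(
    fat: ScalarField3D, water: ScalarField3D, mask: np.ndarray
) -> tuple[ScalarField3D, ScalarField3D]:
    """Exchange fat and water inside a mask, emulating a reconstruction swap.

    IP and OP are untouched by construction — swaps only occur in the fat
    and water volumes. Applying the same mask twice restores the originals.
    """
    _require_same_shape("fat", fat.values, "mask", np.asarray(mask))
    _require_same_shape("fat", fat.values, "water", water.values)
    mask = np.asarray(mask, dtype=bool)
    fat_new = np.where(mask, water.values, fat.values)
    water_new = np.where(mask, fat.values, water.values)
    return fat.with_values(fat_new), water.with_values(water_new)


def default_template(edge: int = 64) -> PhantomSpec:
    """Body-like template with swap-prone and stable tissue.

    A fat-dominant outer shell (subcutaneous fat, fat fraction ~0.9 — the
    voxels the analytic inversion returns swapped) encloses a lean torso and
    water-dominant organs. Each region carries a ``fat_fraction_range``: the
    per-subject fat content of a tissue varies substantially across a cohort
    (hepatic fat alone spans a few percent to tens of percent), and that
    variation is precisely the information carried by the opposed-phase
    channel — IP = W + F is blind to it.
    """
    c = (edge - 1) / 2.0
    r = edge / 2.0
    body = TissueRegion(  # subcutaneous fat shell (fills the body outline)
        geometry="ellipsoid",
        center=(c, c, c),
        semi_axes=(0.92 * r, 0.80 * r, 0.95 * r),
        fat_fraction=0.9,
        fat_fraction_range=(0.85, 0.95),
        intensity=100.0,
    )
    torso = TissueRegion(  # lean interior: muscle + viscera background
        geometry="ellipsoid",
        center=(c, c, c),
        semi_axes=(0.74 * r, 0.62 * r, 0.86 * r),
        fat_fraction=0.25,
        fat_fraction_range=(0.1, 0.4),
        intensity=100.0,
    )
    organ_a = TissueRegion(  # large organ (liver-like)
        geometry="ellipsoid",
        center=(0.62 * edge, 0.48 * edge, 0.40 * edge),
        semi_axes=(0.17 * edge, 0.14 * edge, 0.13 * edge),
        fat_fraction=0.08,
        fat_fraction_range=(0.02, 0.3),
        intensity=120.0,
    )
    organ_b = TissueRegion(  # small organ (kidney-like)
        geometry="ellipsoid",
        center=(0.33 * edge, 0.50 * edge, 0.62 * edge),
        semi_axes=(0.08 * edge, 0.08 * edge, 0.11 * edge),
        fat_fraction=0.02,
        fat_fraction_range=(0.02, 0.15),
        intensity=110.0,
    )
    muscle = TissueRegion(  # paraspinal-muscle-like cylinder
        geometry="cylinder",
        center=(0.48 * edge, 0.70 * edge, 0.50 * edge),
        semi_axes=(0.09 * edge, 0.06 * edge, 0.32 * edge),
        fat_fraction=0.3,
        fat_fraction_range=(0.15, 0.45),
        intensity=90.0,
    )
    return PhantomSpec(
        shape=(edge, edge, edge),
        regions=(body, torso, organ_a, organ_b, muscle),
        noise_sigma=1.0,
        texture_amp=0.2,
        texture_scale=5.0,
        seed=0,
    )


@dataclass(frozen=True)
class SubjectSample:
    """One synthetic subject: clean channels, scanner-style (possibly
    swap-corrupted) channels, labels and the injected-swap mask."""

    clean: DixonChannels
    scanner: DixonChannels
    labels: LabelMap
    swap_mask: np.ndarray


def _jitter_region(region: TissueRegion, rng: np.random.Generator, scale: float) -> TissueRegion:
    center = tuple(c * (1 + rng.uniform(-scale, scale)) for c in region.center)
    semi = tuple(max(1.0, a * (1 + rng.uniform(-scale, scale))) for a in region.semi_axes)
    if region.fat_fraction_range is not None:
        lo, hi = region.fat_fraction_range
        ff = float(rng.uniform(lo, hi))
    else:
        ff = float(np.clip(region.fat_fraction + rng.uniform(-0.05, 0.05), 0.0, 1.0))
    inten = region.intensity * (1 + rng.uniform(-scale, scale))
    return replace(region, center=center, semi_axes=semi, fat_fraction=ff, intensity=inten)


def make_dataset(
    n_subjects: int,
    template: PhantomSpec | None = None,
    jitter: float = 0.06,
    swap_fraction: float = 0.5,
    swap_kinds: tuple[str, ...] = ("slab", "region_label", "boundary_shell", "blob"),
    seed: int = 0,
) -> list[SubjectSample]:
    """Generate a cohort of phantoms with per-subject anatomical jitter.

    A ``swap_fraction`` of subjects get a swap injected into their
    scanner-style F/W channels (the clean channels are retained as training
    labels), cycling through ``swap_kinds``. Deterministic under ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0.0 <= jitter < 0.5:
        raise ValueError(f"jitter must be in [0, 0.5), got {jitter}")
    if not 0.0 <= swap_fraction <= 1.0:
        raise ValueError(f"swap_fraction must be in [0, 1], got {swap_fraction}")
    if template is None:
        template = default_template()
    master = np.random.default_rng(seed)
    edge = template.shape
    samples: list[SubjectSample] = []
    n_swapped = int(round(swap_fraction * n_subjects))
    for i in range(n_subjects):
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        regions = tuple(_jitter_region(r, rng, jitter) for r in template.regions)
        spec = replace(template, regions=regions, seed=sub_seed)
        clean, labels = generate_phantom(spec)
        mask = np.zeros(clean.shape, dtype=bool)
        if i < n_swapped:
            kind = swap_kinds[i % len(swap_kinds)]
            mask = _random_swap_mask(kind, clean.shape, labels, rng)
        fat_s, water_s = inject_swap(clean.fat, clean.water, mask)
        scanner = clean.replace(fat=fat_s, water=water_s)
        samples.append(SubjectSample(clean=clean, scanner=scanner, labels=labels, swap_mask=mask))
    return samples


def _random_swap_mask(
    kind: str, shape: tuple[int, int, int], labels: LabelMap, rng: np.random.Generator
) -> np.ndarray:
    if kind == "slab":
        axis = 2
        width = shape[axis] // 2
        lo = int(rng.integers(0, shape[axis] - width + 1))
        spec = SwapSpec(kind="slab", axis=axis, lo=lo, hi=lo + width)
    elif kind == "region_label":
        ids = labels.ids()
        spec = SwapSpec(kind="region_label", label=int(rng.choice(ids)))
    elif kind == "boundary_shell":
        spec = SwapSpec(kind="boundary_shell", thickness=int(rng.integers(2, 5)))
    elif kind == "blob":
        center = tuple(float(rng.uniform(0.3, 0.7) * d) for d in shape)
        spec = SwapSpec(kind="blob", center=center, radius=float(rng.uniform(0.08, 0.18) * min(shape)))
    elif kind == "full_volume":
        spec = SwapSpec(kind="full_volume")
    else:
        raise ValueError(f"unknown swap kind {kind!r}")
    return realize_swap_mask(spec, labels)
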