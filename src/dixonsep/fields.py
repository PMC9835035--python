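"""Volumetric containers for two-point Dixon data.

A two-point Dixon acquisition yields two magnitude volumes, in-phase (IP)
and opposed-phase (OP); the scanner derives fat (F) and water (W) volumes
from them. All four are co-registered non-negative 3D scalar fields sharing
one voxel grid, which is what :class:`DixonChannels` bundles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScalarField3D", "DixonChannels"]


@dataclass(frozen=True)
class ScalarField3D:
    """A rank-3 scalar field with voxel spacing in millimetres.

    Parameters
    ----------
    values : ndarray
        Rank-3 array of signal values (arbitrary units).
    spacing : tuple of float
        Voxel edge lengths in mm along (x, y, z); strictly positive.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 3:
            raise ValueError(f"expected a rank-3 field, got shape {values.shape}")
        if any(d < 1 for d in values.shape):
            raise ValueError(f"every dimension must be >= 1, got {values.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        object.__setattr__(self, "spacing", spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive reals, got {spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def with_values(self, values: np.ndarray) -> "ScalarField3D":
        return ScalarField3D(values, self.spacing)


def _require_same_shape(name_a: str, a: np.ndarray, name_b: str, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(
            f"shape mismatch: {name_a} has shape {a.shape}, {name_b} has shape {b.shape}"
        )


@dataclass(frozen=True)
class DixonChannels:
    """The four co-registered magnitude volumes of one subject.

    ``ip`` and ``op`` are the acquired in-phase / opposed-phase volumes;
    ``fat`` and ``water`` are the separated channels (scanner output, ground
    truth, or prediction depending on context). All four share shape and
    spacing and are non-negative.
    """

    ip: ScalarField3D
    op: ScalarField3D
    fat: ScalarField3D
    water: ScalarField3D

    def __post_init__(self) -> None:
        ref = self.ip
        for name in ("op", "fat", "water"):
            f: ScalarField3D = getattr(self, name)
            if f.shape != ref.shape:
                raise ValueError(
                    f"shape mismatch: ip has shape {ref.shape}, {name} has shape {f.shape}"
                )
        for name in ("ip", "op", "fat", "water"):
            f = getattr(self, name)
            if np.any(f.values < 0):
                raise ValueError(f"channel {name!r} contains negative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ip.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.ip.spacing

    def replace(self, **kwargs: ScalarField3D) -> "DixonChannels":
        fields = {"ip": self.ip, "op": self.op, "fat": self.fat, "water": self.water}
        fields.update(kwargs)
        return DixonChannels(**fields)

    def stack(self) -> np.ndarray:
        """Channels as one (4, X, Y, Z) array in (ip, op, fat, water) order."""
        return np.stack(
            [self.ip.values, self.op.values, self.fat.values, self.water.values]
        )
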