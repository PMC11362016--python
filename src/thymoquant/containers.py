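"""Core in-memory containers for volumetric imaging data.

Conventions
-----------
Arrays are indexed ``(z, y, x)``; ``spacing`` is the per-axis voxel pitch in
micrometres in the same order.  A voxel index ``(i, j, k)`` sits at physical
coordinate ``(i*sz, j*sy, k*sx)`` μm (0-based, grid registered at voxel
centres).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: (z, y, x) voxel pitch of the light-sheet preset, μm.
LIGHTSHEET_SPACING = (4.9, 0.915, 0.915)
#: (z, y, x) voxel pitch of the confocal preset, μm.
CONFOCAL_SPACING = (2.0, 0.22, 0.22)

REGION_NAMES = ("lobe", "medulla", "hd", "cortex")


@dataclass
class ImageStack:
    """Multi-channel 3D intensity volume with physical voxel spacing.

    Parameters
    ----------
    channels
        Mapping of channel name to a 3D non-negative float array. All
        channels must share one grid shape.
    spacing
        Voxel pitch ``(z, y, x)`` in μm, strictly positive.
    """

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack needs at least one channel")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        shapes = {ch: np.asarray(v).shape for ch, v in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channels disagree on grid shape: {shapes}")
        for ch, v in self.channels.items():
            arr = np.asarray(v, dtype=np.float64)
            if arr.ndim != 3:
                raise ValueError(f"channel {ch!r} is not 3D")
            self.channels[ch] = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return float(np.prod(self.spacing))

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not present; available: {self.channel_names}"
            )
        return self.channels[name]


@dataclass
class RegionMask:
    """A single binary region volume on a spaced grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_um3(self) -> float:
        """Region volume = voxel count × voxel volume (μm³)."""
        return self.voxel_count * self.voxel_volume


@dataclass
class RegionMaskSet:
    """Disjoint lobe/medulla/HD/cortex masks with exact volume bookkeeping.

    Invariants (enforced at construction): ``medulla``, ``hd`` and ``cortex``
    are pairwise disjoint subsets of ``lobe`` and their union equals ``lobe``,
    so ``volume(cortex) + volume(medulla) + volume(hd) == volume(lobe)``
    exactly on integer voxel counts.
    """

    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    volumes: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        missing = set(REGION_NAMES) - set(self.masks)
        if missing:
            raise ValueError(f"missing region masks: {sorted(missing)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        lobe = self.masks["lobe"]
        for name in ("medulla", "hd", "cortex"):
            if np.any(self.masks[name] & ~lobe):
                raise ValueError(f"region {name!r} extends outside the lobe")
        if np.any(self.masks["medulla"] & self.masks["hd"]):
            raise ValueError("medulla and hd overlap")
        union = self.masks["medulla"] | self.masks["hd"] | self.masks["cortex"]
        if np.any(union != lobe):
            raise ValueError("cortex ∪ medulla ∪ hd must equal lobe")
        voxvol = float(np.prod(self.spacing))
        self.volumes = {
            name: int(self.masks[name].sum()) * voxvol for name in REGION_NAMES
        }

    def region(self, name: str) -> RegionMask:
        return RegionMask(self.masks[name], self.spacing)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))
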