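"""Core volumetric containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Intensity clip windows per modality (lower, upper). CT in Hounsfield
#: units, PET in standardized uptake values.
CLIP_WINDOWS: dict[str, tuple[float, float]] = {
    "CT": (-500.0, 200.0),
    "PET": (0.01, 20.0),
}

MODALITY_UNITS = {"CT": "HU", "PET": "SUV"}


@dataclass
class VolumeImage:
    """A 3D scalar field with voxel spacing, indexed (x, y, z)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if isinstance(self.spacing, (int, float)):
            self.spacing = (float(self.spacing),) * 3
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not self.units:
            self.units = MODALITY_UNITS.get(self.modality, "")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SegmentationMask:
    """Binary tumor mask aligned to a :class:`VolumeImage` (1 = tumor)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        if isinstance(self.spacing, (int, float)):
            self.spacing = (float(self.spacing),) * 3
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class ROIVolume:
    """Fixed-size, intensity-clipped region of interest around a tumor.

    ``origin_offset`` is the (possibly negative) index of the ROI's first
    voxel in the source volume, recorded so that risk maps computed on the
    ROI can be mapped back to source coordinates exactly.
    """

    data: np.ndarray
    modality: str
    spacing: float = 1.0
    origin_offset: tuple[int, int, int] = (0, 0, 0)
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"ROI must be 3D, got shape {self.data.shape}")
        self.origin_offset = tuple(int(o) for o in self.origin_offset)
        if not self.units:
            self.units = MODALITY_UNITS.get(self.modality, "")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape
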