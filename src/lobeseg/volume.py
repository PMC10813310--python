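"""In-memory containers for CT volumes, lobe label maps, and training slices.

Axis convention: all arrays are (z, y, x), 0-based voxel indices; ``spacing``
follows the same order in millimetres.  I/O adapters (``lobeseg.cli_io``)
convert external formats to this convention at the boundary.

Label semantics (6 classes): 0 background, 1 upper-left lobe, 2 lower-left
lobe, 3 upper-right lobe, 4 middle-right lobe, 5 lower-right lobe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_CLASSES = 6
LOBE_NAMES = {
    0: "background",
    1: "upper_left",
    2: "lower_left",
    3: "upper_right",
    4: "middle_right",
    5: "lower_right",
}


@dataclass
class Volume:
    """A 3D intensity image with physical-space metadata.

    data : (z, y, x) float array, finite everywhere.
    spacing_mm : per-axis spacing (z, y, x), all positive.
    origin / direction : physical-space metadata, passed through unmodified
    by every processing step.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume.data must be 3D (z,y,x), got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume.data contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive values, got {self.spacing_mm}")
        self.direction = np.asarray(self.direction, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMap:
    """Integer lobe labels aligned voxel-for-voxel with a :class:`Volume`."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelMap.data must be 3D (z,y,x), got ndim={self.data.ndim}")
        if self.data.dtype.kind not in "iu":
            raise ValueError(f"LabelMap.data must be integer-typed, got {self.data.dtype}")
        vals = np.unique(self.data)
        if vals.min() < 0 or vals.max() >= N_CLASSES:
            raise ValueError(f"label values must lie in 0..{N_CLASSES - 1}, got {vals}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        self.direction = np.asarray(self.direction, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def label_counts(self) -> dict[int, int]:
        counts = np.bincount(self.data.ravel(), minlength=N_CLASSES)
        return {k: int(counts[k]) for k in range(N_CLASSES)}


@dataclass
class SliceSample:
    """One axial training unit: a normalized 256x256 image and its mask."""

    image: np.ndarray  # (1, 256, 256) float in [0, 1]
    mask: np.ndarray  # (256, 256) int in {0..5}
    volume_id: str = ""
    slice_index: int = -1

    SIZE = 256

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim == 2:
            self.image = self.image[None]
        if self.image.shape != (1, self.SIZE, self.SIZE):
            raise ValueError(f"image must be (1,{self.SIZE},{self.SIZE}), got {self.image.shape}")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image intensities must lie in [0, 1]")
        self.mask = np.asarray(self.mask)
        if self.mask.shape != (self.SIZE, self.SIZE):
            raise ValueError(f"mask must be ({self.SIZE},{self.SIZE}), got {self.mask.shape}")
        if self.mask.dtype.kind not in "iu":
            raise ValueError("mask must be integer-typed")
        if self.mask.min() < 0 or self.mask.max() >= N_CLASSES:
            raise ValueError("mask values must lie in 0..5")
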