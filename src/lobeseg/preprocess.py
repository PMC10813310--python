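"""Volume preprocessing: z-resampling, intensity normalization, 256x256 slicing.

The pipeline is 2D slice-based, so resampling only harmonizes the through-
plane (z) spacing — to 2 mm by default — while the in-plane geometry is
handled by the per-slice resize to 256x256.  Images are interpolated with
cubic B-splines (SimpleITK), label maps with nearest neighbor so the label
set can never grow.
"""

from __future__ import annotations

import numpy as np
import SimpleITK as sitk
from skimage.transform import resize

from .volume import LabelMap, SliceSample, Volume

TARGET_Z_MM = 2.0
SLICE_SIZE = 256


class AlignmentError(ValueError):
    """Volume and label geometry disagree."""


class DegenerateVolumeError(ValueError):
    """The volume carries no usable intensity range."""


def _to_sitk(data: np.ndarray, spacing_zyx: tuple[float, float, float]) -> sitk.Image:
    img = sitk.GetImageFromArray(data)
    sz, sy, sx = spacing_zyx
    img.SetSpacing((sx, sy, sz))
    return img


def _resample_z(
    data: np.ndarray, spacing: tuple[float, float, float], target_z: float, interpolator
) -> tuple[np.ndarray, tuple[float, float, float]]:
    nz, ny, nx = data.shape
    sz, sy, sx = spacing
    # sample points: floor(physical z-extent / target) + 1
    new_nz = int(np.floor((nz - 1) * sz / target_z)) + 1
    img = _to_sitk(data, spacing)
    out = sitk.Resample(
        img,
        (nx, ny, new_nz),
        sitk.Transform(),
        interpolator,
        img.GetOrigin(),
        (sx, sy, target_z),
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
    )
    return sitk.GetArrayFromImage(out), (target_z, sy, sx)


def resample_to_spacing(volume: Volume, target_z_mm: float = TARGET_Z_MM) -> Volume:
    """Resample to a uniform slice spacing with cubic B-spline interpolation.

    In-plane geometry is unchanged; the new slice count is
    ``floor((n-1) * old_z / target_z) + 1`` (sample points over the same
    physical extent).  If the spacing already matches, data pass through
    unchanged.
    """
    if target_z_mm <= 0:
        raise ValueError(f"target_z_mm must be > 0, got {target_z_mm}")
    if abs(volume.spacing_mm[0] - target_z_mm) < 1e-9:
        return Volume(volume.data.copy(), volume.spacing_mm, volume.origin, volume.direction)
    data, spacing = _resample_z(
        volume.data.astype(np.float64), volume.spacing_mm, target_z_mm, sitk.sitkBSpline
    )
    return Volume(data.astype(np.float32), spacing, volume.origin, volume.direction)


def resample_labels(labels: LabelMap, target_z_mm: float = TARGET_Z_MM) -> LabelMap:
    """Nearest-neighbor z-resampling with the same geometry as the image path."""
    if target_z_mm <= 0:
        raise ValueError(f"target_z_mm must be > 0, got {target_z_mm}")
    if abs(labels.spacing_mm[0] - target_z_mm) < 1e-9:
        return LabelMap(labels.data.copy(), labels.spacing_mm, labels.origin, labels.direction)
    data, spacing = _resample_z(
        labels.data.astype(np.uint8), labels.spacing_mm, target_z_mm, sitk.sitkNearestNeighbor
    )
    return LabelMap(data.astype(np.uint8), spacing, labels.origin, labels.direction)


def normalize_intensity(volume: Volume, hu_window: tuple[float, float] | None = None) -> Volume:
    """Min-max scale intensities to [0, 1] (per volume).

    An optional HU clipping window is applied first; off by default.
    Idempotent on its own output.  A constant volume is rejected rather than
    silently mapped to zeros.
    """
    data = volume.data.astype(np.float32)
    if hu_window is not None:
        lo, hi = hu_window
        if hi <= lo:
            raise ValueError(f"hu_window must satisfy hi > lo, got {hu_window}")
        data = np.clip(data, lo, hi)
    vmin, vmax = float(data.min()), float(data.max())
    if vmax <= vmin:
        raise DegenerateVolumeError("cannot normalize a constant-intensity volume")
    data = (data - vmin) / (vmax - vmin)
    return Volume(data, volume.spacing_mm, volume.origin, volume.direction)


def volume_to_slices(
    volume: Volume, labels: LabelMap, volume_id: str = "", size: int = SLICE_SIZE
) -> list[SliceSample]:
    """Cut a normalized volume into per-slice training samples.

    Each axial slice is resized to ``size`` x ``size``: bilinear for the
    image, nearest-neighbor for the mask.  Slice order is preserved.
    """
    if volume.shape != labels.shape:
        raise AlignmentError(
            f"volume shape {volume.shape} does not match labels shape {labels.shape}"
        )
    if volume.data.min() < 0 or volume.data.max() > 1:
        raise ValueError("volume must be normalized to [0, 1] before slicing")
    samples = []
    for k in range(volume.shape[0]):
        img = volume.data[k]
        msk = labels.data[k]
        if img.shape != (size, size):
            img = resize(img, (size, size), order=1, preserve_range=True, anti_aliasing=False)
            msk = resize(
                msk, (size, size), order=0, preserve_range=True, anti_aliasing=False
            ).astype(labels.data.dtype)
        img = np.clip(img, 0.0, 1.0).astype(np.float32)
        samples.append(SliceSample(img[None], msk.copy(), volume_id=volume_id, slice_index=k))
    return samples


def preprocess_volume(
    volume: Volume,
    labels: LabelMap,
    target_z_mm: float = TARGET_Z_MM,
    hu_window: tuple[float, float] | None = None,
    volume_id: str = "",
) -> list[SliceSample]:
    """Full pipeline: resample to uniform z spacing, normalize, slice."""
    vol = resample_to_spacing(volume, target_z_mm)
    lab = resample_labels(labels, target_z_mm)
    vol = normalize_intensity(vol, hu_window=hu_window)
    return volume_to_slices(vol, lab, volume_id=volume_id)
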