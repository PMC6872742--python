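"""ROI preprocessing: isotropic resampling, centroid cropping, intensity
clipping, and rigid training-pair augmentation.

Coordinate conventions (the source protocol is silent on all of them):
0-based voxel indices; a voxel's physical position is ``index * spacing``;
crop windows are half-open; the mask centroid is rounded per axis as
``floor(c + 0.5)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .types import CLIP_WINDOWS, ROIVolume, SegmentationMask, VolumeImage


def resample_isotropic(
    volume: VolumeImage | SegmentationMask,
    target_spacing: float = 1.0,
    order: int | None = None,
) -> VolumeImage | SegmentationMask:
    """Resample a volume (or mask) to isotropic ``target_spacing``.

    Interpolation is linear for images and nearest-neighbor for masks unless
    ``order`` overrides it. Output voxel ``j`` samples the input at physical
    position ``j * target_spacing`` (edge-clamped).
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    is_mask = isinstance(volume, SegmentationMask)
    if order is None:
        order = 0 if is_mask else 1
    spacing = np.asarray(volume.spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("input spacing must be positive")
    in_shape = np.asarray(volume.data.shape)
    out_shape = np.maximum(1, np.round(in_shape * spacing / target_spacing)).astype(int)
    axes = [np.arange(n) * target_spacing / s for n, s in zip(out_shape, spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    data = volume.data.astype(float, copy=False)
    out = ndimage.map_coordinates(data, np.stack(coords), order=order, mode="nearest")
    new_spacing = (float(target_spacing),) * 3
    if is_mask:
        return SegmentationMask(out > 0.5, new_spacing)
    return replace(volume, data=out, spacing=new_spacing)


def mask_centroid(mask: SegmentationMask) -> tuple[int, int, int]:
    """Center of mass of the mask, rounded per axis as floor(c + 0.5)."""
    if not mask.data.any():
        raise ValueError("mask is empty; cannot locate a tumor centroid")
    c = np.argwhere(mask.data).mean(axis=0)
    return tuple(int(np.floor(ci + 0.5)) for ci in c)


def _crop(data: np.ndarray, center, out_shape, pad_value) -> tuple[np.ndarray, tuple[int, ...]]:
    """Half-open crop ``[start, start + out_shape)`` with constant padding."""
    out = np.full(out_shape, pad_value, dtype=data.dtype if data.dtype.kind == "f" else float)
    if data.dtype == bool:
        out = np.zeros(out_shape, bool)
    start = tuple(int(c) - s // 2 for c, s in zip(center, out_shape))
    src, dst = [], []
    for st, n_out, n_in in zip(start, out_shape, data.shape):
        lo, hi = max(st, 0), min(st + n_out, n_in)
        if lo >= hi:
            return out, start
        src.append(slice(lo, hi))
        dst.append(slice(lo - st, hi - st))
    out[tuple(dst)] = data[tuple(src)]
    return out, start


def crop_roi(
    volume: VolumeImage,
    mask: SegmentationMask,
    roi_shape: tuple[int, int, int] = (96, 96, 48),
) -> ROIVolume:
    """Crop a fixed-size ROI centered on the tumor's center of mass.

    Out-of-bounds regions are padded with the modality's lower clip bound so
    the padding is inert after clipping. The crop start index is recorded as
    ``origin_offset`` for exact back-mapping of risk maps.
    """
    if volume.modality not in CLIP_WINDOWS:
        raise ValueError(f"unknown modality {volume.modality!r}")
    center = mask_centroid(mask)
    pad = CLIP_WINDOWS[volume.modality][0]
    data, start = _crop(volume.data, center, tuple(roi_shape), pad)
    return ROIVolume(data, volume.modality, spacing=volume.spacing[0], origin_offset=start)


def crop_mask(
    mask: SegmentationMask,
    roi_shape: tuple[int, int, int] = (96, 96, 48),
    center: tuple[int, int, int] | None = None,
) -> SegmentationMask:
    """Crop the mask itself to the ROI window (zero padding)."""
    if center is None:
        center = mask_centroid(mask)
    data, _ = _crop(mask.data, center, tuple(roi_shape), False)
    return SegmentationMask(data, mask.spacing)


def embed_roi(
    roi_data: np.ndarray,
    origin_offset: tuple[int, int, int],
    source_shape: tuple[int, int, int],
    fill: float = 0.0,
) -> np.ndarray:
    """Place ROI-space data back at its source coordinates (crop inverse)."""
    out = np.full(source_shape, fill, dtype=float)
    src, dst = [], []
    for st, n_roi, n_src in zip(origin_offset, roi_data.shape, source_shape):
        lo, hi = max(st, 0), min(st + n_roi, n_src)
        if lo >= hi:
            return out
        dst.append(slice(lo, hi))
        src.append(slice(lo - st, hi - st))
    out[tuple(dst)] = roi_data[tuple(src)]
    return out


def clip_intensities(volume: VolumeImage | ROIVolume) -> VolumeImage | ROIVolume:
    """Clip intensities to the modality window (CT [-500, 200], PET [0.01, 20]).

    Values outside the window map to the nearest bound; order inside is
    preserved. Idempotent.
    """
    if volume.modality not in CLIP_WINDOWS:
        raise ValueError(f"unknown modality {volume.modality!r}")
    lo, hi = CLIP_WINDOWS[volume.modality]
    return replace(volume, data=np.clip(volume.data, lo, hi))


@dataclass(frozen=True)
class RigidTransform:
    """Axis flips, right-angle in-plane rotation, and integer translation."""

    flips: tuple[bool, bool, bool] = (False, False, False)
    k90: int = 0  # quarter-turns in the (x, y) plane
    shift: tuple[int, int, int] = (0, 0, 0)


def apply_rigid(data: np.ndarray, t: RigidTransform, fill) -> np.ndarray:
    """Apply rotation, then flips, then translation (constant fill)."""
    out = data
    if t.k90 % 4:
        if data.shape[0] != data.shape[1]:
            raise ValueError("in-plane rotation requires square (x, y) dimensions")
        out = np.rot90(out, k=t.k90 % 4, axes=(0, 1))
    for ax, f in enumerate(t.flips):
        if f:
            out = np.flip(out, axis=ax)
    if any(t.shift):
        shifted = np.full_like(out, fill)
        src, dst = [], []
        for s, n in zip(t.shift, out.shape):
            lo, hi = max(-s, 0), min(n - s, n)
            if lo >= hi:
                return shifted
            src.append(slice(lo, hi))
            dst.append(slice(lo + s, hi + s))
        shifted[tuple(dst)] = out[tuple(src)]
        out = shifted
    return np.ascontiguousarray(out)


def apply_rigid_pair(
    image: ROIVolume, mask: SegmentationMask, t: RigidTransform
) -> tuple[ROIVolume, SegmentationMask]:
    """Apply one rigid transform identically to an image and its mask."""
    fill = CLIP_WINDOWS.get(image.modality, (0.0, 0.0))[0]
    img = replace(image, data=apply_rigid(image.data, t, fill))
    msk = SegmentationMask(apply_rigid(mask.data, t, False), mask.spacing)
    return img, msk


def augment(
    image: ROIVolume,
    mask: SegmentationMask,
    n_aug: int,
    seed: int = 0,
    max_shift: int = 5,
    allow_rotation: bool = True,
) -> list[tuple[ROIVolume, SegmentationMask]]:
    """Generate ``n_aug`` rigidly transformed copies of an (image, mask) pair.

    Each copy combines random axis flips, a random right-angle rotation in
    the axial plane (when the plane is square), and a bounded integer
    translation; the same transform is applied to image and mask so the pair
    never desynchronizes. Deterministic under ``seed``.
    """
    if n_aug < 0:
        raise ValueError("n_aug must be nonnegative")
    if image.data.shape != mask.data.shape:
        raise ValueError("image and mask shapes disagree")
    rng = np.random.default_rng(seed)
    rotatable = allow_rotation and image.data.shape[0] == image.data.shape[1]
    pairs = []
    for _ in range(n_aug):
        t = RigidTransform(
            flips=tuple(bool(b) for b in rng.integers(0, 2, 3)),
            k90=int(rng.integers(0, 4)) if rotatable else 0,
            shift=tuple(int(s) for s in rng.integers(-max_shift, max_shift + 1, 3)),
        )
        pairs.append(apply_rigid_pair(image, mask, t))
    return pairs
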