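"""NIfTI volume I/O and artifact serialization helpers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .types import SegmentationMask, VolumeImage

# modality is stashed in the NIfTI descrip field
_DESCRIP_PREFIX = "seg2surv:"


def write_volume(volume: VolumeImage | SegmentationMask, path) -> None:
    """Write a volume or mask as NIfTI with spacing in the affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, SegmentationMask):
        data = volume.data.astype(np.uint8)
        modality = "MASK"
    else:
        data = volume.data.astype(np.float32)
        modality = volume.modality
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header["descrip"] = f"{_DESCRIP_PREFIX}{modality}".encode()
    zooms = tuple(float(s) for s in volume.spacing)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_volume(path) -> VolumeImage | SegmentationMask:
    """Read a NIfTI volume; spacing is taken from the header zooms."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="replace")
    except Exception as exc:  # malformed file
        raise ValueError(f"cannot parse NIfTI file {path}: {exc}") from exc
    modality = descrip[len(_DESCRIP_PREFIX):] if descrip.startswith(_DESCRIP_PREFIX) else ""
    if modality == "MASK":
        return SegmentationMask(data > 0, spacing)
    return VolumeImage(data.astype(np.float64), spacing, modality or "CT")
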