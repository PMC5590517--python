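"""File I/O: NIfTI volumes and maps, FSL bval/bvec text, TIFF histology
images with pixel-size metadata, and deterministic JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .containers import DwiVolume
from .histology import HistologyImage

__all__ = [
    "save_dwi",
    "load_dwi",
    "save_map",
    "load_map",
    "save_histology_tiff",
    "load_histology_tiff",
    "write_json_report",
]


def _affine(voxel_size_mm):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_dwi(dwi: DwiVolume, protocol, prefix):
    """Write ``<prefix>.nii.gz``, ``<prefix>_mask.nii.gz``, ``<prefix>.bval``
    and ``<prefix>.bvec`` (FSL dialect)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(dwi.voxel_size_mm)
    nib.save(nib.Nifti1Image(dwi.signal.astype(np.float32), aff), f"{prefix}.nii.gz")
    nib.save(nib.Nifti1Image(dwi.mask.astype(np.uint8), aff), f"{prefix}_mask.nii.gz")
    protocol.save(f"{prefix}.bval", f"{prefix}.bvec")


def load_dwi(prefix):
    from .protocol import AcquisitionProtocol

    prefix = Path(prefix)
    img = nib.load(f"{prefix}.nii.gz")
    mask = nib.load(f"{prefix}_mask.nii.gz").get_fdata() > 0
    voxel = tuple(np.abs(np.diag(img.affine))[:3])
    dwi = DwiVolume(img.get_fdata(), mask, voxel)
    prot = AcquisitionProtocol.load(f"{prefix}.bval", f"{prefix}.bvec")
    return dwi, prot


def save_map(arr, voxel_size_mm, path):
    """Write a 2-D/3-D metric map as NIfTI (2-D maps gain a singleton z)."""
    arr = np.asarray(arr, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    vs = tuple(voxel_size_mm) + (1.0,) * (3 - len(voxel_size_mm))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(arr, _affine(vs[:3])), str(path))


def load_map(path):
    return np.squeeze(nib.load(str(path)).get_fdata())


def save_histology_tiff(img: HistologyImage, path):
    """16-bit grayscale TIFF with pixel size recorded in the resolution
    tags (pixels per centimeter)."""
    data = np.clip(img.data, 0.0, 1.0)
    data16 = np.round(data * 65535).astype(np.uint16)
    px_per_cm = 1e4 / img.pixel_size_um
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        str(path), data16, resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def load_histology_tiff(path, pixel_size_um=None):
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = page.asarray().astype(np.float32) / 65535.0
        if pixel_size_um is None:
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is not None and unit is not None and unit.value == 3:
                num, den = res.value
                pixel_size_um = 1e4 * den / num
            else:
                raise ValueError("TIFF lacks resolution metadata; pass pixel_size_um")
    return HistologyImage(data, pixel_size_um)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json_report(report: dict, path):
    """Deterministic JSON (sorted keys, fixed separators) so identical
    runs produce byte-identical reports."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
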