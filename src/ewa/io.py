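"""Image and contour I/O.

Images travel as NIfTI (slice axis last on disk, first in memory); contours
as JSON mapping slice index -> {"endo": [[x, y], ...], "epi": [...]}.
Single-frame DICOM reading picks geometry up from the PixelSpacing and
SliceThickness tags.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import ImageStack, LVSegmentation
from .errors import InputError

_MODE_KEY = "descrip"


def save_image(img: ImageStack, path) -> None:
    """Write a stack as NIfTI; voxel size goes into the affine/zooms and the
    acquisition mode into the descrip header field."""
    data = np.transpose(img.intensities, (2, 1, 0))  # (x, y, z) on disk
    affine = np.diag([img.pixel_spacing, img.pixel_spacing,
                      img.slice_thickness + img.slice_gap, 1.0])
    nii = nib.Nifti1Image(data.astype(np.float32), affine)
    nii.header[_MODE_KEY] = f"mode={img.mode}".encode()
    nib.save(nii, str(path))


def load_image(path, mode: str | None = None) -> ImageStack:
    """Read a NIfTI (or single-frame DICOM) stack."""
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        return _load_dicom(path, mode or "IR")
    nii = nib.load(str(path))
    data = np.asarray(nii.get_fdata(), dtype=float)
    if data.ndim == 2:
        data = data[..., None]
    zooms = nii.header.get_zooms()[:3]
    if mode is None:
        descrip = bytes(nii.header[_MODE_KEY].tobytes()).split(b"\0")[0]
        mode = descrip.decode(errors="ignore").removeprefix("mode=") or "IR"
        if mode not in ("IR", "PSIR", "T1w"):
            mode = "IR"
    return ImageStack(np.transpose(data, (2, 1, 0)),
                      pixel_spacing=float(zooms[0]),
                      slice_thickness=float(zooms[2]), mode=mode)


def _load_dicom(path, mode: str) -> ImageStack:
    import pydicom

    ds = pydicom.dcmread(str(path))
    spacing = float(ds.PixelSpacing[0])
    thickness = float(getattr(ds, "SliceThickness", 8.0))
    arr = ds.pixel_array.astype(float)[None, ...]
    return ImageStack(arr, spacing, thickness, mode=mode)


def save_label_map(core: np.ndarray, mvo: np.ndarray, like: ImageStack,
                   path) -> None:
    """Write a NIfTI label map: 0 background, 1 infarct core, 2 MVO."""
    labels = np.zeros(core.shape, dtype=np.uint8)
    labels[np.asarray(core, dtype=bool)] = 1
    labels[np.asarray(mvo, dtype=bool)] = 2
    affine = np.diag([like.pixel_spacing, like.pixel_spacing,
                      like.slice_thickness + like.slice_gap, 1.0])
    nib.save(nib.Nifti1Image(np.transpose(labels, (2, 1, 0)), affine),
             str(path))


def save_contours(seg: LVSegmentation, path) -> None:
    data = {
        str(s): {"endo": np.asarray(seg.endo[s]).tolist(),
                 "epi": np.asarray(seg.epi[s]).tolist()}
        for s in sorted(seg.endo)
    }
    Path(path).write_text(json.dumps(data, indent=1))


def load_contours(path, grid_shape) -> LVSegmentation:
    """Read a contour JSON and rasterize the myocardial mask."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise InputError(f"cannot parse contour file: {e}") from e
    endo, epi = {}, {}
    for key, val in data.items():
        s = int(key)
        endo[s] = np.asarray(val["endo"], dtype=float)
        epi[s] = np.asarray(val["epi"], dtype=float)
    return LVSegmentation.from_contours(endo, epi, grid_shape)
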