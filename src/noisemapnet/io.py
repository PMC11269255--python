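"""NIfTI-1 reading and writing for dynamic image series.

Axis convention: on disk the NIfTI data array is ordered
``(x = col, y = row, slice, dynamic)``; in memory an
:class:`~noisemapnet.phantom.ImageSeries` is ``(slice, dynamic, row, col)``.
Pixel spacing travels in the header zooms ``(col_mm, row_mm, slice_mm,
frame_interval_s)``. A 3D file is treated as a single-dynamic multi-slice
stack, a 2D file as one slice / one dynamic. Masks are written as uint8.
"""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import ImageSeries

__all__ = ["read_series", "write_series", "write_mask", "read_mask"]


class SeriesFormatError(ValueError):
    """Unreadable file or unsupported dimensionality."""


def write_series(series: ImageSeries, path) -> None:
    data = np.transpose(series.voxels, (3, 2, 0, 1))   # (col, row, slice, dyn)
    sr, sc = series.pixel_spacing_mm
    affine = np.diag([sc, sr, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms((sc, sr, 1.0, series.frame_interval_s))
    nib.save(img, str(path))


def read_series(path) -> ImageSeries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:
        raise SeriesFormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if data.ndim == 2:
        data = data[:, :, None, None]
    elif data.ndim == 3:
        data = data[:, :, :, None]
    elif data.ndim != 4:
        raise SeriesFormatError(
            f"{path}: expected 2-4 dimensions, got {data.ndim}")
    zooms = img.header.get_zooms()
    sc = float(zooms[0]) if len(zooms) > 0 and zooms[0] > 0 else 1.0
    sr = float(zooms[1]) if len(zooms) > 1 and zooms[1] > 0 else 1.0
    dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    voxels = np.transpose(data, (2, 3, 1, 0))   # (slice, dyn, row, col)
    return ImageSeries(voxels, pixel_spacing_mm=(sr, sc), frame_interval_s=dt)


def write_mask(mask: np.ndarray, path, pixel_spacing_mm=(1.0, 1.0)) -> None:
    """2D boolean mask as a uint8 NIfTI volume."""
    data = np.asarray(mask, dtype=np.uint8).T[:, :, None]   # (col, row, 1)
    sr, sc = pixel_spacing_mm
    img = nib.Nifti1Image(data, np.diag([sc, sr, 1.0, 1.0]))
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3:
        data = data[:, :, 0]
    return data.T.astype(bool)
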