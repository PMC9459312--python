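"""In-memory containers for 4D scans and 3D maps, plus NIfTI and text I/O.

Conventions used throughout the package: voxel indices are 0-based, world
coordinates are millimetres obtained through the NIfTI affine, and time is
the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np


def _default_affine(voxel_size_mm=(3.0, 3.0, 3.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class Volume4D:
    """A masked 4D intensity image (x, y, z, t).

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        BOLD-like intensities.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform in mm.
    tr_seconds : float
        Repetition time (sampling interval of the time axis).
    mask : ndarray of bool, shape (x, y, z)
        Analysis mask; voxels outside are ignored by every stage.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} != spatial shape {self.data.shape[:3]}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray) -> "Volume4D":
        return replace(self, data=np.asarray(data, dtype=np.float64))


@dataclass
class ScalarMap:
    """A 3D voxelwise map (ReHo, dReHo variability, t-values, ...)."""

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    label: str = "map"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape must equal data shape")

    @property
    def in_mask(self) -> np.ndarray:
        return self.data[self.mask]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray, label: str | None = None) -> "ScalarMap":
        out = replace(self, data=np.asarray(data, dtype=np.float64))
        if label is not None:
            out.label = label
        return out


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path, mask=None, tr_seconds: float | None = None) -> Volume4D:
    """Read a 4D NIfTI file into a :class:`Volume4D`.

    ``mask`` may be a path to a 3D NIfTI or an ndarray; when omitted, every
    voxel is in-mask. TR is taken from the header zooms unless overridden.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got {data.ndim}D")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if mask is None:
        mask_arr = np.ones(data.shape[:3], dtype=bool)
    elif isinstance(mask, (str, Path)):
        mask_arr = read_mask(mask)
    else:
        mask_arr = np.asarray(mask, dtype=bool)
    return Volume4D(data=data, affine=img.affine, tr_seconds=tr_seconds, mask=mask_arr)


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got {data.ndim}D")
    return data > 0


def read_map(path, mask=None, label: str = "map") -> ScalarMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    if mask is None:
        mask_arr = np.isfinite(data) & (data != 0)
    elif isinstance(mask, (str, Path)):
        mask_arr = read_mask(mask)
    else:
        mask_arr = np.asarray(mask, dtype=bool)
    return ScalarMap(data=data, affine=img.affine, mask=mask_arr, label=label)


def write_volume(vol: Volume4D, path) -> None:
    img = nib.Nifti1Image(vol.data, vol.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = vol.tr_seconds
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def write_map(m: ScalarMap, path, zero_outside_mask: bool = True) -> None:
    data = np.where(m.mask, m.data, 0.0) if zero_outside_mask else m.data
    nib.save(nib.Nifti1Image(data, m.affine), str(path))


def write_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


# ---------------------------------------------------------------------------
# Motion-parameter text I/O (6 columns: 3 translations mm, 3 rotations deg)


def read_motion_trace(path) -> np.ndarray:
    trace = np.loadtxt(str(path))
    trace = np.atleast_2d(trace)
    if trace.shape[1] != 6:
        raise ValueError(f"{path}: motion trace must have 6 columns, got {trace.shape[1]}")
    return trace


def write_motion_trace(trace: np.ndarray, path) -> None:
    trace = np.asarray(trace)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError("motion trace must be (n_volumes, 6)")
    np.savetxt(str(path), trace, fmt="%.6f")
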