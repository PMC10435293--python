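"""NIfTI and FSL gradient-table I/O.

Volumes are NIfTI-1 (.nii / .nii.gz) read and written through nibabel;
gradient tables are FSL-style whitespace-delimited text (bval: 1 x N,
bvec: 3 x N, image coordinate frame).  Voxel indices are 0-based; world
coordinates come from the NIfTI affine; no reslicing or reorientation is
performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .scheme import AcquisitionScheme

__all__ = ["DWIVolume", "read_dwi", "write_map", "read_bval_bvec", "write_bval_bvec"]


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted acquisition with its scheme and geometry."""

    signal: np.ndarray  # (x, y, z, n_volumes), non-negative within mask
    scheme: AcquisitionScheme
    affine: np.ndarray  # 4x4
    mask: np.ndarray  # (x, y, z) boolean

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        if self.signal.shape[3] != self.scheme.n_volumes:
            raise ValueError(
                f"signal has {self.signal.shape[3]} volumes, scheme has "
                f"{self.scheme.n_volumes}"
            )
        if self.mask is None:
            self.mask = np.ones(self.signal.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.signal.shape[:3]:
            raise ValueError("mask shape does not match signal grid")
        inside = self.signal[self.mask]
        if not np.all(np.isfinite(inside)) or np.any(inside < 0):
            raise ValueError("signal must be finite and >= 0 within the mask")

    @property
    def shape(self):
        return self.signal.shape[:3]


def read_bval_bvec(bval_path, bvec_path):
    """Read FSL-style bval (1 x N) and bvec (3 x N) text tables."""
    bvals = np.atleast_1d(np.loadtxt(bval_path, dtype=float).ravel())
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.shape[0] != 3:
        if bvecs.shape[1] == 3:  # tolerate transposed N x 3 tables
            bvecs = bvecs.T
        else:
            raise ValueError(f"bvec table must be 3 x N, got {bvecs.shape}")
    if bvecs.shape[1] != bvals.size:
        raise ValueError(
            f"bval lists {bvals.size} volumes but bvec lists {bvecs.shape[1]}"
        )
    return bvals, bvecs.T  # directions as (N, 3)


def write_bval_bvec(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.b_values[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.9f")


def read_dwi(
    image_path,
    bval_path,
    bvec_path,
    mask_path=None,
    echo_time: float = 67.0,
    repetition_time: float = 10_000.0,
) -> DWIVolume:
    """Load a 4D DWI NIfTI with its FSL gradient table.

    Directions at b > 0 that are not unit-norm are normalized with a
    warning; zero vectors at b = 0 are kept as-is.  A volume-count mismatch
    between image and tables is a format error.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{image_path}: expected a 4D image, got {data.ndim}D")
    bvals, dirs = read_bval_bvec(bval_path, bvec_path)
    if bvals.size != data.shape[3]:
        raise ValueError(
            f"{image_path} has {data.shape[3]} volumes but the gradient "
            f"table lists {bvals.size}"
        )
    dwi = bvals > 0
    norms = np.linalg.norm(dirs[dwi], axis=1)
    bad = np.abs(norms - 1.0) > 1e-6
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} bvec column(s) with b > 0 are not unit-norm; "
            "normalizing",
            stacklevel=2,
        )
        dirs[dwi] = dirs[dwi] / norms[:, None]
    scheme = AcquisitionScheme(bvals, dirs, echo_time, repetition_time)
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return DWIVolume(signal=data, scheme=scheme, affine=img.affine, mask=mask)


def write_map(values: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a parameter map as NIfTI-1, round-trip exact to float64."""
    values = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(values) | np.isnan(values)):
        raise ValueError("map contains non-finite values other than NaN")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(values, np.asarray(affine, dtype=float)), str(path))


def read_map(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D map; returns (values, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine
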