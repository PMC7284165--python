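"""NIfTI and gradient-table input/output.

Images are written as NIfTI-1 with the in-plane voxel size and the 0.1 mm
slice thickness in the affine; gradient tables use the FSL text dialect
(one space-separated row of b-values; three rows of direction components).
Float64 data and %.17g formatting make every round trip bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .dwisim import DWIStack, GradientScheme

__all__ = [
    "save_map",
    "load_map",
    "save_labels",
    "load_labels",
    "save_bvals_bvecs",
    "load_bvals_bvecs",
    "save_stack",
    "load_stack",
]

SLICE_THICKNESS_MM = 0.1


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, SLICE_THICKNESS_MM, 1.0])


def save_map(data: np.ndarray, voxel_size: float, path) -> None:
    """Write a 2D scalar map (or 2D+volumes array) as NIfTI-1."""
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[..., None]
    elif arr.ndim == 3:
        arr = arr[:, :, None, :]
    img = nib.Nifti1Image(arr, _affine(voxel_size))
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def _voxel_size(img) -> float:
    # NIfTI-1 stores zooms as float32; round away the representation error
    return float(round(float(img.header.get_zooms()[0]), 6))


def load_map(path) -> tuple[np.ndarray, float]:
    """Read a NIfTI map back as (array, in-plane voxel size)."""
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    voxel = _voxel_size(img)
    return np.squeeze(arr, axis=2) if arr.ndim >= 3 and arr.shape[2] == 1 \
        else arr, voxel


def save_labels(labels: np.ndarray, voxel_size: float, path) -> None:
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16)[..., None],
                          _affine(voxel_size))
    img.header.set_data_dtype(np.int16)
    nib.save(img, str(path))


def load_labels(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.int16)
    return np.squeeze(arr, axis=2), _voxel_size(img)


def save_bvals_bvecs(scheme: GradientScheme, bvals_path, bvecs_path) -> None:
    """FSL-style text tables covering all volumes (b=0 images included)."""
    bvals = scheme.full_bvals()
    bvecs = scheme.full_bvecs()
    with open(bvals_path, "w") as fh:
        fh.write(" ".join(f"{b:.17g}" for b in bvals) + "\n")
    with open(bvecs_path, "w") as fh:
        for row in bvecs.T:             # 3 x N
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def load_bvals_bvecs(bvals_path, bvecs_path) -> GradientScheme:
    bvals = np.loadtxt(bvals_path, ndmin=1)
    bvecs = np.loadtxt(bvecs_path, ndmin=2).T   # N x 3
    if bvecs.shape[0] != bvals.shape[0]:
        raise ValueError("bvals and bvecs volume counts disagree")
    weighted = bvals > 0
    n_b0 = int((~weighted).sum())
    # b=0 images must come first in this package's volume ordering
    order = np.argsort(weighted, kind="stable")
    return GradientScheme(bvecs=bvecs[order][n_b0:],
                          bvals=bvals[order][n_b0:], n_b0=n_b0)


def save_stack(stack: DWIStack, dwi_path, bvals_path, bvecs_path) -> None:
    save_map(stack.data, stack.voxel_size, dwi_path)
    save_bvals_bvecs(stack.scheme, bvals_path, bvecs_path)


def load_stack(dwi_path, bvals_path, bvecs_path,
               s0: float | None = None) -> DWIStack:
    data, voxel = load_map(dwi_path)
    scheme = load_bvals_bvecs(bvals_path, bvecs_path)
    if s0 is None:
        s0 = float(np.median(data[..., : scheme.n_b0])) if scheme.n_b0 \
            else float(np.median(data))
    return DWIStack(data=data, scheme=scheme, s0=s0, voxel_size=voxel)
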