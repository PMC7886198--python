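"""File formats: NIfTI-1 volumes, FSL bval/bvec, TrackVis .trk, TSV tables."""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .gradients import GradientScheme
from .grid import Grid, LabelMask
from .tensor import DWIVolume, ScalarMaps
from .tracking import StreamlineSet

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

__all__ = [
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "read_dwi",
    "write_dwi",
    "read_volume",
    "write_volume",
    "write_mask",
    "write_streamlines_trk",
    "write_streamlines_tsv",
]


def _grid_from_img(img: nib.Nifti1Image) -> Grid:
    shape = tuple(int(s) for s in img.shape[:3])
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Grid(shape, voxel_size)


def read_bvals_bvecs(bval_path: PathLike, bvec_path: PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Parse FSL-dialect gradient files.

    bval: one row of whitespace-separated b-values; bvec: 3 rows x N
    columns. A transposed bvec file (N rows x 3 columns) is auto-detected
    and accepted with a warning.
    """
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.atleast_2d(np.loadtxt(bvec_path))
    if bvecs.shape[0] != 3 and bvecs.shape[1] == 3:
        warnings.warn(
            f"bvec file {bvec_path} looks transposed ({bvecs.shape[0]}x3 "
            "instead of 3xN); transposing",
            stacklevel=2,
        )
        bvecs = bvecs.T
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvec file must be 3xN or Nx3, got shape {bvecs.shape}")
    return bvals, bvecs.T  # (N, 3)


def write_bvals_bvecs(bval_path: PathLike, bvec_path: PathLike, scheme: GradientScheme) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")


def read_dwi(nifti_path: PathLike, bval_path: PathLike, bvec_path: PathLike,
             brain_mask: Optional[LabelMask] = None) -> DWIVolume:
    """Load and validate a 4-D DWI volume with its gradient scheme.

    b-vectors within 1e-3 of unit norm are renormalized; farther off is an
    error. The bval/bvec length must match the 4th NIfTI dimension.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected a 4-D DWI volume, got {data.ndim}-D")
    bvals, bvecs = read_bvals_bvecs(bval_path, bvec_path)
    if len(bvals) != data.shape[3] or bvecs.shape[0] != data.shape[3]:
        raise ValueError(
            f"gradient table length ({len(bvals)} bvals, {bvecs.shape[0]} bvecs) "
            f"does not match the {data.shape[3]} DWI volumes"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    nz = bvals > 0
    off = np.abs(norms[nz] - 1.0)
    if np.any(off > 1e-3):
        raise ValueError(
            f"{int((off > 1e-3).sum())} non-zero b-vectors deviate from unit "
            "norm by more than 1e-3"
        )
    bvecs = bvecs.copy()
    bvecs[nz] = bvecs[nz] / norms[nz][:, None]
    scheme = GradientScheme(bvals=bvals, bvecs=bvecs)
    return DWIVolume(data=data, scheme=scheme, grid=_grid_from_img(img), brain_mask=brain_mask)


def write_dwi(nifti_path: PathLike, bval_path: PathLike, bvec_path: PathLike,
              dwi: DWIVolume) -> None:
    img = nib.Nifti1Image(dwi.data.astype(np.float32), dwi.grid.affine)
    img.header.set_zooms(tuple(dwi.grid.voxel_size) + (1.0,))
    nib.save(img, str(nifti_path))
    write_bvals_bvecs(bval_path, bvec_path, dwi.scheme)


def read_volume(path: PathLike) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), _grid_from_img(img)


def write_volume(path: PathLike, data: np.ndarray, grid: Grid,
                 dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), grid.affine)
    img.header.set_zooms(tuple(grid.voxel_size))
    nib.save(img, str(path))


def write_mask(path: PathLike, mask: LabelMask) -> None:
    write_volume(path, mask.data.astype(np.uint8), mask.grid, dtype=np.uint8)


def write_scalar_maps(out_dir: PathLike, maps: ScalarMaps, prefix: str = "") -> dict[str, Path]:
    out_dir = Path(out_dir)
    paths = {}
    for kind in ("fa", "ad", "rd", "md"):
        p = out_dir / f"{prefix}{kind}.nii.gz"
        write_volume(p, maps[kind], maps.grid)
        paths[kind] = p
    return paths


def write_streamlines_trk(path: PathLike, tracts: StreamlineSet) -> None:
    """Save streamlines in TrackVis format (mm/rasmm coordinates)."""
    grid = tracts.grid
    tractogram = nib.streamlines.Tractogram(
        tracts.streamlines, affine_to_rasmm=np.eye(4)
    )
    header = {
        "voxel_sizes": tuple(grid.voxel_size),
        "dimensions": tuple(grid.shape),
        "voxel_to_rasmm": grid.affine.astype(np.float32),
        "voxel_order": "RAS",
    }
    nib.streamlines.save(tractogram, str(path), header=header)


def write_streamlines_tsv(path: PathLike, tracts: StreamlineSet) -> None:
    """Plain-text streamline dump: one row per point, mm coordinates."""
    rows = []
    for sid, sl in enumerate(tracts.streamlines):
        for pid, (x, y, z) in enumerate(sl):
            rows.append((sid, pid, x, y, z))
    df = pd.DataFrame(rows, columns=["streamline", "point", "x_mm", "y_mm", "z_mm"])
    df.to_csv(path, sep="\t", index=False, float_format="%.5f")
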