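"""Per-voxel diffusion tensor estimation and DTI scalar maps.

The tensor is fitted by ordinary least squares on the log-signal against the
standard seven-column design

    ln S_i = ln S0 - b_i (g_x^2 Dxx + g_y^2 Dyy + g_z^2 Dzz
                          + 2 g_x g_y Dxy + 2 g_x g_z Dxz + 2 g_y g_z Dyz)

which is the log-linear fit performed by the common DTI toolboxes. From the
sorted eigenvalues (l1 >= l2 >= l3) the maps are

    FA = sqrt(3/2) * ||l - lbar|| / ||l||      (0 isotropic .. 1 stick)
    AD = l1,  RD = (l2 + l3) / 2,  MD = (l1 + l2 + l3) / 3

with FA defined as 0 when all eigenvalues vanish. Negative fitted
eigenvalues (a noise artifact) are clamped to zero for the maps but retained
raw, and the affected voxels are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .gradients import GradientScheme
from .grid import Grid, LabelMask

__all__ = [
    "DWIVolume",
    "TensorField",
    "Eigensystem",
    "ScalarMaps",
    "design_matrix",
    "fit_tensor",
    "eigendecompose",
    "scalar_maps",
]

# lower-triangular packing order of the 6 unique tensor elements
TENSOR_ELEMENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")

_LOG_FLOOR_FRAC = 1e-6  # signal floor = max(S, 1e-6 * S0 estimate) before log


@dataclass
class DWIVolume:
    """4-D diffusion-weighted signal (x, y, z, direction) plus its scheme."""

    data: np.ndarray
    scheme: GradientScheme
    grid: Grid
    brain_mask: Optional[LabelMask] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"DWI data must be 4-D, got shape {self.data.shape}")
        if self.data.shape[:3] != tuple(self.grid.shape):
            raise ValueError(
                f"DWI spatial shape {self.data.shape[:3]} does not match grid {self.grid.shape}"
            )
        if self.data.shape[3] != len(self.scheme):
            raise ValueError(
                f"DWI has {self.data.shape[3]} volumes but the gradient scheme "
                f"describes {len(self.scheme)}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DWI signal contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("DWI signal must be non-negative")
        if self.brain_mask is None:
            self.brain_mask = LabelMask(
                np.ones(self.grid.shape, dtype=bool), self.grid, "brain"
            )


@dataclass
class TensorField:
    """Fitted tensors: 6 unique elements per voxel (mm^2/s), ln S0, fit flag."""

    elements: np.ndarray  # (x, y, z, 6) in TENSOR_ELEMENTS order
    log_s0: np.ndarray    # (x, y, z)
    fit_ok: np.ndarray    # (x, y, z) bool
    grid: Grid

    def as_matrices(self) -> np.ndarray:
        """Expand to full symmetric (x, y, z, 3, 3) tensors."""
        dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(self.elements, -1, 0)
        out = np.empty(self.elements.shape[:3] + (3, 3))
        out[..., 0, 0] = dxx
        out[..., 1, 1] = dyy
        out[..., 2, 2] = dzz
        out[..., 0, 1] = out[..., 1, 0] = dxy
        out[..., 0, 2] = out[..., 2, 0] = dxz
        out[..., 1, 2] = out[..., 2, 1] = dyz
        return out


@dataclass
class Eigensystem:
    """Sorted eigendecomposition of a TensorField."""

    values: np.ndarray    # (x, y, z, 3) descending, raw (may be negative)
    vectors: np.ndarray   # (x, y, z, 3, 3); vectors[..., i, :] pairs values[..., i]
    fit_ok: np.ndarray    # (x, y, z) bool, finite voxels only
    had_negative: np.ndarray  # (x, y, z) bool
    grid: Grid

    @property
    def clamped_values(self) -> np.ndarray:
        """Eigenvalues with negatives clamped to 0 (used for scalar maps)."""
        return np.maximum(self.values, 0.0)

    @property
    def principal_direction(self) -> np.ndarray:
        return self.vectors[..., 0, :]


@dataclass
class ScalarMaps:
    """FA (dimensionless) and AD/RD/MD (mm^2/s) volumes on a common grid."""

    fa: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    md: np.ndarray
    grid: Grid

    def __getitem__(self, kind: str) -> np.ndarray:
        kind = kind.lower()
        if kind not in ("fa", "ad", "rd", "md"):
            raise KeyError(f"unknown scalar map {kind!r}")
        return getattr(self, kind)


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Log-linear design: columns [1, -b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz]."""
    b = scheme.bvals
    g = scheme.bvecs
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensor(dwi: DWIVolume) -> TensorField:
    """OLS log-linear tensor fit at every brain-mask voxel.

    Signals are clipped to ``1e-6 * S0_estimate`` (per voxel) before the log
    so Rician noise cannot produce ``-inf``. Raises if the gradient scheme is
    rank-deficient for the seven-parameter fit.
    """
    X = design_matrix(dwi.scheme)
    if X.shape[0] < 7 or np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            "gradient scheme is rank-deficient for the tensor fit: need at "
            "least 1 b=0 plus 6 non-collinear directions"
        )
    mask = dwi.brain_mask.data
    sig = dwi.data[mask]  # (nvox, ndir)
    b0 = dwi.scheme.b0_mask
    s0_est = sig[:, b0].mean(axis=1)
    floor = np.maximum(s0_est * _LOG_FLOOR_FRAC, np.finfo(float).tiny)
    logs = np.log(np.maximum(sig, floor[:, None]))
    coef, *_ = np.linalg.lstsq(X, logs.T, rcond=None)  # (7, nvox)

    shape = tuple(dwi.grid.shape)
    elements = np.zeros(shape + (6,))
    log_s0 = np.zeros(shape)
    elements[mask] = coef[1:].T
    log_s0[mask] = coef[0]
    fit_ok = mask & np.all(np.isfinite(elements), axis=-1) & np.isfinite(log_s0)
    return TensorField(elements=elements, log_s0=log_s0, fit_ok=fit_ok, grid=dwi.grid)


def eigendecompose(field: TensorField) -> Eigensystem:
    """Per-voxel eigenvalues (descending) and eigenvectors of the fitted tensors.

    Non-finite tensors are flagged not-ok and excluded from downstream maps.
    Eigenvector sign is fixed by making the first non-zero component
    positive, so outputs are deterministic.
    """
    mats = field.as_matrices()
    finite = np.all(np.isfinite(mats), axis=(-2, -1))
    ok = field.fit_ok & finite
    safe = np.where(finite[..., None, None], mats, 0.0)
    vals, vecs = np.linalg.eigh(safe)  # ascending; vecs[..., :, i] is i-th
    vals = vals[..., ::-1]
    vecs = np.swapaxes(vecs, -1, -2)[..., ::-1, :]  # (..., 3 evec, 3 comp)
    # deterministic sign: first component with |c| > tol positive
    comp = vecs
    tol = 1e-12
    first = np.where(
        np.abs(comp[..., 0:1]) > tol,
        comp[..., 0:1],
        np.where(np.abs(comp[..., 1:2]) > tol, comp[..., 1:2], comp[..., 2:3]),
    )
    sign = np.where(first < 0, -1.0, 1.0)
    vecs = vecs * sign
    vals = np.where(ok[..., None], vals, 0.0)
    return Eigensystem(
        values=vals,
        vectors=vecs,
        fit_ok=ok,
        had_negative=ok & np.any(vals < 0, axis=-1),
        grid=field.grid,
    )


def scalar_maps(eigs: Eigensystem) -> ScalarMaps:
    """Compute FA/AD/RD/MD from (clamped) sorted eigenvalues."""
    lam = eigs.clamped_values
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    md = (l1 + l2 + l3) / 3.0
    norm2 = l1**2 + l2**2 + l3**2
    dev2 = (l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * dev2 / norm2)
    fa = np.where(norm2 > 0, fa, 0.0)
    fa = np.clip(np.where(eigs.fit_ok, fa, 0.0), 0.0, 1.0)
    zero = lambda a: np.where(eigs.fit_ok, a, 0.0)
    return ScalarMaps(
        fa=fa, ad=zero(l1), rd=zero((l2 + l3) / 2.0), md=zero(md), grid=eigs.grid
    )
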