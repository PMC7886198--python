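"""Diffusion gradient schemes (FSL-dialect b-values and b-vectors)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GradientScheme", "fibonacci_directions", "default_scheme"]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class GradientScheme:
    """b-values (s/mm^2) and unit gradient directions, one row per volume.

    At least one b=0 entry and at least six non-collinear non-zero directions
    are required for the diffusion tensor to be identifiable. The zero vector
    is allowed (and expected) for b=0 entries.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals length {bvals.shape[0]} does not match bvecs length {bvecs.shape[0]}"
            )
        if np.any(bvals < 0):
            raise ValueError("negative b-values are not allowed")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        norms = np.linalg.norm(bvecs, axis=1)
        nz = bvals > 0
        if not np.any(~nz):
            raise ValueError("scheme needs at least one b=0 entry")
        if np.any(np.abs(norms[nz] - 1.0) > _UNIT_TOL):
            raise ValueError("non-zero b-vectors must be unit-norm within 1e-6")
        # identifiability: the 6 quadratic-form columns must span R^6
        g = bvecs[nz]
        quad = np.column_stack(
            [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
             g[:, 0] * g[:, 1], g[:, 0] * g[:, 2], g[:, 1] * g[:, 2]]
        )
        if g.shape[0] < 6 or np.linalg.matrix_rank(quad) < 6:
            raise ValueError(
                "gradient directions are too few or too collinear: the tensor "
                "is not identifiable (need >= 6 non-collinear directions)"
            )

    def __len__(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` roughly uniform unit vectors on the half-sphere (golden spiral).

    Deterministic and well spread; diffusion directions are sign-symmetric so
    the half-sphere suffices.
    """
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = i / n  # upper half-sphere
    r = np.sqrt(1 - z**2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def default_scheme(n_directions: int = 30, b: float = 1000.0, n_b0: int = 1) -> GradientScheme:
    """The study acquisition: ``n_b0`` b=0 volumes plus 30 directions at b=1000 s/mm^2."""
    dirs = fibonacci_directions(n_directions)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, b)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(bvals=bvals, bvecs=bvecs)
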