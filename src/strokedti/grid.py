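"""Voxel-grid bookkeeping shared by every imaging stage.

All images in the pipeline live on a common axis-aligned grid. Voxel indices
are 0-based, voxel centers sit at ``(i + 0.5) * voxel_size``, and world
coordinates come from a diagonal NIfTI affine. The first axis is
left--right: the midsagittal plane is the boundary between columns
``nx/2 - 1`` and ``nx/2``, which requires an even first dimension so that
mirror reflection is an exact index flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid", "LabelMask"]


@dataclass(frozen=True)
class Grid:
    """Shape and spacing of a 3-D voxel grid (mm)."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel size must be three positive floats, got {self.voxel_size}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    @property
    def affine(self) -> np.ndarray:
        """Diagonal voxel-to-world affine (mm), origin at the corner voxel center."""
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    def axis_offsets_mm(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along ``axis``, measured from the axis midplane.

        Computed as ``(i + 0.5 - n/2) * dx`` so that flipping the index
        negates the offset exactly in floating point -- the property the
        mirror-symmetry guarantees of the phantom rest on.
        """
        n = self.shape[axis]
        dx = self.voxel_size[axis]
        return (np.arange(n) + 0.5 - n / 2) * dx

    def center_offsets_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (x, y, z) voxel-center offsets from the grid center, mm."""
        xo = self.axis_offsets_mm(0)[:, None, None]
        yo = self.axis_offsets_mm(1)[None, :, None]
        zo = self.axis_offsets_mm(2)[None, None, :]
        return xo, yo, zo

    def require_even_lr(self) -> None:
        if self.shape[0] % 2 != 0:
            raise ValueError(
                f"first (left-right) dimension must be even for an exact midline "
                f"reflection; got {self.shape[0]}"
            )


@dataclass
class LabelMask:
    """A named boolean voxel set on a grid."""

    data: np.ndarray
    grid: Grid
    name: str = "mask"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError(
                f"mask {self.name!r} shape {self.data.shape} does not match "
                f"grid shape {self.grid.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.count * self.grid.voxel_volume

    def same_grid(self, other: "LabelMask") -> bool:
        return self.grid == other.grid
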