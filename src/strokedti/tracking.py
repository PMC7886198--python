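"""Deterministic streamline tractography and the fiber-density statistic.

Streamlines are integrated with fixed-step Euler steps along the principal
eigenvector field, bidirectionally from each seed, with the two classical
stopping rules: terminate where FA falls below the threshold (default 0.15)
or where the turning angle between consecutive steps exceeds the maximum
(default 45 degrees). The eigenvector is looked up nearest-neighbor (which
sidesteps the sign ambiguity of interpolating eigenvectors) while FA is
interpolated trilinearly so stopping is smooth. Fiber density (FD) is the
number of reconstructed streamlines divided by the number of seed voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grid import Grid, LabelMask
from .tensor import Eigensystem

__all__ = ["TrackingParams", "StreamlineSet", "track", "fiber_density"]


@dataclass(frozen=True)
class TrackingParams:
    """Stopping rules and integration settings for deterministic tracking.

    ``step_size`` and ``min_length`` default to half and twice the smallest
    voxel dimension respectively when left ``None``.
    """

    fa_threshold: float = 0.15
    max_angle_deg: float = 45.0
    step_size: Optional[float] = None   # mm; default 0.5 * min voxel dim
    max_steps: int = 500
    min_length: Optional[float] = None  # mm; default 2 * min voxel dim
    seeds_per_voxel: int = 1
    seed: int = 0                       # rng for seed jitter when seeds_per_voxel > 1

    def __post_init__(self) -> None:
        if not (0 < self.fa_threshold < 1):
            raise ValueError(f"fa_threshold must be in (0, 1), got {self.fa_threshold}")
        if not (0 < self.max_angle_deg < 90):
            raise ValueError(f"max_angle_deg must be in (0, 90), got {self.max_angle_deg}")
        if self.step_size is not None and self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.seeds_per_voxel < 1:
            raise ValueError("seeds_per_voxel must be >= 1")

    def resolved(self, voxel_size: tuple[float, float, float]) -> "TrackingParams":
        mn = float(min(voxel_size))
        step = self.step_size if self.step_size is not None else 0.5 * mn
        minlen = self.min_length if self.min_length is not None else 2.0 * mn
        return TrackingParams(
            fa_threshold=self.fa_threshold,
            max_angle_deg=self.max_angle_deg,
            step_size=step,
            max_steps=self.max_steps,
            min_length=minlen,
            seeds_per_voxel=self.seeds_per_voxel,
            seed=self.seed,
        )


@dataclass
class StreamlineSet:
    """Reconstructed tracts (mm coordinates) with seed bookkeeping."""

    streamlines: list[np.ndarray]   # each (n_points, 3), n_points >= 2
    seed_voxel_index: list[tuple[int, int, int]]
    n_seed_voxels: int
    grid: Grid

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths_mm(self) -> np.ndarray:
        return np.array(
            [np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in self.streamlines]
        )


def _interp_fa(fa: np.ndarray, pos_vox: np.ndarray) -> float:
    """Trilinear FA at a voxel-index-space position (voxel centers at integers).

    Hand-rolled rather than ``scipy.ndimage.map_coordinates`` because it is
    called once per Euler step inside the tracking loop; outside the volume
    the value is 0. Matches map_coordinates(order=1, mode='constant').
    """
    nx, ny, nz = fa.shape
    x, y, z = pos_vox
    x0, y0, z0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
    fx, fy, fz = x - x0, y - y0, z - z0
    acc = 0.0
    for dx_ in (0, 1):
        wx = fx if dx_ else 1.0 - fx
        if wx == 0.0:
            continue
        i = x0 + dx_
        if i < 0 or i >= nx:
            continue
        for dy_ in (0, 1):
            wy = fy if dy_ else 1.0 - fy
            if wy == 0.0:
                continue
            j = y0 + dy_
            if j < 0 or j >= ny:
                continue
            for dz_ in (0, 1):
                wz = fz if dz_ else 1.0 - fz
                if wz == 0.0:
                    continue
                kk = z0 + dz_
                if kk < 0 or kk >= nz:
                    continue
                acc += wx * wy * wz * fa[i, j, kk]
    return acc


def _trace_half(
    pos: np.ndarray,
    direction: np.ndarray,
    fa: np.ndarray,
    evec: np.ndarray,
    vsz: np.ndarray,
    shape: np.ndarray,
    p: TrackingParams,
) -> list[np.ndarray]:
    """One unidirectional Euler walk; returns points after (not including) the seed."""
    cos_max = np.cos(np.deg2rad(p.max_angle_deg))
    points: list[np.ndarray] = []
    d_prev = direction
    for _ in range(p.max_steps):
        new = pos + p.step_size * d_prev
        vox = new / vsz - 0.5
        if np.any(new < 0) or np.any(new >= shape * vsz):
            break
        if _interp_fa(fa, vox) < p.fa_threshold:
            break
        idx = tuple(np.clip(np.floor(new / vsz).astype(int), 0, shape - 1))
        e = evec[idx]
        ne = np.linalg.norm(e)
        if ne == 0:
            break
        e = e / ne
        if np.dot(e, d_prev) < 0:
            e = -e
        if np.dot(e, d_prev) < cos_max:
            break
        points.append(new)
        pos = new
        d_prev = e
    return points


def track(
    eigs: Eigensystem,
    fa_map: np.ndarray,
    seed_mask: LabelMask,
    params: Optional[TrackingParams] = None,
) -> StreamlineSet:
    """Deterministic bidirectional tracking from every seed voxel.

    Seeds default to voxel centers (one per mask voxel); with
    ``seeds_per_voxel > 1`` additional seeds are jittered uniformly inside
    the voxel by a seeded rng. A streamline is the merge of the two
    half-walks through its seed; streamlines shorter than ``min_length`` or
    with fewer than two points are discarded. Seeds whose FA is already
    below threshold produce nothing.
    """
    if seed_mask.count == 0:
        raise ValueError("empty seed mask: nothing to track")
    grid = eigs.grid
    if tuple(fa_map.shape) != tuple(grid.shape) or seed_mask.grid != grid:
        raise ValueError(
            "FA map, eigenvector field and seed mask must share one grid; "
            f"got FA {fa_map.shape}, eigs {grid.shape}, seeds {seed_mask.grid.shape}"
        )
    p = (params or TrackingParams()).resolved(grid.voxel_size)
    vsz = np.asarray(grid.voxel_size)
    shape = np.asarray(grid.shape)
    evec = eigs.principal_direction
    rng = np.random.default_rng(p.seed)

    streamlines: list[np.ndarray] = []
    seed_ids: list[tuple[int, int, int]] = []
    seed_voxels = np.argwhere(seed_mask.data)
    for vox in seed_voxels:
        for k in range(p.seeds_per_voxel):
            if k == 0:
                offset = np.full(3, 0.5)
            else:
                offset = rng.uniform(0.0, 1.0, 3)
            pos = (vox + offset) * vsz
            if _interp_fa(fa_map, pos / vsz - 0.5) < p.fa_threshold:
                continue
            e = evec[tuple(vox)]
            ne = np.linalg.norm(e)
            if ne == 0:
                continue
            e = e / ne
            fwd = _trace_half(pos, e, fa_map, evec, vsz, shape, p)
            bwd = _trace_half(pos, -e, fa_map, evec, vsz, shape, p)
            pts = bwd[::-1] + [pos] + fwd
            if len(pts) < 2:
                continue
            sl = np.asarray(pts)
            if np.linalg.norm(np.diff(sl, axis=0), axis=1).sum() < p.min_length:
                continue
            streamlines.append(sl)
            seed_ids.append(tuple(int(v) for v in vox))
    return StreamlineSet(
        streamlines=streamlines,
        seed_voxel_index=seed_ids,
        n_seed_voxels=int(seed_mask.count),
        grid=grid,
    )


def fiber_density(tracts: StreamlineSet) -> float:
    """FD = reconstructed streamline count / seed voxel count."""
    if tracts.n_seed_voxels <= 0:
        raise ValueError("fiber density undefined: zero seed voxels")
    return len(tracts) / tracts.n_seed_voxels
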