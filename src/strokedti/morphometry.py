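"""T2-based lesion segmentation, ventricular volumetry, and day-1 normalization.

The infarct rule is the classic intensity threshold: a voxel is lesion if
its T2-weighted signal exceeds mean + k*SD of normal tissue in the
contralateral hemisphere (k = 2 by default). "Normal tissue" excludes CSF
via a ventricle/exclusion mask, since CSF hyperintensity would inflate the
threshold. Ventricular volume uses the same thresholding machinery
restricted to a prior mask and a contiguous slice range (8 slices by
default). Lesion and ventricle volume series are normalized to day 1 to
compensate for between-animal size differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .grid import Grid, LabelMask

__all__ = [
    "SegmentationResult",
    "VolumeSeries",
    "segment_lesion",
    "measure_ventricles",
    "normalize_series",
]

log = logging.getLogger(__name__)


@dataclass
class SegmentationResult:
    mask: LabelMask
    threshold: float
    reference_mean: float
    reference_sd: float


@dataclass
class VolumeSeries:
    """Absolute (mm^3) and day-1-normalized volumes over timepoints."""

    subject: str
    structure: str  # "lesion" or "ventricle"
    timepoints: tuple[str, ...]
    volumes_mm3: tuple[float, ...]
    normalized: tuple[float, ...]


def _reference_stats(
    t2: np.ndarray, contralateral_mask: LabelMask, exclude: Optional[LabelMask]
) -> tuple[float, float, np.ndarray]:
    ref = contralateral_mask.data.copy()
    if exclude is not None:
        ref &= ~exclude.data
    if not ref.any():
        raise ValueError("contralateral normal-tissue mask is empty")
    vals = t2[ref]
    return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0, ref


def segment_lesion(
    t2: np.ndarray,
    contralateral_mask: LabelMask,
    ipsilateral_mask: LabelMask,
    exclude: Optional[LabelMask] = None,
    sd_multiplier: float = 2.0,
) -> SegmentationResult:
    """Threshold-based infarct segmentation on the ipsilesional hemisphere.

    Lesion = ipsilateral voxels with intensity above
    ``mean + sd_multiplier * sd`` of contralateral normal tissue (the
    contralateral mask minus ``exclude``, typically the ventricle prior).
    The computed threshold is logged and returned.
    """
    if t2.shape != tuple(contralateral_mask.grid.shape):
        raise ValueError("T2 image and masks must share one grid")
    mean, sd, _ = _reference_stats(t2, contralateral_mask, exclude)
    if sd == 0:
        warnings.warn(
            "contralateral reference has zero variance; threshold falls back to the mean",
            stacklevel=2,
        )
    threshold = mean + sd_multiplier * sd
    data = ipsilateral_mask.data & (t2 > threshold)
    log.info(
        "lesion segmentation: reference mean=%.3f sd=%.3f threshold=%.3f -> %d voxels",
        mean, sd, threshold, int(data.sum()),
    )
    return SegmentationResult(
        mask=LabelMask(data, contralateral_mask.grid, "lesion_segmented"),
        threshold=threshold,
        reference_mean=mean,
        reference_sd=sd,
    )


def measure_ventricles(
    t2: np.ndarray,
    ventricle_prior: LabelMask,
    slice_range: Optional[Sequence[int]] = None,
    contralateral_mask: Optional[LabelMask] = None,
    sd_multiplier: float = 2.0,
) -> float:
    """Ventricular volume (mm^3) from CSF-hyperintense voxels within a prior.

    ``slice_range`` selects contiguous slices along the last axis (default:
    the 8 central slices, matching delineation from 8 contiguous images).
    When a contralateral reference is given, voxels must also exceed its
    mean + k*SD (CSF is hyperintense); without a reference the prior is
    counted directly (noiseless/ground-truth use).
    """
    grid = ventricle_prior.grid
    nz = grid.shape[2]
    if slice_range is None:
        n = min(8, nz)
        lo = (nz - n) // 2
        slice_range = range(lo, lo + n)
    slices = np.asarray(list(slice_range))
    if slices.size and (slices.min() < 0 or slices.max() >= nz):
        raise ValueError(f"slice range {slices.min()}..{slices.max()} outside volume (nz={nz})")
    sel = np.zeros(grid.shape, dtype=bool)
    sel[:, :, slices] = True
    region = ventricle_prior.data & sel
    if contralateral_mask is not None:
        mean, sd, _ = _reference_stats(t2, contralateral_mask, ventricle_prior)
        region = region & (t2 > mean + sd_multiplier * sd)
    vol = float(region.sum()) * grid.voxel_volume
    log.info("ventricle volumetry: %d voxels -> %.3f mm^3", int(region.sum()), vol)
    return vol


def normalize_series(
    subject: str,
    structure: str,
    timepoints: Sequence[str],
    volumes_mm3: Sequence[float],
) -> VolumeSeries:
    """Normalize a volume series to its day-1 (first-timepoint) value."""
    if len(timepoints) != len(volumes_mm3):
        raise ValueError("timepoints and volumes must have equal length")
    vols = [float(v) for v in volumes_mm3]
    if any(v < 0 for v in vols):
        raise ValueError("volumes must be non-negative")
    if vols[0] <= 0:
        raise ValueError(
            f"{subject}/{structure}: day-1 volume is zero; normalization undefined"
        )
    norm = tuple(v / vols[0] for v in vols)
    return VolumeSeries(
        subject=subject,
        structure=structure,
        timepoints=tuple(timepoints),
        volumes_mm3=tuple(vols),
        normalized=norm,
    )
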