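"""Recovery-ROI construction and relative (ipsi/contra) DTI metrics.

The recovery ROI is the set difference of the day-1 lesion and the 5-week
lesion: tissue that looked infarcted acutely but no longer does, where
microstructural reorganization is quantified. Its contralesional control is
the exact mirror across the midsagittal plane. Relative metrics (rFA, rAD,
rRD, rFD) divide the ipsilesional ROI value by the mirrored ROI value,
normalizing between-animal variation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .grid import LabelMask
from .tensor import ScalarMaps

__all__ = ["ROIPair", "RelativeMetrics", "recovery_roi", "mirror_roi", "relative_metrics"]

log = logging.getLogger(__name__)


@dataclass
class ROIPair:
    ipsi: LabelMask
    contra: LabelMask
    provenance: tuple[str, str] = ("lesion_day1", "lesion_wk5")


@dataclass
class RelativeMetrics:
    subject: str
    timepoint: str
    rfa: float
    rad: float
    rrd: float
    rfd: Optional[float] = None

    def as_dict(self) -> dict[str, float]:
        d = {"rFA": self.rfa, "rAD": self.rad, "rRD": self.rrd}
        if self.rfd is not None:
            d["rFD"] = self.rfd
        return d


def recovery_roi(lesion_day1: LabelMask, lesion_wk5: LabelMask) -> LabelMask:
    """Day-1 lesion minus 5-week lesion (voxelwise set difference)."""
    if lesion_day1.grid != lesion_wk5.grid:
        raise ValueError(
            f"lesion masks live on different grids: {lesion_day1.grid} vs {lesion_wk5.grid}"
        )
    data = lesion_day1.data & ~lesion_wk5.data
    if not data.any():
        warnings.warn(
            "recovery ROI is empty: the 5-week lesion covers the day-1 lesion",
            stacklevel=2,
        )
    return LabelMask(data, lesion_day1.grid, "recovery_roi")


def mirror_roi(ipsi: LabelMask) -> LabelMask:
    """Exact reflection across the midsagittal plane (index flip, axis 0).

    Requires an even left-right dimension so the midplane is a voxel
    boundary; the reflection is an involution and preserves voxel count
    exactly.
    """
    ipsi.grid.require_even_lr()
    return LabelMask(ipsi.data[::-1, :, :].copy(), ipsi.grid, f"mirror({ipsi.name})")


def relative_metrics(
    roi: ROIPair,
    maps: ScalarMaps,
    subject: str = "",
    timepoint: str = "",
    fd_ipsi: Optional[float] = None,
    fd_contra: Optional[float] = None,
    statistic: str = "mean",
) -> RelativeMetrics:
    """Ipsi/contra ratios of ROI-aggregated FA, AD, RD (and FD when given).

    The ROI aggregate is the mean by default (median behind the
    ``statistic`` flag). Raises when a contralateral aggregate is zero,
    naming the offending metric.
    """
    if roi.ipsi.count == 0 or roi.contra.count == 0:
        raise ValueError("relative metrics need non-empty ROIs on both sides")
    agg = np.median if statistic == "median" else np.mean
    out = {}
    for name in ("fa", "ad", "rd"):
        img = maps[name]
        num = float(agg(img[roi.ipsi.data]))
        den = float(agg(img[roi.contra.data]))
        if den == 0:
            raise ValueError(f"contralateral ROI mean of {name.upper()} is zero")
        out[name] = num / den
    rfd = None
    if fd_ipsi is not None or fd_contra is not None:
        if fd_contra is None or fd_contra == 0:
            raise ValueError("contralateral FD is zero or missing; rFD undefined")
        rfd = float(fd_ipsi) / float(fd_contra)
    log.info(
        "relative metrics %s/%s: rFA=%.4f rAD=%.4f rRD=%.4f rFD=%s",
        subject, timepoint, out["fa"], out["ad"], out["rd"],
        "n/a" if rfd is None else f"{rfd:.4f}",
    )
    return RelativeMetrics(
        subject=subject, timepoint=timepoint,
        rfa=out["fa"], rad=out["ad"], rrd=out["rd"], rfd=rfd,
    )
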