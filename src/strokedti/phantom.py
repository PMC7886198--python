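"""Synthetic longitudinal rodent-brain phantoms with planted ground truth.

The generator emulates the structure of a unilateral ischemic-stroke study:
a two-hemisphere ellipsoidal "brain" on the study's acquisition grid
(0.156 x 0.156 x 0.75 mm voxels, 30 diffusion directions at b = 1000 s/mm^2),
with

* a straight left-right cylindrical white-matter bundle through both
  hemispheres (coherent anisotropic tensors, known orientation),
* mirrored ellipsoidal lateral ventricles (CSF, T2-hyperintense) that may
  enlarge over time,
* a spherical lesion confined to the right (ipsilesional) hemisphere whose
  radius shrinks from day 1 to 5 weeks, and
* mNSS behavioral trajectories and an enrollment ledger with the exclusion
  structure of a three-arm cell-therapy cohort (PBS-only / FBS-hMSCs /
  SS-hMSCs, planted severity ordering SS < FBS < PBS).

All shapes are defined on voxel-center offsets from the grid midplanes, so
with the lesion absent the two hemispheres are *exact* mirror images (index
flip), which downstream modules exploit for bit-exact null tests.

DWI signal follows the monoexponential tensor model
``S = S0 exp(-b g^T D g)`` with Rician noise ``sqrt((S+n1)^2 + n2^2)``,
``n ~ N(0, sigma^2)``, ``sigma = (white-matter b0 signal) / SNR``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .gradients import GradientScheme, default_scheme
from .grid import Grid, LabelMask
from .tensor import DWIVolume

__all__ = [
    "TissueModel",
    "PhantomSpec",
    "GroupEffects",
    "LabelStack",
    "default_tissues",
    "build_label_volume",
    "simulate_dwi",
    "simulate_t2",
    "simulate_cohort",
    "default_enrollment_ledger",
    "GROUPS",
    "TIMEPOINTS",
]

GROUPS = ("PBS-only", "FBS-hMSCs", "SS-hMSCs")
TIMEPOINTS = ("day1", "wk2", "wk5")


@dataclass(frozen=True)
class TissueModel:
    """Ground-truth diffusion and T2 properties of one tissue class.

    Eigenvalues are diffusivities in mm^2/s, sorted descending and strictly
    positive. ``principal_direction`` orients the largest eigenvalue (only
    meaningful for anisotropic tissue; isotropic tissues may use any unit
    vector). T2 intensities are arbitrary units; ``s0`` is the b=0 DWI
    signal level.
    """

    label: str
    tensor_eigenvalues: tuple[float, float, float]
    principal_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    t2_intensity_mean: float = 100.0
    t2_intensity_sd: float = 5.0
    s0: float = 1000.0

    def __post_init__(self) -> None:
        lam = self.tensor_eigenvalues
        if any(v <= 0 for v in lam):
            raise ValueError(f"{self.label}: eigenvalues must be strictly positive, got {lam}")
        if not lam[0] >= lam[1] >= lam[2]:
            raise ValueError(f"{self.label}: eigenvalues must be sorted descending, got {lam}")
        n = float(np.linalg.norm(self.principal_direction))
        if abs(n - 1.0) > 1e-8:
            raise ValueError(f"{self.label}: principal_direction must be unit norm, |v|={n}")
        if self.t2_intensity_sd < 0:
            raise ValueError(f"{self.label}: negative T2 intensity sd")

    def tensor(self) -> np.ndarray:
        """Assemble the 3x3 tensor: principal eigenvalue along the stated direction."""
        e1 = np.asarray(self.principal_direction, dtype=float)
        # complete an orthonormal frame around e1
        trial = np.array([0.0, 1.0, 0.0]) if abs(e1[0]) > 0.9 else np.array([1.0, 0.0, 0.0])
        e2 = np.cross(e1, trial)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        R = np.column_stack([e1, e2, e3])
        return R @ np.diag(self.tensor_eigenvalues) @ R.T


def default_tissues() -> dict[str, TissueModel]:
    """Literature-typical rodent tissue values (not a claim about any one study).

    Gray matter is modeled exactly isotropic (FA = 0) so sub-threshold
    tracking tests are clean; white matter is strongly prolate along x
    (FA ~ 0.8); CSF is fast-isotropic and T2-hyperintense.
    """
    return {
        "background": TissueModel(
            "background", (0.3e-3, 0.3e-3, 0.3e-3),
            t2_intensity_mean=5.0, t2_intensity_sd=2.0, s0=20.0,
        ),
        "gray": TissueModel(
            "gray", (0.8e-3, 0.8e-3, 0.8e-3),
            t2_intensity_mean=100.0, t2_intensity_sd=5.0, s0=900.0,
        ),
        "white": TissueModel(
            "white", (1.7e-3, 0.3e-3, 0.3e-3), principal_direction=(1.0, 0.0, 0.0),
            t2_intensity_mean=95.0, t2_intensity_sd=5.0, s0=1000.0,
        ),
        "csf": TissueModel(
            "csf", (3.0e-3, 3.0e-3, 3.0e-3),
            t2_intensity_mean=180.0, t2_intensity_sd=6.0, s0=1500.0,
        ),
    }


def lesion_tissue(base: TissueModel, eigenvalue_factor: float, t2_mean: float = 130.0,
                  t2_sd: float = 5.0) -> TissueModel:
    """Lesioned variant of a tissue: all eigenvalues scaled by one factor.

    Uniform scaling changes AD/RD/MD by the factor but leaves FA unchanged
    (FA is scale-invariant) -- a property the ROI-metric tests exploit to
    verify each relative metric reads the correct map. The lesion is
    T2-hyperintense (default mean 130 vs normal 100 +/- 5, i.e. 6 sd above,
    comfortably past the mean + 2 sd segmentation rule).
    """
    if eigenvalue_factor <= 0:
        raise ValueError("lesion eigenvalue factor must be positive")
    lam = tuple(v * eigenvalue_factor for v in base.tensor_eigenvalues)
    return TissueModel(
        label=f"lesion_{base.label}",
        tensor_eigenvalues=lam,
        principal_direction=base.principal_direction,
        t2_intensity_mean=t2_mean,
        t2_intensity_sd=t2_sd,
        s0=base.s0,
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to realize one animal's longitudinal phantom.

    Geometry is parameterized in mm relative to the grid center; the lesion
    center x-offset is measured from the midsagittal plane into the right
    (ipsilesional) hemisphere. Lesion radii must be non-increasing over
    timepoints (infarcts consolidate), ventricle volume scales must be >= 1.
    ``snr = None`` disables noise entirely.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 16)
    voxel_size: tuple[float, float, float] = (0.156, 0.156, 0.75)
    timepoints: tuple[str, ...] = TIMEPOINTS
    lesion_radius_by_timepoint: tuple[float, ...] = (2.0, 1.2, 0.8)
    ventricle_scale_by_timepoint: tuple[float, ...] = (1.0, 1.25, 1.5)
    lesion_eigenvalue_factor_by_timepoint: tuple[float, ...] = (0.6, 0.75, 0.9)
    snr: Optional[float] = 30.0
    seed: int = 0
    # geometry (mm)
    brain_semiaxes: tuple[float, float, float] = (4.6, 4.3, 5.2)
    bundle_radius: float = 0.9
    bundle_center_yz: tuple[float, float] = (-1.8, 0.0)
    ventricle_semiaxes: tuple[float, float, float] = (0.55, 1.3, 1.6)
    ventricle_center: tuple[float, float, float] = (1.5, 1.5, 0.0)  # |x| from midline
    lesion_center: tuple[float, float, float] = (2.4, -1.8, 0.0)    # x from midline, ipsi

    def __post_init__(self) -> None:
        self.grid.require_even_lr()
        ntp = len(self.timepoints)
        for name in ("lesion_radius_by_timepoint", "ventricle_scale_by_timepoint",
                     "lesion_eigenvalue_factor_by_timepoint"):
            v = getattr(self, name)
            if len(v) != ntp:
                raise ValueError(f"{name} must have one entry per timepoint ({ntp}), got {v}")
        radii = self.lesion_radius_by_timepoint
        if any(r < 0 for r in radii):
            raise ValueError("lesion radii must be non-negative")
        if any(radii[i] < radii[i + 1] for i in range(len(radii) - 1)):
            raise ValueError(
                f"lesion radii must be non-increasing over time, got {radii}"
            )
        if any(s < 1 for s in self.ventricle_scale_by_timepoint):
            raise ValueError("ventricle scales must be >= 1")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive (or None to disable noise)")
        # lesion strictly inside the ipsilesional hemisphere and grid
        rmax = max(radii)
        cx = self.lesion_center[0]
        half_fov_x = self.grid_shape[0] * self.voxel_size[0] / 2
        if rmax > 0 and (cx - rmax < 0 or cx + rmax > half_fov_x):
            raise ValueError(
                f"lesion (center offset {cx} mm, radius {rmax} mm) exceeds the "
                f"ipsilesional hemisphere extent [0, {half_fov_x:.2f}] mm"
            )

    @property
    def grid(self) -> Grid:
        return Grid(tuple(self.grid_shape), tuple(self.voxel_size))

    def timepoint_index(self, timepoint: str) -> int:
        try:
            return self.timepoints.index(timepoint)
        except ValueError:
            raise ValueError(
                f"unknown timepoint {timepoint!r}; spec defines {self.timepoints}"
            ) from None


@dataclass
class LabelStack:
    """Mutually disjoint tissue masks covering the grid.

    ``masks`` keys: background, gray, white, csf, lesion_gray, lesion_white.
    The lesion sub-labels remember which normal tissue each lesioned voxel
    replaced, so the DWI simulator can apply the eigenvalue attenuation to
    the correct baseline tensor.
    """

    masks: dict[str, LabelMask]
    grid: Grid

    @property
    def lesion(self) -> LabelMask:
        data = self.masks["lesion_gray"].data | self.masks["lesion_white"].data
        return LabelMask(data, self.grid, "lesion")

    @property
    def brain(self) -> LabelMask:
        if "background" in self.masks:
            data = ~self.masks["background"].data
        else:
            data = np.zeros(self.grid.shape, dtype=bool)
            for m in self.masks.values():
                data |= m.data
        return LabelMask(data, self.grid, "brain")

    @property
    def ventricles(self) -> LabelMask:
        return self.masks["csf"]

    def hemisphere(self, side: str) -> LabelMask:
        """Boolean mask of the left (x<0, contralesional) or right hemisphere."""
        xo = self.grid.axis_offsets_mm(0)
        if side == "right":
            col = xo > 0
        elif side == "left":
            col = xo < 0
        else:
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        data = np.zeros(self.grid.shape, dtype=bool)
        data[col, :, :] = True
        return LabelMask(data, self.grid, f"hemisphere_{side}")


def _ellipsoid(xo, yo, zo, center, semiaxes) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((xo - cx) / ax) ** 2 + ((yo - cy) / ay) ** 2 + ((zo - cz) / az) ** 2 <= 1.0


def build_label_volume(spec: PhantomSpec, timepoint: str) -> LabelStack:
    """Realize the tissue label masks for one timepoint.

    Precedence where shapes overlap: CSF > lesion > white > gray. The two
    ventricles and the bundle depend on the left-right coordinate only
    through |x|, so with lesion radius 0 the stack is exactly mirror
    symmetric.
    """
    it = spec.timepoint_index(timepoint)
    grid = spec.grid
    xo, yo, zo = grid.center_offsets_mm()

    brain = _ellipsoid(xo, yo, zo, (0, 0, 0), spec.brain_semiaxes)

    by, bz = spec.bundle_center_yz
    bundle = brain & ((yo - by) ** 2 + (zo - bz) ** 2 <= spec.bundle_radius**2)

    vs = spec.ventricle_scale_by_timepoint[it] ** (1.0 / 3.0)  # volume scale -> axes
    vcx, vcy, vcz = spec.ventricle_center
    vax = tuple(a * vs for a in spec.ventricle_semiaxes)
    csf = _ellipsoid(np.abs(xo), yo, zo, (vcx, vcy, vcz), vax) & brain

    r = spec.lesion_radius_by_timepoint[it]
    lx, ly, lz = spec.lesion_center
    if r > 0:
        lesion = ((xo - lx) ** 2 + (yo - ly) ** 2 + (zo - lz) ** 2 <= r**2) & brain & ~csf
    else:
        lesion = np.zeros(grid.shape, dtype=bool)

    white = bundle & ~csf & ~lesion
    gray = brain & ~csf & ~lesion & ~white
    masks = {
        "background": ~brain,
        "gray": gray,
        "white": white,
        "csf": csf,
        "lesion_white": lesion & bundle,
        "lesion_gray": lesion & ~bundle,
    }
    total = sum(m.sum() for m in masks.values())
    assert total == np.prod(grid.shape), "label masks must partition the grid"
    return LabelStack(
        masks={k: LabelMask(v, grid, k) for k, v in masks.items()}, grid=grid
    )


def _tissues_for_stack(spec: PhantomSpec, timepoint: str,
                       tissues: Optional[Mapping[str, TissueModel]]) -> dict[str, TissueModel]:
    base = dict(tissues) if tissues is not None else default_tissues()
    it = spec.timepoint_index(timepoint)
    f = spec.lesion_eigenvalue_factor_by_timepoint[it]
    base.setdefault("lesion_gray", lesion_tissue(base["gray"], f))
    base.setdefault("lesion_white", lesion_tissue(base["white"], f))
    return base


def _rician(noiseless: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: sqrt((S + n1)^2 + n2^2), n ~ N(0, sigma^2)."""
    n1 = rng.normal(0.0, sigma, size=noiseless.shape)
    n2 = rng.normal(0.0, sigma, size=noiseless.shape)
    return np.sqrt((noiseless + n1) ** 2 + n2**2)


def simulate_dwi(
    labels: LabelStack,
    tissues: Mapping[str, TissueModel],
    scheme: Optional[GradientScheme] = None,
    snr: Optional[float] = 30.0,
    seed: int = 0,
) -> DWIVolume:
    """Forward-simulate the DWI signal from tissue tensors.

    Per voxel the noiseless signal is ``S_i = S0 exp(-b_i g_i^T D g_i)``
    with ``D`` assembled from the voxel's tissue eigenvalues and
    orientation; Rician noise is then applied at the stated SNR
    (``sigma = white-matter b0 signal / snr``; ``snr=None`` disables it).
    Output is bit-reproducible under ``seed``.
    """
    if scheme is None:
        scheme = default_scheme()
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive (or None for noiseless)")
    missing = [k for k in labels.masks if k not in tissues and labels.masks[k].count > 0]
    if missing:
        raise ValueError(f"no tissue model for labeled class(es): {missing}")

    grid = labels.grid
    data = np.zeros(tuple(grid.shape) + (len(scheme),))
    b = scheme.bvals
    g = scheme.bvecs
    for name, mask in labels.masks.items():
        if mask.count == 0:
            continue
        t = tissues[name]
        D = t.tensor()
        atten = np.exp(-b * np.einsum("ij,jk,ik->i", g, D, g))
        data[mask.data] = t.s0 * atten

    if snr is not None:
        sigma = tissues["white"].s0 / snr
        rng = np.random.default_rng(seed)
        data = _rician(data, sigma, rng)
    return DWIVolume(data=data, scheme=scheme, grid=grid, brain_mask=labels.brain)


def simulate_t2(
    labels: LabelStack,
    tissues: Mapping[str, TissueModel],
    seed: int = 0,
    noise: bool = True,
) -> np.ndarray:
    """T2-weighted image: Gaussian intensity per tissue class, seeded.

    With ``noise=False`` the image is piecewise constant at the tissue
    means. Lesion tissue must sit well above the contralateral normal mean
    for the mean + 2 sd segmentation rule to have power; the defaults put it
    6 sd above.
    """
    rng = np.random.default_rng(seed)
    img = np.zeros(labels.grid.shape)
    for name, mask in labels.masks.items():
        if mask.count == 0:
            continue
        t = tissues[name]
        if t.t2_intensity_sd < 0:
            raise ValueError(f"{name}: negative T2 sd")
        if noise and t.t2_intensity_sd > 0:
            img[mask.data] = rng.normal(t.t2_intensity_mean, t.t2_intensity_sd, mask.count)
        else:
            img[mask.data] = t.t2_intensity_mean
    return img


# ---------------------------------------------------------------------------
# cohort-level simulation


@dataclass(frozen=True)
class GroupEffects:
    """Planted per-group trajectories for lesion anatomy and behavior.

    ``mnss_mean_by_timepoint`` are expected total mNSS scores (higher =
    worse); ``lesion_radius_by_timepoint`` in mm. Defaults (see
    ``default_group_effects``) plant the treated < control severity ordering
    SS-hMSCs < FBS-hMSCs < PBS-only at week 5 while all groups start alike
    on day 1, mirroring a therapy that acts over weeks.
    """

    lesion_radius_by_timepoint: tuple[float, ...]
    mnss_mean_by_timepoint: tuple[float, ...]
    mnss_sd: float = 1.2
    lesion_radius_sd: float = 0.1
    ventricle_scale_by_timepoint: tuple[float, ...] = (1.0, 1.25, 1.5)
    ventricle_scale_sd: float = 0.08


def default_group_effects() -> dict[str, GroupEffects]:
    """Planted trajectories: controls stay worse, treated arms recover more.

    Week-5 severity ordering SS-hMSCs < FBS-hMSCs < PBS-only on lesion size,
    ventricular enlargement and mNSS; all arms start alike on day 1.
    """
    return {
        "PBS-only": GroupEffects((2.0, 1.6, 1.3), (12.0, 10.5, 9.5),
                                 ventricle_scale_by_timepoint=(1.0, 1.4, 1.8)),
        "FBS-hMSCs": GroupEffects((2.0, 1.4, 1.0), (12.0, 9.0, 7.5),
                                  ventricle_scale_by_timepoint=(1.0, 1.3, 1.6)),
        "SS-hMSCs": GroupEffects((2.0, 1.2, 0.8), (12.0, 7.5, 5.5),
                                 ventricle_scale_by_timepoint=(1.0, 1.2, 1.4)),
    }


# enrollment ledger mirroring the published three-arm cohort: 45 randomized,
# 4 early deaths, 4 without deficits, 2 subarachnoid hemorrhages -> 35 analyzed
_LEDGER_COUNTS = {
    "SS-hMSCs": {"n": 15, "died_24h": 2, "no_deficit": 1, "SAH": 1},
    "FBS-hMSCs": {"n": 15, "died_24h": 1, "no_deficit": 1, "SAH": 1},
    "PBS-only": {"n": 15, "died_24h": 1, "no_deficit": 2, "SAH": 0},
}


def default_enrollment_ledger() -> pd.DataFrame:
    """The study-structure enrollment ledger as a CohortTable DataFrame."""
    rows = []
    for group, c in _LEDGER_COUNTS.items():
        flags = (
            ["died_24h"] * c["died_24h"]
            + ["no_deficit"] * c["no_deficit"]
            + ["SAH"] * c["SAH"]
        )
        flags += ["none"] * (c["n"] - len(flags))
        for i, flag in enumerate(flags):
            rows.append(
                {
                    "animal": f"{group.split('-')[0]}-{i + 1:02d}",
                    "group": group,
                    "exclusion": flag,
                    "assay": "MRI+behavior",
                }
            )
    return pd.DataFrame(rows)


def _distribute_mnss_items(total: int, rng: np.random.Generator) -> dict[str, int]:
    """Split a target total across the rubric items (tail 0-3, sensory 0-12, beam 0-6).

    Greedy randomized allocation respecting each subscale's bound; the
    resulting record always re-scores to ``total`` (clamped to [0, 21]).
    """
    total = int(np.clip(total, 0, 21))
    caps = {"tail": 3, "sensory": 12, "beam": 6}
    alloc = {k: 0 for k in caps}
    keys = list(caps)
    remaining = total
    while remaining > 0:
        open_keys = [k for k in keys if alloc[k] < caps[k]]
        k = open_keys[rng.integers(len(open_keys))]
        alloc[k] += 1
        remaining -= 1
    record: dict[str, int] = {}
    # tail: three binary items
    tail_items = ["tail_forelimb_flexion", "tail_hindlimb_flexion", "tail_head_movement"]
    order = rng.permutation(3)
    for j, idx in enumerate(order):
        record[tail_items[idx]] = 1 if j < alloc["tail"] else 0
    # sensory: four 0-3 items
    sens_items = [
        "sensory_visual_forelimb",
        "sensory_tactile_forelimb",
        "sensory_proprioceptive_hindlimb",
        "sensory_tactile_hindlimb",
    ]
    left = alloc["sensory"]
    order = rng.permutation(4)
    for j, idx in enumerate(order):
        cap_rest = 3 * (3 - j)
        v = int(np.clip(left - cap_rest, 0, 3))
        hi = min(3, left)
        v = int(rng.integers(v, hi + 1)) if hi > v else v
        record[sens_items[idx]] = v
        left -= v
    record["beam_balance"] = alloc["beam"]
    return record


def simulate_cohort(
    n_per_group: int = 6,
    group_effects: Optional[Mapping[str, GroupEffects]] = None,
    seed: int = 0,
    base_spec: Optional[PhantomSpec] = None,
    exclusions: bool = False,
) -> tuple[pd.DataFrame, dict[str, PhantomSpec], pd.DataFrame]:
    """Simulate a three-arm cohort: ledger, per-animal phantom specs, mNSS records.

    Returns ``(cohort, specs, mnss)`` where ``cohort`` is a CohortTable
    (animal, group, exclusion, assay), ``specs`` maps animal id to its
    longitudinal :class:`PhantomSpec` (per-animal lesion radii drawn around
    the group trajectory, monotonized), and ``mnss`` holds item-level
    rubric responses per animal x timepoint whose totals track the group
    trajectory. With ``exclusions=True`` a small fraction of animals
    receives non-``none`` flags (rates matching the study ledger: ~9%
    death, ~9% no deficit, ~4% SAH).
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 animals per group")
    effects = dict(group_effects) if group_effects is not None else default_group_effects()
    unknown = set(effects) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}; expected {GROUPS}")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    # largest lesion the geometry admits: sphere must stay inside the
    # ipsilesional half of the field of view
    cx = base.lesion_center[0]
    half_fov_x = base.grid_shape[0] * base.voxel_size[0] / 2
    r_max = min(cx, half_fov_x - cx)

    rows, specs, mnss_rows = [], {}, []
    for group in GROUPS:
        eff = effects[group]
        for i in range(n_per_group):
            animal = f"{group.split('-')[0]}-{i + 1:02d}"
            if exclusions:
                u = rng.random()
                flag = ("died_24h" if u < 0.09 else
                        "no_deficit" if u < 0.18 else
                        "SAH" if u < 0.22 else "none")
            else:
                flag = "none"
            rows.append({"animal": animal, "group": group, "exclusion": flag,
                         "assay": "MRI+behavior"})
            radii = np.array(eff.lesion_radius_by_timepoint) + rng.normal(
                0, eff.lesion_radius_sd, len(base.timepoints)
            )
            radii = np.maximum.accumulate(radii[::-1])[::-1]  # enforce shrinkage
            radii = np.clip(radii, 0.0, r_max)
            vscale = np.array(eff.ventricle_scale_by_timepoint) * (
                1 + rng.normal(0, eff.ventricle_scale_sd, len(base.timepoints))
            )
            vscale = np.maximum(np.maximum.accumulate(vscale), 1.0)  # enlargement only
            specs[animal] = replace(
                base,
                lesion_radius_by_timepoint=tuple(radii),
                ventricle_scale_by_timepoint=tuple(vscale),
                seed=int(rng.integers(2**31 - 1)),
            )
            for it, tp in enumerate(base.timepoints):
                target = int(round(rng.normal(eff.mnss_mean_by_timepoint[it], eff.mnss_sd)))
                rec = _distribute_mnss_items(target, rng)
                mnss_rows.append({"animal": animal, "group": group, "timepoint": tp, **rec})
    return pd.DataFrame(rows), specs, pd.DataFrame(mnss_rows)
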