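"""End-to-end pipeline driver and its configuration.

``run_all`` executes the full analysis in the study's order on a simulated
cohort: phantom generation -> tensor fit -> scalar maps -> T2 lesion and
ventricle segmentation -> day-1 normalization -> recovery-ROI construction
-> ROI-seeded tractography -> relative metrics -> mNSS scoring -> GEE
interaction gate -> per-timepoint ANOVA + Tukey (only when the gate passes)
-> Pearson correlations between morphology and DTI metrics. Everything is
deterministic under the config seed, every threshold used is logged, and
results are written as tidy TSV plus a JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import morphometry as morph
from . import phantom as ph
from . import roi as roi_mod
from . import stats as st
from .gradients import default_scheme
from .grid import LabelMask
from .tensor import eigendecompose, fit_tensor, scalar_maps
from .tracking import TrackingParams, fiber_density, track

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated parameters for one pipeline run.

    ``roi_mode`` selects the ipsilesional analysis region: ``recovery``
    (day-1 minus 5-week segmented lesion, the study definition) or
    ``bundle`` (ground-truth white-matter bundle in the ipsilesional
    hemisphere, the control used for lesion-free cohorts).
    """

    n_per_group: int = 6
    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    voxel_size: tuple[float, float, float] = (0.156, 0.156, 0.75)
    snr: Optional[float] = 30.0
    lesion_free: bool = False
    roi_mode: str = "recovery"
    sd_multiplier: float = 2.0
    n_ventricle_slices: int = 8
    fa_threshold: float = 0.15
    max_angle_deg: float = 45.0
    gate_alpha: float = 0.05
    working_correlation: str = "exchangeable"
    force_posthoc: bool = False   # run ANOVA/Tukey even if the GEE gate fails
    track_fd: bool = True         # run ROI-seeded tractography for rFD
    ipsilesional_side: str = "right"

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.roi_mode not in ("recovery", "bundle"):
            raise ValueError(f"roi_mode must be 'recovery' or 'bundle', got {self.roi_mode!r}")
        if not (0 < self.gate_alpha < 1):
            raise ValueError("gate_alpha must be in (0, 1)")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        if self.ipsilesional_side not in ("left", "right"):
            raise ValueError("ipsilesional_side must be 'left' or 'right'")
        if self.n_ventricle_slices < 1:
            raise ValueError("n_ventricle_slices must be >= 1")
        # delegate range checks on tracking / geometry parameters
        TrackingParams(fa_threshold=self.fa_threshold, max_angle_deg=self.max_angle_deg)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("grid_shape", "voxel_size"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        d["voxel_size"] = list(d["voxel_size"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def normal_cohort_relative_metrics(
    n_subjects: int = 6,
    snr: Optional[float] = 30.0,
    seed: int = 0,
    base_spec: Optional[ph.PhantomSpec] = None,
    track_fd: bool = False,
) -> pd.DataFrame:
    """Relative DTI metrics of intact (lesion-free) animals.

    Emulates the normal-rat control measurement: for each subject, simulate a
    mirror-symmetric lesion-free phantom, fit the tensor, and divide the
    ipsilesional white-matter-bundle ROI mean by the mirrored contralesional
    ROI mean. Returns one row per subject with rFA/rAD/rRD (and rFD when
    ``track_fd``). With noise the ratios scatter around 1; noiseless they are
    exactly 1.
    """
    base = base_spec if base_spec is not None else ph.PhantomSpec()
    base = replace(base, lesion_radius_by_timepoint=(0.0,) * len(base.timepoints),
                   ventricle_scale_by_timepoint=(1.0,) * len(base.timepoints), snr=snr)
    rng = np.random.default_rng(seed)
    scheme = default_scheme()
    tp = base.timepoints[0]
    stack = ph.build_label_volume(base, tp)  # identical for every subject
    tissues = ph._tissues_for_stack(base, tp, None)
    ipsi = LabelMask(
        stack.masks["white"].data & stack.hemisphere("right").data,
        base.grid, "bundle_ipsi",
    )
    pair = roi_mod.ROIPair(ipsi=ipsi, contra=roi_mod.mirror_roi(ipsi),
                           provenance=("bundle", "bundle"))
    rows = []
    for i in range(n_subjects):
        sub_seed = int(rng.integers(2**31 - 1))
        dwi = ph.simulate_dwi(stack, tissues, scheme, snr=snr, seed=sub_seed)
        eigs = eigendecompose(fit_tensor(dwi))
        maps = scalar_maps(eigs)
        fd_i = fd_c = None
        if track_fd:
            params = TrackingParams(seed=sub_seed)
            fd_i = fiber_density(track(eigs, maps.fa, pair.ipsi, params))
            fd_c = fiber_density(track(eigs, maps.fa, pair.contra, params))
        rel = roi_mod.relative_metrics(
            pair, maps, subject=f"normal-{i + 1:02d}", timepoint=tp,
            fd_ipsi=fd_i, fd_contra=fd_c,
        )
        rows.append({"subject": rel.subject, **rel.as_dict()})
    return pd.DataFrame(rows)


def _result_row(outcome, timepoint, r: st.ComparisonResult) -> dict:
    return {
        "outcome": outcome,
        "timepoint": timepoint,
        "contrast": r.contrast,
        "estimate": r.estimate,
        "se": r.se,
        "stat": r.statistic,
        "p": r.p_value,
        "p_adj": r.p_adjusted,
    }


def _analyze_subject(animal: str, spec: ph.PhantomSpec, cfg: PipelineConfig) -> list[dict]:
    """Image-analysis chain for one animal; returns tidy metric rows."""
    scheme = default_scheme()
    tissues_by_tp, stacks, t2s, maps_by_tp, eigs_by_tp = {}, {}, {}, {}, {}
    for k, tp in enumerate(spec.timepoints):
        stack = ph.build_label_volume(spec, tp)
        tissues = ph._tissues_for_stack(spec, tp, None)
        sub_seed = (spec.seed + 7919 * k) % (2**31 - 1)
        dwi = ph.simulate_dwi(stack, tissues, scheme, snr=cfg.snr, seed=sub_seed)
        t2 = ph.simulate_t2(stack, tissues, seed=sub_seed + 1, noise=cfg.snr is not None)
        field = fit_tensor(dwi)
        eigs = eigendecompose(field)
        stacks[tp], t2s[tp], tissues_by_tp[tp] = stack, t2, tissues
        eigs_by_tp[tp], maps_by_tp[tp] = eigs, scalar_maps(eigs)

    grid = spec.grid
    first_tp, last_tp = spec.timepoints[0], spec.timepoints[-1]
    ipsi_hemi = stacks[first_tp].hemisphere(cfg.ipsilesional_side)
    contra_hemi = stacks[first_tp].hemisphere(
        "left" if cfg.ipsilesional_side == "right" else "right"
    )

    rows: list[dict] = []
    lesion_masks, lesion_vols, vent_vols = {}, [], []
    nz = grid.shape[2]
    n_sl = min(cfg.n_ventricle_slices, nz)
    lo = (nz - n_sl) // 2
    slice_range = range(lo, lo + n_sl)
    for tp in spec.timepoints:
        stack, t2 = stacks[tp], t2s[tp]
        brain = stack.brain
        contra_mask = LabelMask(contra_hemi.data & brain.data, grid, "contra_brain")
        ipsi_mask = LabelMask(ipsi_hemi.data & brain.data, grid, "ipsi_brain")
        seg = morph.segment_lesion(
            t2, contra_mask, ipsi_mask,
            exclude=stack.ventricles, sd_multiplier=cfg.sd_multiplier,
        )
        lesion_masks[tp] = seg.mask
        lesion_vols.append(seg.mask.volume_mm3)
        vent_vols.append(
            morph.measure_ventricles(
                t2, stack.ventricles, slice_range=slice_range,
                contralateral_mask=contra_mask, sd_multiplier=cfg.sd_multiplier,
            )
        )

    for structure, vols in (("lesion", lesion_vols), ("ventricle", vent_vols)):
        try:
            series = morph.normalize_series(animal, structure, spec.timepoints, vols)
        except ValueError as exc:
            warnings.warn(f"{animal}: {exc}; skipping {structure} series", stacklevel=2)
            continue
        for tp, vol, nv in zip(spec.timepoints, series.volumes_mm3, series.normalized):
            rows.append({"animal": animal, "timepoint": tp,
                         "metric": f"{structure}_volume_mm3", "value": vol})
            rows.append({"animal": animal, "timepoint": tp,
                         "metric": f"{structure}_volume_norm", "value": nv})

    # analysis ROI: recovery region (study rule) or white-matter bundle control
    if cfg.roi_mode == "bundle":
        wm = stacks[last_tp].masks["white"].data | stacks[last_tp].masks["lesion_white"].data
        ipsi_roi = LabelMask(wm & ipsi_hemi.data, grid, "bundle_ipsi")
    else:
        ipsi_roi = recovery = roi_mod.recovery_roi(lesion_masks[first_tp], lesion_masks[last_tp])
    if ipsi_roi.count == 0:
        warnings.warn(f"{animal}: empty analysis ROI; relative metrics skipped", stacklevel=2)
        return rows
    pair = roi_mod.ROIPair(ipsi=ipsi_roi, contra=roi_mod.mirror_roi(ipsi_roi))

    tracking = TrackingParams(
        fa_threshold=cfg.fa_threshold, max_angle_deg=cfg.max_angle_deg, seed=spec.seed
    )
    for tp in spec.timepoints:
        fd_i = fd_c = None
        if cfg.track_fd:
            fd_i = fiber_density(track(eigs_by_tp[tp], maps_by_tp[tp].fa, pair.ipsi, tracking))
            fd_c = fiber_density(track(eigs_by_tp[tp], maps_by_tp[tp].fa, pair.contra, tracking))
            if fd_c == 0:
                warnings.warn(f"{animal}/{tp}: contralateral FD is 0; rFD skipped", stacklevel=2)
                fd_i = fd_c = None
        rel = roi_mod.relative_metrics(
            pair, maps_by_tp[tp], subject=animal, timepoint=tp,
            fd_ipsi=fd_i, fd_contra=fd_c,
        )
        for name, value in rel.as_dict().items():
            rows.append({"animal": animal, "timepoint": tp, "metric": name, "value": value})
    return rows


def run_all(cfg: PipelineConfig, out_dir=None,
            base_spec: Optional[ph.PhantomSpec] = None) -> dict:
    """Run the full study pipeline on a simulated cohort; return the report.

    The report carries the metric table, exclusion report, GEE gate results,
    per-timepoint post-hoc contrasts (gated at ``cfg.gate_alpha``), and
    Pearson correlations between normalized volumes and relative DTI
    metrics. When ``out_dir`` is given, writes ``metrics.tsv``,
    ``stats_results.tsv``, ``exclusions.json`` and ``summary.json``.
    """
    effects = ph.default_group_effects()
    if cfg.lesion_free:
        effects = {
            g: replace(e, lesion_radius_by_timepoint=(0.0,) * 3, lesion_radius_sd=0.0,
                       ventricle_scale_by_timepoint=(1.0,) * 3, ventricle_scale_sd=0.0)
            for g, e in effects.items()
        }
    if base_spec is None:
        base_spec = ph.PhantomSpec(
            grid_shape=cfg.grid_shape, voxel_size=cfg.voxel_size, snr=cfg.snr,
            lesion_radius_by_timepoint=(0.0, 0.0, 0.0) if cfg.lesion_free else (2.0, 1.2, 0.8),
        )
    else:
        base_spec = replace(base_spec, snr=cfg.snr)
        if cfg.lesion_free:
            base_spec = replace(base_spec, lesion_radius_by_timepoint=(0.0,) * 3,
                                ventricle_scale_by_timepoint=(1.0,) * 3)
        else:
            # rescale planted lesion trajectories to the phantom's anatomical scale
            scale = base_spec.lesion_radius_by_timepoint[0] / 2.0
            if scale != 1.0:
                effects = {
                    g: replace(
                        e,
                        lesion_radius_by_timepoint=tuple(
                            r * scale for r in e.lesion_radius_by_timepoint
                        ),
                        lesion_radius_sd=e.lesion_radius_sd * scale,
                    )
                    for g, e in effects.items()
                }
    cohort, specs, mnss = ph.simulate_cohort(
        cfg.n_per_group, group_effects=effects, seed=cfg.seed,
        base_spec=base_spec, exclusions=False,
    )
    if cfg.lesion_free:
        specs = {a: replace(s, lesion_radius_by_timepoint=(0.0, 0.0, 0.0)) for a, s in specs.items()}
    included, excl_report = bh.apply_exclusions(cohort)
    group_of = dict(zip(included["animal"], included["group"]))

    log.info(
        "pipeline: n=%d animals, grid=%s, snr=%s, roi_mode=%s, lesion threshold "
        "mean+%.1f sd, FA stop %.2f, angle stop %.0f deg, gate alpha %.2f",
        len(included), cfg.grid_shape, cfg.snr, cfg.roi_mode,
        cfg.sd_multiplier, cfg.fa_threshold, cfg.max_angle_deg, cfg.gate_alpha,
    )

    metric_rows: list[dict] = []
    for animal in included["animal"]:
        metric_rows.extend(_analyze_subject(animal, specs[animal], cfg))
    scored = bh.score_mnss_frame(mnss[mnss["animal"].isin(group_of)])
    for _, r in scored.iterrows():
        metric_rows.append({"animal": r["animal"], "timepoint": r["timepoint"],
                            "metric": "mnss_total", "value": float(r["mnss_total"])})
    metrics = pd.DataFrame(metric_rows)
    metrics["group"] = metrics["animal"].map(group_of)
    metrics = metrics[["animal", "group", "timepoint", "metric", "value"]]

    # ---- inference layer -------------------------------------------------
    timepoints = list(base_spec.timepoints)
    gate_results, posthoc_rows = {}, []
    outcomes = [m for m in
                ("mnss_total", "lesion_volume_norm", "ventricle_volume_norm",
                 "rFA", "rAD", "rRD", "rFD")
                if m in set(metrics["metric"])]
    for outcome in outcomes:
        sub = metrics[metrics["metric"] == outcome].rename(
            columns={"animal": "subject"})[["subject", "group", "timepoint", "value"]]
        if sub["timepoint"].nunique() < 2 or sub["group"].nunique() < 2:
            continue
        try:
            gate = st.gee_interaction(sub, working_correlation=cfg.working_correlation)
        except Exception as exc:  # singular designs on degenerate cohorts
            warnings.warn(f"GEE failed for {outcome}: {exc}", stacklevel=2)
            continue
        gate_results[outcome] = gate
        posthoc_rows.append(_result_row(outcome, "all", gate))
        if gate.p_value < cfg.gate_alpha or cfg.force_posthoc:
            for tp in timepoints:
                at = sub[sub["timepoint"] == tp]
                groups = {g: d["value"].to_numpy() for g, d in at.groupby("group")}
                if any(len(v) < 2 for v in groups.values()) or len(groups) < 2:
                    continue
                anova, pairwise = st.anova_tukey(groups)
                posthoc_rows.append(_result_row(outcome, tp, anova))
                posthoc_rows.extend(_result_row(outcome, tp, p) for p in pairwise)

    correlations = []
    wide = metrics.pivot_table(index=["animal", "timepoint"], columns="metric",
                               values="value").reset_index()
    for tp in timepoints[1:]:
        at = wide[wide["timepoint"] == tp]
        for xm in ("lesion_volume_norm", "ventricle_volume_norm"):
            for ym in ("rFA", "rFD"):
                if xm in at and ym in at:
                    sub = at[[xm, ym]].dropna()
                    if len(sub) >= 3 and sub[xm].std() > 0 and sub[ym].std() > 0:
                        r = st.pearson(sub[xm], sub[ym])
                        correlations.append({
                            "timepoint": tp, "x": xm, "y": ym,
                            "r": r.estimate, "p": r.p_value, "n": len(sub),
                        })

    results = pd.DataFrame(posthoc_rows)
    report = {
        "config": dataclasses.asdict(cfg),
        "exclusions": excl_report,
        "metrics": metrics,
        "gate": {k: {"stat": v.statistic, "p": v.p_value} for k, v in gate_results.items()},
        "results": results,
        "correlations": pd.DataFrame(correlations),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.6f")
        results.to_csv(out / "stats_results.tsv", sep="\t", index=False, float_format="%.6g")
        (out / "exclusions.json").write_text(json.dumps(excl_report, indent=2))
        summary = {
            "config": report["config"],
            "gate": report["gate"],
            "correlations": report["correlations"].to_dict(orient="records"),
            "group_means": metrics.groupby(["metric", "timepoint", "group"])["value"]
            .mean().round(4).reset_index().to_dict(orient="records"),
        }
        summary["config"]["snr"] = cfg.snr
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return report
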