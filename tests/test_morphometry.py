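"""Lesion segmentation, ventricular volumetry, and day-1 normalization."""

from dataclasses import replace

import numpy as np
import pytest
import scipy.stats as sps

from strokedti.grid import LabelMask
from strokedti.morphometry import measure_ventricles, normalize_series, segment_lesion
from strokedti.phantom import _tissues_for_stack, build_label_volume, simulate_t2


def _hemis(stack):
    grid = stack.grid
    brain = stack.brain.data
    ipsi = LabelMask(stack.hemisphere("right").data & brain, grid, "ipsi")
    contra = LabelMask(stack.hemisphere("left").data & brain, grid, "contra")
    return ipsi, contra


class TestSegmentLesion:
    def test_planted_lesion_recovered_and_threshold_near_110(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        tissues = _tissues_for_stack(default_spec, "day1", None)
        t2 = simulate_t2(stack, tissues, seed=21)
        ipsi, contra = _hemis(stack)
        seg = segment_lesion(t2, contra, ipsi, exclude=stack.ventricles)
        lesion = stack.lesion.data
        recovered = (seg.mask.data & lesion).sum() / lesion.sum()
        assert recovered >= 0.99  # lesion mean is 4 sd above the threshold
        assert seg.threshold == pytest.approx(110.0, abs=1.0)

    def test_noiseless_piecewise_image_segments_exactly(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        tissues = _tissues_for_stack(default_spec, "day1", None)
        t2 = simulate_t2(stack, tissues, noise=False)
        ipsi, contra = _hemis(stack)
        seg = segment_lesion(t2, contra, ipsi, exclude=stack.ventricles)
        # noiseless: threshold collapses to the (mixed gray/white) mean and
        # everything brighter on the ipsi side is lesion or CSF
        expected = (stack.lesion.data | stack.ventricles.data) & ipsi.data
        assert np.array_equal(seg.mask.data, expected | (seg.mask.data & expected))
        assert np.all(stack.lesion.data[ipsi.data] <= seg.mask.data[ipsi.data])

    def test_lesion_free_false_positive_rate_matches_gaussian_tail(self, default_spec):
        spec = replace(default_spec, lesion_radius_by_timepoint=(0.0, 0.0, 0.0))
        stack = build_label_volume(spec, "day1")
        # homogeneous tissue: single Gaussian everywhere in brain
        tissues = _tissues_for_stack(spec, "day1", None)
        n_trials, rate_sum, n_vox = 10, 0.0, 0
        counts = []
        for s in range(n_trials):
            t2 = simulate_t2(stack, tissues, seed=100 + s)
            ipsi, contra = _hemis(stack)
            # restrict to gray matter so the reference and test populations
            # share one distribution (bundle/CSF have different means)
            gray_ipsi = LabelMask(stack.masks["gray"].data & ipsi.data, stack.grid)
            gray_contra = LabelMask(stack.masks["gray"].data & contra.data, stack.grid)
            seg = segment_lesion(t2, gray_contra, gray_ipsi)
            counts.append(seg.mask.count)
            n_vox = gray_ipsi.count
        p = sps.norm.sf(2.0)  # 0.02275
        total = np.sum(counts)
        n_total = n_trials * n_vox
        lo, hi = sps.binom.interval(0.99, n_total, p)
        assert lo <= total <= hi

    def test_threshold_monotonicity_in_sd_multiplier(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        tissues = _tissues_for_stack(default_spec, "day1", None)
        t2 = simulate_t2(stack, tissues, seed=3)
        ipsi, contra = _hemis(stack)
        seg2 = segment_lesion(t2, contra, ipsi, exclude=stack.ventricles, sd_multiplier=2.0)
        seg3 = segment_lesion(t2, contra, ipsi, exclude=stack.ventricles, sd_multiplier=3.0)
        assert np.all(seg3.mask.data <= seg2.mask.data)

    def test_lesion_mask_subset_of_ipsilateral(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        tissues = _tissues_for_stack(default_spec, "day1", None)
        t2 = simulate_t2(stack, tissues, seed=4)
        ipsi, contra = _hemis(stack)
        seg = segment_lesion(t2, contra, ipsi, exclude=stack.ventricles)
        assert np.all(seg.mask.data <= ipsi.data)

    def test_empty_contralateral_mask_rejected(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        grid = stack.grid
        t2 = np.zeros(grid.shape)
        empty = LabelMask(np.zeros(grid.shape, bool), grid)
        ipsi, _ = _hemis(stack)
        with pytest.raises(ValueError, match="empty"):
            segment_lesion(t2, empty, ipsi)

    def test_zero_variance_reference_warns_and_uses_mean(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        grid = stack.grid
        t2 = np.full(grid.shape, 100.0)
        ipsi, contra = _hemis(stack)
        with pytest.warns(UserWarning, match="zero variance"):
            seg = segment_lesion(t2, contra, ipsi)
        assert seg.threshold == 100.0


class TestVentricles:
    def test_noiseless_volume_equals_planted_count(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        grid = stack.grid
        t2 = np.zeros(grid.shape)
        vol = measure_ventricles(t2, stack.ventricles, slice_range=range(grid.shape[2]))
        assert vol == stack.ventricles.count * grid.voxel_volume

    def test_planted_scaling_recovered_within_10pct(self, default_spec):
        spec = replace(default_spec, ventricle_scale_by_timepoint=(1.0, 1.25, 1.5))
        tissues = _tissues_for_stack(spec, "day1", None)
        vols = {}
        for tp in ("day1", "wk5"):
            stack = build_label_volume(spec, tp)
            t2 = simulate_t2(stack, tissues, seed=8)
            _, contra = _hemis(stack)
            vols[tp] = measure_ventricles(
                t2, stack.ventricles, contralateral_mask=contra
            )
        assert vols["wk5"] / vols["day1"] == pytest.approx(1.5, rel=0.10)

    def test_zero_volume_prior(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        empty = LabelMask(np.zeros(stack.grid.shape, bool), stack.grid)
        assert measure_ventricles(np.zeros(stack.grid.shape), empty) == 0.0

    def test_out_of_range_slices_rejected(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        with pytest.raises(ValueError, match="slice range"):
            measure_ventricles(
                np.zeros(stack.grid.shape), stack.ventricles, slice_range=range(10, 30)
            )


class TestNormalizeSeries:
    def test_worked_arithmetic(self):
        s = normalize_series("r1", "lesion", ("day1", "wk2", "wk5"), (50.0, 30.0, 20.0))
        assert s.normalized == (1.0, 0.6, 0.4)

    def test_constant_series_all_ones(self):
        s = normalize_series("r1", "ventricle", ("day1", "wk2", "wk5"), (7.0, 7.0, 7.0))
        assert s.normalized == (1.0, 1.0, 1.0)

    def test_day1_always_exactly_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vols = rng.uniform(1.0, 100.0, 3)
            s = normalize_series("x", "lesion", ("a", "b", "c"), vols)
            assert s.normalized[0] == 1.0

    def test_zero_day1_rejected(self):
        with pytest.raises(ValueError, match="day-1"):
            normalize_series("r1", "lesion", ("day1", "wk5"), (0.0, 5.0))

    def test_cohort_phantom_shrinkage_recovered(self, default_spec):
        # planted radii (2.0, 1.2, 0.8) -> volume ratios (r/r1)^3
        vols = [
            build_label_volume(default_spec, tp).lesion.volume_mm3
            for tp in default_spec.timepoints
        ]
        s = normalize_series("r1", "lesion", default_spec.timepoints, vols)
        planted = [(r / 2.0) ** 3 for r in default_spec.lesion_radius_by_timepoint]
        # voxelization error dominates for the ~1-voxel-thick 5-week sphere
        assert np.allclose(s.normalized, planted, atol=0.02)
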