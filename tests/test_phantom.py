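"""Phantom generator: geometry, signal model, noise, and cohort structure."""

from dataclasses import replace

import numpy as np
import pytest

from strokedti.gradients import GradientScheme, default_scheme, fibonacci_directions
from strokedti.phantom import (
    GroupEffects,
    PhantomSpec,
    TissueModel,
    _distribute_mnss_items,
    _tissues_for_stack,
    build_label_volume,
    default_enrollment_ledger,
    default_group_effects,
    default_tissues,
    simulate_cohort,
    simulate_dwi,
    simulate_t2,
)
from strokedti.behavior import MNSSRecord, score_mnss, apply_exclusions


class TestGeometry:
    def test_masks_partition_grid(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        total = np.zeros(default_spec.grid.shape, dtype=int)
        for m in stack.masks.values():
            total += m.data
        assert np.all(total == 1)

    def test_lesion_free_phantom_is_exact_mirror(self, default_spec):
        spec = replace(default_spec, lesion_radius_by_timepoint=(0.0, 0.0, 0.0))
        stack = build_label_volume(spec, "wk5")
        for name, m in stack.masks.items():
            assert np.array_equal(m.data, m.data[::-1, :, :]), name

    def test_lesion_count_strictly_decreasing_over_timepoints(self, default_spec):
        counts = [
            build_label_volume(default_spec, tp).lesion.count
            for tp in default_spec.timepoints
        ]
        assert counts[0] > counts[1] > counts[2] > 0

    def test_sphere_voxel_count_matches_analytic_volume(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        r = default_spec.lesion_radius_by_timepoint[0]
        analytic = 4 / 3 * np.pi * r**3 / default_spec.grid.voxel_volume
        assert abs(stack.lesion.count - analytic) / analytic < 0.10

    def test_ventricle_volume_scale_is_planted(self, default_spec):
        spec = replace(default_spec, ventricle_scale_by_timepoint=(1.0, 1.25, 1.5))
        v1 = build_label_volume(spec, "day1").ventricles.count
        v3 = build_label_volume(spec, "wk5").ventricles.count
        assert abs(v3 / v1 - 1.5) < 0.10 * 1.5

    def test_oversized_lesion_rejected(self, default_spec):
        with pytest.raises(ValueError, match="hemisphere"):
            replace(default_spec, lesion_radius_by_timepoint=(4.0, 3.0, 2.0))

    def test_growing_lesion_rejected(self, default_spec):
        with pytest.raises(ValueError, match="non-increasing"):
            replace(default_spec, lesion_radius_by_timepoint=(1.0, 1.5, 2.0))

    def test_odd_lr_dimension_rejected(self):
        with pytest.raises(ValueError, match="even"):
            PhantomSpec(grid_shape=(63, 64, 16))


class TestGradientScheme:
    def test_default_matches_acquisition(self):
        s = default_scheme()
        assert len(s) == 31
        assert (s.bvals == 0).sum() == 1
        assert np.all(s.bvals[1:] == 1000.0)
        assert np.allclose(np.linalg.norm(s.bvecs[1:], axis=1), 1.0, atol=1e-12)

    def test_collinear_directions_rejected(self):
        g = np.tile([1.0, 0.0, 0.0], (8, 1))
        with pytest.raises(ValueError, match="collinear|identifiable"):
            GradientScheme(bvals=np.r_[0.0, np.ones(8) * 1000], bvecs=np.vstack([[0, 0, 0], g]))

    def test_missing_b0_rejected(self):
        d = fibonacci_directions(10)
        with pytest.raises(ValueError, match="b=0"):
            GradientScheme(bvals=np.full(10, 1000.0), bvecs=d)


class TestSignalModel:
    @pytest.mark.parametrize(
        "eigenvalues,direction,g,expected",
        [
            ((1e-3, 1e-3, 1e-3), (1, 0, 0), (1, 0, 0), np.exp(-1.0)),
            ((1.7e-3, 0.2e-3, 0.2e-3), (1, 0, 0), (1, 0, 0), np.exp(-1.7)),
            ((1.7e-3, 0.2e-3, 0.2e-3), (1, 0, 0), (0, 1, 0), np.exp(-0.2)),
        ],
    )
    def test_monoexponential_attenuation_closed_form(self, eigenvalues, direction, g, expected):
        t = TissueModel("t", eigenvalues, principal_direction=direction)
        D = t.tensor()
        g = np.asarray(g, dtype=float)
        atten = np.exp(-1000.0 * g @ D @ g)
        assert atten == pytest.approx(expected, rel=1e-12)

    def test_simulated_signal_uses_tissue_s0_and_tensor(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        tissues = _tissues_for_stack(default_spec, "day1", None)
        dwi = simulate_dwi(stack, tissues, default_scheme(), snr=None, seed=0)
        wm = stack.masks["white"].data
        b0 = dwi.data[wm][:, 0]
        assert np.allclose(b0, tissues["white"].s0)

    def test_same_seed_bit_identical(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        tissues = _tissues_for_stack(default_spec, "day1", None)
        a = simulate_dwi(stack, tissues, default_scheme(), snr=30, seed=42)
        b = simulate_dwi(stack, tissues, default_scheme(), snr=30, seed=42)
        assert np.array_equal(a.data, b.data)
        c = simulate_dwi(stack, tissues, default_scheme(), snr=30, seed=43)
        assert not np.array_equal(a.data, c.data)

    def test_invalid_snr_rejected(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        tissues = _tissues_for_stack(default_spec, "day1", None)
        with pytest.raises(ValueError, match="snr"):
            simulate_dwi(stack, tissues, default_scheme(), snr=0.0)

    def test_missing_tissue_model_rejected(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        with pytest.raises(ValueError, match="tissue model"):
            simulate_dwi(stack, {"gray": default_tissues()["gray"]}, default_scheme())


class TestT2:
    def test_noiseless_image_piecewise_constant(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        tissues = _tissues_for_stack(default_spec, "day1", None)
        img = simulate_t2(stack, tissues, noise=False)
        for name, m in stack.masks.items():
            if m.count:
                assert np.all(img[m.data] == tissues[name].t2_intensity_mean)

    def test_seed_reproducibility(self, default_spec):
        stack = build_label_volume(default_spec, "day1")
        tissues = _tissues_for_stack(default_spec, "day1", None)
        assert np.array_equal(
            simulate_t2(stack, tissues, seed=7), simulate_t2(stack, tissues, seed=7)
        )

    def test_planted_lesion_exceeds_threshold_with_normal_tail_probability(self, default_spec):
        # lesion N(130, 5) vs threshold 110 = normal mean + 2 sd: exceedance ~ Phi(4)
        stack = build_label_volume(default_spec, "day1")
        tissues = _tissues_for_stack(default_spec, "day1", None)
        img = simulate_t2(stack, tissues, seed=11)
        lesion = stack.lesion.data
        frac = np.mean(img[lesion] > 110.0)
        assert frac > 0.999

    def test_csf_hyperintense_invariant(self):
        t = default_tissues()
        assert t["csf"].t2_intensity_mean > t["gray"].t2_intensity_mean


class TestCohort:
    def test_enrollment_ledger_reproduces_study_exclusion_arithmetic(self):
        ledger = default_enrollment_ledger()
        assert len(ledger) == 45
        included, report = apply_exclusions(ledger)
        assert len(included) == 35
        assert report["by_reason"] == {"died_24h": 4, "no_deficit": 4, "SAH": 2}

    def test_null_effects_give_equal_group_means(self):
        eff = {g: GroupEffects((2.0, 1.2, 0.8), (10.0, 8.0, 6.0)) for g in
               ("PBS-only", "FBS-hMSCs", "SS-hMSCs")}
        _, _, mnss = simulate_cohort(50, group_effects=eff, seed=2)
        from strokedti.behavior import score_mnss_frame

        scored = score_mnss_frame(mnss)
        wk5 = scored[scored["timepoint"] == "wk5"]
        means = wk5.groupby("group")["mnss_total"].mean()
        assert means.max() - means.min() < 0.8  # sampling noise only at n=50

    def test_planted_ordering_recovered_at_large_n(self):
        _, specs, mnss = simulate_cohort(50, seed=3)
        from strokedti.behavior import score_mnss_frame

        scored = score_mnss_frame(mnss)
        wk5 = scored[scored["timepoint"] == "wk5"]
        means = wk5.groupby("group")["mnss_total"].mean()
        assert means["SS-hMSCs"] < means["FBS-hMSCs"] < means["PBS-only"]
        radii = {a: s.lesion_radius_by_timepoint[-1] for a, s in specs.items()}
        import pandas as pd

        r = pd.Series(radii)
        grp = r.index.str.split("-").str[0]
        rm = r.groupby(grp).mean()
        assert rm["SS"] < rm["FBS"] < rm["PBS"]

    def test_per_animal_specs_are_valid_and_deterministic(self):
        c1, s1, m1 = simulate_cohort(4, seed=9)
        c2, s2, m2 = simulate_cohort(4, seed=9)
        assert c1.equals(c2) and m1.equals(m2)
        assert all(
            s1[a].lesion_radius_by_timepoint == s2[a].lesion_radius_by_timepoint
            for a in s1
        )

    def test_unknown_group_label_rejected(self):
        eff = default_group_effects()
        eff["mystery"] = eff.pop("PBS-only")
        with pytest.raises(ValueError, match="unknown group"):
            simulate_cohort(3, group_effects=eff)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_cohort(1)

    @pytest.mark.parametrize("total", [0, 1, 3, 7, 12, 18, 21])
    def test_mnss_item_allocation_rescores_to_target(self, total):
        rng = np.random.default_rng(total)
        for _ in range(20):
            items = _distribute_mnss_items(total, rng)
            rec = MNSSRecord(subject="x", timepoint="wk5", **items)
            assert score_mnss(rec).total == total
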