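"""Deterministic tracking: stopping rules, geometry, and fiber density."""

import numpy as np
import pytest

from strokedti.grid import Grid, LabelMask
from strokedti.phantom import build_label_volume
from strokedti.tensor import Eigensystem
from strokedti.tracking import StreamlineSet, TrackingParams, fiber_density, track, _interp_fa


def _synthetic_field(shape, voxel_size, fa, evec):
    """Build an Eigensystem directly from an FA volume and a unit-vector field."""
    grid = Grid(shape, voxel_size)
    vals = np.zeros(shape + (3,))
    vals[..., 0] = 1.0
    vecs = np.zeros(shape + (3, 3))
    vecs[..., 0, :] = evec
    return Eigensystem(
        values=vals,
        vectors=vecs,
        fit_ok=np.ones(shape, bool),
        had_negative=np.zeros(shape, bool),
        grid=grid,
    ), grid


def _straight_bundle(shape=(40, 11, 11), voxel_size=(0.5, 0.5, 0.5), fa_in=0.8):
    """x-oriented bundle of high FA through an isotropic background."""
    fa = np.zeros(shape)
    fa[:, 3:8, 3:8] = fa_in
    evec = np.zeros(shape + (3,))
    evec[..., 0] = 1.0
    eigs, grid = _synthetic_field(shape, voxel_size, fa, evec)
    return eigs, fa, grid


class TestTrack:
    def test_straight_bundle_streamlines_span_it_along_x(self):
        eigs, fa, grid = _straight_bundle()
        seeds = np.zeros(grid.shape, bool)
        seeds[18:22, 5, 5] = True
        out = track(eigs, fa, LabelMask(seeds, grid, "seeds"), TrackingParams())
        assert len(out) == 4
        bundle_len = grid.shape[0] * grid.voxel_size[0]
        for sl in out.streamlines:
            # spans the bundle to within one step of each end
            extent = sl[:, 0].max() - sl[:, 0].min()
            assert extent > bundle_len - 3 * 0.25
            d = np.diff(sl, axis=0)
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            mean_dir = d.mean(axis=0)
            mean_dir /= np.linalg.norm(mean_dir)
            angle = np.degrees(np.arccos(np.clip(abs(mean_dir[0]), -1, 1)))
            assert angle < 5.0

    def test_isotropic_subthreshold_seeds_yield_nothing(self):
        eigs, fa, grid = _straight_bundle(fa_in=0.8)
        seeds = np.zeros(grid.shape, bool)
        seeds[5:15, 0:2, 0:2] = True  # FA = 0 region, below the 0.15 stop
        out = track(eigs, fa, LabelMask(seeds, grid, "seeds"), TrackingParams())
        assert len(out) == 0
        assert fiber_density(out) == 0.0

    def test_right_angle_bend_blocks_at_45_degree_rule(self):
        # bundle runs along +x then turns 90 degrees to +y at x index 20
        shape = (40, 40, 5)
        fa = np.zeros(shape)
        fa[:21, 3:8, 1:4] = 0.8      # horizontal arm (y band)
        fa[17:22, 3:40, 1:4] = 0.8   # vertical arm
        evec = np.zeros(shape + (3,))
        evec[:21, :, :, 0] = 1.0
        evec[21:, :, :, :] = 0
        evec[17:22, 8:, :, 0] = 0.0
        evec[17:22, 8:, :, 1] = 1.0
        eigs, grid = _synthetic_field(shape, (0.5, 0.5, 0.5), fa, evec)
        seeds = np.zeros(shape, bool)
        seeds[2:6, 5, 2] = True
        out = track(eigs, fa, LabelMask(seeds, grid, "seeds"),
                    TrackingParams(max_angle_deg=45.0))
        assert len(out) > 0
        for sl in out.streamlines:
            assert sl[:, 1].max() < 8 * 0.5 + 1.0  # nobody rounds the corner

    def test_no_point_below_fa_threshold_audit(self, noiseless_day1):
        labels = noiseless_day1["labels"]
        eigs, maps = noiseless_day1["eigs"], noiseless_day1["maps"]
        seeds = labels.masks["white"]
        p = TrackingParams()
        out = track(eigs, maps.fa, seeds, p)
        assert len(out) > 0
        vsz = np.asarray(labels.grid.voxel_size)
        for sl in out.streamlines[::10]:
            for pt in sl:
                assert _interp_fa(maps.fa, pt / vsz - 0.5) >= p.fa_threshold

    def test_fd_monotone_nonincreasing_in_fa_threshold(self, noiseless_day1):
        labels = noiseless_day1["labels"]
        eigs, maps = noiseless_day1["eigs"], noiseless_day1["maps"]
        seeds = labels.masks["white"]
        fds = [
            fiber_density(track(eigs, maps.fa, seeds, TrackingParams(fa_threshold=t)))
            for t in (0.10, 0.15, 0.30, 0.60, 0.85)
        ]
        assert all(a >= b for a, b in zip(fds, fds[1:]))

    def test_mirror_symmetric_phantom_gives_rfd_exactly_one(self, noiseless_symmetric):
        from strokedti.roi import mirror_roi

        labels = noiseless_symmetric["labels"]
        eigs, maps = noiseless_symmetric["eigs"], noiseless_symmetric["maps"]
        ipsi = LabelMask(
            labels.masks["white"].data & labels.hemisphere("right").data,
            labels.grid, "bundle_ipsi",
        )
        contra = mirror_roi(ipsi)
        fd_i = fiber_density(track(eigs, maps.fa, ipsi, TrackingParams()))
        fd_c = fiber_density(track(eigs, maps.fa, contra, TrackingParams()))
        assert fd_i > 0
        assert fd_i == fd_c  # exact: geometry and field are exact mirrors

    def test_empty_seed_mask_rejected(self, noiseless_day1):
        labels = noiseless_day1["labels"]
        empty = LabelMask(np.zeros(labels.grid.shape, bool), labels.grid, "empty")
        with pytest.raises(ValueError, match="empty seed"):
            track(noiseless_day1["eigs"], noiseless_day1["maps"].fa, empty)

    def test_misaligned_grids_rejected(self, noiseless_day1):
        other = Grid((8, 8, 8), (1.0, 1.0, 1.0))
        seeds = LabelMask(np.ones((8, 8, 8), bool), other, "seeds")
        with pytest.raises(ValueError, match="grid"):
            track(noiseless_day1["eigs"], noiseless_day1["maps"].fa, seeds)

    def test_seeds_per_voxel_jitter_is_seeded(self):
        eigs, fa, grid = _straight_bundle()
        seeds = np.zeros(grid.shape, bool)
        seeds[19:21, 5, 5] = True
        p = TrackingParams(seeds_per_voxel=3, seed=5)
        a = track(eigs, fa, LabelMask(seeds, grid), p)
        b = track(eigs, fa, LabelMask(seeds, grid), p)
        assert len(a) == len(b)
        assert all(np.array_equal(x, y) for x, y in zip(a.streamlines, b.streamlines))


class TestFiberDensity:
    def _set(self, n_streamlines, n_seed_voxels):
        grid = Grid((4, 4, 4), (1.0, 1.0, 1.0))
        sl = [np.array([[0.0, 0, 0], [1.0, 0, 0]])] * n_streamlines
        return StreamlineSet(sl, [(0, 0, 0)] * n_streamlines, n_seed_voxels, grid)

    def test_one_streamline_per_seed(self):
        assert fiber_density(self._set(100, 100)) == 1.0

    def test_no_streamlines(self):
        assert fiber_density(self._set(0, 100)) == 0.0

    def test_zero_seed_voxels_rejected(self):
        with pytest.raises(ValueError, match="zero seed"):
            fiber_density(self._set(1, 0))

    def test_pipeline_fd_equals_manual_count(self, noiseless_day1):
        labels = noiseless_day1["labels"]
        seeds = labels.masks["white"]
        out = track(noiseless_day1["eigs"], noiseless_day1["maps"].fa, seeds)
        assert fiber_density(out) == len(out.streamlines) / seeds.count


class TestParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(fa_threshold=0.0), dict(fa_threshold=1.0),
                   dict(max_angle_deg=0.0), dict(max_angle_deg=95.0),
                   dict(step_size=-1.0), dict(seeds_per_voxel=0)]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrackingParams(**kwargs)

    def test_defaults_resolve_from_voxel_size(self):
        p = TrackingParams().resolved((0.156, 0.156, 0.75))
        assert p.step_size == pytest.approx(0.078)
        assert p.min_length == pytest.approx(0.312)
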