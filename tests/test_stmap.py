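"""Spatiotemporal volumes: projection, interpolation, smoothing, inference."""

import warnings

import numpy as np
import pytest
from scipy import stats

from scalpmap import stmap
from scalpmap.stmap import ContrastSpec, PermScheme, StVolume


def _volume(data, mask, time=None):
    if time is None:
        time = -100.0 + 5.0 * np.arange(data.shape[2])
    return StVolume(data=data, time=time, mask=mask)


def _noise_volumes(grid, rng, n=8, effect=None, smooth=True):
    """Subject volumes: smoothed white noise (+ optional fixed effect)."""
    out = []
    for _ in range(n):
        data = rng.normal(size=(32, 32, 101))
        if effect is not None:
            data += effect
        vol = _volume(data * grid.mask[:, :, None], grid.mask)
        if smooth:
            vol = stmap.smooth_volume(vol)
        out.append(vol)
    return out


class TestProjection:
    def test_vertex_maps_to_grid_centre(self, montage, grid):
        cz = grid.electrode_xy[grid.channels.index("Cz")]
        assert abs(cz[0] - 15.5) <= 1.0 and abs(cz[1] - 15.5) <= 1.0

    def test_left_right_mirror_symmetry(self, grid):
        for left, right in [("C3", "C4"), ("F3", "F4"), ("P7", "P8"), ("O1", "O2")]:
            xl = grid.electrode_xy[grid.channels.index(left)]
            xr = grid.electrode_xy[grid.channels.index(right)]
            assert abs((xl[0] - 15.5) + (xr[0] - 15.5)) <= 1.0  # mirrored in x
            assert abs(xl[1] - xr[1]) <= 1.0

    def test_all_electrodes_inside_mask(self, grid):
        for x, y in grid.electrode_xy:
            assert grid.mask[int(round(x)), int(round(y))]
        assert grid.mask.sum() < 32 * 32  # mask is a proper subset

    def test_mask_connected(self, grid):
        from scipy import ndimage

        _, n = ndimage.label(grid.mask)
        assert n == 1


class TestInterpolation:
    def test_constant_field(self, grid):
        frame = stmap.interpolate_scalp_frame(np.full(64, 5.0), grid)
        assert np.allclose(frame[grid.mask], 5.0)
        assert np.all(frame[~grid.mask] == 0.0)

    def test_linear_field_reproduced(self, grid):
        """Barycentric interpolation is exact for affine functions of the
        projected coordinates, so pixel values equal the plane directly."""
        a, b, c = 0.3, -0.7, 2.0
        vals = a * grid.electrode_xy[:, 0] + b * grid.electrode_xy[:, 1] + c
        frame = stmap.interpolate_scalp_frame(vals, grid)
        gx, gy = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
        expected = a * gx + b * gy + c
        hull = grid.triangulation.find_simplex(
            np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
        ).reshape(32, 32) >= 0
        assert np.allclose(frame[hull], expected[hull], atol=1e-9)

    def test_single_channel_peak_near_electrode(self, grid):
        idx = grid.channels.index("FCz")
        vals = np.zeros(64)
        vals[idx] = 1.0
        frame = stmap.interpolate_scalp_frame(vals, grid)
        px, py = np.unravel_index(np.argmax(frame), frame.shape)
        ex, ey = grid.electrode_xy[idx]
        assert np.hypot(px - ex, py - ey) <= 1.5

    def test_missing_value_rejected(self, grid):
        vals = np.full(64, 1.0)
        vals[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            stmap.interpolate_scalp_frame(vals, grid)


class TestBuildVolume:
    def _erp(self, montage, rng):
        from scalpmap.erpstats import Erp

        return Erp(data=rng.normal(size=(64, 101)), time=-100.0 + 5.0 * np.arange(101),
                   channels=list(montage.labels), fs=200.0, condition="x", n_trials=10)

    def test_dimensions_and_time_axis(self, montage, grid, rng):
        vol = stmap.build_volume(self._erp(montage, rng), grid)
        assert vol.data.shape == (32, 32, 101)
        assert np.allclose(np.diff(vol.time), 5.0)
        assert np.all(np.diff(vol.time) > 0)

    def test_frames_match_per_bin_interpolation(self, montage, grid, rng):
        erp = self._erp(montage, rng)
        vol = stmap.build_volume(erp, grid)
        for k in (0, 37, 100):
            assert np.allclose(vol.data[:, :, k],
                               stmap.interpolate_scalp_frame(erp.data[:, k], grid))

    def test_wrong_rate_rejected(self, montage, grid, rng):
        erp = self._erp(montage, rng)
        erp.fs = 1024.0
        with pytest.raises(ValueError, match="Hz"):
            stmap.build_volume(erp, grid)


class TestSmoothing:
    def test_constant_preserved(self, grid):
        vol = _volume(np.full((32, 32, 101), 3.3) * grid.mask[:, :, None], grid.mask)
        out = stmap.smooth_volume(vol)
        assert np.allclose(out.data[grid.mask], 3.3, atol=1e-9)

    def test_impulse_mass_preserved(self, grid):
        data = np.zeros((32, 32, 101))
        data[16, 16, 50] = 1.0
        out = stmap.smooth_volume(_volume(data, grid.mask))
        # away from mask edges the renormalised kernel integrates to ~1
        assert out.data.sum() == pytest.approx(1.0, abs=0.05)

    def test_matches_brute_force_convolution(self, rng):
        """Independent oracle: dense separable Gaussian convolution with the
        same sigmas and truncation on a small fully-unmasked volume."""
        shape = (8, 8, 9)
        data = rng.normal(size=shape)
        mask = np.ones(shape[:2], dtype=bool)
        fwhm = (8.0, 8.0, 20.0)
        out = stmap.smooth_volume(_volume(data, mask, time=np.arange(9.0)), fwhm)

        factor = 2 * np.sqrt(2 * np.log(2))
        sigmas = (fwhm[0] / stmap.MM_PER_PIXEL / factor,
                  fwhm[1] / stmap.MM_PER_PIXEL / factor,
                  fwhm[2] / stmap.TIME_BIN_MS / factor)

        def kernel(sigma):
            r = int(4 * sigma + 0.5)
            x = np.arange(-r, r + 1)
            k = np.exp(-0.5 * (x / sigma) ** 2)
            return k / k.sum()

        def conv_axis(arr, k, axis):
            pad = len(k) // 2
            arr = np.moveaxis(arr, axis, 0)
            padded = np.concatenate(
                [np.zeros((pad, *arr.shape[1:])), arr, np.zeros((pad, *arr.shape[1:]))]
            )
            res = np.zeros_like(arr)
            for i in range(arr.shape[0]):
                res[i] = np.tensordot(k, padded[i : i + len(k)], axes=(0, 0))
            return np.moveaxis(res, 0, axis)

        num = data.copy()
        den = np.ones(shape)
        for ax, s in enumerate(sigmas):
            k = kernel(s)
            num = conv_axis(num, k, ax)
            den = conv_axis(den, k, ax)
        assert np.allclose(out.data, num / den, atol=1e-9)

    def test_linearity_of_volume_pipeline(self, montage, grid, rng):
        from scalpmap.erpstats import Erp

        def pipe(chan_data):
            erp = Erp(data=chan_data, time=-100.0 + 5.0 * np.arange(101),
                      channels=list(montage.labels), fs=200.0, condition="x", n_trials=1)
            return stmap.smooth_volume(stmap.build_volume(erp, grid)).data

        x, y = rng.normal(size=(64, 101)), rng.normal(size=(64, 101))
        lhs = pipe(2.0 * x - 0.5 * y)
        rhs = 2.0 * pipe(x) - 0.5 * pipe(y)
        assert np.allclose(lhs, rhs, atol=1e-9)


class TestContrastsAndGroupMap:
    def _cells(self, grid, values):
        names = ["odd_narrow", "odd_broad", "mean_narrow", "mean_broad"]
        return {
            n: _volume(np.full((32, 32, 101), v) * grid.mask[:, :, None], grid.mask)
            for n, v in zip(names, values)
        }

    def test_hand_computed_contrasts(self, grid):
        cells = self._cells(grid, [4.0, 2.0, 1.0, 1.0])
        surprise = ContrastSpec("surprise", {"odd_narrow": 0.5, "odd_broad": 0.5,
                                             "mean_narrow": -0.5, "mean_broad": -0.5})
        inter = ContrastSpec("sxv", {"odd_narrow": 1.0, "odd_broad": -1.0,
                                     "mean_narrow": -1.0, "mean_broad": 1.0})
        s = stmap.subject_contrast(cells, surprise)
        i = stmap.subject_contrast(cells, inter)
        assert np.allclose(s.data[grid.mask], 2.0)
        assert np.allclose(i.data[grid.mask], 2.0)

    def test_interaction_of_equal_volumes_is_zero(self, grid):
        cells = self._cells(grid, [2.0, 2.0, 2.0, 2.0])
        inter = ContrastSpec("sxv", {"odd_narrow": 1.0, "odd_broad": -1.0,
                                     "mean_narrow": -1.0, "mean_broad": 1.0})
        assert np.allclose(stmap.subject_contrast(cells, inter).data, 0.0)

    def test_missing_condition_rejected(self, grid):
        cells = self._cells(grid, [1.0, 1.0, 1.0, 1.0])
        del cells["odd_broad"]
        with pytest.raises(ValueError, match="missing"):
            stmap.subject_contrast(
                cells, ContrastSpec("s", {"odd_narrow": 1.0, "odd_broad": -1.0})
            )

    def test_group_t_closed_form(self, grid, rng):
        vols = _noise_volumes(grid, rng, n=7, smooth=False)
        tmap = stmap.group_t_map(vols)
        stack = np.stack([v.data for v in vols])
        with np.errstate(invalid="ignore", divide="ignore"):
            expected = stack.mean(0) / (stack.std(0, ddof=1) / np.sqrt(7))
        assert tmap.df == 6
        assert np.allclose(tmap.data[grid.mask], expected[grid.mask], atol=1e-10)

    def test_two_subject_antisymmetric_t_zero(self, grid):
        a = _volume(np.ones((32, 32, 101)), grid.mask)
        b = _volume(-np.ones((32, 32, 101)), grid.mask)
        tmap = stmap.group_t_map([a, b])
        assert np.allclose(tmap.data[grid.mask], 0.0)

    def test_zero_variance_sentinel(self, grid):
        vols = [_volume(np.ones((32, 32, 101)), grid.mask) for _ in range(4)]
        with pytest.warns(UserWarning, match="zero-variance"):
            tmap = stmap.group_t_map(vols)
        assert np.all(np.isinf(tmap.data[grid.mask]))
        assert tmap.degenerate[grid.mask].all()


class TestPermutationFwe:
    def test_planted_effect_detected_and_localised(self, grid, rng):
        effect = np.zeros((32, 32, 101))
        ex, ey, et = 16, 18, 45  # pixel (16,18), bin 45 -> 125 ms
        gx, gy, gt = np.meshgrid(np.arange(32), np.arange(32), np.arange(101),
                                 indexing="ij")
        effect = 2.0 * np.exp(-((gx - ex) ** 2 + (gy - ey) ** 2) / 8.0
                              - (gt - et) ** 2 / 18.0)
        vols = _noise_volumes(grid, rng, n=10, effect=effect)
        tmap, table = stmap.permutation_fwe(vols, PermScheme(400, seed=2))
        assert len(table) >= 1
        top = table.iloc[0]
        assert top.p_fwe_cluster < 0.05
        assert abs(top.peak_x - ex) <= 2 and abs(top.peak_y - ey) <= 2
        assert abs(top.peak_time_ms - 125.0) <= 10.0

    def test_low_permutation_count_warns_and_quantises_p(self, grid, rng):
        effect = np.zeros((32, 32, 101))
        effect[16, 16, 50] = 5.0
        vols = _noise_volumes(grid, rng, n=8, effect=effect, smooth=False)
        with pytest.warns(UserWarning, match="granularity"):
            scheme = PermScheme(10, seed=0)
        _, table = stmap.permutation_fwe(vols, scheme)
        if len(table):
            ps = np.concatenate([table.p_fwe_peak, table.p_fwe_cluster])
            assert np.allclose(np.round(ps * 11), ps * 11)

    def test_permutations_capped_at_unique_flips(self, grid, rng):
        vols = _noise_volumes(grid, rng, n=6, smooth=False)
        with pytest.warns(UserWarning, match="unique sign flips"):
            stmap.permutation_fwe(vols, PermScheme(500, seed=0))

    def test_too_few_subjects_rejected(self, grid, rng):
        vols = _noise_volumes(grid, rng, n=4, smooth=False)
        with pytest.raises(ValueError, match=">= 6"):
            stmap.permutation_fwe(vols, PermScheme(100, seed=0))


class TestSmallVolumeCorrection:
    def _planted(self, grid, rng, n=9):
        gx, gy, gt = np.meshgrid(np.arange(32), np.arange(32), np.arange(101),
                                 indexing="ij")
        effect = 1.2 * np.exp(-((gx - 16) ** 2 + (gy - 18) ** 2) / 8.0
                              - (gt - 45) ** 2 / 18.0)
        return _noise_volumes(grid, rng, n=n, effect=effect)

    def test_whole_volume_mask_reduces_to_fwe(self, grid, rng):
        vols = self._planted(grid, rng)
        scheme = PermScheme(200, seed=3)
        mask3 = grid.mask[:, :, None] & np.ones(101, dtype=bool)
        _, whole = stmap.permutation_fwe(vols, scheme)
        svc = stmap.small_volume_correct(vols, scheme, mask3)
        assert np.allclose(svc.p_fwe_peak.values, whole.p_fwe_peak.values)

    def test_svc_p_not_larger_than_whole_volume(self, grid, rng):
        vols = self._planted(grid, rng)
        scheme = PermScheme(200, seed=3)
        _, whole = stmap.permutation_fwe(vols, scheme)
        small = np.zeros((32, 32, 101), dtype=bool)
        small[10:23, 12:25, 30:60] = True
        small &= grid.mask[:, :, None]
        svc = stmap.small_volume_correct(vols, scheme, small)
        assert len(svc) >= 1
        assert svc.p_fwe_peak.min() <= whole.p_fwe_peak.min() + 1e-12

    def test_orthogonality_audit_refuses_biased_mask(self, grid, rng):
        vols = self._planted(grid, rng)
        conditions = ["odd_narrow", "odd_broad", "mean_narrow", "mean_broad"]
        surprise = ContrastSpec("surprise", {"odd_narrow": 0.5, "odd_broad": 0.5,
                                             "mean_narrow": -0.5, "mean_broad": -0.5})
        same = ContrastSpec("surprise_again", dict(surprise.weights))
        mask3 = grid.mask[:, :, None] & np.ones(101, dtype=bool)
        with pytest.raises(ValueError, match="orthogonal"):
            stmap.small_volume_correct(vols, PermScheme(100, seed=0), mask3,
                                       tested=same, mask_source=surprise,
                                       conditions=conditions)

    def test_empty_mask_rejected(self, grid, rng):
        vols = self._planted(grid, rng)
        with pytest.raises(ValueError, match="empty"):
            stmap.small_volume_correct(
                vols, PermScheme(100, seed=0), np.zeros((32, 32, 101), dtype=bool)
            )


class TestNiftiRoundTrip:
    def test_volume_round_trip(self, grid, rng, tmp_path):
        vol = _volume(rng.normal(size=(32, 32, 101)) * grid.mask[:, :, None], grid.mask)
        vol.condition = "surprise"
        path = tmp_path / "vol.nii"
        stmap.write_volume_nifti(vol, path)
        back = stmap.read_volume_nifti(path, mask=grid.mask)
        assert np.allclose(back.data, vol.data)
        assert np.allclose(back.time, vol.time)
        assert back.condition == "surprise"
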