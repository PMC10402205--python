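"""ULM workflow: motion gating, SVD filter, slow-time filtering,
localization, tracking, rendering."""

import numpy as np
import pytest

from paulm.beamform import Volume, VoxelGrid
from paulm.errors import ArgumentError, PipelineError
from paulm.ulm import (IQSeries, Localization, directional_split,
                       localize_radial_symmetry, power_doppler, reject_motion,
                       render_maps, svd_filter, temporal_bandpass,
                       track_bubbles)

FR = 215.0


def _series(data, spacing=0.06, frame_rate=FR):
    grid = VoxelGrid.centered(data.shape[1:], spacing)
    return IQSeries(data=np.asarray(data), grid=grid, frame_rate=frame_rate,
                    fc=4e6, c=1540.0)


def _gaussian_blob(shape, center, sigma=1.5):
    idx = np.indices(shape).astype(float)
    r2 = sum((idx[k] - center[k]) ** 2 for k in range(3))
    return np.exp(-r2 / (2 * sigma**2))


def _clutter_bubble_series(n_frames=40, shape=(12, 12, 12)):
    """Rank-1 static clutter plus one bubble sweeping across the volume."""
    rng = np.random.default_rng(0)
    clutter = 10.0 * rng.standard_normal(shape) * np.exp(
        2j * np.pi * rng.random(shape))
    frames = np.empty((n_frames,) + shape, dtype=complex)
    path = []
    for k in range(n_frames):
        c = (2.0 + 8.0 * k / (n_frames - 1), 6.0, 6.0)
        path.append(c)
        frames[k] = clutter + _gaussian_blob(shape, c)
    return frames, clutter, path


class TestRejectMotion:
    def test_identical_frames_all_kept(self):
        frames = np.tile(_gaussian_blob((8, 8, 8), (4, 4, 4)), (10, 1, 1, 1))
        kept = reject_motion(_series(frames.astype(complex)), 0.99)
        assert kept.all()

    def test_shifted_outlier_frames_dropped_exactly(self):
        base = _gaussian_blob((20, 20, 8), (10, 10, 4), sigma=1.2)
        frames = np.tile(base, (100, 1, 1, 1)).astype(complex)
        bad = [3, 17, 25, 38, 42, 55, 61, 70, 84, 99]
        for b in bad:
            frames[b] = np.roll(base, 10, axis=0)
        kept = reject_motion(_series(frames), threshold=0.99)
        assert sorted(np.where(~kept)[0]) == bad

    def test_zero_threshold_keeps_everything(self):
        rng = np.random.default_rng(0)
        frames = rng.standard_normal((6, 8, 8, 8)) + 0j
        assert reject_motion(_series(frames), 0.0).all()

    def test_everything_rejected_raises(self):
        rng = np.random.default_rng(0)
        frames = rng.standard_normal((8, 8, 8, 8)) + 0j
        with pytest.raises(PipelineError):
            reject_motion(_series(frames), threshold=1.1)


class TestSVDFilter:
    def test_zero_removal_is_identity(self):
        rng = np.random.default_rng(0)
        frames = rng.standard_normal((10, 6, 6, 6)) \
            + 1j * rng.standard_normal((10, 6, 6, 6))
        out = svd_filter(_series(frames), block_size=10, n_remove=0)
        assert np.allclose(out.data, frames, atol=1e-9)

    def test_removal_count_must_fit_block(self):
        frames = np.zeros((10, 4, 4, 4), dtype=complex)
        with pytest.raises(ArgumentError):
            svd_filter(_series(frames), block_size=10, n_remove=10)

    def test_clutter_suppressed_bubble_preserved(self):
        frames, clutter, path = _clutter_bubble_series()
        out = svd_filter(_series(frames), block_size=40, n_remove=1)
        clutter_mask = np.abs(clutter) > np.percentile(np.abs(clutter), 80)
        in_energy = (np.abs(frames[:, clutter_mask]) ** 2).sum()
        out_energy = (np.abs(out.data[:, clutter_mask]) ** 2).sum()
        assert out_energy <= 0.01 * in_energy
        # bubble peak at its voxel survives
        k = 20
        c = tuple(int(round(x)) for x in path[k])
        assert np.abs(out.data[k][c]) >= 0.5

    def test_energy_never_grows(self):
        rng = np.random.default_rng(2)
        frames = rng.standard_normal((12, 5, 5, 5)) + 0j
        s = _series(frames)
        for nr in (0, 1, 3):
            out = svd_filter(s, block_size=12, n_remove=nr)
            assert (np.abs(out.data) ** 2).sum() <= (np.abs(frames) ** 2).sum() \
                + 1e-9
            if nr > 0:
                assert (np.abs(out.data) ** 2).sum() \
                    < (np.abs(frames) ** 2).sum()

    def test_partial_final_block_scales_cutoff(self):
        # 15 frames with block 10: final block of 5 removes floor(2*5/10)=1
        rng = np.random.default_rng(3)
        frames = rng.standard_normal((15, 4, 4, 4)) + 0j
        out = svd_filter(_series(frames), block_size=10, n_remove=2)
        assert out.data.shape == frames.shape


class TestTemporalBandpass:
    def test_dc_removed(self):
        frames = np.full((64, 4, 4, 4), 2.0 + 1j)
        out = temporal_bandpass(_series(frames), (20.0, 107.0))
        assert (np.abs(out.data) ** 2).sum() <= 1e-6 * (np.abs(frames) ** 2).sum()

    @pytest.mark.parametrize("freq,check", [(50.0, "pass"), (5.0, "stop")])
    def test_band_edges(self, freq, check):
        t = np.arange(256) / FR
        tone = np.exp(2j * np.pi * freq * t)
        frames = tone[:, None, None, None] * np.ones((1, 3, 3, 3))
        out = temporal_bandpass(_series(frames), (20.0, 107.0))
        mid = slice(64, 192)
        gain = (np.abs(out.data[mid, 1, 1, 1]).mean()
                / np.abs(frames[mid, 1, 1, 1]).mean())
        if check == "pass":
            assert gain == pytest.approx(1.0, abs=0.05)
        else:
            assert gain < 0.1  # >= 20 dB attenuation

    def test_invalid_band_rejected(self):
        frames = np.zeros((16, 3, 3, 3), dtype=complex)
        with pytest.raises(ArgumentError):
            temporal_bandpass(_series(frames), (50.0, 20.0))
        with pytest.raises(ArgumentError):
            temporal_bandpass(_series(frames), (20.0, 200.0))


def _translating_series(v_sign, n_frames=64, nz=48):
    """Baseband field of a blob translating along z with the phase signature
    of pulse-echo imaging: g(z - z_s) * exp(-i k0 z_s)."""
    spacing = 0.06
    k0 = 4 * np.pi * 4e6 / (1540.0 * 1e3)  # rad/mm two-way
    z = (np.arange(nz) - nz / 2) * spacing
    frames = np.empty((n_frames, 3, 3, nz), dtype=complex)
    for k in range(n_frames):
        zs = v_sign * (-0.8 + 1.6 * k / (n_frames - 1))
        g = np.exp(-((z - zs) ** 2) / (2 * 0.12**2))
        frames[k] = (g * np.exp(-1j * k0 * zs))[None, None, :]
    return _series(frames, spacing=spacing)


class TestDirectionalSplit:
    def test_up_down_sum_to_input(self):
        rng = np.random.default_rng(0)
        frames = rng.standard_normal((16, 4, 4, 16)) \
            + 1j * rng.standard_normal((16, 4, 4, 16))
        s = _series(frames)
        up, down = directional_split(s)
        assert np.allclose(up.data + down.data, frames, atol=1e-9)

    def test_static_pattern_splits_evenly(self):
        rng = np.random.default_rng(1)
        pattern = rng.standard_normal((4, 4, 16)) \
            + 1j * rng.standard_normal((4, 4, 16))
        frames = np.tile(pattern, (16, 1, 1, 1))
        up, down = directional_split(_series(frames))
        eu = (np.abs(up.data) ** 2).sum()
        ed = (np.abs(down.data) ** 2).sum()
        assert abs(eu - ed) / (eu + ed) < 0.05

    def test_moving_target_concentrates_in_matching_channel(self):
        up, down = directional_split(_translating_series(+1))
        eu = (np.abs(up.data) ** 2).sum()
        ed = (np.abs(down.data) ** 2).sum()
        assert eu / (eu + ed) >= 0.80

    def test_reversing_motion_swaps_channels(self):
        s = _translating_series(+1)
        rev = _series(s.data[::-1].copy())  # time reversal flips the motion
        up1, down1 = directional_split(s)
        up2, down2 = directional_split(rev)
        e = lambda x: (np.abs(x.data) ** 2).sum()
        assert e(up1) == pytest.approx(e(down2), rel=0.01)
        assert e(down1) == pytest.approx(e(up2), rel=0.01)


class TestPowerDoppler:
    def test_constant_amplitude(self):
        frames = np.full((7, 3, 3, 3), 2.0 - 1.0j)
        pd = power_doppler(_series(frames))
        assert np.allclose(pd.data, 5.0)

    def test_zero_input(self):
        pd = power_doppler(_series(np.zeros((3, 2, 2, 2), dtype=complex)))
        assert np.all(pd.data == 0)

    def test_svd_filtering_empties_clutter_pd(self):
        frames, clutter, _ = _clutter_bubble_series()
        s = _series(frames)
        pd_raw = power_doppler(s)
        pd_filt = power_doppler(svd_filter(s, block_size=40, n_remove=1))
        mask = np.abs(clutter) > np.percentile(np.abs(clutter), 80)
        assert pd_filt.data[mask].sum() <= 0.01 * pd_raw.data[mask].sum()


class TestLocalization:
    def _volume(self, data, spacing=0.06):
        grid = VoxelGrid.centered(data.shape, spacing)
        return Volume(grid=grid, data=data, kind="pd")

    def test_on_grid_blob_recovered_exactly(self):
        vol = self._volume(_gaussian_blob((15, 15, 15), (7, 7, 7)))
        locs = localize_radial_symmetry(vol, detect_threshold=0.5, window=5)
        assert len(locs) == 1
        err = np.abs(vol.grid.world_to_voxel(locs[0].position) - 7)
        assert err.max() < 1e-6

    def test_off_grid_blob_recovered_subvoxel(self):
        center = (7.3, 6.8, 7.4)
        vol = self._volume(_gaussian_blob((15, 15, 15), center))
        locs = localize_radial_symmetry(vol, detect_threshold=0.5, window=5)
        err = np.abs(vol.grid.world_to_voxel(locs[0].position) - center)
        assert err.max() < 0.1

    def test_two_blobs_separated(self):
        data = (_gaussian_blob((20, 12, 12), (6, 6, 6))
                + _gaussian_blob((20, 12, 12), (12, 6, 6)))
        vol = self._volume(data)
        locs = localize_radial_symmetry(vol, detect_threshold=0.5, window=5)
        assert len(locs) == 2
        got = sorted(vol.grid.world_to_voxel(l.position)[0] for l in locs)
        assert abs(got[0] - 6) < 0.15 and abs(got[1] - 12) < 0.15

    def test_flat_volume_yields_nothing(self):
        vol = self._volume(np.ones((9, 9, 9)))
        assert localize_radial_symmetry(vol, detect_threshold=0.5) == []

    def test_window_validation(self):
        vol = self._volume(_gaussian_blob((9, 9, 9), (4, 4, 4)))
        with pytest.raises(ArgumentError):
            localize_radial_symmetry(vol, window=4)


def _constant_velocity_locs(speed=5.0, n_frames=50, frame_rate=FR,
                            start=(-1.0, 0.0, 0.0), direction=(1.0, 0, 0)):
    step = speed / frame_rate
    d = np.asarray(direction) / np.linalg.norm(direction)
    out = []
    for k in range(n_frames):
        p = np.asarray(start) + k * step * d
        out.append([Localization(position=p, frame_index=k, intensity=1.0)])
    return out


class TestTracking:
    def test_constant_velocity_speed_recovered(self):
        per_frame = _constant_velocity_locs()
        ts = track_bubbles(per_frame, FR, max_link=0.05, min_length=5)
        assert ts.n_tracks == 1
        assert ts.tracks[0].mean_speed == pytest.approx(5.0, rel=0.01)

    def test_parallel_bubbles_no_identity_swaps(self):
        step = 5.0 / FR
        per_frame = []
        for k in range(30):
            per_frame.append([
                Localization(position=np.array([k * step, 0.0, 0.0]),
                             frame_index=k, intensity=1.0),
                Localization(position=np.array([k * step, 3 * step, 0.0]),
                             frame_index=k, intensity=1.0),
            ])
        ts = track_bubbles(per_frame, FR, max_link=2 * step, min_length=5)
        assert ts.n_tracks == 2
        for tr in ts.tracks:
            ys = tr.positions[:, 1]
            assert np.ptp(ys) < 1e-12  # each track stays in its own lane

    def test_gap_closing(self):
        per_frame = _constant_velocity_locs(n_frames=40)
        per_frame[20] = []  # one dropped detection
        ts = track_bubbles(per_frame, FR, max_link=0.05, max_gap=2,
                           min_length=5)
        assert ts.n_tracks == 1
        assert ts.tracks[0].n_points == 39

    def test_empty_frames_empty_trackset(self):
        ts = track_bubbles([[], [], []], FR, max_link=0.1)
        assert ts.n_tracks == 0

    def test_invalid_max_link(self):
        with pytest.raises(ArgumentError):
            track_bubbles([[]], FR, max_link=0.0)


class TestRenderMaps:
    def test_straight_track_density_hugs_the_line(self):
        grid = VoxelGrid.centered((21, 11, 11), 0.1)
        per_frame = _constant_velocity_locs(speed=5.0, n_frames=60,
                                            start=(-0.7, 0.013, -0.008))
        ts = track_bubbles(per_frame, FR, max_link=0.05, min_length=5)
        density, _ = render_maps(ts, grid, upsample=4)
        pts = np.argwhere(density.data > 0)
        world = density.grid.voxel_to_world(pts)
        # distance to the true line y=0.013, z=-0.008
        d = np.sqrt((world[:, 1] - 0.013) ** 2 + (world[:, 2] + 0.008) ** 2)
        assert d.max() <= np.max(density.grid.spacing) * 1.001

    def test_constant_speed_velocity_map(self):
        grid = VoxelGrid.centered((21, 11, 11), 0.1)
        per_frame = _constant_velocity_locs(speed=5.0, n_frames=60,
                                            start=(-0.7, 0.0, 0.0))
        ts = track_bubbles(per_frame, FR, max_link=0.05, min_length=5)
        _, velocity = render_maps(ts, grid, upsample=4)
        support = np.isfinite(velocity.data)
        assert support.any()
        assert np.allclose(velocity.data[support], 5.0, rtol=0.01)

    def test_undefined_voxels_flagged(self):
        grid = VoxelGrid.centered((5, 5, 5), 0.1)
        ts = track_bubbles([[], []], FR, max_link=0.1)
        density, velocity = render_maps(ts, grid, upsample=2)
        assert np.all(density.data == 0)
        assert np.all(np.isnan(velocity.data))

    def test_upsample_validation(self):
        grid = VoxelGrid.centered((5, 5, 5), 0.1)
        ts = track_bubbles([[]], FR, max_link=0.1)
        with pytest.raises(ArgumentError):
            render_maps(ts, grid, upsample=0)
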