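"""Ultrasound localization microscopy on beamformed IQ volume series.

The workflow follows four steps: (1) spatio-temporal SVD clutter
filtering on the Casorati (voxels x frames) matrix, (2) slow-time
band-pass and directional filtering plus power-Doppler integration,
(3) radial-symmetry sub-voxel microbubble localization, and (4) optimal
frame-to-frame assignment tracking with density / velocity map rendering
on a super-resolved grid.  Breathing-type motion is rejected beforehand by
correlating lateral maximum-intensity projections against their mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
from scipy import ndimage, signal
from scipy.optimize import linear_sum_assignment

from .beamform import Volume, VoxelGrid
from .errors import ArgumentError, PipelineError

MM_PER_M = 1e3


@dataclass
class IQSeries:
    """Slow-time stack of complex IQ volumes on a single grid.

    data: (n_frames, nx, ny, nz) complex; frame_rate in Hz; ``fc`` and ``c``
    describe the carrier for direction-sensitive processing; ``kept`` is the
    motion-gating mask (length n_frames).
    """

    data: np.ndarray
    grid: VoxelGrid
    frame_rate: float
    fc: float = 4e6
    c: float = 1540.0
    kept: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ArgumentError("IQSeries data must be (frames, nx, ny, nz)")
        if self.frame_rate <= 0:
            raise ArgumentError("frame_rate must be > 0")
        if self.kept is None:
            self.kept = np.ones(self.data.shape[0], dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def compact(self) -> "IQSeries":
        """Drop rejected frames (the kept mask of the result is all-true)."""
        return IQSeries(data=self.data[self.kept], grid=self.grid,
                        frame_rate=self.frame_rate, fc=self.fc, c=self.c)

    def frame_volume(self, i: int, kind: str = "bmode_iq") -> Volume:
        return Volume(grid=self.grid, data=self.data[i], kind=kind,
                      meta={"fc": self.fc, "c": self.c})


@dataclass
class Localization:
    """One sub-voxel microbubble position (mm) in one slow-time frame."""

    position: np.ndarray
    frame_index: int
    intensity: float
    direction_channel: str = "none"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class Track:
    """A linked microbubble trajectory with per-step velocity vectors."""

    localizations: List[Localization]
    velocities: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    @property
    def n_points(self) -> int:
        return len(self.localizations)

    @property
    def positions(self) -> np.ndarray:
        return np.array([l.position for l in self.localizations])

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([l.frame_index for l in self.localizations])

    @property
    def mean_speed(self) -> float:
        if len(self.velocities) == 0:
            return 0.0
        return float(np.mean(np.linalg.norm(self.velocities, axis=1)))


@dataclass
class TrackSet:
    tracks: List[Track] = field(default_factory=list)
    frame_rate: float = 1.0

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    def all_speeds(self) -> np.ndarray:
        out = [np.linalg.norm(t.velocities, axis=1) for t in self.tracks
               if len(t.velocities)]
        return np.concatenate(out) if out else np.zeros(0)


# ---------------------------------------------------------------------------
# motion gating
# ---------------------------------------------------------------------------


def reject_motion(series: IQSeries, threshold: float = 0.99) -> np.ndarray:
    """Flag frames whose lateral MIP decorrelates from the mean-MIP reference.

    Returns the kept mask; the data are untouched.  Correlation is the
    Pearson coefficient between each frame's maximum-intensity projection
    along z and the average MIP.
    """
    if series.n_frames < 2:
        raise ArgumentError("need at least 2 frames")
    mip = np.abs(series.data).max(axis=3)  # (T, nx, ny)
    ref = mip.mean(axis=0).ravel()
    ref = ref - ref.mean()
    ref_n = np.linalg.norm(ref)
    corr = np.empty(series.n_frames)
    for i in range(series.n_frames):
        m = mip[i].ravel()
        m = m - m.mean()
        denom = np.linalg.norm(m) * ref_n
        corr[i] = (m @ ref) / denom if denom > 0 else 1.0
    kept = corr >= threshold
    if not kept.any():
        raise PipelineError(
            "every frame rejected by motion gating; lower the correlation threshold"
        )
    return kept


# ---------------------------------------------------------------------------
# clutter filtering and slow-time conditioning
# ---------------------------------------------------------------------------


def svd_filter(series: IQSeries, block_size: int = 600, n_remove: int = 150) -> IQSeries:
    """Spatio-temporal SVD clutter rejection.

    Within each non-overlapping block of frames the Casorati matrix
    (voxels x frames) is decomposed and the ``n_remove`` largest singular
    values zeroed.  A final partial block scales the cutoff proportionally
    (floor), preserving the removal fraction.
    """
    T = series.n_frames
    if block_size < 1:
        raise ArgumentError("block_size must be >= 1")
    if n_remove >= min(block_size, T):
        raise ArgumentError("n_remove must be smaller than the block frame count")
    out = np.empty_like(series.data)
    spatial = series.data.shape[1:]
    for a in range(0, T, block_size):
        blk = series.data[a : a + block_size]
        tb = blk.shape[0]
        nr = n_remove if tb == block_size else int(np.floor(n_remove * tb / block_size))
        cas = blk.reshape(tb, -1).T  # (voxels, frames)
        if nr == 0:
            out[a : a + block_size] = blk
            continue
        if nr >= tb:
            raise ArgumentError("n_remove exceeds a block's frame count")
        u, s, vh = np.linalg.svd(cas, full_matrices=False)
        s[:nr] = 0.0
        out[a : a + block_size] = (u @ (s[:, None] * vh)).T.reshape(tb, *spatial)
    return replace(series, data=out)


def temporal_bandpass(series: IQSeries, band) -> IQSeries:
    """Zero-phase slow-time band-pass per voxel; DC is removed."""
    lo, hi = band
    if lo >= hi:
        raise ArgumentError("band must satisfy lo < hi")
    if hi > series.frame_rate / 2:
        raise ArgumentError("band upper edge exceeds the slow-time Nyquist rate")
    data = series.data - series.data.mean(axis=0, keepdims=True)
    sos = signal.butter(4, [lo, hi], btype="band", fs=series.frame_rate, output="sos")
    if np.iscomplexobj(data):
        filt = (signal.sosfiltfilt(sos, data.real, axis=0)
                + 1j * signal.sosfiltfilt(sos, data.imag, axis=0))
    else:
        filt = signal.sosfiltfilt(sos, data, axis=0)
    return replace(series, data=filt)


def directional_split(series: IQSeries, axis: int = 2):
    """Split the series into +z- and -z-moving channels.

    Implemented as quadrant selection in the 2D Fourier domain spanned by
    the spatial depth axis and slow time.  The baseband IQ is first
    re-modulated by the two-way carrier exp(+i k0 z) (k0 = 4 pi fc / c) so
    the spatial spectrum sits on the positive-k side; a scatterer moving at
    axial speed v then occupies the line f = -v k with k > 0, and the two
    motion directions fall in opposite (f, k) quadrants.  The zero-frequency
    planes are split evenly, so up + down reproduces the input exactly.

    Returns ``(up, down)`` where "up" collects motion along +z (away from
    the array).
    """
    if series.n_frames < 4:
        raise ArgumentError("need at least 4 frames for directional filtering")
    z = series.grid.axis_coords(axis)
    k0 = 4.0 * np.pi * series.fc / (series.c * MM_PER_M)  # rad/mm, two-way
    carrier = np.exp(1j * k0 * z)
    shape = [1, 1, 1, 1]
    shape[axis + 1] = len(z)
    carrier = carrier.reshape(shape)
    mod = series.data * carrier

    F = np.fft.fft2(mod, axes=(0, axis + 1))
    f = np.fft.fftfreq(series.n_frames)
    k = np.fft.fftfreq(series.data.shape[axis + 1])
    fsgn = np.sign(f)
    ksgn = np.sign(k)
    # the Nyquist plane is direction-ambiguous: split it evenly like DC
    if series.n_frames % 2 == 0:
        fsgn[series.n_frames // 2] = 0.0
    if series.data.shape[axis + 1] % 2 == 0:
        ksgn[series.data.shape[axis + 1] // 2] = 0.0
    fsgn = fsgn.reshape(-1, 1)
    ksgn = ksgn.reshape(1, -1)
    w_shape = [1, 1, 1, 1]
    w_shape[0] = series.n_frames
    w_shape[axis + 1] = len(k)
    w_up = (np.where(fsgn * ksgn < 0, 1.0,
                     np.where(fsgn * ksgn == 0, 0.5, 0.0))).reshape(w_shape)
    up = np.fft.ifft2(F * w_up, axes=(0, axis + 1)) * np.conj(carrier)
    down = np.fft.ifft2(F * (1.0 - w_up), axes=(0, axis + 1)) * np.conj(carrier)
    return replace(series, data=up), replace(series, data=down)


def power_doppler(series: IQSeries) -> Volume:
    """Mean |IQ|^2 over frames: the flow-sensitive power-Doppler volume."""
    if series.n_frames < 1:
        raise ArgumentError("need at least 1 frame")
    pd = np.mean(np.abs(series.data) ** 2, axis=0)
    return Volume(grid=series.grid, data=pd, kind="pd")


# ---------------------------------------------------------------------------
# sub-voxel localization
# ---------------------------------------------------------------------------


def _radial_symmetry_center(win: np.ndarray) -> np.ndarray:
    """3D radial-symmetry center of an intensity window (voxel units).

    Finds the point minimizing the gradient-magnitude-weighted sum of
    squared distances to the lines through each voxel along its intensity
    gradient.  Returns coordinates relative to the window origin.
    """
    g = np.stack(np.gradient(win.astype(float)), axis=-1)  # (wx, wy, wz, 3)
    gn2 = np.sum(g ** 2, axis=-1)
    mask = gn2 > 0
    if not mask.any():
        return (np.array(win.shape, dtype=float) - 1) / 2.0
    idx = np.argwhere(mask).astype(float)
    gv = g[mask]
    w = gn2[mask]
    ghat = gv / np.sqrt(w)[:, None]
    # A = sum w (I - g g^T),  b = A_i x_i summed
    P = np.eye(3)[None, :, :] - ghat[:, :, None] * ghat[:, None, :]
    Pw = P * w[:, None, None]
    A = Pw.sum(axis=0)
    b = np.einsum("nij,nj->i", Pw, idx)
    try:
        center = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        center = idx.mean(axis=0)
    return center


def robust_noise_floor(data: np.ndarray) -> float:
    """Median absolute deviation scaled to a Gaussian sigma."""
    d = np.abs(data).ravel()
    med = np.median(d)
    return float(med + 1.4826 * np.median(np.abs(d - med)))


def localize_radial_symmetry(
    volume: Volume,
    detect_threshold: Optional[float] = None,
    window: int = 5,
    frame_index: int = 0,
    direction_channel: str = "none",
) -> List[Localization]:
    """Detect local maxima and refine each to a sub-voxel center.

    ``detect_threshold`` is a fraction of the volume maximum; when omitted
    the threshold is 3x the MAD-based robust noise floor.  Detections
    closer than window/2 voxels are merged keeping the brighter one.
    """
    if window < 3 or window % 2 == 0:
        raise ArgumentError("window must be odd and >= 3")
    data = np.abs(volume.data).astype(float)
    vmax = data.max()
    if vmax <= 0 or np.isclose(data.min(), vmax):
        return []
    if detect_threshold is not None:
        if not 0 < detect_threshold < 1:
            raise ArgumentError("detect_threshold must be in (0, 1)")
        thr = detect_threshold * vmax
    else:
        thr = 3.0 * robust_noise_floor(data)
    local_max = (data == ndimage.maximum_filter(data, size=window)) & (data > thr)
    peaks = np.argwhere(local_max)
    if len(peaks) == 0:
        return []
    vals = data[tuple(peaks.T)]
    order = np.argsort(vals)[::-1]
    peaks, vals = peaks[order], vals[order]
    kept, kept_vals = [], []
    merge_r = window / 2.0
    for p, v in zip(peaks, vals):
        if all(np.linalg.norm(p - q) >= merge_r for q in kept):
            kept.append(p)
            kept_vals.append(v)
    half = window // 2
    shape = np.array(data.shape)
    out = []
    for p, v in zip(kept, kept_vals):
        lo = np.clip(p - half, 0, shape - window)
        win = data[lo[0]:lo[0]+window, lo[1]:lo[1]+window, lo[2]:lo[2]+window]
        c = _radial_symmetry_center(win)
        c = np.clip(c, 0, window - 1)
        vox = lo + c
        out.append(Localization(position=volume.grid.voxel_to_world(vox),
                                frame_index=frame_index, intensity=float(v),
                                direction_channel=direction_channel))
    return out


def localize_frames(series: IQSeries, detect_threshold: Optional[float] = None,
                    window: int = 5) -> List[List[Localization]]:
    """Per-frame localization on |IQ| volumes of a (filtered) series."""
    out = []
    for i in range(series.n_frames):
        vol = Volume(grid=series.grid, data=np.abs(series.data[i]), kind="pd")
        out.append(localize_radial_symmetry(vol, detect_threshold, window,
                                            frame_index=i))
    return out


def merge_directional_localizations(per_frame_up, per_frame_down,
                                    min_sep_mm: float):
    """Merge up/down channel detections, suppressing near-duplicates."""
    merged = []
    for up, down in zip(per_frame_up, per_frame_down):
        frame = list(up)
        for d in down:
            if all(np.linalg.norm(d.position - u.position) >= min_sep_mm
                   for u in frame):
                frame.append(d)
            else:
                for j, u in enumerate(frame):
                    if (np.linalg.norm(d.position - u.position) < min_sep_mm
                            and d.intensity > u.intensity):
                        frame[j] = d
        merged.append(frame)
    return merged


# ---------------------------------------------------------------------------
# tracking and rendering
# ---------------------------------------------------------------------------


def track_bubbles(
    per_frame: List[List[Localization]],
    frame_rate: float,
    max_link: float,
    max_gap: int = 2,
    min_length: int = 5,
) -> TrackSet:
    """Link localizations into trajectories by optimal bipartite assignment.

    Frame-to-frame links minimize total Euclidean distance (Hungarian
    algorithm); links longer than ``max_link * gap`` mm are forbidden, track
    ends survive up to ``max_gap`` missed frames, and tracks with fewer than
    ``min_length`` points are discarded.  Per-step velocity is displacement
    times frame rate over the frame gap (mm/s).
    """
    if max_link <= 0:
        raise ArgumentError("max_link must be > 0")
    active = []  # list of lists of Localization
    finished = []
    for f, dets in enumerate(per_frame):
        # retire stale tracks
        still = []
        for tr in active:
            if f - tr[-1].frame_index > max_gap + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        if not dets:
            continue
        if active:
            cost = np.empty((len(active), len(dets)))
            for i, tr in enumerate(active):
                gap = f - tr[-1].frame_index
                limit = max_link * gap
                d = np.linalg.norm(
                    np.array([det.position for det in dets]) - tr[-1].position,
                    axis=1,
                )
                cost[i] = np.where(d <= limit, d, 1e9)
            rows, cols = linear_sum_assignment(cost)
            assigned = set()
            for i, j in zip(rows, cols):
                if cost[i, j] < 1e9:
                    active[i].append(dets[j])
                    assigned.add(j)
            for j, det in enumerate(dets):
                if j not in assigned:
                    active.append([det])
        else:
            for det in dets:
                active.append([det])
    finished.extend(active)

    tracks = []
    for tr in finished:
        if len(tr) < min_length:
            continue
        pos = np.array([l.position for l in tr])
        fr = np.array([l.frame_index for l in tr])
        dt = np.diff(fr) / frame_rate
        vel = np.diff(pos, axis=0) / dt[:, None]
        tracks.append(Track(localizations=tr, velocities=vel))
    return TrackSet(tracks=tracks, frame_rate=frame_rate)


def render_maps(tracks: TrackSet, grid: VoxelGrid, upsample: int = 4):
    """Accumulate trajectories into super-resolved density and velocity maps.

    The rendering grid covers the same physical extent as ``grid`` with
    ``upsample``-times finer voxels.  Track segments are interpolated at
    half-super-voxel steps; density counts deposited samples, velocity is
    the density-weighted mean speed with NaN where undefined.
    """
    if upsample < 1 or int(upsample) != upsample:
        raise ArgumentError("upsample must be a positive integer")
    up = int(upsample)
    fine_shape = tuple(n * up for n in grid.shape)
    fine_spacing = tuple(s / up for s in grid.spacing)
    fine_origin = tuple(
        o - s / 2.0 + fs / 2.0
        for o, s, fs in zip(grid.origin, grid.spacing, fine_spacing)
    )
    fine = VoxelGrid(shape=fine_shape, spacing=fine_spacing, origin=fine_origin)
    density = np.zeros(fine_shape)
    vsum = np.zeros(fine_shape)
    step = min(fine_spacing) / 2.0
    for tr in tracks.tracks:
        pos = tr.positions
        for k in range(len(pos) - 1):
            a, b = pos[k], pos[k + 1]
            speed = float(np.linalg.norm(tr.velocities[k]))
            seg = np.linalg.norm(b - a)
            n = max(1, int(np.ceil(seg / step)))
            ts = np.arange(n) / n if k < len(pos) - 2 else np.linspace(0, 1, n + 1)
            pts = a[None, :] + ts[:, None] * (b - a)[None, :]
            vox = np.rint(fine.world_to_voxel(pts)).astype(int)
            ok = np.all((vox >= 0) & (vox < np.array(fine_shape)), axis=1)
            for v in vox[ok]:
                density[tuple(v)] += 1
                vsum[tuple(v)] += speed
    with np.errstate(invalid="ignore", divide="ignore"):
        velocity = np.where(density > 0, vsum / np.maximum(density, 1), np.nan)
    return (
        Volume(grid=fine, data=density, kind="density"),
        Volume(grid=fine, data=velocity, kind="velocity",
               meta={"valid_mask": density > 0}),
    )
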