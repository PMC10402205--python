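"""Analytic acoustic forward simulation.

Replaces the physical scanner: point photoacoustic sources propagate one
way to the receivers (delay r/c, amplitude ~ 1/r), point ultrasound
scatterers echo two ways per synthetic-aperture transmit event (delay
(r_tx + r_rx)/c, amplitude ~ 1/(r_tx*r_rx)).  All delays are applied with
band-limited interpolation: the PA path shifts spectra exactly in the
frequency domain, the US path deposits a pre-computed bank of
FFT-fractionally-shifted pulses (64 sub-sample shifts, i.e. delay
quantization 1/(64*fs)), so sub-voxel localization downstream is
physically meaningful.

Units: positions mm, times s, c in m/s, frequencies Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import signal
from numpy.fft import rfft, irfft, rfftfreq

from .errors import ArgumentError, SimulationError
from .geometry import ArrayGeometry, Sequence

MM_PER_M = 1e3


@dataclass
class ImpulseResponse:
    """Receive impulse response: sampled waveform plus its time origin.

    ``center_index`` is the sample corresponding to t = 0 of the pulse, so
    delaying by tau places the pulse center at tau.
    """

    waveform: np.ndarray
    fs: float
    center_frequency: float
    fractional_bandwidth: float
    center_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.center_index is None:
            env = np.abs(signal.hilbert(self.waveform))
            self.center_index = int(np.argmax(env))

    @property
    def duration(self) -> float:
        return len(self.waveform) / self.fs

    def resampled(self, fs: float) -> "ImpulseResponse":
        """Fourier resampling onto a new sample clock."""
        if np.isclose(fs, self.fs):
            return self
        n_new = max(2, int(round(len(self.waveform) * fs / self.fs)))
        wave = signal.resample(self.waveform, n_new)
        return ImpulseResponse(
            waveform=wave,
            fs=fs,
            center_frequency=self.center_frequency,
            fractional_bandwidth=self.fractional_bandwidth,
            center_index=int(round(self.center_index * fs / self.fs)),
        )


def gaussian_pulse(fc: float, fractional_bw: float, fs: float) -> ImpulseResponse:
    """Gaussian-modulated sinusoid with the requested -6 dB fractional bandwidth.

    Stand-in for the measured receive impulse response of the array.
    """
    if not 0 < fractional_bw < 2:
        raise ArgumentError("fractional_bw must lie in (0, 2)")
    if fs <= 4 * fc:
        raise ArgumentError("fs must exceed 4*fc for a well-sampled pulse")
    tc = signal.gausspulse("cutoff", fc=fc, bw=fractional_bw, bwr=-6, tpr=-80)
    n_half = int(np.ceil(tc * fs))
    t = np.arange(-n_half, n_half + 1) / fs
    wave = signal.gausspulse(t, fc=fc, bw=fractional_bw, bwr=-6)
    return ImpulseResponse(
        waveform=wave,
        fs=fs,
        center_frequency=fc,
        fractional_bandwidth=fractional_bw,
        center_index=n_half,
    )


@dataclass
class PASource:
    """Point optical absorber: position, absorbed energy, relative spectrum."""

    position: np.ndarray
    absorbed_energy: float = 1.0
    spectrum: dict = field(default_factory=lambda: {700.0: 1.0})

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if any(v < 0 for v in self.spectrum.values()):
            raise ArgumentError("relative absorption must be >= 0")


@dataclass
class Scatterer:
    """Point ultrasound scatterer with a slow-time trajectory.

    ``positions`` is either a single (3,) static position or an
    (n_frames, 3) trajectory indexed by slow-time frame.
    """

    positions: np.ndarray
    echogenicity: float = 1.0
    kind: str = "microbubble"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)

    def position(self, frame_index: int) -> np.ndarray:
        if self.positions.ndim == 1:
            return self.positions
        return self.positions[frame_index]


@dataclass
class RFDataset:
    """Channel-time data.

    data shape: PA mode (n_elements, n_samples); US mode
    (n_tx, n_elements, n_samples).  A leading frames axis may be added by
    the pipeline when stacking slow-time acquisitions.  ``t0`` is the time
    of the first sample of the record window.
    """

    data: np.ndarray
    fs: float
    mode: str
    geometry: ArrayGeometry
    sequence: Optional[Sequence] = None
    wavelength: Optional[float] = None
    sound_speed: float = 1540.0
    t0: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]


# ---------------------------------------------------------------------------
# photoacoustic propagation (one-way)
# ---------------------------------------------------------------------------


def simulate_pa_rf(
    sources,
    geometry: ArrayGeometry,
    wavelength: float,
    fs: float,
    ir: ImpulseResponse,
    c: float = 1540.0,
    noise_rms: float = 0.0,
    seed: int = 0,
    t0: float = 0.0,
    n_samples: Optional[int] = None,
) -> RFDataset:
    """One-way propagation of impulsive point absorbers to every element.

    Each element receives the impulse response delayed by r/c and scaled by
    absorbed_energy * spectrum(wavelength) / r (spherical spreading), summed
    over sources, plus seeded white Gaussian noise.
    """
    ir = ir.resampled(fs)
    elem = geometry.element_positions
    E = elem.shape[0]

    src_pos = np.array([s.position for s in sources], dtype=float).reshape(-1, 3)
    if len(sources) > 0:
        radii = np.linalg.norm(src_pos, axis=1)
        if np.any(radii > geometry.curvature_radius):
            raise SimulationError("sources must lie inside the array sphere")
        amps0 = []
        for s in sources:
            if wavelength not in s.spectrum:
                raise SimulationError(
                    f"source spectrum has no entry at {wavelength} nm"
                )
            amps0.append(s.absorbed_energy * s.spectrum[wavelength])
        amps0 = np.asarray(amps0)
        d = np.linalg.norm(elem[:, None, :] - src_pos[None, :, :], axis=2)  # (E, S)
        if np.any(d < 1e-9):
            raise SimulationError("source coincides with an element (zero range)")
        tau = d / MM_PER_M / c
        if n_samples is None:
            n_samples = int(np.ceil((tau.max() - t0) * fs)) + len(ir.waveform) + 8
    else:
        tau = np.zeros((E, 0))
        amps0 = np.zeros(0)
        d = np.ones((E, 0))
        if n_samples is None:
            n_samples = int(np.ceil((2 * geometry.curvature_radius / MM_PER_M / c) * fs))

    f = rfftfreq(n_samples, 1.0 / fs)
    ir_f = rfft(ir.waveform, n_samples) * np.exp(2j * np.pi * f * ir.center_index / fs)
    data = np.zeros((E, n_samples))
    if len(sources) > 0:
        amp = amps0[None, :] / d  # (E, S)
        phase = np.exp(-2j * np.pi * f[None, None, :] * (tau[:, :, None] - t0))
        spec = (amp[:, :, None] * phase).sum(axis=1) * ir_f[None, :]
        data = irfft(spec, n_samples)

    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_rms, data.shape)
    return RFDataset(
        data=data,
        fs=fs,
        mode="pa",
        geometry=geometry,
        wavelength=wavelength,
        sound_speed=c,
        t0=t0,
    )


# ---------------------------------------------------------------------------
# pulse-echo propagation (two-way, synthetic aperture)
# ---------------------------------------------------------------------------

_BANK_UPSAMPLE = 64
_BANK_PAD = 16


def _pulse_bank(pulse: ImpulseResponse):
    """Bank of band-limited fractional shifts of the pulse (cached on the pulse)."""
    cached = getattr(pulse, "_bank_cache", None)
    if cached is not None:
        return cached
    w = pulse.waveform
    L = len(w) + 2 * _BANK_PAD
    base = np.zeros(L)
    base[_BANK_PAD : _BANK_PAD + len(w)] = w
    F = rfft(base)
    f = rfftfreq(L)
    shifts = np.arange(_BANK_UPSAMPLE) / _BANK_UPSAMPLE
    bank = irfft(F[None, :] * np.exp(-2j * np.pi * f[None, :] * shifts[:, None]), L)
    center = pulse.center_index + _BANK_PAD
    pulse._bank_cache = (bank, center)
    return bank, center


def simulate_us_rf(
    scatterers,
    geometry: ArrayGeometry,
    sequence: Sequence,
    frame_index: int = 0,
    fs: float = 20.83e6,
    pulse: Optional[ImpulseResponse] = None,
    c: float = 1540.0,
    noise_rms: float = 0.0,
    seed: int = 0,
    t0: float = 0.0,
    n_samples: Optional[int] = None,
) -> RFDataset:
    """Pulse-echo records for one synthetic-aperture frame.

    One record per (tx, rx) pair: the transmit pulse delayed by the two-way
    time of flight and scaled by echogenicity over the product of the two
    ranges, superposed over scatterers.  An empty scatterer list yields
    noise-only data.
    """
    if pulse is None:
        pulse = gaussian_pulse(geometry.center_frequency, 0.75, fs)
    pulse = pulse.resampled(fs)
    elem = geometry.element_positions
    E = elem.shape[0]
    tx = sequence.tx_indices
    T = len(tx)
    bank, center = _pulse_bank(pulse)
    L = bank.shape[1]

    spos = np.array([s.position(frame_index) for s in scatterers], dtype=float).reshape(-1, 3)
    S = spos.shape[0]
    if S > 0:
        r_rx = np.linalg.norm(elem[:, None, :] - spos[None, :, :], axis=2)  # (E, S)
        if np.any(r_rx < 1e-9):
            raise SimulationError("scatterer coincides with an element (zero range)")
        r_tx = r_rx[tx]  # (T, S)
        tau = (r_tx[:, None, :] + r_rx[None, :, :]) / MM_PER_M / c  # (T, E, S)
        ech = np.array([s.echogenicity for s in scatterers])
        amp = ech[None, None, :] / (r_tx[:, None, :] * r_rx[None, :, :])
        if n_samples is None:
            n_samples = int(np.ceil((tau.max() - t0) * fs)) + L + 8
    else:
        if n_samples is None:
            n_samples = int(
                np.ceil((4 * geometry.curvature_radius / MM_PER_M / c - t0) * fs)
            )

    out = np.zeros(T * E * n_samples)
    if S > 0:
        q = (tau.reshape(-1) - t0) * fs  # pulse-center sample, fractional
        base = np.floor(q).astype(np.int64)
        frac = q - base
        u = np.rint(frac * _BANK_UPSAMPLE).astype(np.int64)
        carry = u == _BANK_UPSAMPLE
        u[carry] = 0
        base[carry] += 1
        start = base - center  # first tap sample within the channel
        ch = (np.arange(T)[:, None, None] * E + np.arange(E)[None, :, None]) \
            * n_samples + np.zeros(S, dtype=np.int64)[None, None, :]
        ch = ch.reshape(-1)
        local = start[:, None] + np.arange(L)[None, :]  # (N, L)
        valid = (local >= 0) & (local < n_samples)
        idx = (ch[:, None] + local)[valid]
        vals = (amp.reshape(-1)[:, None] * bank[u])[valid]
        np.add.at(out, idx, vals)
    data = out.reshape(T, E, n_samples)

    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_rms, data.shape)
    return RFDataset(
        data=data,
        fs=fs,
        mode="us",
        geometry=geometry,
        sequence=sequence,
        sound_speed=c,
        t0=t0,
    )


# ---------------------------------------------------------------------------
# slow-time scene builders
# ---------------------------------------------------------------------------


def _polyline_arclength(path: np.ndarray):
    seg = np.diff(path, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    return cum, cum[-1]


def _point_on_path(path: np.ndarray, cum: np.ndarray, s):
    s = np.atleast_1d(s)
    return np.column_stack([np.interp(s, cum, path[:, k]) for k in range(3)])


def _path_tangent(path: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    i = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(cum) - 2)
    t = path[i + 1] - path[i]
    n = np.linalg.norm(t)
    return t / n if n > 0 else np.array([1.0, 0.0, 0.0])


def make_flow_phantom(
    paths,
    radius: float,
    speed: float,
    bubbles_per_frame: int,
    frame_rate: float,
    n_frames: int,
    seed: int = 0,
):
    """Microbubbles advected along vessel paths at constant speed.

    Each of ``bubbles_per_frame`` bubbles per path starts at a random
    arclength and advances speed/frame_rate mm per frame, riding at a fixed
    random lateral offset of magnitude <= radius.  Bubbles leaving the far
    end re-enter at the start (with a fresh offset), so the instantaneous
    count is exactly stationary.
    """
    if radius < 0:
        raise ArgumentError("radius must be >= 0")
    if speed < 0 or frame_rate <= 0:
        raise ArgumentError("speed >= 0 and frame_rate > 0 required")
    rng = np.random.default_rng(seed)
    step = speed / frame_rate
    scatterers = []
    for path in paths:
        path = np.asarray(path, dtype=float)
        if path.ndim != 2 or path.shape[0] < 2:
            raise ArgumentError("each path must be an (n>=2, 3) polyline")
        cum, total = _polyline_arclength(path)
        if total <= 0:
            raise ArgumentError("degenerate path with zero length")
        for _ in range(bubbles_per_frame):
            s0 = rng.uniform(0.0, total)
            offs = _random_disk_offset(rng, radius)
            pos = np.empty((n_frames, 3))
            cur_off = offs
            prev_lap = 0
            for k in range(n_frames):
                s = s0 + k * step
                lap = int(s // total) if total > 0 else 0
                if lap != prev_lap:  # wrapped: fresh lateral offset
                    cur_off = _random_disk_offset(rng, radius)
                    prev_lap = lap
                sm = s % total
                p = _point_on_path(path, cum, sm)[0]
                tan = _path_tangent(path, cum, sm)
                pos[k] = p + _offset_in_plane(tan, cur_off)
            scatterers.append(Scatterer(positions=pos, echogenicity=1.0, kind="microbubble"))
    return scatterers


def _random_disk_offset(rng, radius):
    r = radius * np.sqrt(rng.uniform())
    a = rng.uniform(0, 2 * np.pi)
    return r, a


def _offset_in_plane(tangent: np.ndarray, offset) -> np.ndarray:
    r, a = offset
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(tangent, helper)) > 0.9 * np.linalg.norm(tangent):
        helper = np.array([1.0, 0.0, 0.0])
    u = np.cross(tangent, helper)
    u /= np.linalg.norm(u)
    v = np.cross(tangent, u)
    v /= np.linalg.norm(v)
    return r * (np.cos(a) * u + np.sin(a) * v)


def make_clutter(
    n: int,
    region,
    echogenicity_scale: float = 1.0,
    jitter_rms: float = 0.0,
    seed: int = 0,
    n_frames: int = 1,
):
    """Static tissue-like scatterers with a sub-wavelength random walk.

    ``region`` is ((xlo, xhi), (ylo, yhi), (zlo, zhi)) in mm.  jitter_rms is
    the RMS 3D displacement per frame; echogenicities are exponential with
    the given scale (a crude speckle statistic).
    """
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    region = np.asarray(region, dtype=float)
    base = rng.uniform(region[:, 0], region[:, 1], size=(n, 3))
    ech = rng.exponential(echogenicity_scale, size=n)
    out = []
    for i in range(n):
        if jitter_rms > 0 and n_frames > 1:
            steps = rng.normal(0.0, jitter_rms / np.sqrt(3.0), size=(n_frames, 3))
            steps[0] = 0.0
            pos = base[i] + np.cumsum(steps, axis=0)
        else:
            pos = np.tile(base[i], (n_frames, 1)) if n_frames > 1 else base[i]
        out.append(Scatterer(positions=pos, echogenicity=float(ech[i]), kind="clutter"))
    return out
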