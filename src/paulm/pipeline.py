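"""Config-driven pipeline: simulate -> beamform -> so2 / ulm -> quantify.

Every run is fully described by a :class:`RunConfig` (strictly validated:
unknown keys are rejected) plus one global seed.  The seed fans out to
per-stage sub-seeds by a stable CRC32 hash of the stage name, so adding a
stage never perturbs the randomness of the others; per-frame seeds are
stage_seed + frame.  Deterministic stages rerun bit-identically from the
saved config, which the run log verifies with SHA-256 checksums of every
artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import containers
from .beamform import VoxelGrid, build_sparse_das, das_pa, envelope
from .errors import ConfigurationError, DependencyError
from .geometry import Sequence, build_spherical_array, select_tx_subset, volumetric_frame_rate
from .simulate import PASource, RFDataset, gaussian_pulse, make_clutter, make_flow_phantom, simulate_pa_rf, simulate_us_rf
from .spectral import ExtinctionTable, unmix_so2
from .ulm import (IQSeries, directional_split, localize_frames,
                  merge_directional_localizations, power_doppler, reject_motion,
                  render_maps, svd_filter, temporal_bandpass, track_bubbles)
from .quantify import extract_vessel_functions, segment_vessels

SCHEMA_VERSION = 1
ALL_STAGES = ("simulate", "beamform", "so2", "ulm", "quantify")


def _from_dict(cls, d: dict):
    import typing

    if not isinstance(d, dict):
        raise ConfigurationError(f"{cls.__name__} config must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    hints = typing.get_type_hints(cls)
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        t = hints.get(f.name)
        if dataclasses.is_dataclass(t) and isinstance(v, dict):
            v = _from_dict(t, v)
        elif f.name == "vessels":
            v = tuple(_from_dict(VesselConfig, x) if isinstance(x, dict) else x
                      for x in v)
        elif isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class GeometryConfig:
    n_elements: int = 64
    curvature_radius: float = 40.0
    aperture_diameter: float = 57.0
    layout_seed: int = 0
    center_frequency: float = 4e6
    rx_bandwidth: float = 0.75


@dataclass
class SequenceConfig:
    n_tx: int = 6
    pri: float = 775.2e-6  # chosen so the volume rate stays ~215 Hz with 6 Tx
    fs: float = 20.83e6
    n_frames: int = 200


@dataclass
class GridConfig:
    shape: tuple = (32, 24, 24)
    spacing: float = 0.1


@dataclass
class VesselConfig:
    path: tuple = ()
    radius: float = 0.05
    so2: float = 0.78
    hemisphere: str = ""


@dataclass
class PhantomConfig:
    vessels: tuple = ()
    speed: float = 10.0
    bubbles_per_vessel: int = 2
    clutter_n: int = 100
    clutter_echogenicity: float = 0.5
    clutter_jitter_rms: float = 1e-4
    noise_rms: float = 2e-5
    sound_speed: float = 1540.0


@dataclass
class PAConfig:
    enabled: bool = True
    wavelengths: tuple = (700.0, 750.0)
    fs: float = 20.83e6
    sources_per_vessel: int = 5
    amp_threshold: float = 0.1
    noise_rms: float = 0.0


@dataclass
class ULMConfig:
    motion_threshold: float = 0.95
    block_size: int = 200
    n_remove: int = 50
    band: tuple = (10.0, 100.0)
    directional: bool = False
    window: int = 5
    detect_threshold: float = 0.25
    max_link: float = 0.15
    max_gap: int = 2
    min_length: int = 5
    upsample: int = 4


@dataclass
class QuantifyConfig:
    smooth_sigma: float = 0.08
    threshold: float = 0.3
    min_voxels: int = 10
    dilate: int = 2


@dataclass
class RunConfig:
    seed: int = 0
    schema_version: int = SCHEMA_VERSION
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    sequence: SequenceConfig = field(default_factory=SequenceConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    pa: PAConfig = field(default_factory=PAConfig)
    ulm: ULMConfig = field(default_factory=ULMConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = _from_dict(cls, d)
        if cfg.schema_version != SCHEMA_VERSION:
            raise ConfigurationError(
                f"config schema {cfg.schema_version} != supported {SCHEMA_VERSION}"
            )
        return cfg

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def demo_config(seed: int = 0, n_frames: int = 200) -> RunConfig:
    """Two oblique vessels diving through the focal zone, plus clutter.

    The vessels run along x with a z component steep enough that 10 mm/s
    flow produces a slow-time Doppler shift inside the 10-100 Hz band at
    the 215 Hz volume rate.
    """
    v1 = VesselConfig(path=((-1.2, -0.4, -0.6), (1.2, -0.4, 0.6)),
                      radius=0.05, so2=0.78, hemisphere="left")
    v2 = VesselConfig(path=((-1.2, 0.4, 0.6), (1.2, 0.4, -0.6)),
                      radius=0.05, so2=0.70, hemisphere="right")
    cfg = RunConfig(seed=seed)
    cfg.sequence.n_frames = n_frames
    cfg.phantom.vessels = (v1, v2)
    return cfg


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def record(self, stage: str, params: dict, artifacts: dict) -> None:
        sums = {Path(p).name: _sha256(p) for p in artifacts.values()}
        line = json.dumps({"stage": stage, "params": params, "artifacts": sums},
                          sort_keys=True)
        with open(self.path, "a") as f:
            f.write(line + "\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _build_scene(cfg: RunConfig):
    geom = build_spherical_array(
        cfg.geometry.n_elements, cfg.geometry.curvature_radius,
        cfg.geometry.aperture_diameter, cfg.geometry.layout_seed,
        center_frequency=cfg.geometry.center_frequency,
        fractional_bandwidth_rx=cfg.geometry.rx_bandwidth,
    )
    tx = select_tx_subset(geom, cfg.sequence.n_tx)
    seq = Sequence(tx_indices=tx, pulse_repetition_interval=cfg.sequence.pri,
                   n_frames=cfg.sequence.n_frames, fs=cfg.sequence.fs, mode="us")
    grid = VoxelGrid.centered(cfg.grid.shape, cfg.grid.spacing)
    return geom, seq, grid


def run_pipeline(config: RunConfig, stages=None, out_dir="run") -> Path:
    """Execute the requested stages in order and return the run directory."""
    stages = tuple(ALL_STAGES) if stages is None else tuple(stages)
    for s in stages:
        if s not in ALL_STAGES:
            raise ConfigurationError(f"unknown stage '{s}'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(config.to_json())
    log = _RunLog(out / "log.jsonl")
    geom, seq, grid = _build_scene(config)
    frame_rate = volumetric_frame_rate(seq.n_tx, seq.pulse_repetition_interval)

    if "simulate" in stages:
        _stage_simulate(config, geom, seq, out, log)
    if "beamform" in stages:
        if not (out / "rf.h5").exists():
            raise DependencyError("beamform stage needs rf.h5 (run simulate first)")
        _stage_beamform(config, grid, out, log, frame_rate)
    if "so2" in stages:
        if not config.pa.enabled:
            raise ConfigurationError("so2 stage requested but pa.enabled is false")
        missing = [w for w in config.pa.wavelengths
                   if not (out / f"pa_rf_{int(w)}.h5").exists()]
        if missing:
            raise DependencyError(
                f"so2 stage needs PA RF at {missing} nm (run simulate first)"
            )
        _stage_so2(config, grid, out, log)
    if "ulm" in stages:
        if not (out / "iq.h5").exists():
            raise DependencyError("ulm stage needs iq.h5 (run beamform first)")
        _stage_ulm(config, out, log)
    if "quantify" in stages:
        if not (out / "pd.nii").exists():
            raise DependencyError("quantify stage needs pd.nii (run ulm first)")
        _stage_quantify(config, out, log)
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg, geom, seq, out, log):
    seed = stage_seed(cfg.seed, "simulate")
    frame_rate = volumetric_frame_rate(seq.n_tx, seq.pulse_repetition_interval)
    paths = [np.asarray(v.path, dtype=float) for v in cfg.phantom.vessels]
    bubbles = make_flow_phantom(
        paths, radius=max(v.radius for v in cfg.phantom.vessels),
        speed=cfg.phantom.speed, bubbles_per_frame=cfg.phantom.bubbles_per_vessel,
        frame_rate=frame_rate, n_frames=seq.n_frames, seed=seed,
    ) if paths else []
    allp = np.concatenate([p for p in paths]) if paths else np.zeros((1, 3))
    lo, hi = allp.min(axis=0) - 0.3, allp.max(axis=0) + 0.3
    clutter = make_clutter(cfg.phantom.clutter_n, list(zip(lo, hi)),
                           cfg.phantom.clutter_echogenicity,
                           cfg.phantom.clutter_jitter_rms,
                           seed=seed + 1, n_frames=seq.n_frames)
    scat = bubbles + clutter
    pulse = gaussian_pulse(geom.center_frequency, geom.fractional_bandwidth_rx,
                           seq.fs)
    first = simulate_us_rf(scat, geom, seq, 0, seq.fs, pulse,
                           c=cfg.phantom.sound_speed,
                           noise_rms=cfg.phantom.noise_rms, seed=seed)
    n_samples = first.n_samples
    data = np.empty((seq.n_frames,) + first.data.shape, dtype=np.float32)
    data[0] = first.data
    for k in range(1, seq.n_frames):
        rf_k = simulate_us_rf(scat, geom, seq, k, seq.fs, pulse,
                              c=cfg.phantom.sound_speed,
                              noise_rms=cfg.phantom.noise_rms, seed=seed + 2 + k,
                              t0=first.t0, n_samples=n_samples)
        data[k] = rf_k.data
    rf = RFDataset(data=data, fs=seq.fs, mode="us", geometry=geom, sequence=seq,
                   sound_speed=cfg.phantom.sound_speed, t0=first.t0)
    containers.save_rf(out / "rf.h5", rf)
    artifacts = {"rf": out / "rf.h5"}

    if cfg.pa.enabled and paths:
        table = ExtinctionTable.default()
        sources = []
        for v, path in zip(cfg.phantom.vessels, paths):
            cum = np.linspace(0, 1, cfg.pa.sources_per_vessel)
            pts = path[0] + cum[:, None] * (path[-1] - path[0])
            for p in pts:
                spec = {w: table.mixed_absorption(w, v.so2) / 1e3
                        for w in cfg.pa.wavelengths}
                sources.append(PASource(position=p, absorbed_energy=1.0,
                                        spectrum=spec))
        ir = gaussian_pulse(geom.center_frequency, geom.fractional_bandwidth_rx,
                            cfg.pa.fs)
        for w in cfg.pa.wavelengths:
            pa_rf = simulate_pa_rf(sources, geom, w, cfg.pa.fs, ir,
                                   c=cfg.phantom.sound_speed,
                                   noise_rms=cfg.pa.noise_rms,
                                   seed=seed + 10_000 + int(w))
            containers.save_rf(out / f"pa_rf_{int(w)}.h5", pa_rf)
            artifacts[f"pa_rf_{int(w)}"] = out / f"pa_rf_{int(w)}.h5"
    log.record("simulate", {"seed": seed, "n_scatterers": len(scat)}, artifacts)


def _stage_beamform(cfg, grid, out, log, frame_rate):
    rf = containers.load_rf(out / "rf.h5")
    op = build_sparse_das(rf.geometry, grid, rf.sound_speed, rf.fs,
                          rf.n_samples, t0=rf.t0, sequence=rf.sequence,
                          mode="us")
    frames = np.empty((rf.data.shape[0],) + tuple(grid.shape), dtype=np.complex64)
    for k in range(rf.data.shape[0]):
        frames[k] = op.apply(rf.data[k]).data
    series = IQSeries(data=frames, grid=grid, frame_rate=frame_rate,
                      fc=rf.geometry.center_frequency, c=rf.sound_speed)
    save_iq(out / "iq.h5", series)
    bmode = envelope(series.frame_volume(0))
    bmode.kind = "bmode"
    containers.save_volume(out / "bmode.nii", bmode)
    log.record("beamform", {"n_voxels": grid.n_voxels},
               {"iq": out / "iq.h5", "bmode": out / "bmode.nii"})


def _stage_so2(cfg, grid, out, log):
    table = ExtinctionTable.default()
    vols = []
    for w in cfg.pa.wavelengths:
        pa_rf = containers.load_rf(out / f"pa_rf_{int(w)}.h5")
        vols.append(envelope(das_pa(pa_rf, grid, pa_rf.sound_speed)))
    so2 = unmix_so2(vols[0], vols[1], table, amp_threshold=cfg.pa.amp_threshold)
    for w, v in zip(cfg.pa.wavelengths, vols):
        containers.save_volume(out / f"pa_{int(w)}.nii", v)
    containers.save_volume(out / "so2.nii", so2)
    artifacts = {f"pa_{int(w)}": out / f"pa_{int(w)}.nii"
                 for w in cfg.pa.wavelengths}
    artifacts["so2"] = out / "so2.nii"
    log.record("so2", {"wavelengths": list(cfg.pa.wavelengths)}, artifacts)


def _stage_ulm(cfg, out, log):
    series = load_iq(out / "iq.h5")
    u = cfg.ulm
    kept = reject_motion(series, u.motion_threshold)
    series.kept = kept
    series = series.compact()
    filtered = svd_filter(series, u.block_size, u.n_remove)
    if u.band is not None:
        filtered = temporal_bandpass(filtered, tuple(u.band))
    pd_vol = power_doppler(filtered)
    if u.directional:
        up, down = directional_split(filtered)
        locs = merge_directional_localizations(
            localize_frames(up, u.detect_threshold, u.window),
            localize_frames(down, u.detect_threshold, u.window),
            min_sep_mm=u.window / 2 * min(series.grid.spacing),
        )
    else:
        locs = localize_frames(filtered, u.detect_threshold, u.window)
    tracks = track_bubbles(locs, series.frame_rate, u.max_link, u.max_gap,
                           u.min_length)
    density, velocity = render_maps(tracks, series.grid, u.upsample)
    containers.save_volume(out / "pd.nii", pd_vol)
    containers.save_volume(out / "density.nii", density)
    containers.save_volume(out / "velocity.nii", velocity)
    containers.save_tracks(out / "tracks.csv", tracks)
    log.record("ulm",
               {"kept_frames": int(kept.sum()), "n_tracks": tracks.n_tracks},
               {"pd": out / "pd.nii", "density": out / "density.nii",
                "velocity": out / "velocity.nii", "tracks": out / "tracks.csv"})


def _stage_quantify(cfg, out, log):
    q = cfg.quantify
    pd_vol = containers.load_volume(out / "pd.nii")
    vessels = segment_vessels(pd_vol, q.smooth_sigma, q.threshold, q.min_voxels)
    so2 = velocity = None
    if (out / "so2.nii").exists():
        so2 = containers.load_volume(out / "so2.nii")
    if (out / "velocity.nii").exists():
        vel_fine = containers.load_volume(out / "velocity.nii")
        # velocity lives on the super-resolved grid; pool it onto the PD grid
        velocity = _pool_to_grid(vel_fine, pd_vol.grid)
    vessels = extract_vessel_functions(vessels, so2, velocity, q.dilate)
    for v in vessels:
        v.hemisphere = "left" if np.mean(v.centerline[:, 1]) < 0 else "right"
    containers.save_vessels(out / "vessels.csv", vessels)
    log.record("quantify", {"n_vessels": len(vessels)},
               {"vessels": out / "vessels.csv"})


def _pool_to_grid(fine, coarse_grid):
    """Block-average a super-resolved volume back onto a coarse grid (NaN-aware)."""
    from .beamform import Volume

    up = np.array(fine.grid.shape) // np.array(coarse_grid.shape)
    if np.any(up < 1):
        return fine
    d = fine.data
    u0, u1, u2 = int(up[0]), int(up[1]), int(up[2])
    d = d[: coarse_grid.shape[0] * u0, : coarse_grid.shape[1] * u1,
          : coarse_grid.shape[2] * u2]
    blocks = d.reshape(coarse_grid.shape[0], u0, coarse_grid.shape[1], u1,
                       coarse_grid.shape[2], u2)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        pooled = np.nanmean(blocks, axis=(1, 3, 5))
    return Volume(grid=coarse_grid, data=pooled, kind=fine.kind)


# ---------------------------------------------------------------------------
# IQ series container (HDF5)
# ---------------------------------------------------------------------------


def save_iq(path, series: IQSeries) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("iq", data=series.data.astype(np.complex64),
                         track_times=False)
        f.create_dataset("kept", data=series.kept, track_times=False)
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["frame_rate_hz"] = series.frame_rate
        f.attrs["fc_hz"] = series.fc
        f.attrs["c_mps"] = series.c
        f.attrs["grid_shape"] = series.grid.shape
        f.attrs["grid_spacing_mm"] = series.grid.spacing
        f.attrs["grid_origin_mm"] = series.grid.origin


def load_iq(path) -> IQSeries:
    import h5py

    from .errors import VersionError

    with h5py.File(path, "r") as f:
        try:
            version = int(f.attrs["schema_version"])
            fr = float(f.attrs["frame_rate_hz"])
            fc = float(f.attrs["fc_hz"])
            c = float(f.attrs["c_mps"])
            grid = VoxelGrid(shape=tuple(int(s) for s in f.attrs["grid_shape"]),
                             spacing=tuple(float(s) for s in f.attrs["grid_spacing_mm"]),
                             origin=tuple(float(s) for s in f.attrs["grid_origin_mm"]))
        except KeyError as exc:
            raise VersionError(f"corrupt IQ container: {exc}") from exc
        if version != SCHEMA_VERSION:
            raise VersionError(f"IQ schema {version} != supported {SCHEMA_VERSION}")
        data = f["iq"][()]
        kept = f["kept"][()].astype(bool)
    return IQSeries(data=data, grid=grid, frame_rate=fr, fc=fc, c=c, kept=kept)
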