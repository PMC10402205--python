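"""Persistent containers: HDF5 RF data, NIfTI volumes, CSV tracks/vessels.

NIfTI headers store voxel spacing as float32; a JSON sidecar written next
to every volume carries the float64 spacing/origin and payload metadata
and takes precedence on load, so metric round trips are exact.  HDF5
datasets are created with ``track_times=False`` and volumes are written
uncompressed, so rerunning a pipeline reproduces byte-identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .beamform import Volume, VoxelGrid
from .errors import VersionError
from .geometry import ArrayGeometry, Sequence
from .simulate import RFDataset
from .ulm import Localization, Track, TrackSet
from .quantify import VesselRecord

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# RF data (HDF5)
# ---------------------------------------------------------------------------


def save_rf(path, rf: RFDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=rf.data.astype(np.float32), track_times=False)
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["fs_hz"] = rf.fs
        f.attrs["t0_s"] = rf.t0
        f.attrs["mode"] = rf.mode
        f.attrs["sound_speed_mps"] = rf.sound_speed
        f.attrs["wavelength_nm"] = -1.0 if rf.wavelength is None else rf.wavelength
        f.attrs["geometry_json"] = rf.geometry.to_json()
        f.attrs["sequence_json"] = "" if rf.sequence is None else rf.sequence.to_json()


def load_rf(path) -> RFDataset:
    with h5py.File(path, "r") as f:
        try:
            version = int(f.attrs["schema_version"])
            fs = float(f.attrs["fs_hz"])
            t0 = float(f.attrs["t0_s"])
            mode = str(f.attrs["mode"])
            c = float(f.attrs["sound_speed_mps"])
            wl = float(f.attrs["wavelength_nm"])
            geom = ArrayGeometry.from_json(str(f.attrs["geometry_json"]))
            seq_json = str(f.attrs["sequence_json"])
        except (KeyError, ValueError, json.JSONDecodeError) as exc:
            raise VersionError(f"corrupt or incompatible RF container: {exc}") from exc
        if version != SCHEMA_VERSION:
            raise VersionError(
                f"RF container schema {version} != supported {SCHEMA_VERSION}"
            )
        data = f["rf"][()]
    seq = Sequence.from_json(seq_json) if seq_json else None
    return RFDataset(data=data, fs=fs, mode=mode, geometry=geom, sequence=seq,
                     wavelength=None if wl < 0 else wl, sound_speed=c, t0=t0)


# ---------------------------------------------------------------------------
# volumes (NIfTI + JSON sidecar)
# ---------------------------------------------------------------------------


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return p.with_name(name[: -len(suf)] + ".meta.json")
    return p.with_suffix(p.suffix + ".meta.json")


def save_volume(path, volume: Volume) -> None:
    data = volume.data
    if np.iscomplexobj(data):
        data = data.astype(np.complex64)
    else:
        data = data.astype(np.float32)
    affine = np.diag(list(volume.grid.spacing) + [1.0])
    affine[:3, 3] = volume.grid.origin
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, str(path))
    meta = {
        "schema_version": SCHEMA_VERSION,
        "kind": volume.kind,
        "wavelength_nm": volume.wavelength,
        "spacing_mm": list(volume.grid.spacing),
        "origin_mm": list(volume.grid.origin),
        "shape": list(volume.grid.shape),
        "meta": {k: v for k, v in volume.meta.items()
                 if np.isscalar(v) or isinstance(v, (tuple, list, str))},
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_volume(path) -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise VersionError(f"missing volume sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
        version = int(meta["schema_version"])
        spacing = tuple(float(s) for s in meta["spacing_mm"])
        origin = tuple(float(o) for o in meta["origin_mm"])
        shape = tuple(int(s) for s in meta["shape"])
        kind = meta["kind"]
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise VersionError(f"corrupt volume sidecar: {exc}") from exc
    if version != SCHEMA_VERSION:
        raise VersionError(f"volume schema {version} != supported {SCHEMA_VERSION}")
    grid = VoxelGrid(shape=shape, spacing=spacing, origin=origin)
    return Volume(grid=grid, data=data, kind=kind,
                  wavelength=meta.get("wavelength_nm"),
                  meta=dict(meta.get("meta", {})))


# ---------------------------------------------------------------------------
# tracks and vessels (CSV)
# ---------------------------------------------------------------------------


def tracks_to_dataframe(tracks: TrackSet) -> pd.DataFrame:
    rows = []
    for tid, tr in enumerate(tracks.tracks):
        for k, loc in enumerate(tr.localizations):
            v = tr.velocities[min(k, len(tr.velocities) - 1)] \
                if len(tr.velocities) else np.zeros(3)
            rows.append(
                dict(track_id=tid, frame=int(loc.frame_index),
                     x_mm=loc.position[0], y_mm=loc.position[1],
                     z_mm=loc.position[2], intensity=loc.intensity,
                     vx_mms=v[0], vy_mms=v[1], vz_mms=v[2])
            )
    cols = ["track_id", "frame", "x_mm", "y_mm", "z_mm", "intensity",
            "vx_mms", "vy_mms", "vz_mms"]
    return pd.DataFrame(rows, columns=cols)


def save_tracks(path, tracks: TrackSet) -> None:
    tracks_to_dataframe(tracks).to_csv(path, index=False)


def load_tracks(path, frame_rate: float = 1.0) -> TrackSet:
    df = pd.read_csv(path)
    tracks = []
    for _, grp in df.groupby("track_id"):
        grp = grp.sort_values("frame")
        locs = [
            Localization(position=np.array([r.x_mm, r.y_mm, r.z_mm]),
                         frame_index=int(r.frame), intensity=float(r.intensity))
            for r in grp.itertuples()
        ]
        pos = np.array([l.position for l in locs])
        fr = np.array([l.frame_index for l in locs])
        vel = (np.diff(pos, axis=0) * frame_rate / np.maximum(np.diff(fr), 1)[:, None]
               if len(locs) > 1 else np.zeros((0, 3)))
        tracks.append(Track(localizations=locs, velocities=vel))
    return TrackSet(tracks=tracks, frame_rate=frame_rate)


def vessels_to_dataframe(vessels) -> pd.DataFrame:
    rows = [
        dict(vessel_id=i, hemisphere=v.hemisphere, radius_mm=v.radius,
             length_mm=v.length, volume_mm3=v.volume, mean_so2=v.mean_so2,
             mean_speed_mms=v.mean_speed)
        for i, v in enumerate(vessels)
    ]
    cols = ["vessel_id", "hemisphere", "radius_mm", "length_mm", "volume_mm3",
            "mean_so2", "mean_speed_mms"]
    return pd.DataFrame(rows, columns=cols)


def save_vessels(path, vessels) -> None:
    vessels_to_dataframe(vessels).to_csv(path, index=False)
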