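"""Spherical-cap transducer array geometry and acquisition arithmetic.

Coordinate frame
----------------
The origin sits at the geometric focus (the center of the sphere the
elements lie on).  The z axis is the array axis and points *away* from the
array, so elements live at negative z and the imaged object around the
origin.  All positions are metric millimetres; frequencies Hz; times
seconds.

The physical 256-element arrangement of the array is not published, so
:func:`build_spherical_array` generates a deterministic quasi-uniform
Fibonacci-spiral layout on the cap.  Resolution is governed by aperture,
frequency and bandwidth rather than the exact tiling, which is why this
stand-in is adequate for point-spread-function work.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ArgumentError, GeometryError

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

SCHEMA_VERSION = 1


@dataclass
class ArrayGeometry:
    """Receiver array on a spherical cap focused at the origin.

    element_positions : (n, 3) float array, mm
    element_normals   : (n, 3) unit vectors pointing at the focus
    curvature_radius  : sphere radius, mm
    aperture_diameter : chord diameter of the cap, mm
    center_frequency  : Hz
    fractional_bandwidth_rx : -6 dB receive fractional bandwidth
    """

    element_positions: np.ndarray
    element_normals: np.ndarray
    curvature_radius: float
    aperture_diameter: float
    center_frequency: float = 4e6
    fractional_bandwidth_rx: float = 0.75

    def __post_init__(self) -> None:
        self.element_positions = np.asarray(self.element_positions, dtype=float)
        self.element_normals = np.asarray(self.element_normals, dtype=float)
        r = np.linalg.norm(self.element_positions, axis=1)
        if not np.allclose(r, self.curvature_radius, atol=1e-9):
            raise GeometryError("element positions do not lie on the stated sphere")
        sin_cap = (self.aperture_diameter / 2.0) / self.curvature_radius
        rho = np.linalg.norm(self.element_positions[:, :2], axis=1)
        if np.any(rho > self.curvature_radius * sin_cap + 1e-9):
            raise GeometryError("elements fall outside the stated aperture cone")

    @property
    def n_elements(self) -> int:
        return self.element_positions.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "element_positions_mm": self.element_positions.tolist(),
                "element_normals": self.element_normals.tolist(),
                "curvature_radius_mm": self.curvature_radius,
                "aperture_diameter_mm": self.aperture_diameter,
                "center_frequency_hz": self.center_frequency,
                "fractional_bandwidth_rx": self.fractional_bandwidth_rx,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ArrayGeometry":
        d = json.loads(text)
        return cls(
            element_positions=np.array(d["element_positions_mm"]),
            element_normals=np.array(d["element_normals"]),
            curvature_radius=d["curvature_radius_mm"],
            aperture_diameter=d["aperture_diameter_mm"],
            center_frequency=d["center_frequency_hz"],
            fractional_bandwidth_rx=d["fractional_bandwidth_rx"],
        )


@dataclass
class Sequence:
    """Transmit sequence: which elements fire, how often, and the record clock."""

    tx_indices: np.ndarray
    pulse_repetition_interval: float
    n_frames: int = 1
    fs: float = 20.83e6
    mode: str = "us"

    def __post_init__(self) -> None:
        self.tx_indices = np.asarray(self.tx_indices, dtype=int)
        if self.pulse_repetition_interval <= 0:
            raise ArgumentError("pulse_repetition_interval must be > 0")
        if len(np.unique(self.tx_indices)) != len(self.tx_indices):
            raise ArgumentError("tx_indices must be unique")
        if self.mode not in ("pa", "us"):
            raise ArgumentError("mode must be 'pa' or 'us'")

    @property
    def n_tx(self) -> int:
        return len(self.tx_indices)

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "tx_indices": self.tx_indices.tolist(),
                "pulse_repetition_interval_s": self.pulse_repetition_interval,
                "n_frames": self.n_frames,
                "fs_hz": self.fs,
                "mode": self.mode,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Sequence":
        d = json.loads(text)
        return cls(
            tx_indices=np.array(d["tx_indices"]),
            pulse_repetition_interval=d["pulse_repetition_interval_s"],
            n_frames=d["n_frames"],
            fs=d["fs_hz"],
            mode=d["mode"],
        )


@dataclass
class ScanGrid:
    """Raster-scan lattice of lateral stage positions for FOV stitching."""

    n_x: int
    n_y: int
    step: float
    base_fov: tuple = (8.0, 8.0, 8.0)

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ArgumentError("n_x and n_y must be >= 1")
        if self.step < 0:
            raise ArgumentError("step must be >= 0")

    @property
    def positions(self) -> np.ndarray:
        """(n_x*n_y, 2) lateral offsets in mm, centered on the lattice mean."""
        xs = (np.arange(self.n_x) - (self.n_x - 1) / 2.0) * self.step
        ys = (np.arange(self.n_y) - (self.n_y - 1) / 2.0) * self.step
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])


def build_spherical_array(
    n_elements: int,
    curvature_radius: float,
    aperture_diameter: float,
    layout_seed: int = 0,
    center_frequency: float = 4e6,
    fractional_bandwidth_rx: float = 0.75,
) -> ArrayGeometry:
    """Quasi-uniform Fibonacci-spiral element layout on a spherical cap.

    Equal-area rings in polar angle combined with golden-angle azimuthal
    increments give near-uniform element density.  The seed only rotates the
    whole spiral about the array axis, so layouts are deterministic and two
    seeds differ by a rigid rotation.
    """
    if n_elements < 1:
        raise ArgumentError("n_elements must be >= 1")
    if aperture_diameter <= 0 or aperture_diameter > 2 * curvature_radius:
        raise GeometryError("aperture must satisfy 0 < D <= 2*R")
    theta_max = np.arcsin((aperture_diameter / 2.0) / curvature_radius)
    rng = np.random.default_rng(layout_seed)
    phi0 = rng.uniform(0.0, 2 * np.pi)

    if n_elements == 1:
        theta = np.array([0.0])
        phi = np.array([0.0])
    else:
        i = np.arange(n_elements)
        # equal-area in cos(theta) over the cap
        cos_t = 1.0 - (1.0 - np.cos(theta_max)) * (i + 0.5) / n_elements
        theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
        phi = phi0 + i * GOLDEN_ANGLE

    r = curvature_radius
    pos = np.column_stack(
        [
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
            -r * np.cos(theta),
        ]
    )
    normals = -pos / np.linalg.norm(pos, axis=1, keepdims=True)
    return ArrayGeometry(
        element_positions=pos,
        element_normals=normals,
        curvature_radius=curvature_radius,
        aperture_diameter=aperture_diameter,
        center_frequency=center_frequency,
        fractional_bandwidth_rx=fractional_bandwidth_rx,
    )


def select_tx_subset(geometry: ArrayGeometry, n_tx: int) -> np.ndarray:
    """Spatially uniform transmit subset by farthest-point (maximin) sampling.

    The subset is seeded with the globally most distant element pair
    (exhaustive search), then grown greedily by always adding the element
    farthest from the current subset.  Ties break toward the lowest index,
    so the result is deterministic for a fixed geometry.  Returns sorted
    element indices.
    """
    n = geometry.n_elements
    if not 1 <= n_tx <= n:
        raise ArgumentError(f"n_tx must be in [1, {n}]")
    if n_tx == n:
        return np.arange(n)
    pos = geometry.element_positions
    if n_tx == 1:
        # single transmitter: the element nearest the cap pole (array axis)
        rho = np.linalg.norm(pos[:, :2], axis=1)
        return np.array([int(np.argmin(rho))])

    dist = squareform(pdist(pos))
    flat = int(np.argmax(dist))  # first occurrence -> lowest index pair
    i, j = divmod(flat, n)
    chosen = [min(i, j), max(i, j)]
    # distance from every element to the chosen set
    d_to_set = np.minimum(dist[chosen[0]], dist[chosen[1]])
    while len(chosen) < n_tx:
        nxt = int(np.argmax(d_to_set))  # argmax -> lowest index on ties
        chosen.append(nxt)
        d_to_set = np.minimum(d_to_set, dist[nxt])
    return np.sort(np.array(chosen))


def volumetric_frame_rate(n_tx: int, pri: float) -> float:
    """Volumes per second for a synthetic-aperture sequence: 1 / (n_tx * PRI)."""
    if n_tx < 1:
        raise ArgumentError("n_tx must be >= 1")
    if pri <= 0:
        raise ArgumentError("pri must be > 0")
    return 1.0 / (n_tx * pri)


def stitched_fov(grid: ScanGrid) -> tuple:
    """Extent of the union FOV: lateral base + (n-1)*step, axial unchanged."""
    bx, by, bz = grid.base_fov
    return (
        bx + (grid.n_x - 1) * grid.step,
        by + (grid.n_y - 1) * grid.step,
        bz,
    )


def piston_directivity(angle_rad, radius_mm: float, frequency: float, c: float = 1540.0):
    """Far-field directivity of a circular piston of the given radius.

    2*J1(ka sin t)/(ka sin t).  Used as an optional element-sensitivity
    weight; the physical trapezoidal element is approximated by a circular
    piston of equal area.
    """
    from scipy.special import j1

    k = 2 * np.pi * frequency / (c * 1e3)  # rad/mm
    x = k * radius_mm * np.sin(np.asarray(angle_rad, dtype=float))
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = 2.0 * j1(x[nz]) / x[nz]
    return out
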