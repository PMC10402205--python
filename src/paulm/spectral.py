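"""Two-wavelength linear unmixing of oxy-/deoxy-hemoglobin into sO2 maps.

Per voxel the measured PA amplitudes at wavelengths (l1, l2) are modeled
as ``[pa1; pa2] = E [C_HbO2; C_Hb]`` with E the 2x2 molar extinction
matrix; sO2 = C_HbO2 / (C_HbO2 + C_Hb).  No fluence compensation is
applied: at nearby near-infrared wavelengths the fluence distributions are
comparable, and any shared positive scale cancels in the ratio.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beamform import Volume
from .errors import AlignmentError, ArgumentError, ConfigurationError


@dataclass
class ExtinctionTable:
    """Tabulated molar extinction (cm^-1 M^-1) of HbO2 and Hb vs wavelength."""

    wavelengths: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.eps_hbo2 = np.asarray(self.eps_hbo2, dtype=float)
        self.eps_hb = np.asarray(self.eps_hb, dtype=float)
        if np.any(self.eps_hbo2 <= 0) or np.any(self.eps_hb <= 0):
            raise ArgumentError("extinction coefficients must be strictly positive")

    @classmethod
    def from_csv(cls, path) -> "ExtinctionTable":
        df = pd.read_csv(path, comment="#")
        return cls(df["wavelength_nm"].values, df["eps_hbo2"].values,
                   df["eps_hb"].values)

    @classmethod
    def default(cls) -> "ExtinctionTable":
        ref = importlib.resources.files("paulm") / "data" / "hemoglobin_extinction.csv"
        with importlib.resources.as_file(ref) as p:
            return cls.from_csv(p)

    def _row(self, wavelength: float):
        idx = np.where(np.isclose(self.wavelengths, wavelength))[0]
        if len(idx) == 0:
            raise ConfigurationError(f"no extinction entry at {wavelength} nm")
        return self.eps_hbo2[idx[0]], self.eps_hb[idx[0]]

    def matrix(self, w1: float, w2: float) -> np.ndarray:
        """2x2 unmixing matrix rows = wavelengths, cols = (HbO2, Hb)."""
        return np.array([self._row(w1), self._row(w2)])

    def condition_number(self, w1: float, w2: float) -> float:
        return float(np.linalg.cond(self.matrix(w1, w2)))

    def mixed_absorption(self, wavelength: float, so2: float) -> float:
        """Relative absorption of blood at the given saturation (total Hb = 1)."""
        e1, e2 = self._row(wavelength)
        return so2 * e1 + (1.0 - so2) * e2


def unmix_so2(pa_w1: Volume, pa_w2: Volume, table: ExtinctionTable,
              amp_threshold: float = 0.1) -> Volume:
    """Voxelwise 2x2 spectral unmixing into an sO2 volume.

    Voxels whose amplitude falls below ``amp_threshold`` of the volume
    maximum at either wavelength, or whose concentrations are both
    non-positive, are flagged invalid (NaN payload plus a boolean
    ``valid_mask`` in meta).  A single negative concentration is clipped to
    zero before the ratio.
    """
    if pa_w1.grid != pa_w2.grid:
        raise AlignmentError("PA volumes must share a voxel grid")
    if pa_w1.wavelength is None or pa_w2.wavelength is None:
        raise ArgumentError("PA volumes must carry wavelength tags")
    E = table.matrix(pa_w1.wavelength, pa_w2.wavelength)
    det = E[0, 0] * E[1, 1] - E[0, 1] * E[1, 0]
    if not np.isfinite(det) or np.isclose(det, 0.0) or np.linalg.cond(E) > 1e12:
        raise ConfigurationError(
            f"singular unmixing matrix for wavelength pair "
            f"({pa_w1.wavelength}, {pa_w2.wavelength}) nm"
        )
    v1 = np.abs(np.asarray(pa_w1.data, dtype=float))
    v2 = np.abs(np.asarray(pa_w2.data, dtype=float))
    # analytic 2x2 inverse
    c_hbo2 = (E[1, 1] * v1 - E[0, 1] * v2) / det
    c_hb = (-E[1, 0] * v1 + E[0, 0] * v2) / det

    above = np.ones(v1.shape, dtype=bool)
    if amp_threshold > 0:
        above = (v1 >= amp_threshold * v1.max()) & (v2 >= amp_threshold * v2.max())
    both_nonpos = (c_hbo2 <= 0) & (c_hb <= 0)
    valid = above & ~both_nonpos
    c_hbo2 = np.clip(c_hbo2, 0.0, None)
    c_hb = np.clip(c_hb, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        so2 = c_hbo2 / (c_hbo2 + c_hb)
    so2 = np.where(valid, so2, np.nan)
    return Volume(grid=pa_w1.grid, data=so2, kind="so2",
                  meta={"valid_mask": valid,
                        "wavelength_pair_nm": (pa_w1.wavelength, pa_w2.wavelength),
                        "condition_number": float(np.linalg.cond(E))})


def so2_difference_stats(so2: Volume, mask_left, mask_right):
    """Masked sO2 means of two disjoint regions and their difference."""
    mask_left = np.asarray(mask_left, dtype=bool)
    mask_right = np.asarray(mask_right, dtype=bool)
    if not mask_left.any() or not mask_right.any():
        raise ArgumentError("masks must be nonempty")
    if np.any(mask_left & mask_right):
        raise ArgumentError("masks must be disjoint")
    mean_left = float(np.nanmean(so2.data[mask_left]))
    mean_right = float(np.nanmean(so2.data[mask_right]))
    return mean_left, mean_right, mean_left - mean_right
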