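"""Overlapping-band imager model.

The imager samples 500-780 nm with 300 heavily overlapping channels whose
Gaussian-like response functions have a nominal 12 nm FWHM (an 8 nm variant
exists).  Channels can be decimated (e.g. every third channel -> 100 bands
at ~3 nm spacing) and adjacent channels can be binned on board to raise
signal-to-noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .optics import fwhm_to_sigma, validate_grid

__all__ = [
    "BandConfig",
    "cyanosat_centers",
    "srf_matrix",
    "apply_srf",
    "decimate",
    "bin_adjacent",
    "save_band_config",
    "load_band_config",
]

N_CHANNELS = 300
RANGE_NM = (500.0, 780.0)


@dataclass(frozen=True)
class BandConfig:
    """Channel centers, FWHM and the discretized spectral response matrix.

    srf has shape (n_channels, n_grid); each row is non-negative, sums to 1
    and peaks at the grid point nearest the channel center.
    """

    centers: np.ndarray
    fwhm: float
    grid: np.ndarray
    srf: np.ndarray
    name: str = ""

    def __post_init__(self):
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("channel centers must be strictly increasing")
        if self.srf.shape != (len(self.centers), len(self.grid)):
            raise ValueError("srf shape must be (n_channels, n_grid)")

    @property
    def n_channels(self) -> int:
        return len(self.centers)


def cyanosat_centers() -> np.ndarray:
    """The imager's 300 evenly spaced channel centers from 500 to 780 nm."""
    return np.linspace(RANGE_NM[0], RANGE_NM[1], N_CHANNELS)


def srf_matrix(centers, fwhm: float, grid, name: str = "") -> BandConfig:
    """Build Gaussian spectral response functions on a wavelength grid.

    Each row is a discretized Gaussian with sigma = FWHM / (2 sqrt(2 ln 2)),
    truncated beyond +/- 3 sigma and renormalized to unit sum.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    grid = validate_grid(grid)
    centers = np.asarray(centers, dtype=float)
    sigma = fwhm_to_sigma(fwhm)
    dist = grid[None, :] - centers[:, None]
    srf = np.exp(-0.5 * (dist / sigma) ** 2)
    srf[np.abs(dist) > 3.0 * sigma] = 0.0
    srf /= srf.sum(axis=1, keepdims=True)
    return BandConfig(centers=centers, fwhm=float(fwhm), grid=grid, srf=srf, name=name)


def apply_srf(values: np.ndarray, config: BandConfig) -> np.ndarray:
    """Resample spectra to the instrument channels (linear in the spectrum).

    values: (..., n_grid) -> (..., n_channels).
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != len(config.grid):
        raise ValueError(
            f"spectrum length {values.shape[-1]} does not match grid "
            f"length {len(config.grid)}")
    return values @ config.srf.T


def decimate(config: BandConfig, step: int = 3) -> BandConfig:
    """Keep every step-th channel (indices 0, step, 2 step, ...)."""
    if step < 1:
        raise ValueError("step must be >= 1")
    if step == 1:
        return config
    return srf_matrix(config.centers[::step], config.fwhm, config.grid,
                      name=f"{config.name}/dec{step}" if config.name else f"dec{step}")


def bin_adjacent(values: np.ndarray, group: int) -> np.ndarray:
    """Average non-overlapping groups of adjacent channels.

    Acts on the last axis; a trailing remainder that does not fill a group
    is dropped with a warning.
    """
    if group < 1:
        raise ValueError("group must be >= 1")
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    if group == 1:
        return values.copy()
    n_groups, rem = divmod(n, group)
    if rem:
        warnings.warn(f"dropping {rem} trailing channel(s) not filling a group of {group}")
        values = values[..., : n_groups * group]
    return values.reshape(*values.shape[:-1], n_groups, group).mean(axis=-1)


def save_band_config(config: BandConfig, path) -> None:
    """Persist centers and FWHM as CSV; the SRF is regenerated on load."""
    pd.DataFrame({"center_nm": config.centers,
                  "fwhm_nm": np.full(config.n_channels, config.fwhm)}
                 ).to_csv(Path(path), index=False)


def load_band_config(path, grid, name: str = "") -> BandConfig:
    frame = pd.read_csv(Path(path))
    fwhm = float(frame["fwhm_nm"].iloc[0])
    return srf_matrix(frame["center_nm"].to_numpy(dtype=float), fwhm, grid, name=name)
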