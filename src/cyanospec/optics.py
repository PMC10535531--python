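"""Shared bio-optical building blocks.

Pure-water absorption/backscattering, Gaussian pigment absorption bases for
the algal and cyanobacterial end members, the canonical vegetation red-edge
spectrum used for adjacency stray light and surface scum, and the two-term
quadratic reflectance closure that maps inherent optical properties to
remote-sensing reflectance.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "default_grid",
    "validate_grid",
    "water_absorption",
    "water_backscatter",
    "gaussian_band",
    "fwhm_to_sigma",
    "vegetation_spectrum",
    "reflectance_from_u",
    "PigmentBases",
]

#: Conversion between a bell curve's full width at half maximum and its sigma.
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.35482


def fwhm_to_sigma(fwhm: float) -> float:
    """Standard deviation of a Gaussian with the given FWHM (same units)."""
    return float(fwhm) * _FWHM_TO_SIGMA


def default_grid() -> np.ndarray:
    """Native simulation grid: 400-800 nm at 1 nm (401 points)."""
    return np.arange(400.0, 801.0, 1.0)


def validate_grid(grid: np.ndarray) -> np.ndarray:
    """Check a wavelength grid is 1-D, strictly increasing and in [400, 900] nm."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("wavelength grid must be a 1-D array of >= 2 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if grid[0] < 400.0 - 1e-9 or grid[-1] > 900.0 + 1e-9:
        raise ValueError("wavelength grid must lie within [400, 900] nm")
    return grid


# Pure-water absorption, m^-1, tabulated at 10 nm from the visible/NIR
# laboratory literature (clear-water values; NIR rise dominates past 700 nm).
# Linearly interpolated onto the simulation grid.
_AW_WAVELENGTHS = np.arange(400.0, 801.0, 10.0)
_AW_VALUES = np.array([
    0.00663, 0.00473, 0.00454, 0.00495, 0.00635,  # 400-440
    0.00922, 0.00979, 0.01060, 0.01270, 0.01500,  # 450-490
    0.02040, 0.03250, 0.04090, 0.04340, 0.04740,  # 500-540
    0.05650, 0.06190, 0.06950, 0.08960, 0.13510,  # 550-590
    0.22240, 0.26440, 0.27550, 0.29160, 0.31080,  # 600-640
    0.34000, 0.41000, 0.43900, 0.46500, 0.51600,  # 650-690
    0.62400, 0.82700, 1.23100, 1.79900, 2.38000,  # 700-740
    2.85000, 2.73000, 2.56000, 2.35000, 2.26000,  # 750-790
    2.07000,                                      # 800
])


def water_absorption(grid: np.ndarray) -> np.ndarray:
    """Pure-water absorption a_w(lambda) in 1/m on the given grid."""
    return np.interp(np.asarray(grid, dtype=float), _AW_WAVELENGTHS, _AW_VALUES)


def water_backscatter(grid: np.ndarray) -> np.ndarray:
    """Pure-water backscattering bb_w(lambda) in 1/m (power-law, ~lambda^-4.32)."""
    grid = np.asarray(grid, dtype=float)
    return 0.0022 * (400.0 / grid) ** 4.32


def gaussian_band(grid: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-peak Gaussian absorption band on the grid (center, FWHM in nm)."""
    sigma = fwhm_to_sigma(fwhm)
    grid = np.asarray(grid, dtype=float)
    return np.exp(-0.5 * ((grid - center) / sigma) ** 2)


def vegetation_spectrum(grid: np.ndarray) -> np.ndarray:
    """Canonical green-vegetation reflectance with a red edge at 715 nm."""
    grid = np.asarray(grid, dtype=float)
    return 0.05 + 0.45 / (1.0 + np.exp(-(grid - 715.0) / 10.0))


def reflectance_from_u(u, g0: float = 0.0949, g1: float = 0.0794):
    """Above-surface remote-sensing reflectance from u = bb/(a+bb).

    Applies the two-term quadratic closure rrs = g0*u + g1*u^2 for the
    sub-surface reflectance, then the standard air-water interface transfer
    Rrs = 0.52*rrs / (1 - 1.7*rrs).  Units: sr^-1.
    """
    u = np.asarray(u, dtype=float)
    rrs_sub = g0 * u + g1 * u * u
    return 0.52 * rrs_sub / (1.0 - 1.7 * rrs_sub)


class PigmentBases:
    """Chl-a specific phytoplankton absorption bases for the two end members.

    The algal end member (carotenoid-containing eukaryotes) is a sum of
    Gaussian bands at 440, 490 and 675 nm.  The cyanobacterial end member has
    bands at 440, 650 (weak) and 675 nm plus a phycocyanin band at 620 nm
    whose amplitude scales with the PC:Chl-a ratio of the simulated water.

    Both non-PC base curves are calibrated (by adding a small 620 nm
    shoulder) so that a_base(620) = eps * a_base(665) exactly.  The
    chlorophyll-correction step of the phycocyanin decomposition therefore
    removes the non-PC pigments exactly, and the PC label is zero for a
    purely algal population by construction.

    Parameters
    ----------
    epsilon
        Chlorophyll-correction factor applied to a_ph(665) when isolating
        phycocyanin absorption at 620 nm.
    a_star_pc_base
        Base PC-specific absorption at 620 nm, m^2/mg.
    pc_band_fwhm
        Width of the phycocyanin absorption band, nm.
    """

    # (center nm, fwhm nm, amplitude m^2/mg) per end member, excluding PC
    ALGAL_BANDS = ((440.0, 60.0, 0.020), (490.0, 50.0, 0.008), (675.0, 25.0, 0.016))
    CYANO_BANDS = ((440.0, 60.0, 0.018), (650.0, 30.0, 0.004), (675.0, 25.0, 0.014))

    def __init__(self, grid: np.ndarray, epsilon: float = 0.24,
                 a_star_pc_base: float = 0.0095, pc_band_fwhm: float = 30.0):
        self.grid = validate_grid(grid)
        self.epsilon = float(epsilon)
        self.a_star_pc_base = float(a_star_pc_base)
        self.pc_band_fwhm = float(pc_band_fwhm)
        self._pc_band = gaussian_band(self.grid, 620.0, pc_band_fwhm)
        self.a_star_alg = self._calibrated(self.ALGAL_BANDS)
        self.a_star_cy_base = self._calibrated(self.CYANO_BANDS)
        # net PC-band weight surviving the chlorophyll correction
        g620 = self._interp(self._pc_band, 620.0)
        g665 = self._interp(self._pc_band, 665.0)
        self.pc_band_gain = g620 - self.epsilon * g665

    def _interp(self, spectrum: np.ndarray, wl: float) -> float:
        return float(np.interp(wl, self.grid, spectrum))

    def _calibrated(self, bands) -> np.ndarray:
        """Sum the Gaussian bands, then pin a(620) = eps * a(665) exactly."""
        base = np.zeros_like(self.grid)
        for center, fwhm, amp in bands:
            base += amp * gaussian_band(self.grid, center, fwhm)
        a620 = self._interp(base, 620.0)
        a665 = self._interp(base, 665.0)
        g620 = self._interp(self._pc_band, 620.0)
        g665 = self._interp(self._pc_band, 665.0)
        delta = (self.epsilon * a665 - a620) / (g620 - self.epsilon * g665)
        out = base + delta * self._pc_band
        if np.any(out < -1e-12):
            raise ValueError("pigment-basis calibration produced negative absorption")
        return np.clip(out, 0.0, None)

    def a_star_cy(self, pc_to_chl: float) -> np.ndarray:
        """Cyanobacterial specific absorption including the PC band, m^2/mg."""
        return self.a_star_cy_base + self.a_star_pc_base * float(pc_to_chl) * self._pc_band

    def a_star_pc_620(self, car: float) -> float:
        """PC-specific absorption at 620 nm, m^2/mg, increasing with CAR."""
        return self.a_star_pc_base * (0.5 + 0.5 * float(car))
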