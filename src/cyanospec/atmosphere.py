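"""Analytic single-scattering atmosphere.

Closed forms for the molecular (Rayleigh) and aerosol path reflectances,
two-way beam transmittances, and the sampled atmosphere state used when
propagating water-leaving reflectance to top-of-atmosphere reflectance.
Gaseous absorption lines are omitted; they do not affect band logic in the
500-780 nm window at this emulation fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AtmosphereState",
    "rayleigh_optical_thickness",
    "rayleigh_phase",
    "path_reflectance",
    "henyey_greenstein",
    "aerosol_optical_thickness",
    "two_way_transmittance",
    "sample_atmosphere",
]

#: Aerosol single-scattering albedo and Henyey-Greenstein asymmetry.
AEROSOL_SSA = 0.95
AEROSOL_ASYMMETRY = 0.7


@dataclass(frozen=True)
class AtmosphereState:
    """One sampled atmosphere + viewing geometry.

    tau_a_550 : aerosol optical depth at 550 nm (>= 0)
    angstrom : Angstrom exponent of the aerosol spectral slope
    theta_s, theta_v : solar and view zenith angles, degrees
    adjacency_weight : fraction of the diffuse path filled by vegetation
        stray light (the adjacency effect), in [0, 0.3]
    """

    tau_a_550: float
    angstrom: float
    theta_s: float
    theta_v: float = 0.0
    adjacency_weight: float = 0.0

    def __post_init__(self):
        if self.tau_a_550 < 0:
            raise ValueError("tau_a_550 must be >= 0")
        if not (0.0 <= self.theta_s < 90.0 and 0.0 <= self.theta_v < 90.0):
            raise ValueError("zenith angles must be in [0, 90) degrees")
        if not (0.0 <= self.adjacency_weight <= 0.3 + 1e-12):
            raise ValueError("adjacency_weight must be in [0, 0.3]")

    @property
    def mu_s(self) -> float:
        return float(np.cos(np.radians(self.theta_s)))

    @property
    def mu_v(self) -> float:
        return float(np.cos(np.radians(self.theta_v)))

    @property
    def cos_scatter(self) -> float:
        # backscattering geometry; azimuth dependence dropped (relative
        # azimuth fixed at 90 degrees)
        return -self.mu_s * self.mu_v


def rayleigh_optical_thickness(grid_nm: np.ndarray) -> np.ndarray:
    """Rayleigh optical thickness tau_r(lambda); lambda supplied in nm."""
    lam_um = np.asarray(grid_nm, dtype=float) / 1000.0
    return 0.008569 * lam_um ** -4 * (1.0 + 0.0113 * lam_um ** -2 + 0.00013 * lam_um ** -4)


def rayleigh_phase(cos_scatter: float) -> float:
    """Rayleigh scattering phase function (3/4)(1 + cos^2 Theta)."""
    return 0.75 * (1.0 + cos_scatter ** 2)


def henyey_greenstein(cos_scatter: float, g: float = AEROSOL_ASYMMETRY) -> float:
    """Henyey-Greenstein phase function."""
    return (1.0 - g * g) / (1.0 + g * g - 2.0 * g * cos_scatter) ** 1.5


def path_reflectance(tau, phase, mu_s: float, mu_v: float):
    """Single-scattering path reflectance tau * P / (4 mu_s mu_v)."""
    return np.asarray(tau, dtype=float) * phase / (4.0 * mu_s * mu_v)


def aerosol_optical_thickness(grid_nm: np.ndarray, tau_a_550: float, angstrom: float) -> np.ndarray:
    """Angstrom power law tau_a(lambda) = tau_a(550) (lambda/550)^-alpha."""
    grid = np.asarray(grid_nm, dtype=float)
    return tau_a_550 * (grid / 550.0) ** (-angstrom)


def two_way_transmittance(tau, mu_s: float, mu_v: float):
    """exp(-tau/2 * (1/mu_s + 1/mu_v)): diffuse two-way transmittance."""
    tau = np.asarray(tau, dtype=float)
    return np.exp(-0.5 * tau * (1.0 / mu_s + 1.0 / mu_v))


def sample_atmosphere(rng: np.random.Generator,
                      tau_a_550_range=(0.02, 0.40),
                      angstrom_range=(0.5, 2.0),
                      theta_s_range=(20.0, 60.0),
                      adjacency_range=(0.0, 0.3)) -> AtmosphereState:
    """Draw one randomized atmosphere (uniform priors, nadir view)."""
    return AtmosphereState(
        tau_a_550=float(rng.uniform(*tau_a_550_range)),
        angstrom=float(rng.uniform(*angstrom_range)),
        theta_s=float(rng.uniform(*theta_s_range)),
        theta_v=0.0,
        adjacency_weight=float(rng.uniform(*adjacency_range)),
    )
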