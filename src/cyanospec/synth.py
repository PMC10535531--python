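"""Labeled synthetic inland-water spectra.

Emulates the statistical structure of a large radiative-transfer training
set for cyanobacteria detection: seven optical water types from oligotrophic
to hypereutrophic scum, mixed cyanobacteria-algae populations controlled by
the cyanobacteria:algae ratio (CAR), phycocyanin labels derived from
phytoplankton absorption at 620 nm, separate Chl-a fluorescence emission at
685 and 730 nm with a reduced cyanobacterial quantum yield, and for each
water two randomized atmospheres yielding top-of-atmosphere (TOAR) and
bottom-of-Rayleigh (BRR) variants of every water-leaving (R_rs) spectrum.

The forward model is a Gordon-style quadratic reflectance closure plus an
analytic single-scattering atmosphere — a desk-scale emulator of the
dataset's statistical structure, not a numerical radiative-transfer code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import optics
from .atmosphere import (
    AtmosphereState,
    aerosol_optical_thickness,
    henyey_greenstein,
    path_reflectance,
    rayleigh_optical_thickness,
    rayleigh_phase,
    sample_atmosphere,
    two_way_transmittance,
)

__all__ = [
    "WATER_TYPES",
    "DATA_TYPES",
    "WaterState",
    "IOPSet",
    "SpectrumRecord",
    "SpectralDataset",
    "GeneratorConfig",
    "sample_water_state",
    "build_iops",
    "phycocyanin_label",
    "fluorescence_term",
    "rrs_forward",
    "toa_forward",
    "brr_from_toar",
    "generate_dataset",
]

WATER_TYPES = (
    "oligotrophic",
    "mixed_eutrophic",
    "sediment_dominated",
    "cdom_dominated",
    "eukaryote_bloom",
    "cyano_bloom",
    "scum",
)

DATA_TYPES = ("RRS", "TOAR", "BRR")

#: Chlorophyll-correction factor in the PC decomposition at 620 nm.
PC_EPSILON = 0.24


@dataclass(frozen=True)
class WaterState:
    """Biogeophysical labels and optical parameters of one simulated water.

    chl_a, pc in ug/L; car (cyanobacterial fraction of phytoplankton
    biomass) and scum_fraction in [0, 1]; cdom_440 in 1/m; nap (non-algal
    particles) in g/m^3; fluor_yield is the dimensionless Chl-a fluorescence
    quantum-yield proxy in [0, 0.02].  cdom_slope (1/nm) and bbp_exponent
    (dimensionless) are the per-water spectral shape parameters of colored
    dissolved organic matter absorption and particulate backscattering.
    """

    chl_a: float
    pc: float
    car: float
    pc_to_chl: float
    water_type: str
    cdom_440: float
    nap: float
    fluor_yield: float
    scum_fraction: float = 0.0
    cdom_slope: float = 0.015
    bbp_exponent: float = 1.0

    def __post_init__(self):
        if self.water_type not in WATER_TYPES:
            raise ValueError(
                f"unknown water_type {self.water_type!r}; valid: {WATER_TYPES}")
        if self.chl_a <= 0:
            raise ValueError("chl_a must be > 0")
        if not 0.0 <= self.car <= 1.0:
            raise ValueError("car must be in [0, 1]")
        for name in ("pc", "pc_to_chl", "cdom_440", "nap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.fluor_yield <= 0.02 + 1e-12:
            raise ValueError("fluor_yield must be in [0, 0.02]")
        if not 0.0 <= self.scum_fraction <= 1.0:
            raise ValueError("scum_fraction must be in [0, 1]")


@dataclass(frozen=True)
class IOPSet:
    """Inherent optical properties of one water on a wavelength grid.

    Absorption (a_*) and backscattering (bb_*) spectra in 1/m; a_pc_620 is
    the phycocyanin part of phytoplankton absorption at 620 nm and
    a_star_pc_620 the PC-specific absorption there (m^2/mg).
    """

    grid: np.ndarray
    a_w: np.ndarray
    a_ph: np.ndarray
    a_cdom: np.ndarray
    a_nap: np.ndarray
    bb_w: np.ndarray
    bb_p: np.ndarray
    a_pc_620: float
    a_star_pc_620: float

    @property
    def a_total(self) -> np.ndarray:
        return self.a_w + self.a_ph + self.a_cdom + self.a_nap

    @property
    def bb_total(self) -> np.ndarray:
        return self.bb_w + self.bb_p


@dataclass(frozen=True)
class SpectrumRecord:
    """One labeled spectrum: RRS (sr^-1) or TOAR/BRR (dimensionless)."""

    data_type: str
    values: np.ndarray
    labels: WaterState
    atmosphere: Optional[AtmosphereState] = None

    def __post_init__(self):
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"data_type must be one of {DATA_TYPES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")


@dataclass
class SpectralDataset:
    """A collection of spectra sharing one wavelength grid."""

    grid: np.ndarray
    records: list
    seed: int
    config_hash: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def filter(self, data_type: str) -> "SpectralDataset":
        if data_type not in DATA_TYPES:
            raise ValueError(f"data_type must be one of {DATA_TYPES}")
        recs = [r for r in self.records if r.data_type == data_type]
        return SpectralDataset(self.grid, recs, self.seed, self.config_hash)

    def spectra(self) -> np.ndarray:
        """All spectra stacked as an (n_records, n_grid) matrix."""
        return np.stack([r.values for r in self.records])

    def labels_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = dataclasses.asdict(r.labels)
            row["data_type"] = r.data_type
            rows.append(row)
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Wide table: data_type, label columns, then one wl_<nm> column each."""
        lab = self.labels_frame()
        wl_cols = [f"wl_{w:g}" for w in self.grid]
        spec = pd.DataFrame(self.spectra(), columns=wl_cols)
        return pd.concat([lab[["data_type"]], lab.drop(columns="data_type"), spec], axis=1)

    def to_csv(self, path) -> None:
        """Write the wide CSV plus a JSON sidecar (grid, seed, config hash)."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "grid_nm": [float(w) for w in self.grid],
            "seed": int(self.seed),
            "config_hash": self.config_hash,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path) -> "SpectralDataset":
        path = Path(path)
        frame = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        grid = np.asarray(sidecar["grid_nm"], dtype=float)
        wl_cols = [f"wl_{w:g}" for w in grid]
        label_cols = [c for c in frame.columns if c not in wl_cols and c != "data_type"]
        records = []
        for _, row in frame.iterrows():
            state = WaterState(**{c: row[c] for c in label_cols})
            records.append(SpectrumRecord(
                data_type=row["data_type"],
                values=row[wl_cols].to_numpy(dtype=float),
                labels=state,
            ))
        return cls(grid, records, int(sidecar["seed"]), sidecar.get("config_hash", ""))


# per-type sampling ranges; "log" ranges are log-uniform
_TYPE_RANGES = {
    #                 chl (log)      car            nap g/m^3 (log)  cdom 1/m (log)
    "oligotrophic":      {"chl": (0.1, 3.0), "car": (0.0, 1.0), "nap": (0.05, 2.0), "cdom": (0.02, 0.5)},
    "mixed_eutrophic":   {"chl": (3.0, 30.0), "car": (0.0, 1.0), "nap": (0.5, 20.0), "cdom": (0.05, 2.0)},
    "sediment_dominated": {"chl": (1.0, 20.0), "car": (0.0, 1.0), "nap": (20.0, 200.0), "cdom": (0.05, 2.0)},
    "cdom_dominated":    {"chl": (1.0, 20.0), "car": (0.0, 1.0), "nap": (0.5, 20.0), "cdom": (1.0, 10.0)},
    "eukaryote_bloom":   {"chl": (30.0, 1000.0), "car": (0.0, 0.3), "nap": (0.5, 20.0), "cdom": (0.05, 2.0)},
    "cyano_bloom":       {"chl": (30.0, 1000.0), "car": (0.7, 1.0), "nap": (0.5, 20.0), "cdom": (0.05, 2.0)},
    "scum":              {"chl": (1000.0, 10000.0), "car": (0.7, 1.0), "nap": (0.5, 20.0), "cdom": (0.05, 2.0)},
}


@dataclass
class GeneratorConfig:
    """Tunable knobs of the synthetic-water generator.

    mixture : per-water-type sampling weights (must sum to 1)
    data_types : which record variants to emit per water
    n_atmospheres : randomized atmospheres per water (TOAR+BRR pair each)
    g0, g1 : coefficients of the quadratic reflectance closure
    epsilon : chlorophyll correction of the PC decomposition
    a_star_pc_base : base PC-specific absorption at 620 nm, m^2/mg
    fluor_scale : Rrs amplitude (sr^-1) of the 685 nm emission per unit
        chl_a * fluor_yield
    """

    mixture: dict = field(default_factory=lambda: {t: 1.0 / 7.0 for t in WATER_TYPES})
    data_types: tuple = DATA_TYPES
    n_atmospheres: int = 2
    g0: float = 0.0949
    g1: float = 0.0794
    epsilon: float = PC_EPSILON
    a_star_pc_base: float = 0.0095
    pc_band_fwhm: float = 30.0
    fluor_scale: float = 0.001
    cdom_slope_range: tuple = (0.010, 0.020)
    bbp_exponent_range: tuple = (0.3, 1.5)
    pc_to_chl_range: tuple = (0.1, 3.0)
    fluor_yield_range: tuple = (0.0, 0.02)
    scum_fraction_range: tuple = (0.3, 1.0)
    bb_star_chl: float = 0.0004   # m^2/mg at 550 nm
    bb_star_nap: float = 0.005    # m^2/g at 550 nm
    tau_a_550_range: tuple = (0.02, 0.40)
    angstrom_range: tuple = (0.5, 2.0)
    theta_s_range: tuple = (20.0, 60.0)
    adjacency_range: tuple = (0.0, 0.3)
    type_ranges: dict = field(default_factory=lambda: {k: dict(v) for k, v in _TYPE_RANGES.items()})

    def __post_init__(self):
        unknown = set(self.mixture) - set(WATER_TYPES)
        if unknown:
            raise ValueError(f"unknown water types in mixture: {sorted(unknown)}")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1 (got {total})")
        bad = set(self.data_types) - set(DATA_TYPES)
        if bad:
            raise ValueError(f"unknown data types: {sorted(bad)}")

    def bases(self, grid: np.ndarray) -> optics.PigmentBases:
        return optics.PigmentBases(grid, epsilon=self.epsilon,
                                   a_star_pc_base=self.a_star_pc_base,
                                   pc_band_fwhm=self.pc_band_fwhm)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["data_types"] = list(self.data_types)
        return d

    def hash(self) -> str:
        return hashlib.sha1(json.dumps(self.to_dict(), sort_keys=True, default=list)
                            .encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("data_types",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _sample_state(rng: np.random.Generator, water_type: str,
                  config: GeneratorConfig, bases: optics.PigmentBases) -> WaterState:
    """Draw one water state; pc is set from its own 620 nm decomposition."""
    ranges = config.type_ranges[water_type]
    chl = _loguniform(rng, *ranges["chl"])
    car = float(rng.uniform(*ranges["car"]))
    nap = _loguniform(rng, *ranges["nap"])
    cdom = _loguniform(rng, *ranges["cdom"])
    pc_to_chl = _loguniform(rng, *config.pc_to_chl_range)
    fluor_yield = float(rng.uniform(*config.fluor_yield_range))
    scum_fraction = (float(rng.uniform(*config.scum_fraction_range))
                     if water_type == "scum" else 0.0)
    state = WaterState(
        chl_a=chl, pc=0.0, car=car, pc_to_chl=pc_to_chl, water_type=water_type,
        cdom_440=cdom, nap=nap, fluor_yield=fluor_yield,
        scum_fraction=scum_fraction,
        cdom_slope=float(rng.uniform(*config.cdom_slope_range)),
        bbp_exponent=float(rng.uniform(*config.bbp_exponent_range)),
    )
    # close the loop: the PC label is what the decomposition of this water's
    # own phytoplankton absorption returns
    iops = build_iops(state, bases.grid, config=config, bases=bases)
    pc = phycocyanin_label(state, iops, epsilon=config.epsilon)
    return dataclasses.replace(state, pc=pc)


def sample_water_state(seed: int, water_type: str = "random",
                       config: Optional[GeneratorConfig] = None,
                       grid: Optional[np.ndarray] = None) -> WaterState:
    """Draw one water state deterministically from a seed.

    water_type "random" draws the type from the configured mixture.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    config = config or GeneratorConfig()
    grid = optics.validate_grid(grid if grid is not None else optics.default_grid())
    rng = np.random.default_rng(seed)
    if water_type == "random":
        types = sorted(config.mixture)
        weights = np.array([config.mixture[t] for t in types])
        water_type = str(rng.choice(types, p=weights / weights.sum()))
    elif water_type not in WATER_TYPES:
        raise ValueError(f"unknown water_type {water_type!r}; valid: {WATER_TYPES}")
    return _sample_state(rng, water_type, config, config.bases(grid))


def build_iops(state: WaterState, grid: np.ndarray,
               config: Optional[GeneratorConfig] = None,
               bases: Optional[optics.PigmentBases] = None) -> IOPSet:
    """Assemble the water's absorption and backscattering spectra.

    Phytoplankton absorption mixes the two end-member bases by CAR:
    a_ph = chl_a * [(1-car) a*_alg + car a*_cy(pc_to_chl)].
    """
    grid = optics.validate_grid(grid)
    if grid[0] > 400.0 or grid[-1] < 800.0:
        raise ValueError("grid must cover 400-800 nm")
    config = config or GeneratorConfig()
    bases = bases or config.bases(grid)
    a_star = (1.0 - state.car) * bases.a_star_alg + state.car * bases.a_star_cy(state.pc_to_chl)
    a_ph = state.chl_a * a_star
    a_cdom = state.cdom_440 * np.exp(-state.cdom_slope * (grid - 440.0))
    a_nap = state.nap * 0.03 * np.exp(-0.011 * (grid - 440.0))
    # particulate backscattering: power law with cyanobacteria-enhanced NIR
    nir_boost = 1.0 + state.car / (1.0 + np.exp(-(grid - 700.0) / 15.0))
    bb_p = ((config.bb_star_chl * state.chl_a + config.bb_star_nap * state.nap)
            * (550.0 / grid) ** state.bbp_exponent * nir_boost)
    a_star_pc_620 = bases.a_star_pc_620(state.car)
    a_pc_620 = (state.chl_a * state.car * bases.a_star_pc_base
                * state.pc_to_chl * bases.pc_band_gain)
    return IOPSet(
        grid=grid,
        a_w=optics.water_absorption(grid),
        a_ph=a_ph,
        a_cdom=a_cdom,
        a_nap=a_nap,
        bb_w=optics.water_backscatter(grid),
        bb_p=bb_p,
        a_pc_620=a_pc_620,
        a_star_pc_620=a_star_pc_620,
    )


def phycocyanin_label(state: WaterState, iops: IOPSet,
                      epsilon: float = PC_EPSILON) -> float:
    """Phycocyanin concentration (ug/L) from the 620 nm decomposition.

    PC = [a_ph(620) - eps * a_ph(665)] / a*_pc(620): phytoplankton
    absorption at 620 nm with the chlorophyll contribution removed, divided
    by the PC-specific absorption coefficient.
    """
    if iops.a_star_pc_620 <= 0:
        raise ValueError("a_star_pc_620 must be > 0")
    a620 = float(np.interp(620.0, iops.grid, iops.a_ph))
    a665 = float(np.interp(665.0, iops.grid, iops.a_ph))
    return max((a620 - epsilon * a665) / iops.a_star_pc_620, 0.0)


def fluorescence_term(state: WaterState, iops: IOPSet, grid: np.ndarray,
                      fluor_scale: float = 0.001) -> np.ndarray:
    """Additive Rrs contribution of sun-induced Chl-a fluorescence.

    Two Gaussian emissions at 685 nm (FWHM 25 nm) and 730 nm (FWHM 50 nm)
    with a secondary/primary amplitude ratio of 0.2.  The amplitude scales
    with chl_a * fluor_yield * (1 - 0.7 car): cyanobacteria hold most Chl-a
    in weakly fluorescing photosystem I, so their apparent yield is reduced.
    """
    grid = np.asarray(grid, dtype=float)
    amp = fluor_scale * state.chl_a * state.fluor_yield * (1.0 - 0.7 * state.car)
    return amp * (optics.gaussian_band(grid, 685.0, 25.0)
                  + 0.2 * optics.gaussian_band(grid, 730.0, 50.0))


def rrs_forward(iops: IOPSet, state: WaterState, grid: np.ndarray,
                config: Optional[GeneratorConfig] = None) -> SpectrumRecord:
    """Water-leaving remote-sensing reflectance of one water, sr^-1."""
    config = config or GeneratorConfig()
    grid = np.asarray(grid, dtype=float)
    a = iops.a_total
    bb = iops.bb_total
    if np.any(a < 0) or np.any(bb < 0):
        raise ValueError("negative inherent optical properties")
    u = bb / (a + bb)
    rrs = optics.reflectance_from_u(u, config.g0, config.g1)
    rrs = rrs + fluorescence_term(state, iops, grid, config.fluor_scale)
    if state.scum_fraction > 0:
        # reflectance closure fails for floating scum; blend toward a
        # vegetation-like red-edge spectrum instead
        veg = optics.vegetation_spectrum(grid) / np.pi
        rrs = (1.0 - state.scum_fraction) * rrs + state.scum_fraction * veg
    return SpectrumRecord("RRS", rrs, state)


def toa_forward(rrs: SpectrumRecord, atm: AtmosphereState,
                grid: np.ndarray) -> SpectrumRecord:
    """Propagate R_rs to top-of-atmosphere reflectance (dimensionless).

    rho_t = rho_r + rho_a + t * pi * Rrs + t * w_adj * rho_veg, with
    single-scattering Rayleigh and aerosol path terms and two-way beam
    transmittance t = t_r * t_a.  The adjacency term injects vegetation
    stray light into the diffuse path.
    """
    if rrs.data_type != "RRS":
        raise ValueError("toa_forward expects an RRS record")
    grid = np.asarray(grid, dtype=float)
    tau_r = rayleigh_optical_thickness(grid)
    tau_a = aerosol_optical_thickness(grid, atm.tau_a_550, atm.angstrom)
    rho_r = path_reflectance(tau_r, rayleigh_phase(atm.cos_scatter), atm.mu_s, atm.mu_v)
    rho_a = path_reflectance(
        tau_a * 0.95 * henyey_greenstein(atm.cos_scatter), 1.0, atm.mu_s, atm.mu_v)
    t_r = two_way_transmittance(tau_r, atm.mu_s, atm.mu_v)
    t_a = two_way_transmittance(tau_a, atm.mu_s, atm.mu_v)
    t = t_r * t_a
    veg = optics.vegetation_spectrum(grid)
    toar = rho_r + rho_a + t * np.pi * rrs.values + t * atm.adjacency_weight * veg
    return SpectrumRecord("TOAR", toar, rrs.labels, atmosphere=atm)


def brr_from_toar(toar: SpectrumRecord, atm: AtmosphereState,
                  grid: np.ndarray) -> SpectrumRecord:
    """Rayleigh-corrected (bottom-of-Rayleigh) reflectance.

    BRR = (TOAR - rho_r) / t_r removes the molecular path and transmittance
    while neglecting aerosols; with an aerosol-free, adjacency-free
    atmosphere it recovers pi * Rrs exactly.
    """
    if toar.data_type != "TOAR":
        raise ValueError("brr_from_toar expects a TOAR record")
    grid = np.asarray(grid, dtype=float)
    tau_r = rayleigh_optical_thickness(grid)
    rho_r = path_reflectance(tau_r, rayleigh_phase(atm.cos_scatter), atm.mu_s, atm.mu_v)
    t_r = two_way_transmittance(tau_r, atm.mu_s, atm.mu_v)
    if np.any(t_r <= 0):
        raise ValueError("Rayleigh transmittance must be > 0")
    return SpectrumRecord("BRR", (toar.values - rho_r) / t_r, toar.labels, atmosphere=atm)


def generate_dataset(n_waters: int, seed: int,
                     config: Optional[GeneratorConfig] = None,
                     grid: Optional[np.ndarray] = None) -> SpectralDataset:
    """Generate the labeled dataset: per water 1 RRS record and, for each of
    n_atmospheres randomized atmospheres, one TOAR and one BRR record.

    Deterministic given (n_waters, seed, config).
    """
    if n_waters < 1:
        raise ValueError("n_waters must be >= 1")
    config = config or GeneratorConfig()
    grid = optics.validate_grid(grid if grid is not None else optics.default_grid())
    bases = config.bases(grid)
    rng = np.random.default_rng(seed)
    types = sorted(config.mixture)
    weights = np.array([config.mixture[t] for t in types])
    records = []
    for _ in range(n_waters):
        water_type = str(rng.choice(types, p=weights / weights.sum()))
        state = _sample_state(rng, water_type, config, bases)
        iops = build_iops(state, grid, config=config, bases=bases)
        rrs = rrs_forward(iops, state, grid, config=config)
        if "RRS" in config.data_types:
            records.append(rrs)
        for _ in range(config.n_atmospheres):
            atm = sample_atmosphere(
                rng,
                tau_a_550_range=config.tau_a_550_range,
                angstrom_range=config.angstrom_range,
                theta_s_range=config.theta_s_range,
                adjacency_range=config.adjacency_range,
            )
            if not ({"TOAR", "BRR"} & set(config.data_types)):
                continue
            toar = toa_forward(rrs, atm, grid)
            if "TOAR" in config.data_types:
                records.append(toar)
            if "BRR" in config.data_types:
                records.append(brr_from_toar(toar, atm, grid))
    return SpectralDataset(grid, records, int(seed), config.hash())
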