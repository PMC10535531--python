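"""Synthetic water generator: sampling, optics, forward models, dataset."""

import dataclasses

import numpy as np
import pytest

import cyanospec as cs
from cyanospec.atmosphere import (aerosol_optical_thickness, henyey_greenstein,
                                  path_reflectance, rayleigh_optical_thickness,
                                  rayleigh_phase, two_way_transmittance)
from cyanospec.optics import PigmentBases, reflectance_from_u
from cyanospec.synth import IOPSet, _sample_state


@pytest.fixture(scope="module")
def gen_config():
    return cs.GeneratorConfig()


class TestWaterStateSampling:
    def test_seeded_determinism(self):
        a = cs.sample_water_state(7, "mixed_eutrophic")
        b = cs.sample_water_state(7, "mixed_eutrophic")
        assert a == b

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="water_type"):
            cs.sample_water_state(0, "seawater")

    def test_car_bounded_and_cyano_blooms_cyano_dominated(self, grid, gen_config):
        rng = np.random.default_rng(0)
        bases = gen_config.bases(grid)
        cars = [_sample_state(rng, "cyano_bloom", gen_config, bases).car
                for _ in range(1000)]
        assert all(0.0 <= c <= 1.0 for c in cars)
        assert np.mean(cars) >= 0.7  # cyano blooms are cyanobacteria-dominated

    def test_random_type_car_bounds(self):
        states = [cs.sample_water_state(s, "random") for s in range(200)]
        assert all(0.0 <= st.car <= 1.0 for st in states)

    def test_zero_car_means_zero_pc(self, grid):
        st = cs.sample_water_state(3, "eukaryote_bloom")
        st = dataclasses.replace(st, car=0.0)
        iops = cs.build_iops(st, grid)
        assert cs.phycocyanin_label(st, iops) == 0.0


class TestIOPs:
    def test_pure_water_limit(self, grid):
        st = cs.WaterState(chl_a=1e-12, pc=0.0, car=0.0, pc_to_chl=1.0,
                           water_type="oligotrophic", cdom_440=0.0, nap=0.0,
                           fluor_yield=0.0)
        iops = cs.build_iops(st, grid)
        assert np.allclose(iops.a_total, iops.a_w, atol=1e-10)

    def test_mixing_formula_at_675(self, grid, gen_config):
        st = cs.WaterState(chl_a=10.0, pc=0.0, car=0.5, pc_to_chl=1.0,
                           water_type="mixed_eutrophic", cdom_440=0.0, nap=0.0,
                           fluor_yield=0.0)
        iops = cs.build_iops(st, grid, config=gen_config)
        bases = gen_config.bases(grid)
        i675 = int(np.searchsorted(grid, 675.0))
        expected = 10.0 * (0.5 * bases.a_star_alg[i675]
                           + 0.5 * bases.a_star_cy(1.0)[i675])
        assert iops.a_ph[i675] == pytest.approx(expected, rel=1e-12)

    def test_all_components_nonnegative(self, grid):
        for seed in range(20):
            st = cs.sample_water_state(seed, "random")
            iops = cs.build_iops(st, grid)
            for name in ("a_w", "a_ph", "a_cdom", "a_nap", "bb_w", "bb_p"):
                assert np.min(getattr(iops, name)) >= 0.0, name

    def test_monotone_in_pigments(self, grid):
        base = cs.sample_water_state(5, "cyano_bloom")
        iops = cs.build_iops(base, grid)
        i620 = int(np.searchsorted(grid, 620.0))
        i675 = int(np.searchsorted(grid, 675.0))
        more_pc = cs.build_iops(
            dataclasses.replace(base, pc_to_chl=base.pc_to_chl * 2), grid)
        assert more_pc.a_ph[i620] > iops.a_ph[i620]
        more_chl = cs.build_iops(
            dataclasses.replace(base, chl_a=base.chl_a * 2), grid)
        assert more_chl.a_ph[i675] > iops.a_ph[i675]

    def test_grid_must_cover_range(self):
        st = cs.sample_water_state(1, "oligotrophic")
        with pytest.raises(ValueError, match="400-800"):
            cs.build_iops(st, np.arange(500.0, 700.0))


class TestPhycocyaninLabel:
    def test_round_trip(self, grid):
        for seed in range(30):
            st = cs.sample_water_state(seed, "random")
            lab = cs.phycocyanin_label(st, cs.build_iops(st, grid))
            assert lab == pytest.approx(st.pc, rel=1e-6, abs=1e-12)

    def test_hand_decomposition(self, grid):
        # a_ph(620)=0.5, a_ph(665)=0.4, eps=0.24, a*_pc=0.007
        # -> (0.5 - 0.096) / 0.007 = 57.714 ug/L
        a_ph = np.interp(grid, [400.0, 620.0, 665.0, 800.0],
                         [0.0, 0.5, 0.4, 0.0])
        zeros = np.zeros_like(grid)
        iops = IOPSet(grid=grid, a_w=zeros, a_ph=a_ph, a_cdom=zeros,
                      a_nap=zeros, bb_w=zeros, bb_p=zeros,
                      a_pc_620=0.0, a_star_pc_620=0.007)
        st = cs.sample_water_state(0, "cyano_bloom")
        assert cs.phycocyanin_label(st, iops) == pytest.approx(57.7142857, rel=1e-6)

    def test_nonpositive_specific_absorption_rejected(self, grid):
        st = cs.sample_water_state(0, "cyano_bloom")
        iops = cs.build_iops(st, grid)
        bad = dataclasses.replace(iops, a_star_pc_620=0.0)
        with pytest.raises(ValueError, match="a_star_pc_620"):
            cs.phycocyanin_label(st, bad)

    def test_basis_calibration_cancels_algal_pigments(self, grid):
        bases = PigmentBases(grid)
        a620 = np.interp(620.0, grid, bases.a_star_alg)
        a665 = np.interp(665.0, grid, bases.a_star_alg)
        assert a620 == pytest.approx(0.24 * a665, rel=1e-9)


class TestReflectanceForward:
    def test_quadratic_closure_hand_case(self):
        # u=0.1: rrs = 0.0949*0.1 + 0.0794*0.01 = 0.010284
        # Rrs = 0.52*0.010284 / (1 - 1.7*0.010284) = 0.005443
        assert reflectance_from_u(0.1) == pytest.approx(0.0054428, abs=1e-6)

    def test_no_scattering_no_signal(self):
        assert reflectance_from_u(0.0) == 0.0

    def test_rrs_nonnegative(self, grid):
        for seed in range(15):
            st = cs.sample_water_state(seed, "random")
            rec = cs.rrs_forward(cs.build_iops(st, grid), st, grid)
            assert rec.data_type == "RRS"
            assert np.min(rec.values) >= 0.0

    def test_scum_blends_toward_red_edge(self, grid):
        st = cs.sample_water_state(2, "scum")
        assert st.scum_fraction > 0
        rec = cs.rrs_forward(cs.build_iops(st, grid), st, grid)
        i550 = int(np.searchsorted(grid, 550.0))
        i760 = int(np.searchsorted(grid, 760.0))
        assert rec.values[i760] > rec.values[i550]  # vegetation-like red edge


class TestFluorescence:
    def _state(self, car, fluor_yield=0.01):
        return cs.WaterState(chl_a=50.0, pc=0.0, car=car, pc_to_chl=1.0,
                             water_type="mixed_eutrophic", cdom_440=0.1,
                             nap=1.0, fluor_yield=fluor_yield)

    def test_zero_yield_zero_spectrum(self, grid):
        st = self._state(car=0.0, fluor_yield=0.0)
        term = cs.fluorescence_term(st, cs.build_iops(st, grid), grid)
        assert np.all(term == 0.0)

    def test_primary_peak_at_685(self, grid):
        st = self._state(car=0.0)
        term = cs.fluorescence_term(st, cs.build_iops(st, grid), grid)
        assert abs(grid[np.argmax(term)] - 685.0) <= 1.0

    def test_secondary_amplitude_ratio(self, grid):
        st = self._state(car=0.0)
        term = cs.fluorescence_term(st, cs.build_iops(st, grid), grid)
        i685 = int(np.searchsorted(grid, 685.0))
        i730 = int(np.searchsorted(grid, 730.0))
        # the emission bands overlap slightly, so the ratio of the summed
        # spectrum sits just off the configured 0.2 component ratio
        assert term[i730] / term[i685] == pytest.approx(0.2, abs=0.025)

    def test_cyanobacteria_fluoresce_less(self, grid):
        alg = self._state(car=0.0)
        cya = self._state(car=1.0)
        t_alg = cs.fluorescence_term(alg, cs.build_iops(alg, grid), grid)
        t_cya = cs.fluorescence_term(cya, cs.build_iops(cya, grid), grid)
        assert t_cya.max() == pytest.approx(0.3 * t_alg.max(), rel=1e-9)


class TestAtmospherePropagation:
    ATM = cs.AtmosphereState(tau_a_550=0.2, angstrom=1.2, theta_s=40.0,
                             adjacency_weight=0.15)
    CLEAR = cs.AtmosphereState(tau_a_550=0.0, angstrom=1.0, theta_s=40.0,
                               adjacency_weight=0.0)

    def test_rayleigh_single_scattering_hand_case(self):
        mu_s = np.cos(np.radians(30.0))
        assert path_reflectance(0.1, 1.5, mu_s, 1.0) == pytest.approx(
            0.1 * 1.5 / (4.0 * mu_s), rel=1e-12)

    def test_path_only_limit(self, grid):
        st = cs.sample_water_state(4, "oligotrophic")
        zero = cs.SpectrumRecord("RRS", np.zeros_like(grid), st)
        toar = cs.toa_forward(zero, self.CLEAR, grid)
        tau_r = rayleigh_optical_thickness(grid)
        rho_r = path_reflectance(tau_r, rayleigh_phase(self.CLEAR.cos_scatter),
                                 self.CLEAR.mu_s, self.CLEAR.mu_v)
        assert np.allclose(toar.values, rho_r, atol=1e-15)

    def test_toar_exceeds_rayleigh_path(self, grid):
        st = cs.sample_water_state(4, "mixed_eutrophic")
        rrs = cs.rrs_forward(cs.build_iops(st, grid), st, grid)
        toar = cs.toa_forward(rrs, self.ATM, grid)
        tau_r = rayleigh_optical_thickness(grid)
        rho_r = path_reflectance(tau_r, rayleigh_phase(self.ATM.cos_scatter),
                                 self.ATM.mu_s, self.ATM.mu_v)
        assert np.all(toar.values >= rho_r - 1e-15)

    def test_aerosol_free_inversion_recovers_pi_rrs(self, grid):
        st = cs.sample_water_state(9, "cyano_bloom")
        rrs = cs.rrs_forward(cs.build_iops(st, grid), st, grid)
        toar = cs.toa_forward(rrs, self.CLEAR, grid)
        brr = cs.brr_from_toar(toar, self.CLEAR, grid)
        assert np.max(np.abs(brr.values - np.pi * rrs.values)) <= 1e-9

    def test_pure_rayleigh_sky_gives_zero_brr(self, grid):
        st = cs.sample_water_state(4, "oligotrophic")
        tau_r = rayleigh_optical_thickness(grid)
        rho_r = path_reflectance(tau_r, rayleigh_phase(self.ATM.cos_scatter),
                                 self.ATM.mu_s, self.ATM.mu_v)
        toar = cs.SpectrumRecord("TOAR", rho_r, st, atmosphere=self.ATM)
        brr = cs.brr_from_toar(toar, self.ATM, grid)
        assert np.allclose(brr.values, 0.0, atol=1e-15)

    def test_aerosol_residual_matches_substitution(self, grid):
        """BRR - pi*Rrs equals the aerosol + adjacency residual over t_r."""
        st = cs.sample_water_state(4, "mixed_eutrophic")
        rrs = cs.rrs_forward(cs.build_iops(st, grid), st, grid)
        atm = self.ATM
        toar = cs.toa_forward(rrs, atm, grid)
        brr = cs.brr_from_toar(toar, atm, grid)
        i = int(np.searchsorted(grid, 650.0))
        tau_a = aerosol_optical_thickness(grid, atm.tau_a_550, atm.angstrom)[i]
        tau_r = rayleigh_optical_thickness(grid)[i]
        rho_a = path_reflectance(tau_a * 0.95 * henyey_greenstein(atm.cos_scatter),
                                 1.0, atm.mu_s, atm.mu_v)
        t_r = two_way_transmittance(tau_r, atm.mu_s, atm.mu_v)
        t_a = two_way_transmittance(tau_a, atm.mu_s, atm.mu_v)
        veg = float(cs.synth.optics.vegetation_spectrum(grid)[i])
        expected = (rho_a + t_r * t_a * atm.adjacency_weight * veg
                    + (t_r * t_a - t_r) * np.pi * rrs.values[i]) / t_r
        assert brr.values[i] - np.pi * rrs.values[i] == pytest.approx(
            expected, rel=1e-9)


class TestDatasetGeneration:
    def test_record_counts(self):
        ds = cs.generate_dataset(10, seed=5)
        assert len(ds.filter("RRS")) == 10
        assert len(ds.filter("TOAR")) == 20
        assert len(ds.filter("BRR")) == 20

    def test_seeded_determinism_byte_identical(self):
        a = cs.generate_dataset(15, seed=21).to_frame().to_csv(index=False)
        b = cs.generate_dataset(15, seed=21).to_frame().to_csv(index=False)
        assert a == b

    def test_uniform_mixture_counts_within_4_sigma(self, grid):
        gen = dataclasses.replace(cs.GeneratorConfig(), data_types=("RRS",))
        ds = cs.generate_dataset(10_000, seed=77, config=gen, grid=grid)
        counts = ds.labels_frame()["water_type"].value_counts()
        n, p = 10_000, 1.0 / 7.0
        sigma = np.sqrt(n * p * (1 - p))
        for t in cs.WATER_TYPES:
            assert abs(counts[t] - n * p) <= 4 * sigma, t

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            cs.GeneratorConfig(mixture={t: 0.2 for t in cs.WATER_TYPES})

    def test_csv_round_trip(self, tmp_path):
        ds = cs.generate_dataset(4, seed=3)
        ds.to_csv(tmp_path / "ds.csv")
        back = cs.SpectralDataset.from_csv(tmp_path / "ds.csv")
        assert len(back) == len(ds)
        assert np.allclose(back.spectra(), ds.spectra())
        assert back.records[0].labels.chl_a == pytest.approx(
            ds.records[0].labels.chl_a)
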