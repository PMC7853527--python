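import numpy as np
import pytest

from frrfprod.optics import (
    AbsorptionBudget,
    KD_MINIMUM,
    a_cdom,
    a_nap,
    absorption_budget,
    fit_kd,
    spectral_correction_factor,
    spectral_irradiance,
)
from frrfprod.spectra import SpectrumOnGrid, aphy_star, default_grid, generate_sunlight_spectrum


class TestFitKd:
    def test_single_layer_recovery_from_field_profile(self):
        # the printed sub-surface PAR / K_d of one sampling date, round-tripped
        z = np.arange(0.0, 20.5, 0.5)
        e = 1630.0 * np.exp(-0.433 * z)
        fit = fit_kd(z, e)
        assert len(fit.kd_per_layer) == 1
        assert fit.kd_per_layer[0] == pytest.approx(0.433, abs=1e-6)

    def test_two_layer_recovery(self):
        # layered attenuation with the printed break at 2 m
        z = np.arange(0.0, 5.01, 0.5)
        e = 650.0 * np.where(
            z <= 2.0,
            np.exp(-1.727 * z),
            np.exp(-1.727 * 2.0 - 0.971 * (z - 2.0)),
        )
        fit = fit_kd(z, e)
        assert len(fit.kd_per_layer) == 2
        assert fit.layer_breaks[1] == pytest.approx(2.0)
        assert fit.kd_per_layer[0] == pytest.approx(1.727, abs=1e-6)
        assert fit.kd_per_layer[1] == pytest.approx(0.971, abs=1e-6)

    def test_constant_light_clamped_and_flagged(self):
        z = np.arange(0.0, 10.0)
        fit = fit_kd(z, np.full_like(z, 500.0))
        assert fit.flagged
        assert fit.kd_per_layer[0] == KD_MINIMUM

    def test_reconstruction_matches_inputs(self):
        z = np.arange(0.0, 12.5, 0.5)
        e = 900.0 * np.exp(-0.6 * z)
        fit = fit_kd(z, e)
        np.testing.assert_allclose(fit.par_at(900.0, z), e, rtol=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_kd([0.0, 1.0], [10.0, 5.0])
        with pytest.raises(ValueError):
            fit_kd([0.0, 1.0, 2.0], [10.0, -5.0, 1.0])

    def test_noisy_recovery_is_unbiased(self, rng):
        z = np.arange(0.0, 15.5, 0.5)
        estimates = []
        for _ in range(50):
            e = 800.0 * np.exp(-0.5 * z) * rng.lognormal(0.0, 0.05, z.size)
            estimates.append(fit_kd(z, e).kd_per_layer[0])
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.01)


class TestAbsorptionModels:
    def test_cdom_anchor_wavelength(self):
        # exponent vanishes at the 320 nm reference
        assert a_cdom(320.0, "north") == pytest.approx(1.03)
        assert a_cdom(320.0, "south") == pytest.approx(2.28)

    def test_cdom_at_440_north(self):
        expected = 1.03 * np.exp(-0.017 * 120.0)
        assert a_cdom(440.0, "north") == pytest.approx(expected, rel=1e-12)
        assert a_cdom(440.0, "north") == pytest.approx(0.134, abs=1e-3)

    def test_basin_ratio_constant_across_wavelengths(self):
        lam = np.linspace(400.0, 700.0, 31)
        ratio = np.asarray(a_cdom(lam, "south")) / np.asarray(a_cdom(lam, "north"))
        np.testing.assert_allclose(ratio, 2.28 / 1.03, rtol=1e-12)

    def test_unknown_basin_rejected(self):
        with pytest.raises(ValueError):
            a_cdom(440.0, "east")

    def test_nap_reference_and_decay(self):
        assert a_nap(440.0) == pytest.approx(0.264)
        assert a_nap(540.0) == pytest.approx(0.264 * np.exp(-0.4), rel=1e-12)
        lam = default_grid()
        values = np.asarray(a_nap(lam))
        assert (np.diff(values) < 0).all()


class TestSpectralIrradiance:
    @pytest.fixture()
    def budget(self):
        return absorption_budget("north", chl=5.0)

    def test_surface_identity(self, budget):
        e0 = generate_sunlight_spectrum(0, "clear", e0=1000.0)
        out = spectral_irradiance(e0, budget, z=0.0)
        np.testing.assert_allclose(out.values, e0.values, rtol=1e-12)

    def test_transparent_water_identity(self):
        grid = default_grid()
        zero = SpectrumOnGrid(grid, np.zeros_like(grid))
        budget = AbsorptionBudget(zero, zero, zero, zero, chl=0.0)
        e0 = generate_sunlight_spectrum(1, "clear", e0=500.0)
        out = spectral_irradiance(e0, budget, z=25.0)
        np.testing.assert_allclose(out.values, e0.values, rtol=1e-12)

    def test_uniform_absorber_closed_form(self):
        grid = default_grid()
        zero = SpectrumOnGrid(grid, np.zeros_like(grid))
        a = SpectrumOnGrid(grid, np.full_like(grid, 0.1))
        budget = AbsorptionBudget(a, zero, zero, zero, chl=0.0)
        flat = SpectrumOnGrid(grid, np.ones_like(grid))
        out = spectral_irradiance(flat, budget, z=10.0)
        np.testing.assert_allclose(out.values, np.exp(-1.0), rtol=1e-12)

    def test_attenuation_multiplicative_in_depth(self, budget):
        e0 = generate_sunlight_spectrum(2, "clear", e0=800.0)
        step1 = spectral_irradiance(e0, budget, z=3.0)
        both = spectral_irradiance(step1, budget, z=4.0)
        direct = spectral_irradiance(e0, budget, z=7.0)
        np.testing.assert_allclose(both.values, direct.values, rtol=1e-10)

    def test_observed_par_rescaling(self, budget):
        e0 = generate_sunlight_spectrum(0, "clear", e0=1200.0)
        out = spectral_irradiance(e0, budget, z=5.0, observed_par=37.5)
        assert out.par_integral() == pytest.approx(37.5, rel=1e-9)


class TestSpectralCorrectionFactor:
    def test_proportional_spectra_give_unity(self):
        aphy = aphy_star("eukaryote")
        e = generate_sunlight_spectrum(0, "clear", e0=100.0)
        for c in (0.01, 1.0, 250.0):
            assert spectral_correction_factor(aphy, e.scaled(c), e) == pytest.approx(
                1.0, rel=1e-12
            )

    def test_flat_absorption_gives_unity(self):
        grid = default_grid()
        flat_a = SpectrumOnGrid(grid, np.full_like(grid, 0.02))
        e1 = generate_sunlight_spectrum(0, "clear", e0=100.0)
        e2 = generate_sunlight_spectrum(5, "overcast", e0=900.0)
        assert spectral_correction_factor(flat_a, e1, e2) == pytest.approx(1.0, rel=1e-12)

    def test_red_shifted_light_with_blue_absorber(self):
        """Blue-peaked a*phy and red-shifted ambient light push the SCF below 1,
        matching an independent literal evaluation of the defining ratio."""
        grid = default_grid()
        aphy = SpectrumOnGrid(grid, np.exp(-0.5 * ((grid - 440.0) / 15.0) ** 2))
        e_frrf = SpectrumOnGrid(grid, np.exp(-0.5 * ((grid - 460.0) / 40.0) ** 2))
        e_insitu = SpectrumOnGrid(grid, np.exp(-0.5 * ((grid - 600.0) / 40.0) ** 2))
        scf = spectral_correction_factor(aphy, e_insitu, e_frrf)
        assert scf < 1.0
        # brute-force literal sums, written out independently
        num = sum(a * e for a, e in zip(aphy.values, e_insitu.values)) * sum(e_frrf.values)
        den = sum(a * e for a, e in zip(aphy.values, e_frrf.values)) * sum(e_insitu.values)
        assert scf == pytest.approx(num / den, rel=1e-12)

    def test_invariant_to_rescaling_any_input(self):
        aphy = aphy_star("cyanobacteria")
        e_insitu = generate_sunlight_spectrum(3, "overcast", e0=50.0)
        e_frrf = generate_sunlight_spectrum(8, "clear", e0=500.0)
        base = spectral_correction_factor(aphy, e_insitu, e_frrf)
        assert spectral_correction_factor(aphy.scaled(7.0), e_insitu, e_frrf) == pytest.approx(base, rel=1e-12)
        assert spectral_correction_factor(aphy, e_insitu.scaled(0.2), e_frrf) == pytest.approx(base, rel=1e-12)
        assert spectral_correction_factor(aphy, e_insitu, e_frrf.scaled(40.0)) == pytest.approx(base, rel=1e-12)

    def test_mismatched_grids_rejected(self):
        aphy = aphy_star("eukaryote", step=1.0)
        e = generate_sunlight_spectrum(0, "clear", e0=100.0, step=2.0)
        with pytest.raises(ValueError):
            spectral_correction_factor(aphy, e, e)
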