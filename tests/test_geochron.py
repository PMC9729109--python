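"""Thermal-age kinetics, depurination fragment lengths, burial dating."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sedadna.geochron import (
    AgePDF,
    BurialConfig,
    TemperatureHistory,
    ThermalConfig,
    arrhenius_ratio,
    burial_age_pdf,
    burial_age_point,
    combine_pdfs,
    expected_fragment_length,
    summarize_max_age,
    thermal_age,
)

R = 8.314462618


class TestArrhenius:
    def test_reference_temperature_gives_one(self):
        assert arrhenius_ratio(283.15) == pytest.approx(1.0)

    def test_minus_17_celsius_hand_evaluation(self):
        """Independent evaluation of the exponent: at -17 C reactions run
        about 295 times slower than at the 10 C reference."""
        expected = math.exp(-127_000.0 / R * (1 / 256.15 - 1 / 283.15))
        ratio = arrhenius_ratio(256.15)
        assert ratio == pytest.approx(expected, rel=1e-12)
        assert 1 / ratio == pytest.approx(295.0, rel=0.01)

    def test_zero_activation_energy_is_temperature_free(self):
        config = ThermalConfig(ea_j_mol=0.0)
        for t in (200.0, 256.15, 300.0):
            assert arrhenius_ratio(t, config) == 1.0

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            arrhenius_ratio(0.0)


def constant_history(t_k: float, duration: float) -> TemperatureHistory:
    return TemperatureHistory(np.array([0.0, duration]), np.array([t_k, t_k]))


class TestThermalAge:
    def test_reference_temperature_counts_calendar_years(self):
        assert thermal_age(constant_history(283.15, 1000.0), 1000.0) == pytest.approx(1000.0)

    def test_constant_minus_17_over_two_myr(self):
        tau = thermal_age(constant_history(256.15, 2.0e6), 2.0e6)
        assert tau == pytest.approx(2.0e6 * arrhenius_ratio(256.15), rel=1e-6)

    def test_two_segment_history_piecewise_closed_form(self):
        """Half the time at T_ref and half at a temperature with rate ratio
        0.5 gives 1500 thermal years over 2000 years."""
        t_half = 1.0 / (1.0 / 283.15 + math.log(2) * R / 127_000.0)
        history = TemperatureHistory(
            np.array([0.0, 1000.0, 2000.0]),
            np.array([283.15, t_half, t_half]),
            interpolation="previous",
        )
        assert thermal_age(history, 2000.0) == pytest.approx(1500.0, rel=1e-9)

    def test_linear_in_duration_and_additive(self):
        h = constant_history(270.0, 10_000.0)
        tau_full = thermal_age(h, 10_000.0)
        tau_half = thermal_age(h, 5_000.0)
        assert tau_full == pytest.approx(2 * tau_half, rel=1e-9)

    def test_altitude_correction_cools_history(self):
        config = ThermalConfig(altitude_km=1.0)
        tau_alt = thermal_age(constant_history(270.0, 1000.0), 1000.0, config)
        tau_flat = thermal_age(constant_history(270.0 - 6.49, 1000.0), 1000.0)
        assert tau_alt == pytest.approx(tau_flat, rel=1e-9)

    def test_history_shorter_than_duration_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            thermal_age(constant_history(270.0, 500.0), 1000.0)


class TestFragmentLength:
    def test_fifty_bp_at_two_percent_scission(self):
        assert expected_fragment_length(0.02, 1.0) == pytest.approx(50.0)

    def test_unit_boundary(self):
        assert expected_fragment_length(1.0, 1.0) == pytest.approx(1.0)

    def test_doubling_thermal_age_halves_length(self):
        assert expected_fragment_length(0.001, 2000.0) == pytest.approx(
            expected_fragment_length(0.001, 1000.0) / 2
        )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            expected_fragment_length(0.0, 1.0)


class TestBurialPoint:
    def test_surface_ratio_gives_zero_age(self):
        config = BurialConfig(r0=6.75)
        age, flagged = burial_age_point(6.75e5, 1e5, config)
        assert age == 0.0 and not flagged

    def test_half_ratio_closed_form(self):
        """ln2 / (lam26 - lam10) with half-lives 0.705 / 1.387 Myr:
        0.705 * 1.387 / (1.387 - 0.705) = 1.4338 Myr."""
        config = BurialConfig(r0=6.75)
        age, _ = burial_age_point(6.75e5 / 2, 1e5, config)
        assert age == pytest.approx(0.705 * 1.387 / (1.387 - 0.705), rel=1e-9)
        assert age == pytest.approx(1.434, abs=0.001)

    def test_ratio_above_initial_flags_and_clamps(self):
        age, flagged = burial_age_point(7.0e5, 1e5, BurialConfig(r0=6.75))
        assert age == 0.0 and flagged

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        ratio=st.floats(0.5, 6.0),
        eps=st.floats(1.0, 500.0),
        r0=st.sampled_from([6.75, 7.42]),
    )
    def test_steady_erosion_never_older_than_zero_erosion(self, ratio, eps, r0):
        zero = BurialConfig(r0=r0)
        steady = BurialConfig(r0=r0, erosion_rate_cm_myr=eps)
        a0, _ = burial_age_point(ratio * 1e5, 1e5, zero)
        a1, _ = burial_age_point(ratio * 1e5, 1e5, steady)
        assert a1 <= a0 + 1e-12

    def test_inverse_consistency_at_zero_noise(self):
        config = BurialConfig(r0=7.42)
        for t in (0.3, 1.0, 2.7, 4.5):
            r = config.r0 * np.exp(-t * (config.lam26 - config.lam10))
            age, _ = burial_age_point(r * 1e5, 1e5, config)
            assert age == pytest.approx(t, abs=1e-10)


def gaussian_pdf(grid: np.ndarray, mu: float, sigma: float) -> AgePDF:
    dens = np.exp(-0.5 * ((grid - mu) / sigma) ** 2)
    return AgePDF(grid, dens).normalize()


class TestPDFs:
    def test_monte_carlo_pdf_integrates_to_one(self):
        pdf = burial_age_pdf(4.0e5, 1.0e5, 2.0e4, 0.5e4, n_draws=20_000, seed=1)
        assert pdf.integral() == pytest.approx(1.0, abs=1e-6)

    def test_combining_one_pdf_is_identity(self):
        grid = BurialConfig().age_grid()
        pdf = gaussian_pdf(grid, 2.0, 0.2)
        out = combine_pdfs([pdf])
        assert np.allclose(out.density, pdf.density)

    def test_three_gaussians_combine_to_third_variance(self):
        grid = np.linspace(0, 6, 2401)
        mu, sigma = 2.5, 0.3
        combined = combine_pdfs([gaussian_pdf(grid, mu, sigma)] * 3)
        half_width = (combined.quantile(1 - 0.15865525) - combined.quantile(0.15865525)) / 2
        assert half_width == pytest.approx(sigma / math.sqrt(3), rel=0.02)

    def test_combination_commutative_and_associative(self):
        grid = np.linspace(0, 6, 1201)
        a = gaussian_pdf(grid, 2.0, 0.3)
        b = gaussian_pdf(grid, 2.4, 0.4)
        c = gaussian_pdf(grid, 2.2, 0.5)
        abc = combine_pdfs([a, b, c])
        cba = combine_pdfs([c, b, a])
        nested = combine_pdfs([combine_pdfs([a, b]), c])
        assert np.allclose(abc.density, cba.density)
        assert np.allclose(abc.density, nested.density, atol=1e-9)

    def test_disjoint_support_is_an_error(self):
        grid = np.linspace(0, 6, 601)
        a = AgePDF(grid, (grid < 1.0).astype(float)).normalize()
        b = AgePDF(grid, (grid > 5.0).astype(float)).normalize()
        with pytest.raises(ValueError, match="inconsistent"):
            combine_pdfs([a, b])

    def test_mismatched_grids_rejected(self):
        a = gaussian_pdf(np.linspace(0, 6, 601), 2, 0.3)
        b = gaussian_pdf(np.linspace(0, 5, 601), 2, 0.3)
        with pytest.raises(ValueError, match="grid"):
            combine_pdfs([a, b])

    def test_midpoint_summary_arithmetic(self):
        grid = np.linspace(0, 6, 2401)
        young = gaussian_pdf(grid, 2.0, 0.1)
        old = gaussian_pdf(grid, 3.0, 0.1)
        s = summarize_max_age([young, old])
        assert s["lo_3s"] == pytest.approx(2.0 - 0.3, abs=0.02)
        assert s["hi_3s"] == pytest.approx(3.0 + 0.3, abs=0.02)
        assert s["midpoint_myr"] == pytest.approx(2.5, abs=0.02)
        assert s["half_range_myr"] == pytest.approx(0.8, abs=0.03)
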