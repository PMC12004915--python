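"""Forward-simulator unit and property tests."""

import numpy as np
import pytest

import itcmicelle as itc
from itcmicelle.protocol import ValidationError
from itcmicelle.simulate import SimulationWarning, _solve_reduced

from conftest import DH_DEMIC, DPS_CMC


class TestCellConcentration:
    def test_nothing_injected(self, dps_protocol):
        assert itc.cell_concentration(dps_protocol, 0) == 0.0

    def test_first_injection_displacement(self, dps_protocol):
        # C_1 = C_syr * v/V0 = 0.04 * 8e-6/1.4e-3
        assert itc.cell_concentration(dps_protocol, 1) == \
            pytest.approx(2.2857142857e-4, rel=1e-9)

    def test_final_concentration_matches_iterative_bookkeeping(
            self, dps_protocol):
        # oracle: step-by-step displacement mixing
        c = 0.0
        f = dps_protocol.injection_volume / dps_protocol.cell_volume
        for _ in range(32):
            c = c * (1 - f) + dps_protocol.syringe_conc * f
        assert itc.cell_concentration(dps_protocol, 32) == \
            pytest.approx(c, rel=1e-12)
        assert c == pytest.approx(6.70e-3, rel=1e-2)

    def test_monotone_increasing_bounded_by_syringe(self, dps_protocol):
        prof = itc.concentration_profile(dps_protocol)
        assert np.all(np.diff(prof) > 0)
        assert prof[-1] < dps_protocol.syringe_conc

    def test_additive_agrees_to_first_order_then_diverges(
            self, dps_protocol):
        # the two bookkeepings agree per injection to O(v/V0) but the
        # cumulative gap grows ~ (i*v/V0)^2/2, reaching ~8% by injection 32
        rel = []
        for i in (1, 16, 32):
            a = itc.cell_concentration(dps_protocol, i, "additive")
            d = itc.cell_concentration(dps_protocol, i, "displacement")
            rel.append(abs(a - d) / d)
        assert rel[0] < 0.01
        assert rel[0] < rel[1] < rel[2] < 0.10

    def test_out_of_range_index(self, dps_protocol):
        with pytest.raises(IndexError):
            itc.cell_concentration(dps_protocol, 33)
        with pytest.raises(IndexError):
            itc.cell_concentration(dps_protocol, -1)


class TestSolveMonomer:
    def test_no_aggregation(self):
        assert itc.solve_monomer(0.7, 0.0, 5) == 0.7

    def test_quadratic_closed_form(self):
        # n=2, K=1: x + 2x^2 = 3  ->  x = 1 (root of 2x^2 + x - 3)
        assert itc.solve_monomer(3.0, 1.0, 2) == pytest.approx(1.0, rel=1e-12)

    def test_sharp_transition_limit(self):
        # textbook convention K = 1/(n cmc^(n-1)); bisection oracle gives
        # x/cmc = 1.04482 at n=50 and c_total = 10 cmc; the overshoot
        # shrinks toward zero as n grows
        cmc = 3.6e-3
        overshoots = []
        for n in (50, 100):
            x = _solve_reduced(10.0, 1.0, n) * cmc
            overshoots.append(x / cmc - 1.0)
        assert overshoots[0] == pytest.approx(0.0448200, rel=1e-5)
        assert overshoots[1] < overshoots[0]
        assert overshoots[1] == pytest.approx(0.0221902, rel=1e-5)

    def test_solution_satisfies_equilibrium(self):
        for c_total, k, n in [(1e-3, 1e5, 3), (5e-3, 2e12, 6),
                              (0.2, 0.5, 2)]:
            x = itc.solve_monomer(c_total, k, n)
            assert 0 <= x <= c_total
            assert x + n * k * x ** n == pytest.approx(c_total, rel=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            itc.solve_monomer(-1.0, 1.0, 2)
        with pytest.raises(ValidationError):
            itc.solve_monomer(1.0, 1.0, 1)
        with pytest.raises(ValidationError):
            itc.solve_monomer(1.0, -1.0, 2)


class TestEnthalpogramSimulation:
    def test_zero_enthalpy_gives_flat_offset(self, dps_protocol):
        m = itc.MicellizationModel("pseudophase", DPS_CMC, 0.0,
                                   dilution_offset=-150.0)
        e = itc.simulate_enthalpogram(dps_protocol, m)
        assert np.allclose(e.heats, -150.0, atol=1e-9)

    def test_pseudophase_limiting_regimes(self, dps_protocol,
                                          pseudophase_model):
        e = itc.simulate_enthalpogram(dps_protocol, pseudophase_model)
        cs = dps_protocol.syringe_conc
        expected_early = DH_DEMIC * (1 - DPS_CMC / cs)
        assert e.heats[0] == pytest.approx(expected_early, rel=1e-9)
        assert abs(e.heats[-1]) < 1e-6 * DH_DEMIC  # pure dilution

    def test_mass_conservation(self, dps_protocol, dps_model):
        # monomer + micellar == total at every injection, 1e-12 relative
        from itcmicelle.simulate import _monomer_curve
        conc = itc.concentration_profile(dps_protocol)[1:]
        mono = _monomer_curve(conc, dps_model)
        mic = conc - mono
        assert np.allclose(mono + mic, conc, rtol=1e-12, atol=0)

    def test_mass_action_is_smooth_pseudophase_is_steplike(
            self, dps_protocol, dps_model, pseudophase_model):
        ma = itc.simulate_enthalpogram(dps_protocol, dps_model).heats
        pp = itc.simulate_enthalpogram(dps_protocol, pseudophase_model).heats
        # the pseudophase swing is concentrated in <= 2 injections (the
        # step may split across the midpoint assignment); the smooth
        # mass-action transition spreads over several
        big_pp = np.sum(np.abs(np.diff(pp)) > 0.05 * np.ptp(pp))
        big_ma = np.sum(np.abs(np.diff(ma)) > 0.05 * np.ptp(ma))
        assert big_pp <= 2
        assert big_ma >= 4

    def test_demicellization_design_required(self, dps_protocol):
        m = itc.MicellizationModel("pseudophase", 0.05, DH_DEMIC)
        with pytest.raises(ValidationError):
            itc.simulate_enthalpogram(dps_protocol, m)

    def test_warns_when_cmc_never_reached(self):
        p = itc.TitrationProtocol(1.4e-3, 8e-6, 5, 0.04)
        m = itc.MicellizationModel("pseudophase", 3.6e-3, DH_DEMIC)
        with pytest.warns(SimulationWarning):
            itc.simulate_enthalpogram(p, m)

    def test_seeded_noise_is_deterministic(self, dps_protocol,
                                           pseudophase_model):
        n1 = itc.NoiseSpec(0.02, seed=42)
        e1 = itc.simulate_enthalpogram(dps_protocol, pseudophase_model, n1)
        e2 = itc.simulate_enthalpogram(dps_protocol, pseudophase_model,
                                       itc.NoiseSpec(0.02, seed=42))
        e3 = itc.simulate_enthalpogram(dps_protocol, pseudophase_model,
                                       itc.NoiseSpec(0.02, seed=43))
        assert np.array_equal(e1.heats, e2.heats)
        assert not np.array_equal(e1.heats, e3.heats)

    def test_post_assignment_shifts_concentrations_half_step(
            self, dps_protocol, pseudophase_model):
        mid = itc.simulate_enthalpogram(dps_protocol, pseudophase_model)
        post = itc.simulate_enthalpogram(dps_protocol, pseudophase_model,
                                         assignment="post")
        prof = itc.concentration_profile(dps_protocol)
        assert np.allclose(post.concentrations, prof[1:], rtol=1e-14)
        assert np.allclose(mid.concentrations,
                           0.5 * (prof[:-1] + prof[1:]), rtol=1e-14)


class TestMassActionPseudophaseLimit:
    def test_convergence_with_aggregation_number(self, dps_protocol,
                                                 pseudophase_model):
        """The n-mer enthalpogram approaches the pseudophase step as n
        grows; the post-CMC tail decays like 1/n, so the sup-deviation
        outside the transition falls monotonically but is still ~6% of
        |dH| at n=100 (textbook convention, matched nominal CMC)."""
        pp = itc.simulate_enthalpogram(dps_protocol, pseudophase_model)
        i_tr = int(np.argmin(np.abs(pp.concentrations - DPS_CMC)))
        outside = np.abs(np.arange(len(pp)) - i_tr) > 1
        devs = []
        for n in (10, 25, 55, 100):
            m = itc.MicellizationModel("mass_action", DPS_CMC, DH_DEMIC,
                                       agg_number=n, k_reduced=1.0)
            ma = itc.simulate_enthalpogram(dps_protocol, m)
            devs.append(np.max(np.abs((ma.heats - pp.heats)[outside]))
                        / DH_DEMIC)
        assert devs[0] > devs[1] > devs[2] > devs[3]
        assert devs[3] < 0.07


class TestPowerTrace:
    def test_single_injection_normalization(self):
        p = itc.TitrationProtocol(1.4e-3, 8e-6, 2, 0.04)
        e = itc.Enthalpogram([1e-4, 2e-4], [5e3, 5e3])
        t = itc.simulate_power_trace(e, p, peak_width=20.0, dt=0.5)
        q_joule = 5e3 * p.moles_per_injection
        total = np.trapezoid(t.powers, t.times)
        assert total == pytest.approx(2 * q_joule, rel=1e-3)

    def test_zero_heat_gives_pure_baseline(self, dps_protocol):
        e = itc.Enthalpogram([1e-4, 2e-4], [0.0, 0.0])
        p = itc.TitrationProtocol(1.4e-3, 8e-6, 2, 0.04)
        t = itc.simulate_power_trace(e, p, baseline_power=1e-6,
                                     baseline_drift=1e-10)
        assert np.allclose(t.powers, 1e-6 + 1e-10 * t.times, rtol=1e-12)

    def test_peak_width_must_fit_spacing(self, dps_protocol):
        e = itc.Enthalpogram([1e-4, 2e-4], [1.0, 1.0])
        p = itc.TitrationProtocol(1.4e-3, 8e-6, 2, 0.04, spacing=100.0)
        with pytest.raises(ValidationError):
            itc.simulate_power_trace(e, p, peak_width=100.0)


class TestTemperatureSeries:
    def test_zero_at_athermal_point(self):
        series = dict(itc.simulate_temperature_series(-400.0, 298.15,
                                                      [298.15, 308.15]))
        assert series[298.15] == 0.0

    def test_linear_law_value(self):
        # dCp = -0.4 kJ/mol/K, T_H = 290.65 K, T = 283.15 K -> +3.0 kJ/mol
        series = dict(itc.simulate_temperature_series(-400.0, 290.65,
                                                      [283.15, 308.15]))
        assert series[283.15] == pytest.approx(3000.0, rel=1e-12)

    def test_duplicates_collapse_with_warning(self):
        with pytest.warns(SimulationWarning):
            out = itc.simulate_temperature_series(-400.0, 290.0,
                                                  [283.15, 283.15, 308.15])
        assert len(out) == 2

    def test_roundtrip_through_heat_capacity(self):
        series = itc.simulate_temperature_series(-400.0, 290.65,
                                                 [283.15, 298.15, 308.15])
        hc = itc.heat_capacity(series)
        assert hc.dcp == pytest.approx(-400.0, rel=1e-12)
        assert hc.t_h == pytest.approx(290.65, abs=1e-9)

    def test_needs_two_distinct_temperatures(self):
        with pytest.raises(ValidationError):
            itc.simulate_temperature_series(-400.0, 290.0, [298.15])


class TestCalibration:
    def test_calibrated_model_keeps_nominal_cmc_operationally(
            self, dps_protocol, dps_model):
        """The ideal continuum curve of the calibrated model, analyzed by
        the standard sigmoid/derivative rule, returns cmc_true."""
        from itcmicelle.simulate import _continuum_heats
        grid = np.linspace(itc.cell_concentration(dps_protocol, 1),
                           itc.cell_concentration(dps_protocol, 32), 256)
        q = _continuum_heats(grid, dps_model, dps_protocol)
        fit = itc.fit_sigmoid(itc.Enthalpogram(grid, q))
        assert fit.cmc == pytest.approx(DPS_CMC, rel=1e-4)

    def test_calibration_is_idempotent(self, dps_protocol, dps_model):
        again = itc.calibrate_mass_action(dps_model, dps_protocol)
        assert again.k_reduced == dps_model.k_reduced
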