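"""Fitting and measurement procedures, checked against closed forms and
constructed data."""

import math

import numpy as np
import pytest

import crcell as cc
from crcell.analysis import (
    IVCurve,
    fit_boltzmann_curve,
    fit_exponential,
    inactivation_curve,
    recovery_tau,
    reversal_from_linreg,
    steady_state_from_conductance,
    tau_m_from_ttp,
)


class TestExponentialFit:
    def test_recovers_constructed_decay(self):
        t = np.arange(0.0, 120.0, 0.5)
        y = 50.0 * np.exp(-t / 23.5)
        fit = fit_exponential(t, y, with_offset=True)
        assert fit.tau == pytest.approx(23.5, rel=1e-6)
        assert fit.amplitude == pytest.approx(50.0, rel=1e-6)

    def test_recovers_membrane_time_constant_scale(self):
        t = np.arange(0.0, 40.0, 0.1)
        y = 100.0 * np.exp(-t / 7.64)
        fit = fit_exponential(t, y, with_offset=False)
        assert fit.tau == pytest.approx(7.64, rel=1e-6)

    def test_constant_trace_flagged_degenerate(self):
        t = np.arange(0.0, 10.0, 0.5)
        fit = fit_exponential(t, np.full_like(t, 3.3))
        assert fit.degenerate
        assert fit.amplitude == 0.0

    def test_negative_amplitude_decay(self):
        t = np.arange(0.0, 50.0, 0.2)
        y = -200.0 * np.exp(-t / 5.5) - 12.0
        fit = fit_exponential(t, y, with_offset=True)
        assert fit.tau == pytest.approx(5.5, rel=1e-6)
        assert fit.amplitude == pytest.approx(-200.0, rel=1e-6)
        assert fit.offset == pytest.approx(-12.0, rel=1e-6)

    def test_refitting_own_prediction_is_idempotent(self):
        t = np.arange(0.0, 60.0, 0.25)
        fit = fit_exponential(t, 80.0 * np.exp(-t / 12.0) + 5.0)
        fit2 = fit_exponential(t, fit.predict(t))
        assert fit2.tau == pytest.approx(fit.tau, rel=1e-6)
        assert fit2.amplitude == pytest.approx(fit.amplitude, rel=1e-6)

    def test_requires_enough_samples(self):
        with pytest.raises(ValueError):
            fit_exponential([0, 1, 2], [1.0, 0.5, 0.25])


class TestBoltzmannFit:
    def test_exact_round_trip(self):
        spec = cc.BoltzmannSpec(v_half=-12.3, z=3.8, amplitude=8.08)
        v = np.arange(-60.0, 41.0, 5.0)
        fit = fit_boltzmann_curve(list(zip(v, spec(v))), direction="rising")
        assert fit.v_half == pytest.approx(-12.3, abs=1e-6)
        assert fit.z == pytest.approx(3.8, rel=1e-6)
        assert fit.amplitude == pytest.approx(8.08, rel=1e-6)

    def test_falling_round_trip_and_z_k_link(self):
        spec = cc.BoltzmannSpec(v_half=-52.7, k=7.59, direction="falling")
        v = np.arange(-100.0, -9.0, 5.0)
        fit = fit_boltzmann_curve(list(zip(v, spec(v))), direction="falling")
        assert fit.v_half == pytest.approx(-52.7, abs=1e-6)
        assert fit.k == pytest.approx(7.59, rel=1e-6)
        assert fit.z * fit.k == pytest.approx(25.69, rel=1e-9)

    def test_needs_five_points(self):
        with pytest.raises(ValueError):
            fit_boltzmann_curve([(0, 1), (1, 2), (2, 3), (3, 4)])


class TestPeakAndZeroTime:
    def test_time_to_peak_matches_closed_form(self):
        """I(t) = (1 - e^{-t})^3 e^{-t/20}: ttp = ln(1 + 3*20/1) = 4.11 ms."""
        dt = 0.005
        t = np.arange(0.0, 80.0, dt)
        i = (1 - np.exp(-t)) ** 3 * np.exp(-t / 20.0) * 100.0
        rec = cc.Recording(
            dt=dt, time=t, v=np.zeros_like(t), i_total=i,
            metadata={"mode": "vc",
                      "protocol": {"segments": [{"duration": 80.0, "level": 0.0}]}})
        res = cc.peak_and_ttp(rec, (0.0, 80.0))
        assert res["ttp"] == pytest.approx(math.log(61.0), rel=0.02)

    def test_monotone_trace_flagged(self):
        dt = 0.1
        t = np.arange(0.0, 20.0, dt)
        rec = cc.Recording(
            dt=dt, time=t, v=np.zeros_like(t), i_total=t.copy(),
            metadata={"mode": "vc",
                      "protocol": {"segments": [{"duration": 20.0, "level": 0.0}]}})
        res = cc.peak_and_ttp(rec, (0.0, 20.0))
        assert "monotone" in res["flags"]
        assert res["ttp"] == pytest.approx(t[-1], abs=2 * dt)

    def test_zero_time_extrapolation_recovers_open_channel_amplitude(self):
        """Constructed p=3 activation with exponential inactivation: the
        decay-fit extrapolation to step onset recovers the 100 pA
        open-channel amplitude within 2%."""
        dt = 0.01
        t = np.arange(0.0, 100.0, dt)
        i = 100.0 * (1 - np.exp(-t / 0.5)) ** 3 * np.exp(-t / 20.0)
        pad_t = np.arange(-10.0, 0.0, dt)
        full_t = np.concatenate([pad_t, t]) + 10.0
        full_i = np.concatenate([np.zeros_like(pad_t), i])
        rec = cc.Recording(
            dt=dt, time=full_t, v=np.zeros_like(full_t), i_total=full_i,
            metadata={"mode": "vc",
                      "protocol": {"segments": [{"duration": 10.0, "level": -100.0},
                                                {"duration": 100.0, "level": 0.0}]}})
        value, fit = cc.zero_time_current(rec)
        assert value == pytest.approx(100.0, rel=0.02)

    def test_pure_decay_from_onset_is_exact(self):
        dt = 0.01
        t = np.arange(0.0, 60.0, dt)
        i = np.concatenate([np.zeros(1000), 55.0 * np.exp(-(t[1000:] - 10.0) / 8.0)])
        rec = cc.Recording(
            dt=dt, time=t, v=np.zeros_like(t), i_total=i,
            metadata={"mode": "vc",
                      "protocol": {"segments": [{"duration": 10.0, "level": -100.0},
                                                {"duration": 50.0, "level": 0.0}]}})
        value, _ = cc.zero_time_current(rec, ttp=1.0)
        assert value == pytest.approx(55.0, rel=1e-4)


class TestConductanceCurve:
    def test_zero_current_gives_zero_conductance(self):
        gv = cc.conductance_curve([(-40.0, 0.0), (0.0, 0.0)], e_rev=-101.0)
        assert all(g == 0.0 for _, g in gv)

    def test_ohmic_current_gives_constant_conductance(self):
        v = np.arange(-60.0, 41.0, 10.0)
        i = 2.5 * (v - (-101.0))
        gv = cc.conductance_curve(list(zip(v, i)), e_rev=-101.0)
        assert all(g == pytest.approx(2.5, rel=1e-12) for _, g in gv)

    def test_point_at_reversal_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="reversal"):
            gv = cc.conductance_curve([(-101.0, 0.0), (0.0, 101.0)], e_rev=-101.0)
        assert len(gv) == 1


class TestSteadyStateExtraction:
    def test_cube_root_at_base_midpoint(self):
        spec = cc.BoltzmannSpec(v_half=-12.3, z=3.8, amplitude=8.08)
        v = [-60.0, -50.0, -40.0, -30.0, -20.0, -12.3, -10.0, 0.0, 10.0,
             20.0, 30.0, 40.0]
        curve, _fit = steady_state_from_conductance(
            [(x, spec(x)) for x in v], g_max=8.08, r=3)
        assert dict(curve)[-12.3] == pytest.approx(0.5 ** (1 / 3), rel=1e-9)

    def test_sodium_gate_midpoint(self):
        """Cube root of the sodium conductance curve crosses 1/2 at
        V0 - (kT/ez) ln 7 = -46.2 mV; a plain Boltzmann approximates the
        root-of-Boltzmann curve with its midpoint pulled ~1 mV leftward."""
        spec = cc.BoltzmannSpec(v_half=-34.6, z=4.3, amplitude=12.7)
        v = np.arange(-80.0, 40.1, 5.0)
        curve, fit = steady_state_from_conductance(list(zip(v, spec(v))),
                                                   g_max=12.7, r=3)
        expected = -34.6 - (25.69 / 4.3) * math.log(7.0)
        vv = np.array([p[0] for p in curve])
        xx = np.array([p[1] for p in curve])
        crossing = float(np.interp(0.5, xx, vv))
        assert crossing == pytest.approx(expected, abs=0.25)
        assert fit.v_half == pytest.approx(expected, abs=2.0)

    def test_clips_conductance_above_maximum(self):
        with pytest.warns(UserWarning, match="clipped"):
            curve, _ = steady_state_from_conductance(
                [(v, g) for v, g in zip(np.arange(-40, 41, 10.0),
                                        np.linspace(0.1, 1.2, 9))],
                g_max=1.0, r=3)
        assert max(x for _, x in curve) == 1.0


class TestInactivationAndRecovery:
    def test_exact_boltzmann_peaks_round_trip(self):
        spec = cc.BoltzmannSpec(v_half=-52.7, k=7.59, direction="falling")
        v = np.arange(-100.0, -9.0, 10.0)
        fit = inactivation_curve(list(zip(v, 930.0 * spec(v))))
        assert fit.v_half == pytest.approx(-52.7, abs=1e-4)
        assert fit.k == pytest.approx(7.59, rel=1e-4)

    def test_all_zero_peaks_degenerate(self):
        with pytest.raises(ValueError):
            inactivation_curve([(v, 0.0) for v in range(-100, -40, 10)])

    def test_recovery_exact_construction(self):
        gaps = np.array([2.0, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0])
        peaks = 800.0 * (1 - np.exp(-gaps / 23.5))
        fit = recovery_tau(list(zip(gaps, peaks)))
        assert fit.tau == pytest.approx(23.5, rel=1e-6)
        assert fit.amplitude == pytest.approx(800.0, rel=1e-6)

    def test_saturated_gaps_flagged(self):
        gaps = np.array([500.0, 600.0, 700.0, 800.0, 900.0])
        peaks = 100.0 * (1 - np.exp(-gaps / 20.0))
        with pytest.warns(UserWarning, match="poorly constrained"):
            fit = recovery_tau(list(zip(gaps, peaks)))
        assert fit.degenerate

    def test_non_monotone_peaks_warn_but_fit(self):
        pts = [(5.0, 10.0), (10.0, 30.0), (20.0, 25.0), (40.0, 60.0),
               (80.0, 80.0)]
        with pytest.warns(UserWarning, match="not monotone"):
            fit = recovery_tau(pts)
        assert fit.tau > 0


class TestTimeToPeakInversion:
    def test_forward_closed_form(self):
        # tau_m = 1, tau_h = 20.32, p = 4: ttp = ln(1 + 4*20.32) = ln 82.28
        ttp = 1.0 * math.log(1 + 4 * 20.32 / 1.0)
        assert ttp == pytest.approx(4.41, abs=0.005)

    def test_newton_inverts_closed_form(self):
        ttp = math.log(82.28)
        assert tau_m_from_ttp(ttp, 20.32, p=4) == pytest.approx(1.0, abs=1e-6)

    def test_equal_time_constants_special_case(self):
        tau = 13.7
        ttp = tau * math.log(2.0)
        assert tau_m_from_ttp(ttp, tau, p=1) == pytest.approx(tau, rel=1e-9)

    @pytest.mark.parametrize("tau_m,tau_h,p", [(0.3, 23.2, 3), (2.0, 8.0, 4),
                                               (0.05, 5.4, 3)])
    def test_round_trip_against_forward_oracle(self, tau_m, tau_h, p):
        ttp = tau_m * math.log1p(p * tau_h / tau_m)
        assert tau_m_from_ttp(ttp, tau_h, p) == pytest.approx(tau_m, rel=1e-9)

    def test_no_root_when_ttp_exceeds_bound(self):
        with pytest.raises(ValueError):
            tau_m_from_ttp(100.0, 20.0, p=4)


class TestReversalRegression:
    def test_collinear_points(self):
        v = np.array([10.0, 20.0, 30.0, 40.0])
        i = 3.0 * (v - 61.4)
        iv = IVCurve(list(zip(v, i)))
        assert reversal_from_linreg(iv) == pytest.approx(61.4, abs=1e-9)

    def test_two_point_line(self):
        iv = IVCurve([(0.0, -10.0), (10.0, 10.0)])
        assert reversal_from_linreg(iv, last_n=2) == pytest.approx(5.0)

    def test_zero_slope_is_an_error(self):
        iv = IVCurve([(0.0, 5.0), (10.0, 5.0), (20.0, 5.0), (30.0, 5.0)])
        with pytest.raises(ValueError):
            reversal_from_linreg(iv)

    def test_voltages_must_increase(self):
        with pytest.raises(ValueError):
            IVCurve([(0.0, 1.0), (0.0, 2.0)])
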