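"""Protocol engine: integrator correctness, clamp invariants, spike and
late-phase measurements."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import crcell as cc
from crcell.protocols import (
    Protocol,
    Segment,
    SweepAxis,
    paired_pulse_protocol,
    recovery_protocol,
)
from crcell.simulate import detect_spikes, late_phase_iv, simulate, simulate_family


def _passive(g_leak=0.5326, c_m=4.07):
    return cc.MembraneModel(c_m=c_m, g_leak=g_leak, e_leak=-70.0, channels=[])


class TestProtocol:
    def test_rejects_bad_segments_and_sweeps(self):
        with pytest.raises(ValueError):
            Segment(0.0, 1.0)
        with pytest.raises(ValueError):
            Protocol(mode="cc", segments=[])
        with pytest.raises(ValueError):
            Protocol(mode="vc", segments=[Segment(10, -70)],
                     sweep_axis=SweepAxis(3, [1.0]))
        with pytest.raises(ValueError):
            Protocol(mode="xx", segments=[Segment(10, -70)])

    def test_sweep_expansion_varies_one_segment(self):
        proto = Protocol(mode="vc",
                         segments=[Segment(10, -100), Segment(20, -40)],
                         sweep_axis=SweepAxis(1, [-40, 0, 40]))
        levels = [p.segments[1].level for p in proto.sweeps()]
        assert levels == [-40, 0, 40]
        assert all(p.segments[0].level == -100 for p in proto.sweeps())

    def test_recovery_gaps_must_be_sorted(self):
        with pytest.raises(ValueError):
            recovery_protocol(20.0, 100.0, -70.0, [50, 5], 20.0)

    def test_dict_round_trip(self):
        proto = paired_pulse_protocol(11.0, 10.0, [15, 30], holding_v=-70.0)
        again = Protocol.from_dict(proto.to_dict())
        assert again.to_dict() == proto.to_dict()


class TestExponentialEulerGates:
    @settings(derandomize=True, max_examples=25)
    @given(v=st.floats(-90, 40), n_steps=st.integers(2, 400))
    def test_update_telescopes_to_analytic_relaxation(self, v, n_steps):
        """For piecewise-constant V the discrete gate update equals
        x(t) = x_inf - (x_inf - x0) exp(-t/tau) at machine precision."""
        model = cc.reference_cr_cell()
        gate = model.channel("I_A").gates[1]
        xinf, tau = gate.x_inf(v), gate.tau_v(v)
        dt = 0.01
        x = x0 = 0.123
        for _ in range(n_steps):
            x = xinf - (xinf - x) * math.exp(-dt / tau)
        analytic = xinf - (xinf - x0) * math.exp(-n_steps * dt / tau)
        assert x == pytest.approx(analytic, rel=1e-10, abs=1e-14)

    def test_vc_gate_traces_match_analytic(self):
        model = cc.reference_cr_cell().isolated("I_A")
        proto = Protocol(mode="vc",
                         segments=[Segment(50.0, -100.0), Segment(50.0, 0.0)])
        rec = simulate(model, proto, dt=0.01)
        gate = model.channel("I_A").gates[1]
        xinf, tau = gate.x_inf(0.0), gate.tau_v(0.0)
        sl = rec.window_slice(50.0, 100.0)
        t_loc = rec.time[sl] - 50.0
        x0 = rec.gates["I_A.ha"][sl.start]
        analytic = xinf - (xinf - x0) * np.exp(-t_loc / tau)
        assert np.allclose(rec.gates["I_A.ha"][sl], analytic, rtol=1e-10)


class TestClampInvariants:
    def test_vc_voltage_equals_command(self):
        model = cc.reference_cr_cell()
        proto = Protocol(mode="vc",
                         segments=[Segment(10.0, -100.0), Segment(10.0, 20.0)])
        rec = simulate(model, proto, dt=0.01)
        assert set(np.unique(rec.v)) == {-100.0, 20.0}

    def test_vc_total_current_is_sum_of_parts(self):
        model = cc.reference_cr_cell()
        proto = Protocol(mode="vc",
                         segments=[Segment(20.0, -100.0), Segment(30.0, 0.0)])
        rec = simulate(model, proto, dt=0.01)
        leak = model.g_leak * (rec.v - model.e_leak)
        total = leak + sum(rec.channel_currents.values())
        assert np.array_equal(rec.i_total, total)

    def test_cc_current_equals_programmed_injection(self):
        rec = simulate(_passive(),
                       Protocol(mode="cc", segments=[Segment(10, 0.0),
                                                     Segment(10, -15.0)]),
                       dt=0.01)
        assert np.all(rec.i_total[rec.window_slice(0, 10)] == 0.0)
        assert np.all(rec.i_total[rec.window_slice(10, 20)] == -15.0)

    def test_all_arrays_equal_length(self):
        model = cc.reference_cr_cell()
        proto = Protocol(mode="vc", segments=[Segment(5.0, -70.0)])
        rec = simulate(model, proto, dt=0.01)
        n = rec.time.size
        assert rec.v.size == n == rec.i_total.size
        assert all(a.size == n for a in rec.channel_currents.values())
        assert all(a.size == n for a in rec.gates.values())

    def test_invalid_dt_and_sweep_protocols(self):
        model = _passive()
        proto = Protocol(mode="cc", segments=[Segment(5.0, 0.0)])
        with pytest.raises(ValueError):
            simulate(model, proto, dt=0.0)
        swept = Protocol(mode="cc", segments=[Segment(5.0, 0.0)],
                         sweep_axis=SweepAxis(0, [0.0, 1.0]))
        with pytest.raises(ValueError):
            simulate(model, swept)


class TestCurrentClamp:
    def test_passive_step_obeys_ohms_law(self):
        rec = simulate(_passive(),
                       Protocol(mode="cc", segments=[Segment(20, 0.0),
                                                     Segment(300, -15.0)]),
                       dt=0.01)
        assert rec.v[-1] - (-70.0) == pytest.approx(-15.0 / 0.5326, abs=0.05)

    def test_reference_cell_rests_at_holding_potential(self, ref_model):
        proto = Protocol(mode="cc", segments=[Segment(1000.0, 0.0)],
                         holding_v=-70.0)
        rec = simulate(ref_model, proto, dt=0.02, record_gates=False)
        assert np.max(np.abs(rec.v + 70.0)) < 0.5

    def test_initial_state_is_steady_state(self):
        # no settling transient: a constant-level protocol stays constant
        rec = simulate(_passive(),
                       Protocol(mode="cc", segments=[Segment(50, -10.0)]),
                       dt=0.01)
        assert np.ptp(rec.v) < 1e-9


class TestVoltageClampFamilies:
    def test_mixed_family_shows_inward_then_outward_transients(self, ref_model):
        """Depolarizing steps after full removal of inactivation evoke a fast
        inward (sodium) then a transient outward (A-type) current, with no
        sustained outward component left at the step end."""
        recs = cc.run_vc_family(ref_model, -100.0, 250.0, [40.0], 100.0, dt=0.01)
        rec = recs[0]
        t0, t1 = rec.segment_times()[1]
        sl = rec.window_slice(t0, t1)
        i = rec.i_total[sl]
        t = rec.time[sl] - t0
        leak_end = ref_model.g_leak * (40.0 - ref_model.e_leak)
        assert i.min() < -100.0 and t[np.argmin(i)] < 1.0  # fast inward
        assert i.max() > 500.0 and 1.0 < t[np.argmax(i)] < 10.0  # outward
        assert abs(i[-1] - leak_end) < 0.05 * i.max()  # transient only

    def test_a_family_peaks_increase_with_depolarization(self, a_iso):
        recs = cc.run_vc_family(a_iso, -100.0, 250.0,
                                np.arange(-40.0, 41.0, 10.0), 100.0, dt=0.01)
        peaks = [cc.peak_and_ttp(r, r.segment_times()[1])["peak"] for r in recs]
        assert all(b > a for a, b in zip(peaks, peaks[1:]))

    def test_depolarized_preconditioning_reduces_availability(self, a_iso):
        """A -50 mV prepulse leaves the availability the steady-state
        inactivation curve dictates (ha_inf(-50) ~ 0.59), so the evoked
        outward current drops accordingly relative to full removal."""
        def peak_after(pre):
            recs = cc.run_vc_family(a_iso, pre, 500.0, [20.0], 100.0, dt=0.01)
            return cc.peak_and_ttp(recs[0], recs[0].segment_times()[1])["peak"]

        ratio = peak_after(-50.0) / peak_after(-100.0)
        ha = a_iso.channel("I_A").gates[1]
        expected = ha.x_inf(-50.0) / ha.x_inf(-100.0)
        assert ratio == pytest.approx(expected, rel=0.15)
        assert ratio < 0.7

    def test_step_to_reversal_evokes_no_channel_current(self, a_iso):
        recs = cc.run_vc_family(a_iso, -100.0, 100.0, [-101.0], 50.0, dt=0.01)
        assert np.max(np.abs(recs[0].channel_currents["I_A"])) < 1e-3

    def test_recovery_peaks_non_decreasing_with_gap(self, a_iso):
        gaps = [5.0, 20.0, 60.0, 120.0, 250.0]
        recs = cc.run_recovery_protocol(a_iso, 20.0, 100.0, -90.0, gaps, 20.0,
                                        dt=0.01)
        peaks = [cc.peak_and_ttp(r, r.segment_times()[3])["peak"] for r in recs]
        assert all(b >= a for a, b in zip(peaks, peaks[1:]))

    def test_short_prepulse_warns(self, a_iso):
        with pytest.warns(UserWarning, match="prepulse duration"):
            cc.run_inactivation_protocol(a_iso, [-100.0, -80.0, -60.0], 50.0,
                                         20.0, test_duration=20.0, dt=0.05)


class TestSpikeDetection:
    def test_flat_trace_has_no_spikes(self):
        rec = simulate(_passive(),
                       Protocol(mode="cc", segments=[Segment(50, 0.0)]), 0.01)
        assert detect_spikes(rec) == []

    def test_rejects_voltage_clamp(self):
        model = cc.reference_cr_cell()
        rec = simulate(model, Protocol(mode="vc", segments=[Segment(5, -70)]),
                       0.01)
        with pytest.raises(ValueError):
            detect_spikes(rec)

    def test_single_overshooting_spike_properties(self, battery):
        assert battery["n_spikes_sustained"] == 1
        assert battery["spike_peak_mv"] > 0.0
        assert battery["spike_width_ms"] > 0.0


class TestLatePhaseIV:
    def test_passive_family_is_perfectly_ohmic(self):
        levels = [-15.0, -5.0, 5.0, 15.0, 25.0]
        proto = Protocol(mode="cc",
                         segments=[Segment(10.0, 0.0), Segment(100.0, levels[0])],
                         sweep_axis=SweepAxis(1, levels))
        recs = simulate_family(_passive(), proto, dt=0.01, record_gates=False)
        iv = late_phase_iv(recs, window=20.0)
        assert iv["r2"] == pytest.approx(1.0, abs=1e-9)
        assert iv["slope_mohm"] == pytest.approx(1000.0 / 0.5326, rel=1e-3)

    def test_window_must_fit_in_step(self):
        proto = Protocol(mode="cc",
                         segments=[Segment(10.0, 0.0), Segment(50.0, -5.0)])
        rec = simulate(_passive(), proto, dt=0.01)
        with pytest.raises(ValueError):
            late_phase_iv([rec], window=80.0)


class TestConvergence:
    def test_halving_dt_changes_results_by_less_than_half_percent(self, ref_model):
        # voltage clamp: peak A-current
        def vc_peak(dt):
            recs = cc.run_vc_family(ref_model.isolated("I_A"), -100.0, 50.0,
                                    [20.0], 60.0, dt=dt)
            return cc.peak_and_ttp(recs[0], recs[0].segment_times()[1])["peak"]

        assert abs(vc_peak(0.005) / vc_peak(0.01) - 1.0) < 0.005

        # current clamp: spike peak
        def spike_peak(dt):
            proto = Protocol(mode="cc",
                             segments=[Segment(10.0, 0.0), Segment(60.0, 11.0)],
                             holding_v=-70.0)
            rec = simulate(ref_model, proto, dt=dt, record_gates=False)
            return detect_spikes(rec)[0].peak_v

        p1, p2 = spike_peak(0.01), spike_peak(0.005)
        # relative to spike amplitude from rest
        assert abs(p2 - p1) / (p1 + 70.0) < 0.005
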