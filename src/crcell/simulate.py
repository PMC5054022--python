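"""Integration of the single-compartment membrane equation under stimulus
programs, plus spike detection and late-phase I-V measurement.

Current clamp integrates ``c_m dV/dt = I_inj - sum(I_chan) - I_leak`` with
forward Euler for V and exponential Euler for the gates, i.e. the closed-form
first-order relaxation ``x <- x_inf - (x_inf - x) exp(-dt/tau)`` evaluated at
the instantaneous potential.  Voltage clamp is ideal (no series resistance,
no capacitive transient): V equals the command, gates relax analytically
within each constant-voltage segment, and the reported current is the
algebraic sum of channel and leak currents.

Because the exponential-Euler update telescopes exactly for constant V, the
vectorized voltage-clamp path and a stepwise integration agree to machine
precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .kinetics import MembraneModel
from .protocols import Protocol, paired_pulse_protocol, recovery_protocol, \
    inactivation_protocol, vc_family

__all__ = [
    "Recording",
    "SpikeEvent",
    "simulate",
    "simulate_family",
    "run_vc_family",
    "run_inactivation_protocol",
    "run_recovery_protocol",
    "run_paired_pulse_cc",
    "detect_spikes",
    "late_phase_iv",
    "resting_state",
    "find_rheobase",
]


@dataclass
class Recording:
    """Sampled traces from one sweep, with enough metadata to re-analyze it."""

    dt: float
    time: np.ndarray
    v: np.ndarray
    i_total: np.ndarray
    channel_currents: dict = field(default_factory=dict)
    gates: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def mode(self) -> str:
        return self.metadata.get("mode", "vc")

    def segment_times(self) -> list[tuple[float, float]]:
        segs = self.metadata["protocol"]["segments"]
        out, t = [], 0.0
        for s in segs:
            out.append((t, t + s["duration"]))
            t += s["duration"]
        return out

    def segment_level(self, index: int) -> float:
        return self.metadata["protocol"]["segments"][index]["level"]

    def window_slice(self, t0: float, t1: float) -> slice:
        i0 = int(np.searchsorted(self.time, t0 - 1e-9))
        i1 = int(np.searchsorted(self.time, t1 - 1e-9))
        return slice(i0, i1)


@dataclass
class SpikeEvent:
    onset: float       # ms, threshold crossing
    peak_time: float   # ms
    peak_v: float      # mV
    amplitude: float   # mV from pre-stimulus baseline
    half_width: float  # ms at half amplitude

    def __post_init__(self) -> None:
        if self.onset > self.peak_time + 1e-9:
            raise ValueError("spike onset must not follow its peak")


# ---------------------------------------------------------------------------


def _segment_grid(protocol: Protocol, dt: float):
    """Sample counts per segment; sample k sits at t = k*dt, left-aligned."""
    counts = [max(1, int(round(s.duration / dt))) for s in protocol.segments]
    return counts


def resting_state(model: MembraneModel, i_inj: float = 0.0,
                  v_window: tuple[float, float] = (-130.0, 50.0)) -> float:
    """Steady-state potential under constant injected current.

    Scans for zero crossings of ``I_inj - I_ss(V)`` and returns the root
    nearest the leak reversal (the physiological rest among multiple roots).
    """
    f = lambda v: i_inj - model.steady_total_current(v)
    grid = np.linspace(v_window[0], v_window[1], 361)
    vals = np.array([f(v) for v in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-10))
    if not roots:
        raise RuntimeError("no steady state found in the scan window")
    return min(roots, key=lambda r: abs(r - model.e_leak))


def _simulate_vc(model: MembraneModel, protocol: Protocol, dt: float,
                 record_gates: bool) -> Recording:
    counts = _segment_grid(protocol, dt)
    n_total = sum(counts)
    time = np.arange(n_total) * dt
    v = np.empty(n_total)
    pairs = model.gate_index()
    gate_tracks = [np.empty(n_total) for _ in pairs] if record_gates else None

    x = [g.x_inf(protocol.segments[0].level) for _, g in pairs]
    gate_vals = [np.empty(n_total) for _ in pairs]
    i0 = 0
    for seg, n in zip(protocol.segments, counts):
        sl = slice(i0, i0 + n)
        local_t = (np.arange(n)) * dt
        v[sl] = seg.level
        for j, (_, gate) in enumerate(pairs):
            xinf = gate.x_inf(seg.level)
            tau = gate.tau_v(seg.level)
            gate_vals[j][sl] = xinf - (xinf - x[j]) * np.exp(-local_t / tau)
            x[j] = xinf - (xinf - x[j]) * math.exp(-seg.duration / tau)
        i0 += n

    channel_currents = {}
    j = 0
    for ch in model.channels:
        open_frac = np.ones(n_total)
        for gate in ch.gates:
            open_frac = open_frac * gate_vals[j] ** gate.p
            j += 1
        channel_currents[ch.name] = ch.g_max * open_frac * (v - ch.e_rev)
    i_leak = model.g_leak * (v - model.e_leak)
    i_total = i_leak + sum(channel_currents.values()) if channel_currents else i_leak

    gates = {}
    if record_gates:
        for jj, (ch, gate) in enumerate(pairs):
            gates[f"{ch.name}.{gate.name}"] = gate_vals[jj]

    return Recording(
        dt=dt, time=time, v=v, i_total=np.asarray(i_total, dtype=float),
        channel_currents=channel_currents, gates=gates,
        metadata={"mode": "vc", "protocol": protocol.to_dict(), "dt": dt,
                  "model": model.fingerprint(), "i_leak0": float(i_leak[0])},
    )


def _simulate_cc(model: MembraneModel, protocol: Protocol, dt: float,
                 record_gates: bool) -> Recording:
    counts = _segment_grid(protocol, dt)
    n_total = sum(counts)
    time = np.arange(n_total) * dt

    # injected current per sample (programmed levels, before holding bias)
    inj = np.empty(n_total)
    i0 = 0
    for seg, n in zip(protocol.segments, counts):
        inj[i0:i0 + n] = seg.level
        i0 += n

    if protocol.holding_v is not None:
        v0 = protocol.holding_v
        bias = model.steady_total_current(v0)
    else:
        bias = 0.0
        v0 = resting_state(model, protocol.segments[0].level)

    pairs = model.gate_index()
    chans = [(ch.g_max, ch.e_rev, [g.p for g in ch.gates], len(ch.gates))
             for ch in model.channels]
    xinf_fns = [g.x_inf for _, g in pairs]
    tau_fns = [g.tau_v for _, g in pairs]

    v = np.empty(n_total)
    chan_tracks = {ch.name: np.empty(n_total) for ch in model.channels}
    gate_tracks = [np.empty(n_total) for _ in pairs] if record_gates else None

    x = [float(fn(v0)) for fn in xinf_fns]
    vk = float(v0)
    g_leak, e_leak, c_m = model.g_leak, model.e_leak, model.c_m
    names = [ch.name for ch in model.channels]
    exp = math.exp

    for k in range(n_total):
        v[k] = vk
        i_ion = g_leak * (vk - e_leak)
        gi = 0
        for (g_max, e_rev, ps, ng), name in zip(chans, names):
            of = 1.0
            for p in ps:
                xx = x[gi]
                if p == 1:
                    of *= xx
                elif p == 3:
                    of *= xx * xx * xx
                elif p == 2:
                    of *= xx * xx
                else:
                    of *= xx ** p
                gi += 1
            i_ch = g_max * of * (vk - e_rev)
            chan_tracks[name][k] = i_ch
            i_ion += i_ch
        if record_gates:
            for j in range(len(x)):
                gate_tracks[j][k] = x[j]
        # advance
        vk = vk + dt * (inj[k] + bias - i_ion) / c_m
        vcur = v[k]
        for j in range(len(x)):
            xinf = xinf_fns[j](vcur)
            tau = tau_fns[j](vcur)
            x[j] = xinf - (xinf - x[j]) * exp(-dt / tau)

    gates = {}
    if record_gates:
        for jj, (ch, gate) in enumerate(pairs):
            gates[f"{ch.name}.{gate.name}"] = gate_tracks[jj]

    return Recording(
        dt=dt, time=time, v=v, i_total=inj + bias,
        channel_currents=chan_tracks, gates=gates,
        metadata={"mode": "cc", "protocol": protocol.to_dict(), "dt": dt,
                  "model": model.fingerprint(), "holding_bias_pa": float(bias),
                  "v0": float(v0)},
    )


def simulate(model: MembraneModel, protocol: Protocol, dt: float = 0.01,
             record_gates: bool = True) -> Recording:
    """Integrate one concrete sweep (protocols with a sweep axis: use
    :func:`simulate_family`)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if protocol.sweep_axis is not None:
        raise ValueError("protocol has a sweep axis; use simulate_family")
    if protocol.mode == "vc":
        return _simulate_vc(model, protocol, dt, record_gates)
    return _simulate_cc(model, protocol, dt, record_gates)


def simulate_family(model: MembraneModel, protocol: Protocol, dt: float = 0.01,
                    record_gates: bool = True) -> list[Recording]:
    return [simulate(model, p, dt, record_gates) for p in protocol.sweeps()]


# ---------------------------------------------------------------------------
# protocol runners


def run_vc_family(model: MembraneModel, pre_level: float, pre_duration: float,
                  step_levels: Sequence[float], step_duration: float,
                  tail_level: Optional[float] = None, tail_duration: float = 100.0,
                  dt: float = 0.01) -> list[Recording]:
    proto = vc_family(pre_level, pre_duration, list(step_levels), step_duration,
                      tail_level, tail_duration)
    return simulate_family(model, proto, dt)


def run_inactivation_protocol(model: MembraneModel, pre_levels: Sequence[float],
                              pre_duration: float, test_level: float,
                              test_duration: float = 60.0,
                              dt: float = 0.01) -> list[Recording]:
    max_tau = max(gate.tau_v(v) for _, gate in model.gate_index()
                  for v in np.linspace(min(pre_levels), max(pre_levels), 41))
    if pre_duration < 5.0 * max_tau:
        warnings.warn(
            f"prepulse duration {pre_duration} ms < 5x the slowest gate "
            f"relaxation ({max_tau:.1f} ms) over the prepulse range",
            stacklevel=2,
        )
    proto = inactivation_protocol(list(pre_levels), pre_duration, test_level,
                                  test_duration)
    return simulate_family(model, proto, dt)


def run_recovery_protocol(model: MembraneModel, inactivating_level: float,
                          inactivating_duration: float, recovery_level: float,
                          gaps: Sequence[float], test_level: float,
                          test_duration: float = 50.0,
                          conditioning_duration: float = 100.0,
                          dt: float = 0.01) -> list[Recording]:
    proto = recovery_protocol(inactivating_level, inactivating_duration,
                              recovery_level, list(gaps), test_level,
                              test_duration, conditioning_duration)
    return simulate_family(model, proto, dt)


def run_paired_pulse_cc(model: MembraneModel, pulse_amp: float, pulse_width: float,
                        intervals: Sequence[float], holding_v: float = -70.0,
                        dt: float = 0.01) -> list[Recording]:
    proto = paired_pulse_protocol(pulse_amp, pulse_width, list(intervals),
                                  holding_v=holding_v)
    return simulate_family(model, proto, dt)


# ---------------------------------------------------------------------------
# trace measurements


def detect_spikes(recording: Recording, threshold: float = 0.0,
                  min_separation: float = 2.0) -> list[SpikeEvent]:
    """Upward threshold crossings of a current-clamp trace, merged within
    ``min_separation`` ms; amplitudes are measured from the pre-stimulus
    baseline (the first protocol segment)."""
    if recording.mode != "cc":
        raise ValueError("spike detection applies to current-clamp recordings")
    v = recording.v
    t = recording.time
    seg0 = recording.segment_times()[0]
    baseline = float(np.mean(v[recording.window_slice(*seg0)]))

    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    events: list[SpikeEvent] = []
    last_end = -np.inf
    for idx in crossings:
        if t[idx] - last_end < min_separation:
            continue
        # extent of this suprathreshold excursion
        end = idx
        while end < len(v) and above[end]:
            end += 1
        peak_rel = int(np.argmax(v[idx:end])) if end > idx else 0
        peak_idx = idx + peak_rel
        peak_v = float(v[peak_idx])
        amp = peak_v - baseline
        half = baseline + amp / 2.0
        # interpolated half-amplitude crossings around the peak
        i_up = peak_idx
        while i_up > 0 and v[i_up - 1] > half:
            i_up -= 1
        i_dn = peak_idx
        while i_dn < len(v) - 1 and v[i_dn + 1] > half:
            i_dn += 1
        def _interp(i_lo, i_hi):
            if v[i_hi] == v[i_lo]:
                return t[i_lo]
            w = (half - v[i_lo]) / (v[i_hi] - v[i_lo])
            return t[i_lo] + w * (t[i_hi] - t[i_lo])
        t_up = _interp(i_up - 1, i_up) if i_up > 0 else t[i_up]
        t_dn = _interp(i_dn + 1, i_dn) if i_dn < len(v) - 1 else t[i_dn]
        events.append(SpikeEvent(
            onset=float(t[idx]), peak_time=float(t[peak_idx]), peak_v=peak_v,
            amplitude=float(amp), half_width=float(abs(t_dn - t_up)),
        ))
        last_end = t[end - 1] if end > idx else t[idx]
    return events


def late_phase_iv(recordings: Sequence[Recording], window: float = 50.0,
                  step_segment: int = 1) -> dict:
    """Mean late-phase V against injected I for a current-clamp step family,
    with the least-squares line (slope in MOhm) and its r^2."""
    points = []
    for rec in recordings:
        if rec.mode != "cc":
            raise ValueError("late-phase I-V applies to current-clamp recordings")
        t0, t1 = rec.segment_times()[step_segment]
        if window > t1 - t0 + 1e-9:
            raise ValueError("window exceeds the step duration")
        sl = rec.window_slice(t1 - window, t1)
        points.append((rec.segment_level(step_segment), float(np.mean(rec.v[sl]))))
    points.sort()
    i_arr = np.array([p[0] for p in points])
    v_arr = np.array([p[1] for p in points])
    slope, intercept = np.polyfit(i_arr, v_arr, 1)  # mV / pA = GOhm
    pred = slope * i_arr + intercept
    ss_res = float(np.sum((v_arr - pred) ** 2))
    ss_tot = float(np.sum((v_arr - v_arr.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"points": points, "slope_mohm": float(slope * 1000.0),
            "intercept_mv": float(intercept), "r2": r2}


def find_rheobase(model: MembraneModel, pulse_width: float = 200.0,
                  holding_v: float = -70.0, i_max: float = 40.0,
                  resolution: float = 0.25, dt: float = 0.01) -> float:
    """Minimal sustained current step evoking a spike, by bisection."""
    from .protocols import Protocol, Segment

    def spikes_at(amp: float) -> bool:
        proto = Protocol(mode="cc",
                         segments=[Segment(20.0, 0.0), Segment(pulse_width, amp)],
                         holding_v=holding_v)
        rec = simulate(model, proto, dt, record_gates=False)
        return len(detect_spikes(rec)) > 0

    lo, hi = 0.0, i_max
    if not spikes_at(hi):
        raise RuntimeError(f"no spike up to {i_max} pA")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return hi
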