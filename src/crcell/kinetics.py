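"""Channel-kinetics data model for conductance-based single-compartment neurons.

Voltage dependences are expressed as Boltzmann sigmoids (parameterized either
by an equivalent gating valence ``z`` or by a slope factor ``k`` in mV, tied
together through the thermal voltage kT/e), and time constants as small
phenomenological laws: exponential-plus-offset, quadratic polynomial, or a
voltage-stitched piecewise combination bridging measured ranges with linear
interpolation.

Units are fixed throughout the package: mV, ms, pA, nS, pF.  Membrane
potential is depolarization-positive and currents are positive outward, so
no unit conversion appears anywhere in the dynamics
(pA = nS * mV, ms = pF / nS * ... all consistent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "THERMAL_VOLTAGE",
    "BoltzmannSpec",
    "RootOfBoltzmann",
    "ExpOffsetTau",
    "QuadraticTau",
    "ScaledTau",
    "StitchedTau",
    "GateSpec",
    "ChannelSpec",
    "MembraneModel",
    "boltzmann_eval",
    "gate_steady_state",
    "gate_tau",
    "nernst",
]

#: kT/e at 25 degC in mV; the convention used for all z <-> slope conversions.
THERMAL_VOLTAGE = 25.69

# High-precision physical constants (CODATA) for the Nernst relation.
_GAS_CONSTANT = 8.314462618  # J / (mol K)
_FARADAY = 96485.33212  # C / mol


def _require_finite(v, name: str = "v") -> None:
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass
class BoltzmannSpec:
    """A sigmoidal voltage dependence.

    ``value(v) = amplitude / (1 + exp(+-(v_half - v) / k))`` with the sign set
    by ``direction``: a ``"rising"`` curve increases with depolarization and
    equals ``amplitude/2`` at ``v_half``; ``"falling"`` is its exact mirror.

    Steepness may be given as the equivalent valence ``z`` (dimensionless) or
    the slope factor ``k`` (mV); they are linked by ``k * z = thermal_voltage``.
    """

    v_half: float
    z: float | None = None
    k: float | None = None
    amplitude: float = 1.0
    direction: str = "rising"
    thermal_voltage: float = THERMAL_VOLTAGE

    def __post_init__(self) -> None:
        if self.direction not in ("rising", "falling"):
            raise ValueError(f"direction must be rising|falling, got {self.direction!r}")
        if self.z is None and self.k is None:
            raise ValueError("one of z or k must be set")
        if self.z is None:
            self.z = self.thermal_voltage / self.k
        elif self.k is None:
            self.k = self.thermal_voltage / self.z
        else:
            if abs(self.k * self.z - self.thermal_voltage) > 1e-9 * self.thermal_voltage:
                raise ValueError(
                    f"inconsistent steepness: k*z = {self.k * self.z} != {self.thermal_voltage}"
                )
        if self.k <= 0 or self.z <= 0:
            raise ValueError("steepness must be positive")

    def __call__(self, v):
        _require_finite(v)
        if isinstance(v, np.ndarray):
            x = (self.v_half - v) / self.k
            if self.direction == "falling":
                x = -x
            return self.amplitude / (1.0 + np.exp(np.clip(x, -700, 700)))
        x = (self.v_half - float(v)) / self.k
        if self.direction == "falling":
            x = -x
        if x > 700.0:
            return 0.0
        return self.amplitude / (1.0 + math.exp(x))

    def to_dict(self) -> dict:
        return {
            "kind": "boltzmann",
            "v_half": self.v_half,
            "z": self.z,
            "amplitude": self.amplitude,
            "direction": self.direction,
            "thermal_voltage": self.thermal_voltage,
        }


@dataclass
class RootOfBoltzmann:
    """r-th root of a normalized Boltzmann: ``(base(v)/base.amplitude)**(1/r)``.

    This is the construction used to extract a single-gate activation curve
    from a macroscopic conductance curve when the channel carries ``r``
    identical activation particles: at ``v = base.v_half`` it evaluates to
    ``(1/2)**(1/r)``, and raised to the r-th power it reproduces the base
    curve exactly at every voltage.
    """

    base: BoltzmannSpec
    r: int = 3

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("root order must be >= 1")

    def __call__(self, v):
        frac = self.base(v) / self.base.amplitude
        if isinstance(frac, np.ndarray):
            return np.power(frac, 1.0 / self.r)
        return frac ** (1.0 / self.r)

    def to_dict(self) -> dict:
        return {"kind": "root_of_boltzmann", "base": self.base.to_dict(), "r": self.r}


# ---------------------------------------------------------------------------
# tau(V) laws


@dataclass
class ExpOffsetTau:
    """tau(V) = a * exp(-V / v_s) + c, clamped below at ``floor`` (ms)."""

    a: float
    v_s: float
    c: float
    floor: float = 0.05

    def _raw(self, v):
        if isinstance(v, np.ndarray):
            return self.a * np.exp(-v / self.v_s) + self.c
        return self.a * math.exp(-float(v) / self.v_s) + self.c

    def __call__(self, v):
        _require_finite(v)
        raw = self._raw(v)
        if isinstance(raw, np.ndarray):
            return np.maximum(raw, self.floor)
        return max(raw, self.floor)

    def to_dict(self) -> dict:
        return {"kind": "exp_offset", "a": self.a, "v_s": self.v_s, "c": self.c,
                "floor": self.floor}


@dataclass
class QuadraticTau:
    """tau(V) = c0 + c1*V + c2*V**2, clamped below at ``floor`` (ms)."""

    c0: float
    c1: float = 0.0
    c2: float = 0.0
    floor: float = 0.05

    def _raw(self, v):
        return self.c0 + self.c1 * v + self.c2 * v * v

    def __call__(self, v):
        _require_finite(v)
        raw = self._raw(np.asarray(v, dtype=float)) if isinstance(v, np.ndarray) \
            else self._raw(float(v))
        if isinstance(raw, np.ndarray):
            return np.maximum(raw, self.floor)
        return max(raw, self.floor)

    def to_dict(self) -> dict:
        return {"kind": "quadratic", "c0": self.c0, "c1": self.c1, "c2": self.c2,
                "floor": self.floor}


@dataclass
class ScaledTau:
    """A tau law multiplied by a constant factor (e.g. 10x faster recovery)."""

    inner: "TauFunction"
    factor: float

    def __call__(self, v):
        return self.inner(v) * self.factor

    @property
    def floor(self) -> float:
        return self.inner.floor * self.factor

    def to_dict(self) -> dict:
        return {"kind": "scaled", "inner": self.inner.to_dict(), "factor": self.factor}


@dataclass
class StitchedTau:
    """Piecewise tau(V): branch laws on declared voltage ranges, linearly
    interpolated across the gaps between consecutive ranges.

    ``branches`` is an ordered list of ``(v_lo, v_hi, law)`` with strictly
    increasing, non-overlapping ranges (use +-inf for open ends).  Inside a
    declared range the branch law applies; inside a gap the value is the
    linear bridge between the left branch evaluated at its upper edge and the
    right branch at its lower edge, which makes the composite continuous.
    """

    branches: Sequence[tuple]
    floor: float = 0.05

    def __post_init__(self) -> None:
        edges = [(lo, hi) for lo, hi, _ in self.branches]
        for (lo, hi) in edges:
            if not lo < hi:
                raise ValueError("branch range must satisfy v_lo < v_hi")
        for (_, hi_prev), (lo_next, _) in zip(edges, edges[1:]):
            if lo_next < hi_prev:
                raise ValueError("branch ranges must be ordered and non-overlapping")

    def _raw_scalar(self, v: float) -> float:
        branches = self.branches
        for i, (lo, hi, law) in enumerate(branches):
            if lo <= v <= hi:
                return law(v)
            if v < lo:
                if i == 0:
                    return law(v)  # extrapolate the first law leftward
                lo_prev, hi_prev, law_prev = branches[i - 1]
                y0, y1 = law_prev(hi_prev), law(lo)
                w = (v - hi_prev) / (lo - hi_prev)
                return (1.0 - w) * y0 + w * y1
        lo, hi, law = branches[-1]
        return law(v)  # extrapolate the last law rightward

    def __call__(self, v):
        _require_finite(v)
        if isinstance(v, np.ndarray):
            out = np.array([self._raw_scalar(float(x)) for x in np.ravel(v)])
            return np.maximum(out.reshape(np.shape(v)), self.floor)
        return max(self._raw_scalar(float(v)), self.floor)

    def to_dict(self) -> dict:
        return {
            "kind": "stitched",
            "branches": [
                {"v_lo": lo, "v_hi": hi, "law": law.to_dict()}
                for lo, hi, law in self.branches
            ],
            "floor": self.floor,
        }


TauFunction = Union[ExpOffsetTau, QuadraticTau, StitchedTau, ScaledTau]
SteadyState = Union[BoltzmannSpec, RootOfBoltzmann]


# ---------------------------------------------------------------------------
# gates, channels, membrane


@dataclass
class GateSpec:
    """One Hodgkin-Huxley gating particle: first-order relaxation to
    ``steady_state(v)`` with time constant ``tau(v)``, entering the channel
    open fraction as ``x**p``."""

    name: str
    p: int
    steady_state: SteadyState
    tau: TauFunction

    def __post_init__(self) -> None:
        if self.p not in (1, 2, 3, 4):
            raise ValueError("gate exponent p must be in {1,2,3,4}")

    def x_inf(self, v):
        return self.steady_state(v)

    def tau_v(self, v):
        return self.tau(v)

    def to_dict(self) -> dict:
        return {"name": self.name, "p": self.p,
                "steady_state": self.steady_state.to_dict(),
                "tau": self.tau.to_dict()}


@dataclass
class ChannelSpec:
    """A conductance: I = g_max * prod(gate^p) * (V - e_rev), ohmic driving force."""

    name: str
    g_max: float
    e_rev: float
    gates: list[GateSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")

    def open_fraction(self, gate_values: Sequence[float]):
        out = 1.0
        for gate, x in zip(self.gates, gate_values):
            out = out * x ** gate.p
        return out

    def current(self, v, gate_values: Sequence[float]):
        return self.g_max * self.open_fraction(gate_values) * (v - self.e_rev)

    def steady_current(self, v: float) -> float:
        return self.current(v, [g.x_inf(v) for g in self.gates])

    def to_dict(self) -> dict:
        return {"name": self.name, "g_max": self.g_max, "e_rev": self.e_rev,
                "gates": [g.to_dict() for g in self.gates]}


@dataclass
class MembraneModel:
    """Single-compartment cell: capacitance, ohmic leak, and a channel list."""

    c_m: float
    g_leak: float
    e_leak: float
    channels: list[ChannelSpec] = field(default_factory=list)
    name: str = "cell"

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ValueError("c_m must be > 0")
        if self.g_leak < 0:
            raise ValueError("g_leak must be >= 0")

    # -- assembly helpers ---------------------------------------------------

    def channel(self, name: str) -> ChannelSpec:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(f"no channel named {name!r}")

    def isolated(self, *names: str, keep_leak: bool = False) -> "MembraneModel":
        """Pharmacological isolation: keep only the named conductances.

        The leak is zeroed by default, mimicking ideal leak subtraction; the
        analysis routines rely on this so that the constant term of a decay
        fit contains only sustained channel current.
        """
        import copy

        kept = [copy.deepcopy(self.channel(n)) for n in names]
        return MembraneModel(
            c_m=self.c_m,
            g_leak=self.g_leak if keep_leak else 0.0,
            e_leak=self.e_leak,
            channels=kept,
            name=f"{self.name}:{'+'.join(names)}",
        )

    def with_gmax(self, name: str, g_max: float) -> "MembraneModel":
        import copy

        model = copy.deepcopy(self)
        model.channel(name).g_max = g_max
        return model

    def with_tau_scaled(self, channel: str, gate: str, factor: float,
                        v_below: float | None = None) -> "MembraneModel":
        """Return a copy with one gate's tau(V) law scaled by ``factor``.

        With ``v_below`` set and a stitched law, only the branches entirely
        below that voltage are scaled (e.g. the removal-of-inactivation
        branch measured at recovery potentials), leaving the depolarized
        kinetics untouched; the bridge re-interpolates automatically.
        """
        import copy

        model = copy.deepcopy(self)
        ch = model.channel(channel)
        for g in ch.gates:
            if g.name != gate:
                continue
            if v_below is not None and isinstance(g.tau, StitchedTau):
                g.tau = StitchedTau(
                    branches=[
                        (lo, hi, ScaledTau(law, factor) if hi <= v_below else law)
                        for lo, hi, law in g.tau.branches
                    ],
                    floor=min(g.tau.floor, g.tau.floor * factor),
                )
            else:
                g.tau = ScaledTau(g.tau, factor)
            return model
        raise KeyError(f"no gate named {gate!r} in channel {channel!r}")

    # -- evaluation ---------------------------------------------------------

    def gate_index(self) -> list[tuple[ChannelSpec, GateSpec]]:
        return [(ch, g) for ch in self.channels for g in ch.gates]

    def steady_gates(self, v: float) -> list[float]:
        return [g.x_inf(v) for _, g in self.gate_index()]

    def channel_currents(self, v, gates: Sequence[float]) -> dict:
        out = {}
        i = 0
        for ch in self.channels:
            n = len(ch.gates)
            out[ch.name] = ch.current(v, gates[i:i + n])
            i += n
        return out

    def leak_current(self, v):
        return self.g_leak * (v - self.e_leak)

    def total_current(self, v, gates: Sequence[float]):
        """Net membrane current (positive outward), channels plus leak."""
        total = self.leak_current(v)
        for i_ch in self.channel_currents(v, gates).values():
            total = total + i_ch
        return total

    def steady_total_current(self, v: float) -> float:
        return self.total_current(v, self.steady_gates(v))

    def to_dict(self) -> dict:
        return {"name": self.name, "c_m": self.c_m, "g_leak": self.g_leak,
                "e_leak": self.e_leak,
                "channels": [ch.to_dict() for ch in self.channels]}

    def fingerprint(self) -> str:
        import hashlib
        import json

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# pure evaluation functions (thin functional API over the dataclasses)


def boltzmann_eval(spec: BoltzmannSpec, v):
    """Evaluate a Boltzmann voltage dependence at ``v`` (mV)."""
    return spec(v)


def gate_steady_state(gate: GateSpec, v):
    """Steady-state open probability of a gate at ``v`` (mV)."""
    return gate.x_inf(v)


def gate_tau(gate: GateSpec, v):
    """Relaxation time constant (ms) of a gate at ``v`` (mV), floor applied."""
    return gate.tau_v(v)


def nernst(c_out: float, c_in: float, valence: int = 1, temperature: float = 25.0) -> float:
    """Nernst equilibrium potential in mV.

    Parameters are the outer/inner concentrations (same units, > 0), the ion
    valence, and the temperature in degrees Celsius.
    """
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be positive")
    if valence == 0:
        raise ValueError("valence must be nonzero")
    t_kelvin = temperature + 273.15
    return 1000.0 * _GAS_CONSTANT * t_kelvin / (valence * _FARADAY) * math.log(c_out / c_in)
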