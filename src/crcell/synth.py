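"""Synthetic whole-cell recordings and cell populations.

Stands in for raw patch-clamp data: simulated sweeps with additive white
Gaussian recording noise on the measured channel (current in voltage clamp,
voltage in current clamp), and populations of cells with log-normal-free,
truncated-Gaussian parameter jitter emulating between-cell variability.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kinetics import BoltzmannSpec, MembraneModel, RootOfBoltzmann
from .protocols import Protocol
from .simulate import Recording, simulate_family, simulate

__all__ = ["NoiseSpec", "PopulationSpec", "SyntheticSet",
           "generate_recording_set", "sample_population"]


@dataclass
class NoiseSpec:
    current_sd: float = 0.0  # pA
    voltage_sd: float = 0.0  # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.current_sd < 0 or self.voltage_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class PopulationSpec:
    n: int
    cv: float = 0.10            # coefficient of variation of scale parameters
    v_half_sd: float = 2.0      # mV, additive jitter of midpoints
    slope_cv: float = 0.05      # relative jitter of slope factors
    truncation: float = 3.0     # +- sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if self.cv < 0 or self.slope_cv < 0 or self.v_half_sd < 0:
            raise ValueError("spreads must be >= 0")


@dataclass
class SyntheticSet:
    recordings: list
    noise: NoiseSpec
    metadata: dict = field(default_factory=dict)


def generate_recording_set(model: MembraneModel, protocol: Protocol,
                           noise: NoiseSpec, dt: float = 0.01) -> SyntheticSet:
    """Simulate a protocol (family) and add Gaussian recording noise to the
    measured channel; the generating model fingerprint and seed are embedded
    in each recording's metadata."""
    rng = np.random.default_rng(noise.seed)
    recs = simulate_family(model, protocol, dt) if protocol.sweep_axis is not None \
        else [simulate(model, protocol, dt)]
    out = []
    for rec in recs:
        noisy = Recording(
            dt=rec.dt, time=rec.time.copy(), v=rec.v.copy(),
            i_total=rec.i_total.copy(),
            channel_currents={k: a.copy() for k, a in rec.channel_currents.items()},
            gates={k: a.copy() for k, a in rec.gates.items()},
            metadata=dict(rec.metadata),
        )
        if rec.mode == "vc" and noise.current_sd > 0:
            noisy.i_total = noisy.i_total + rng.normal(0.0, noise.current_sd,
                                                       noisy.i_total.shape)
        if rec.mode == "cc" and noise.voltage_sd > 0:
            noisy.v = noisy.v + rng.normal(0.0, noise.voltage_sd, noisy.v.shape)
        noisy.metadata["noise"] = {"current_sd": noise.current_sd,
                                   "voltage_sd": noise.voltage_sd,
                                   "seed": noise.seed}
        out.append(noisy)
    return SyntheticSet(recordings=out, noise=noise,
                        metadata={"model": model.fingerprint(),
                                  "protocol": protocol.to_dict(),
                                  "dt": dt, "seed": noise.seed})


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      trunc: float) -> float:
    if sd == 0:
        return mean
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= trunc * sd:
            return x


def _jitter_boltzmann(rng, spec: BoltzmannSpec, pop: PopulationSpec) -> None:
    spec.v_half = _truncated_normal(rng, spec.v_half, pop.v_half_sd, pop.truncation)
    k = max(_truncated_normal(rng, spec.k, pop.slope_cv * spec.k, pop.truncation),
            1e-3)
    spec.k = k
    spec.z = spec.thermal_voltage / k


def sample_population(base: MembraneModel, spec: PopulationSpec) -> list[MembraneModel]:
    """Draw ``spec.n`` cells around ``base``: multiplicative truncated-normal
    jitter on C_m, g_leak and each g_max (coefficient of variation ``cv``),
    additive jitter on Boltzmann midpoints and relative jitter on slopes."""
    rng = np.random.default_rng(spec.seed)
    cells = []
    for idx in range(spec.n):
        cell = copy.deepcopy(base)
        cell.name = f"{base.name}#{idx}"
        cell.c_m = max(_truncated_normal(rng, base.c_m, spec.cv * base.c_m,
                                         spec.truncation), 1e-3)
        cell.g_leak = max(_truncated_normal(rng, base.g_leak, spec.cv * base.g_leak,
                                            spec.truncation), 0.0)
        for ch in cell.channels:
            ch.g_max = max(_truncated_normal(rng, ch.g_max, spec.cv * ch.g_max,
                                             spec.truncation), 0.0)
            for gate in ch.gates:
                ss = gate.steady_state
                if isinstance(ss, RootOfBoltzmann):
                    _jitter_boltzmann(rng, ss.base, spec)
                elif isinstance(ss, BoltzmannSpec):
                    _jitter_boltzmann(rng, ss, spec)
        cells.append(cell)
    return cells
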