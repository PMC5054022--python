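"""Reference parameterization of the calretinin-positive periglomerular cell.

All kinetic laws and most parameters are the published whole-cell
measurements for this cell type: a fast transient sodium current, a large
A-type potassium current (the only potassium conductance these cells
express), a small hyperpolarization-activated cationic current (I_h), a
small persistent L-type calcium current, and an ohmic leak sized from the
~1.9 GOhm input resistance of a ~4 pF cell.

Activation time constants were characterized over depolarized test ranges
and removal-of-inactivation time constants over hyperpolarized recovery
ranges; between the two measured ranges the tau(V) laws are stitched with a
linear bridge, so no dynamics are invented inside a measured range.

The L-type calcium gating was not kinetically resolved in the source data;
its defaults here (half-activation -20 mV, slope 6 mV, tau 1 ms, persistent)
are a conventional L-type description and are configurable.
"""

from __future__ import annotations

import math

from .kinetics import (
    BoltzmannSpec,
    ChannelSpec,
    ExpOffsetTau,
    GateSpec,
    MembraneModel,
    QuadraticTau,
    RootOfBoltzmann,
    StitchedTau,
)

__all__ = ["reference_cr_cell", "CM_PF", "R_IN_MOHM", "G_LEAK_NS", "E_LEAK_MV"]

INF = math.inf

CM_PF = 4.07          # membrane capacitance, pF
R_IN_MOHM = 1877.7    # input resistance, MOhm
G_LEAK_NS = 1000.0 / R_IN_MOHM  # 0.5326 nS
E_LEAK_MV = -70.0     # holding/resting level of the current-clamp recordings

E_K_MV = -101.0
E_NA_NERNST_MV = 61.4  # nernstian value from the recording solutions
E_NA_MV = 63.0         # reversal used by the conductance-voltage analysis


def _a_channel(order: int = 3) -> ChannelSpec:
    """A-type potassium current.

    The macroscopic conductance follows a Boltzmann with V0 = -12.3 mV and
    valence 3.8 saturating at 8.08 nS; the activation gate is the
    ``order``-th root of that curve raised back to the same power, so the
    open-channel conductance of the model reproduces the measured curve
    identically.  Inactivation is a first-order falling Boltzmann
    (-52.7 mV, 7.59 mV).
    """
    g_curve = BoltzmannSpec(v_half=-12.3, z=3.8, amplitude=1.0, direction="rising")
    tau_removal = ExpOffsetTau(a=2968.8, v_s=-15.27, c=11.86, floor=0.5)
    # activation tau measured for V >= -30 mV; deactivation at recovery
    # potentials is governed by the same relaxation that removes inactivation
    tau_act = StitchedTau(
        branches=[
            (-INF, -70.0, tau_removal),
            (-30.0, INF, ExpOffsetTau(a=0.52, v_s=34.6, c=0.26, floor=0.05)),
        ],
        floor=0.05,
    )
    tau_inact = StitchedTau(
        branches=[
            (-INF, -70.0, tau_removal),
            (-30.0, INF, QuadraticTau(c0=20.32, c1=0.09846, c2=0.00227, floor=0.5)),
        ],
        floor=0.5,
    )
    return ChannelSpec(
        name="I_A",
        g_max=8.08,
        e_rev=E_K_MV,
        gates=[
            GateSpec("a", p=order, steady_state=RootOfBoltzmann(g_curve, r=order),
                     tau=tau_act),
            GateSpec("ha", p=1,
                     steady_state=BoltzmannSpec(v_half=-52.7, k=7.59, direction="falling"),
                     tau=tau_inact),
        ],
    )


def _na_channel(e_na: float) -> ChannelSpec:
    g_curve = BoltzmannSpec(v_half=-34.6, z=4.3, amplitude=1.0, direction="rising")
    tau_m = ExpOffsetTau(a=0.07796, v_s=21.752, c=0.00992, floor=0.005)
    tau_h = StitchedTau(
        branches=[
            (-INF, -70.0, ExpOffsetTau(a=3853.0, v_s=-17.58, c=5.11, floor=0.5)),
            (-50.0, INF, ExpOffsetTau(a=0.0679, v_s=13.5, c=5.43, floor=0.5)),
        ],
        floor=0.5,
    )
    return ChannelSpec(
        name="I_Na",
        g_max=12.7,
        e_rev=e_na,
        gates=[
            GateSpec("m", p=3, steady_state=RootOfBoltzmann(g_curve, r=3), tau=tau_m),
            GateSpec("h", p=1,
                     steady_state=BoltzmannSpec(v_half=-70.0, k=9.4, direction="falling"),
                     tau=tau_h),
        ],
    )


def _h_channel(g_h: float, e_h: float) -> ChannelSpec:
    # tau law: monotonically faster with hyperpolarization, 30 ms floor
    tau_n = ExpOffsetTau(a=5908.0, v_s=-51.82, c=-677.48, floor=30.0)
    return ChannelSpec(
        name="I_h",
        g_max=g_h,
        e_rev=e_h,
        gates=[
            GateSpec("n", p=1,
                     steady_state=BoltzmannSpec(v_half=-100.0, k=9.02, direction="falling"),
                     tau=tau_n),
        ],
    )


def _ca_channel(g_ca: float, e_ca: float, v_half: float, k: float, tau_ms: float) -> ChannelSpec:
    return ChannelSpec(
        name="I_Ca",
        g_max=g_ca,
        e_rev=e_ca,
        gates=[
            GateSpec("c", p=1,
                     steady_state=BoltzmannSpec(v_half=v_half, k=k, direction="rising"),
                     tau=QuadraticTau(c0=tau_ms, floor=min(tau_ms, 1.0))),
        ],
    )


def reference_cr_cell(
    a_order: int = 3,
    e_na: float = E_NA_MV,
    g_h: float = 0.1,
    e_h: float = -35.0,
    g_ca: float = 0.15,
    e_ca: float = 65.0,
    ca_v_half: float = -20.0,
    ca_k: float = 6.0,
    ca_tau: float = 1.0,
) -> MembraneModel:
    """Assemble the default calretinin-positive periglomerular cell model.

    ``a_order`` selects the A-current activation order (3 by default, as used
    to extract the single-gate activation curve; 4 is the order assumed by
    the time-to-peak inversion and may be requested instead).
    """
    return MembraneModel(
        c_m=CM_PF,
        g_leak=G_LEAK_NS,
        e_leak=E_LEAK_MV,
        channels=[
            _na_channel(e_na),
            _a_channel(order=a_order),
            _h_channel(g_h, e_h),
            _ca_channel(g_ca, e_ca, ca_v_half, ca_k, ca_tau),
        ],
        name="cr_pg_reference",
    )
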