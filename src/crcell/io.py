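"""Reading and writing model configurations and recordings.

Models are serialized as YAML (nested channels/gates, loss-free round trip);
recordings as a CSV of sampled traces plus a YAML metadata sidecar carrying
the protocol, model fingerprint, dt and noise/seed information.  Floats are
written with 17 significant digits so a read-back reconstructs the arrays
bit-exactly.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import (
    BoltzmannSpec,
    ChannelSpec,
    ExpOffsetTau,
    GateSpec,
    MembraneModel,
    QuadraticTau,
    RootOfBoltzmann,
    ScaledTau,
    StitchedTau,
)
from .protocols import Protocol
from .simulate import Recording

__all__ = [
    "model_to_dict", "model_from_dict", "save_model", "load_model",
    "save_recording", "load_recording",
]


def model_to_dict(model: MembraneModel) -> dict:
    return model.to_dict()


def _steady_from_dict(d: dict):
    if d["kind"] == "boltzmann":
        return BoltzmannSpec(v_half=d["v_half"], z=d["z"], amplitude=d["amplitude"],
                             direction=d["direction"],
                             thermal_voltage=d.get("thermal_voltage", 25.69))
    if d["kind"] == "root_of_boltzmann":
        return RootOfBoltzmann(base=_steady_from_dict(d["base"]), r=d["r"])
    raise ValueError(f"unknown steady-state kind {d['kind']!r}")


def _tau_from_dict(d: dict):
    kind = d["kind"]
    if kind == "exp_offset":
        return ExpOffsetTau(a=d["a"], v_s=d["v_s"], c=d["c"], floor=d["floor"])
    if kind == "quadratic":
        return QuadraticTau(c0=d["c0"], c1=d["c1"], c2=d["c2"], floor=d["floor"])
    if kind == "scaled":
        return ScaledTau(inner=_tau_from_dict(d["inner"]), factor=d["factor"])
    if kind == "stitched":
        return StitchedTau(
            branches=[(b["v_lo"], b["v_hi"], _tau_from_dict(b["law"]))
                      for b in d["branches"]],
            floor=d["floor"])
    raise ValueError(f"unknown tau kind {kind!r}")


def model_from_dict(d: dict) -> MembraneModel:
    channels = []
    for ch in d["channels"]:
        gates = [GateSpec(name=g["name"], p=g["p"],
                          steady_state=_steady_from_dict(g["steady_state"]),
                          tau=_tau_from_dict(g["tau"]))
                 for g in ch["gates"]]
        channels.append(ChannelSpec(name=ch["name"], g_max=ch["g_max"],
                                    e_rev=ch["e_rev"], gates=gates))
    return MembraneModel(c_m=d["c_m"], g_leak=d["g_leak"], e_leak=d["e_leak"],
                         channels=channels, name=d.get("name", "cell"))


def save_model(model: MembraneModel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path: str | os.PathLike) -> MembraneModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# recordings


def save_recording(rec: Recording, path: str | os.PathLike) -> None:
    """Write ``<path>.csv`` (traces) and ``<path>.yaml`` (metadata)."""
    path = Path(path)
    cols = {"time_ms": rec.time, "v_mV": rec.v, "i_pA": rec.i_total}
    for name, arr in rec.channel_currents.items():
        cols[f"i_{name}_pA"] = arr
    for name, arr in rec.gates.items():
        cols[f"gate_{name}"] = arr
    pd.DataFrame(cols).to_csv(path.with_suffix(".csv"), index=False,
                              float_format="%.17g")
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump({"dt": rec.dt, **rec.metadata}, fh, sort_keys=False)


def load_recording(path: str | os.PathLike) -> Recording:
    path = Path(path)
    df = pd.read_csv(path.with_suffix(".csv"), float_precision="round_trip")
    with open(path.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    dt = meta.pop("dt")
    channel_currents = {}
    gates = {}
    for col in df.columns:
        if col.startswith("i_") and col.endswith("_pA") and col != "i_pA":
            channel_currents[col[2:-3]] = df[col].to_numpy()
        elif col.startswith("gate_"):
            gates[col[5:]] = df[col].to_numpy()
    return Recording(dt=dt, time=df["time_ms"].to_numpy(),
                     v=df["v_mV"].to_numpy(), i_total=df["i_pA"].to_numpy(),
                     channel_currents=channel_currents, gates=gates, metadata=meta)
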