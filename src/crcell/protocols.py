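"""Stimulus programs for virtual patch-clamp experiments.

A :class:`Protocol` is an ordered list of constant segments (duration +
level) executed in current clamp (levels in pA) or voltage clamp (levels in
mV), optionally swept: a ``sweep_axis`` varies one segment's level or
duration over a list of values, generating a family of sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

__all__ = [
    "Segment",
    "SweepAxis",
    "Protocol",
    "vc_family",
    "inactivation_protocol",
    "recovery_protocol",
    "paired_pulse_protocol",
]


@dataclass
class Segment:
    duration: float  # ms
    level: float     # pA in current clamp, mV in voltage clamp

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")


@dataclass
class SweepAxis:
    segment_index: int
    values: Sequence[float]
    attribute: str = "level"  # "level" or "duration"

    def __post_init__(self) -> None:
        if self.attribute not in ("level", "duration"):
            raise ValueError("sweep attribute must be 'level' or 'duration'")
        if len(self.values) == 0:
            raise ValueError("sweep values must be non-empty")


@dataclass
class Protocol:
    mode: str  # "cc" | "vc"
    segments: list[Segment]
    sweep_axis: Optional[SweepAxis] = None
    holding_v: Optional[float] = None  # CC only: bias current holds this potential
    label: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("cc", "vc"):
            raise ValueError("mode must be 'cc' or 'vc'")
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if self.sweep_axis is not None:
            if not 0 <= self.sweep_axis.segment_index < len(self.segments):
                raise ValueError("sweep_axis addresses a nonexistent segment")
        if self.mode == "vc" and self.holding_v is not None:
            raise ValueError("holding_v applies to current clamp only")

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def sweeps(self) -> Iterator["Protocol"]:
        """Yield the concrete (sweep-free) protocols of the family."""
        if self.sweep_axis is None:
            yield self
            return
        ax = self.sweep_axis
        for value in ax.values:
            segs = [replace(s) for s in self.segments]
            setattr(segs[ax.segment_index], ax.attribute, value)
            yield Protocol(mode=self.mode, segments=segs, sweep_axis=None,
                           holding_v=self.holding_v,
                           label=f"{self.label}[{ax.attribute}={value}]")

    def segment_times(self) -> list[tuple[float, float]]:
        """(start, end) of each segment in ms from sweep start."""
        out, t = [], 0.0
        for s in self.segments:
            out.append((t, t + s.duration))
            t += s.duration
        return out

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "segments": [{"duration": s.duration, "level": s.level} for s in self.segments],
            "label": self.label,
        }
        if self.holding_v is not None:
            d["holding_v"] = self.holding_v
        if self.sweep_axis is not None:
            d["sweep_axis"] = {
                "segment_index": self.sweep_axis.segment_index,
                "values": list(self.sweep_axis.values),
                "attribute": self.sweep_axis.attribute,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        sweep = None
        if "sweep_axis" in d:
            sweep = SweepAxis(d["sweep_axis"]["segment_index"],
                              list(d["sweep_axis"]["values"]),
                              d["sweep_axis"].get("attribute", "level"))
        return cls(
            mode=d["mode"],
            segments=[Segment(s["duration"], s["level"]) for s in d["segments"]],
            sweep_axis=sweep,
            holding_v=d.get("holding_v"),
            label=d.get("label", ""),
        )


# ---------------------------------------------------------------------------
# canonical protocol builders


def vc_family(pre_level: float, pre_duration: float, step_levels: Sequence[float],
              step_duration: float, tail_level: Optional[float] = None,
              tail_duration: float = 100.0, label: str = "vc_family") -> Protocol:
    """Preconditioning pulse followed by a swept test step (and optional tail)."""
    if len(step_levels) == 0:
        raise ValueError("step_levels must be non-empty")
    segments = [Segment(pre_duration, pre_level), Segment(step_duration, step_levels[0])]
    if tail_level is not None:
        segments.append(Segment(tail_duration, tail_level))
    return Protocol(mode="vc", segments=segments,
                    sweep_axis=SweepAxis(1, list(step_levels)), label=label)


def inactivation_protocol(pre_levels: Sequence[float], pre_duration: float,
                          test_level: float, test_duration: float = 60.0) -> Protocol:
    """Steady-state inactivation: swept prepulse, fixed test pulse."""
    segments = [Segment(pre_duration, pre_levels[0]), Segment(test_duration, test_level)]
    return Protocol(mode="vc", segments=segments,
                    sweep_axis=SweepAxis(0, list(pre_levels)), label="inactivation")


def recovery_protocol(inactivating_level: float, inactivating_duration: float,
                      recovery_level: float, gaps: Sequence[float], test_level: float,
                      test_duration: float = 50.0,
                      conditioning_duration: float = 100.0) -> Protocol:
    """Double-pulse removal-of-inactivation: swept gap at the recovery level."""
    gaps = list(gaps)
    if gaps != sorted(gaps):
        raise ValueError("gaps must be sorted ascending")
    segments = [
        Segment(conditioning_duration, recovery_level),
        Segment(inactivating_duration, inactivating_level),
        Segment(gaps[0], recovery_level),
        Segment(test_duration, test_level),
    ]
    return Protocol(mode="vc", segments=segments,
                    sweep_axis=SweepAxis(2, gaps, attribute="duration"),
                    label="recovery")


def paired_pulse_protocol(pulse_amp: float, pulse_width: float,
                          intervals: Sequence[float], holding_v: float = -70.0,
                          baseline: float = 50.0, post: float = 100.0) -> Protocol:
    """Two identical depolarizing current pulses separated by a swept interval.

    The interval is measured onset-to-onset, as in paired-pulse excitability
    experiments, so the swept gap segment lasts ``interval - pulse_width``.
    """
    gaps = [iv - pulse_width for iv in intervals]
    if any(g <= 0 for g in gaps):
        raise ValueError("intervals must exceed the pulse width")
    segments = [
        Segment(baseline, 0.0),
        Segment(pulse_width, pulse_amp),
        Segment(gaps[0], 0.0),
        Segment(pulse_width, pulse_amp),
        Segment(post, 0.0),
    ]
    return Protocol(mode="cc", segments=segments,
                    sweep_axis=SweepAxis(2, gaps, attribute="duration"),
                    holding_v=holding_v, label="paired_pulse")
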