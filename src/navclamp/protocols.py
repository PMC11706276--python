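"""Episodic voltage-clamp stimulus descriptions.

A protocol is a per-sweep list of segments; one segment may be swept, either
in level (voltage-family protocols) or in duration (the recovery interpulse
interval).  The standard set mirrors routine whole-cell Na+ current
characterization from a holding potential of -120 mV:

* activation: 40-ms steps, -80..+55 mV in 5-mV increments (28 sweeps)
* steady-state inactivation: 100-ms prepulses, -80..+20 mV in 5-mV
  increments, then a 20-ms test pulse to -10 mV (21 sweeps)
* recovery from fast inactivation: paired 20-ms pulses to -10 mV (P1, P2)
  separated by a recovery interval at -120 mV, intervals log-spread from
  0.1 to 30 ms
* persistent current: a single 45-ms step to -10 mV (measurement at 40 ms)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Segment",
    "VoltageProtocol",
    "RecordingConditions",
    "standard_protocols",
    "HOLDING_MV",
    "RECOVERY_INTERVALS_MS",
]

HOLDING_MV = -120.0
#: paired-pulse interpulse intervals (ms); 0.1 ms anchors the
#: inactivated-fraction analysis
RECOVERY_INTERVALS_MS = (0.1, 0.2, 0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 12.0, 20.0, 30.0)


@dataclass(frozen=True)
class Segment:
    """One constant-voltage epoch.  ``level_mV`` or ``duration_ms`` may be
    None, marking the quantity swept across sweeps."""

    level_mV: float | None
    duration_ms: float | None

    def __post_init__(self) -> None:
        if self.duration_ms is not None and self.duration_ms <= 0:
            raise ValueError("segment duration must be > 0")


@dataclass(frozen=True)
class VoltageProtocol:
    """Sweep-structured command description.

    ``sweep_values`` instantiates the single swept segment (a level for
    ``swept="level"`` protocols, a duration for ``swept="duration"``).
    ``roles`` names analysis-relevant segments by index.
    """

    name: str
    holding_mV: float
    segments: tuple[Segment, ...]
    sweep_values: tuple[float, ...]
    swept: str = "level"  # "level" | "duration"
    sample_rate_hz: float = 50_000.0
    roles: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sweep_values) == 0:
            raise ValueError("sweep_values must be non-empty")
        diffs = np.diff(self.sweep_values)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("sweep_values must be strictly monotone")
        n_swept = sum(
            1
            for s in self.segments
            if (s.level_mV is None) or (s.duration_ms is None)
        )
        if n_swept != 1:
            raise ValueError("exactly one segment must be swept")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweep_values)

    def sweep_segments(self, i: int) -> list[tuple[float, float]]:
        """Concrete (level_mV, duration_ms) list for sweep i."""
        value = self.sweep_values[i]
        out = []
        for seg in self.segments:
            level = seg.level_mV if seg.level_mV is not None else value
            dur = seg.duration_ms if seg.duration_ms is not None else value
            out.append((level, dur))
        return out

    def max_duration_ms(self) -> float:
        """Longest sweep duration (sweeps are padded at holding to match)."""
        return max(
            sum(d for _, d in self.sweep_segments(i)) for i in range(self.n_sweeps)
        )


@dataclass(frozen=True)
class RecordingConditions:
    """Virtual-cell recording context.

    c_m: cell capacitance (pF) for current-density normalization; v_rev:
    reversal potential (mV) used in the conductance transform; g_max_total:
    whole-cell maximal conductance (nS).
    """

    c_m: float = 10.0
    v_rev: float = 65.0
    g_max_total: float = 50.0

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ValueError("c_m must be > 0")
        if self.g_max_total <= 0:
            raise ValueError("g_max_total must be > 0")


def activation_protocol() -> VoltageProtocol:
    return VoltageProtocol(
        name="activation",
        holding_mV=HOLDING_MV,
        segments=(
            Segment(HOLDING_MV, 5.0),
            Segment(None, 40.0),
            Segment(HOLDING_MV, 5.0),
        ),
        sweep_values=tuple(np.arange(-80.0, 55.0 + 2.5, 5.0)),
        swept="level",
        roles={"step": 1},
    )


def inactivation_protocol() -> VoltageProtocol:
    return VoltageProtocol(
        name="inactivation",
        holding_mV=HOLDING_MV,
        segments=(
            Segment(HOLDING_MV, 5.0),
            Segment(None, 100.0),
            Segment(-10.0, 20.0),
            Segment(HOLDING_MV, 5.0),
        ),
        sweep_values=tuple(np.arange(-80.0, 20.0 + 2.5, 5.0)),
        swept="level",
        roles={"prepulse": 1, "test": 2},
    )


def recovery_protocol() -> VoltageProtocol:
    return VoltageProtocol(
        name="recovery",
        holding_mV=HOLDING_MV,
        segments=(
            Segment(HOLDING_MV, 5.0),
            Segment(-10.0, 20.0),
            Segment(HOLDING_MV, None),
            Segment(-10.0, 20.0),
            Segment(HOLDING_MV, 5.0),
        ),
        sweep_values=RECOVERY_INTERVALS_MS,
        swept="duration",
        roles={"p1": 1, "gap": 2, "p2": 3},
    )


def persistent_protocol() -> VoltageProtocol:
    return VoltageProtocol(
        name="persistent",
        holding_mV=HOLDING_MV,
        segments=(
            Segment(HOLDING_MV, 5.0),
            Segment(None, 45.0),
            Segment(HOLDING_MV, 5.0),
        ),
        sweep_values=(-10.0,),
        swept="level",
        roles={"step": 1},
    )


def standard_protocols() -> dict[str, VoltageProtocol]:
    """The four standard protocols keyed by name."""
    return {
        "activation": activation_protocol(),
        "inactivation": inactivation_protocol(),
        "recovery": recovery_protocol(),
        "persistent": persistent_protocol(),
    }
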