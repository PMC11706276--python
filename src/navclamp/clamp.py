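"""Forward simulation of voltage-clamp protocols on a channel model.

The command potential is imposed exactly (ideal clamp, no series resistance),
gating is integrated, and the ideal leak-free channel current is recorded at
the protocol sample rate.  Because the command is piecewise constant and the
gate update is exponential-Euler (exact for constant V), each segment is
evaluated in closed form; the sampling interval ``dt`` only sets the
recording grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import gating
from .params import VariantParams
from .protocols import RecordingConditions, VoltageProtocol

__all__ = ["TraceSet", "IVCurve", "run_voltage_clamp", "peak_iv",
           "read_traceset_csv", "PEAK_BLANK_MS"]

#: initial window of each depolarizing step excluded from peak search
#: (capacitive-artifact convention; traces here are artifact-free)
PEAK_BLANK_MS = 0.1

MAX_DT_MS = 0.02  # 50 kHz


@dataclass
class TraceSet:
    """Sweep-structured recording: shared time base, one current and one
    command-voltage array per sweep, plus per-sweep segment windows."""

    protocol: VoltageProtocol
    time_ms: np.ndarray  # (n_t,)
    current_pA: np.ndarray  # (n_sweeps, n_t)
    command_mV: np.ndarray  # (n_sweeps, n_t)
    #: per sweep: list of (t_start, t_end, level_mV) for each segment
    windows: list[list[tuple[float, float, float]]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.current_pA)) and np.all(np.isfinite(self.command_mV))):
            raise FloatingPointError("non-finite values in trace set")

    @property
    def n_sweeps(self) -> int:
        return self.current_pA.shape[0]

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    def segment_slice(self, sweep: int, role: str) -> slice:
        """Sample slice of the protocol segment named ``role`` in ``sweep``."""
        idx = self.protocol.roles[role]
        t0, t1, _ = self.windows[sweep][idx]
        i0 = int(np.searchsorted(self.time_ms, t0 - 1e-9))
        i1 = int(np.searchsorted(self.time_ms, t1 - 1e-9))
        return slice(i0, i1)

    def to_csv(self, path: str | Path) -> None:
        """Write the documented CSV layout (time_ms, one column per sweep)
        plus a YAML metadata sidecar."""
        path = Path(path)
        header = ["time_ms"] + [f"sweep_{v:g}" for v in self.protocol.sweep_values]
        data = np.column_stack([self.time_ms, self.current_pA.T])
        np.savetxt(path, data, delimiter=",", header=",".join(header), comments="")
        sidecar = {
            "protocol": self.protocol.name,
            "holding_mV": float(self.protocol.holding_mV),
            "sample_rate_hz": float(self.protocol.sample_rate_hz),
            "sweep_values": [float(v) for v in self.protocol.sweep_values],
            **{
                k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in self.meta.items()
            },
        }
        path.with_suffix(path.suffix + ".yaml").write_text(
            yaml.safe_dump(sidecar, sort_keys=False)
        )


def read_traceset_csv(path: str | Path) -> TraceSet:
    """Re-import a trace-set CSV written by :meth:`TraceSet.to_csv`.

    The YAML sidecar identifies the protocol; only the standard protocols
    can be reconstructed (command voltages and segment windows are rebuilt
    from the protocol definition)."""
    from .protocols import standard_protocols

    path = Path(path)
    sidecar = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
    try:
        protocol = standard_protocols()[sidecar["protocol"]]
    except KeyError:
        raise ValueError(
            f"cannot reconstruct non-standard protocol {sidecar['protocol']!r}"
        ) from None
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    time = data[:, 0]
    currents = data[:, 1:].T
    total = protocol.max_duration_ms()
    commands = np.empty_like(currents)
    all_windows = []
    for s in range(protocol.n_sweeps):
        segs = protocol.sweep_segments(s)
        dur = sum(d for _, d in segs)
        if dur < total - 1e-9:
            segs = segs + [(protocol.holding_mV, total - dur)]
        t0 = 0.0
        windows = []
        for level, seg_dur in segs:
            t1 = t0 + seg_dur
            mask = (time >= t0 - 1e-9) & ((time < t1 - 1e-9) | (t1 >= total - 1e-9))
            commands[s, mask] = level
            windows.append((t0, t1, level))
            t0 = t1
        all_windows.append(windows)
    meta = {k: v for k, v in sidecar.items()
            if k not in ("protocol", "holding_mV", "sample_rate_hz", "sweep_values")}
    return TraceSet(
        protocol=protocol, time_ms=time, current_pA=currents,
        command_mV=commands, windows=all_windows, meta=meta,
    )


@dataclass
class IVCurve:
    """Peak current-voltage relation: one (V, peak pA, density pA/pF) per sweep."""

    voltage_mV: np.ndarray
    peak_pA: np.ndarray
    density_pA_per_pF: np.ndarray


def run_voltage_clamp(
    params: VariantParams,
    protocol: VoltageProtocol,
    cond: RecordingConditions,
    dt: float = 0.02,
) -> TraceSet:
    """Simulate ``protocol`` on the channel ``params`` under ``cond``.

    Gates start at steady state for the holding potential.  Sweeps of
    duration-swept protocols are padded at holding so all sweeps share one
    time base.  Deterministic; raises on non-finite state.
    """
    if dt <= 0 or dt > MAX_DT_MS + 1e-12:
        raise ValueError(f"dt must be in (0, {MAX_DT_MS}] ms, got {dt}")
    g = cond.g_max_total
    total = protocol.max_duration_ms()
    n_t = int(round(total / dt)) + 1
    time = np.arange(n_t) * dt

    currents = np.empty((protocol.n_sweeps, n_t))
    commands = np.empty_like(currents)
    all_windows: list[list[tuple[float, float, float]]] = []

    for s in range(protocol.n_sweeps):
        segs = protocol.sweep_segments(s)
        dur = sum(d for _, d in segs)
        if dur < total - 1e-9:  # pad to the shared time base
            segs = segs + [(protocol.holding_mV, total - dur)]
        m = float(gating.steady_state_activation(params, protocol.holding_mV))
        h = float(gating.steady_state_inactivation(params, protocol.holding_mV))
        t0 = 0.0
        windows = []
        for level, seg_dur in segs:
            t1 = t0 + seg_dur
            i0 = int(np.searchsorted(time, t0 - 1e-9))
            i1 = n_t if t1 >= total - 1e-9 else int(np.searchsorted(time, t1 - 1e-9))
            tr = time[i0:i1] - t0
            m_inf = float(gating.steady_state_activation(params, level))
            h_inf = float(gating.steady_state_inactivation(params, level))
            tau_m = float(gating.gate_tau(params, "m", level))
            tau_h = float(gating.gate_tau(params, "h", level))
            m_t = m_inf + (m - m_inf) * np.exp(-tr / tau_m)
            h_t = h_inf + (h - h_inf) * np.exp(-tr / tau_h)
            currents[s, i0:i1] = g * m_t * h_t * (level - params.e_na)
            commands[s, i0:i1] = level
            m = m_inf + (m - m_inf) * float(np.exp(-seg_dur / tau_m))
            h = h_inf + (h - h_inf) * float(np.exp(-seg_dur / tau_h))
            windows.append((t0, t1, level))
            t0 = t1
        all_windows.append(windows)

    return TraceSet(
        protocol=protocol,
        time_ms=time,
        current_pA=currents,
        command_mV=commands,
        windows=all_windows,
        meta={"variant": params.name, "g_max_nS": g, "c_m_pF": cond.c_m, "dt_ms": dt},
    )


def peak_inward(traces: TraceSet, sweep: int, role: str) -> float:
    """Most-negative current in the named segment, skipping the first
    PEAK_BLANK_MS after segment onset."""
    sl = traces.segment_slice(sweep, role)
    t0 = traces.windows[sweep][traces.protocol.roles[role]][0]
    t = traces.time_ms[sl]
    seg = traces.current_pA[sweep, sl]
    mask = (t - t0) >= PEAK_BLANK_MS - 1e-9
    if not mask.any():
        raise ValueError("segment shorter than the peak blanking window")
    return float(seg[mask].min())


def peak_iv(traces: TraceSet, cond: RecordingConditions, role: str = "step") -> IVCurve:
    """Peak inward current and current density per sweep of an
    activation-family protocol."""
    if traces.n_sweeps == 0 or traces.current_pA.size == 0:
        raise ValueError("empty trace set")
    peaks = np.array(
        [peak_inward(traces, s, role) for s in range(traces.n_sweeps)]
    )
    return IVCurve(
        voltage_mV=np.asarray(traces.protocol.sweep_values, dtype=float),
        peak_pA=peaks,
        density_pA_per_pF=peaks / cond.c_m,
    )
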