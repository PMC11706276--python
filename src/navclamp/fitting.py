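"""Measurement and curve-fitting pipeline for simulated clamp recordings.

Implements the standard analysis chain: peak I-V -> conductance transform
G = I/(V − V_rev) -> normalized Boltzmann fit for activation; test-pulse
availability -> falling Boltzmann for steady-state inactivation (with the
non-inactivating floor subtracted and the availability renormalized for
variants that do not inactivate fully); percent-of-peak persistent current at
40 ms with the >= 50% "non-determinable" rule; and single-exponential fits of
paired-pulse recovery in two modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .clamp import TraceSet, peak_inward, peak_iv
from .params import VariantParams
from .protocols import RecordingConditions

__all__ = [
    "BoltzmannFit",
    "RecoveryFit",
    "PersistentCurrent",
    "FitError",
    "fit_boltzmann",
    "fit_exponential",
    "activation_analysis",
    "inactivation_analysis",
    "measure_persistent",
    "recovery_analysis",
    "default_recovery_mode",
]

#: sweeps closer than this to the reversal potential are excluded from the
#: conductance transform (division blow-up)
REVERSAL_EXCLUSION_MV = 10.0
#: measured persistent current >= this percent of peak is reported as ND
ND_THRESHOLD_PCT = 50.0
#: gate floors at or above this use the difference-based recovery analysis
DIFF_MODE_FLOOR = 0.02


class FitError(RuntimeError):
    """Degenerate input or non-convergence of a least-squares fit."""


@dataclass(frozen=True)
class BoltzmannFit:
    v_half: float
    k: float
    residual: float
    n_points: int
    direction: str


@dataclass(frozen=True)
class RecoveryFit:
    tau: float
    residual: float
    mode: str
    n_points: int

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("recovery tau must be > 0")


@dataclass(frozen=True)
class PersistentCurrent:
    """Persistent current as percent of transient peak; ``nd`` flags the
    non-inactivating (>= 50%) case where a percent is not reported."""

    percent_of_peak: float
    nd: bool

    def report_value(self) -> str:
        return "ND" if self.nd else f"{self.percent_of_peak:.2f}"


def _boltzmann(V, v_half, k, sign):
    return 1.0 / (1.0 + np.exp(sign * (V - v_half) / k))


def fit_boltzmann(points, direction: str = "rising") -> BoltzmannFit:
    """Least-squares Boltzmann fit of (V, y) pairs with y in [0, 1].

    The midpoint is initialized from the half-maximum crossing by linear
    interpolation; the slope starts at 6 mV.  Degenerate (flat) data and
    non-convergence raise :class:`FitError`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise FitError("need >= 4 (V, y) points")
    V, y = pts[:, 0], pts[:, 1]
    if np.ptp(y) < 1e-3:
        raise FitError("degenerate input: y is (nearly) constant")
    sign = -1.0 if direction == "rising" else 1.0
    order = np.argsort(V)
    Vs, ys = V[order], y[order]
    yc = ys if direction == "rising" else ys[::-1]
    Vc = Vs if direction == "rising" else Vs[::-1]
    v0 = float(np.interp(0.5, np.clip(yc, 0, None), Vc))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda V, vh, k: _boltzmann(V, vh, k, sign),
                V,
                y,
                p0=[v0, 6.0],
                bounds=([-150.0, 0.1], [100.0, 50.0]),
                maxfev=10_000,
            )
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}") from None
    resid = float(np.linalg.norm(y - _boltzmann(V, *popt, sign)))
    if resid > 0.15 * np.sqrt(len(V)):
        raise FitError(
            f"poor fit quality (residual {resid:.3f} over {len(V)} points); "
            "signal may be noise-dominated"
        )
    if not (V.min() <= popt[0] <= V.max()):
        raise FitError(
            f"fitted midpoint {popt[0]:.1f} mV outside the sampled range "
            f"[{V.min():.0f}, {V.max():.0f}]"
        )
    return BoltzmannFit(
        v_half=float(popt[0]),
        k=float(popt[1]),
        residual=resid,
        n_points=len(V),
        direction=direction,
    )


def fit_exponential(points, t0: float = 0.0, mode: str = "standard") -> RecoveryFit:
    """Fit y = 1 − exp(−(t − t0)/tau) to (t, y) recovery points.

    tau is initialized by log-linear regression of 1 − y.  Non-monotone y
    (beyond a 2% tolerance) triggers a warning; non-convergence raises
    :class:`FitError`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise FitError("need >= 4 (t, y) points")
    t, y = pts[:, 0], pts[:, 1]
    if np.any(np.diff(y[np.argsort(t)]) < -0.02):
        warnings.warn("recovery data non-monotone beyond noise tolerance")
    resid0 = 1.0 - y
    ok = resid0 > 1e-12
    if ok.sum() >= 2:
        slope = np.polyfit(t[ok], np.log(resid0[ok]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else 1.0
    else:
        tau0 = 1.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda t, tau: 1.0 - np.exp(-(t - t0) / tau),
                t,
                y,
                p0=[max(tau0, 1e-3)],
                bounds=(1e-6, 1e4),
                maxfev=10_000,
            )
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from None
    resid = float(np.linalg.norm(y - (1.0 - np.exp(-(t - t0) / popt[0]))))
    return RecoveryFit(tau=float(popt[0]), residual=resid, mode=mode, n_points=len(t))


def activation_analysis(traces: TraceSet, cond: RecordingConditions) -> BoltzmannFit:
    """Activation curve from an activation-protocol trace set.

    Peak currents are converted to conductance G = I/(V − V_rev), sweeps
    within REVERSAL_EXCLUSION_MV of the reversal potential are excluded,
    G/G_max is fit with a rising Boltzmann.
    """
    iv = peak_iv(traces, cond)
    keep = np.abs(iv.voltage_mV - cond.v_rev) >= REVERSAL_EXCLUSION_MV
    if not keep.any():
        raise FitError("all sweeps excluded by the reversal window")
    G = iv.peak_pA[keep] / (iv.voltage_mV[keep] - cond.v_rev)
    g_max = G.max()
    if g_max <= 0:
        raise FitError("no inward conductance measured")
    pts = np.column_stack([iv.voltage_mV[keep], G / g_max])
    return fit_boltzmann(pts, direction="rising")


def inactivation_analysis(
    traces: TraceSet, floor_subtract: bool = True
) -> BoltzmannFit:
    """Availability curve from a steady-state-inactivation trace set.

    Test-pulse peak currents are normalized to the most hyperpolarized
    prepulse.  By default the non-inactivating floor — the availability
    remaining after the most depolarized prepulse — is subtracted and the
    curve renormalized, so the fit describes the inactivatable current
    fraction only.  For fully inactivating channels the subtraction is a
    numerical no-op; for channels with a persistent floor it is what makes
    the availability midpoint identifiable at all.
    """
    peaks = np.array(
        [peak_inward(traces, s, "test") for s in range(traces.n_sweeps)]
    )
    ref = peaks[0]  # most hyperpolarized prepulse
    if ref >= 0:
        raise FitError("no inward test-pulse current")
    avail = peaks / ref
    if floor_subtract:
        lo, hi = avail.min(), avail.max()
        if hi - lo < 1e-3:
            raise FitError("flat availability curve")
        avail = (avail - lo) / (hi - lo)
    if np.ptp(avail) < 1e-3:
        raise FitError("flat availability curve")
    pts = np.column_stack([np.asarray(traces.protocol.sweep_values), avail])
    return fit_boltzmann(pts, direction="falling")


def measure_persistent(traces: TraceSet, role: str = "step") -> PersistentCurrent:
    """Persistent current 40 ms after step onset, percent of inward peak.

    Values >= 50% of peak are flagged ND (non-inactivating) rather than
    reported as a percentage.  Runs on the -10 mV sweep of a step protocol
    whose step lasts >= 40 ms.
    """
    sweep_vals = np.asarray(traces.protocol.sweep_values, dtype=float)
    candidates = np.where(np.isclose(sweep_vals, -10.0))[0]
    if len(candidates) == 0:
        raise ValueError("protocol has no -10 mV sweep")
    s = int(candidates[0])
    idx = traces.protocol.roles[role]
    t0, t1, _ = traces.windows[s][idx]
    if t1 - t0 < 40.0 - 1e-9:
        raise ValueError("step must last >= 40 ms for the persistent measurement")
    peak = peak_inward(traces, s, role)
    if peak >= 0:
        raise ValueError("inward peak is zero; persistent fraction undefined")
    i40 = int(round((t0 + 40.0) / traces.dt_ms))
    pct = 100.0 * float(traces.current_pA[s, i40]) / peak
    return PersistentCurrent(percent_of_peak=pct, nd=pct >= ND_THRESHOLD_PCT)


def default_recovery_mode(params: VariantParams) -> str:
    """Analysis mode appropriate for a variant: the difference-based
    (inactivated-fraction) estimator whenever a persistent floor exists,
    since the P2/P1 ratio then never starts from zero availability."""
    return (
        "inactivated_fraction"
        if params.persistent_frac >= DIFF_MODE_FLOOR
        else "standard"
    )


def recovery_analysis(traces: TraceSet, mode: str = "standard") -> RecoveryFit:
    """Recovery time constant from a paired-pulse trace set.

    standard: fits I/I_max = 1 − exp(−t/tau) to P2/P1 peak ratios.
    inactivated_fraction: the inactivated fraction is the P1−P2 peak
    difference; its recovery relative to the t = 0.1 ms reference is fitted
    with the same exponential form anchored at that reference interval
    (the closed form of the normalized difference signal).
    """
    if mode not in ("standard", "inactivated_fraction"):
        raise ValueError(f"unknown recovery mode {mode!r}")
    intervals = np.asarray(traces.protocol.sweep_values, dtype=float)
    if len(intervals) < 6:
        raise FitError("need >= 6 interpulse intervals")
    p1 = np.array([peak_inward(traces, s, "p1") for s in range(traces.n_sweeps)])
    p2 = np.array([peak_inward(traces, s, "p2") for s in range(traces.n_sweeps)])
    if np.any(p1 >= 0):
        raise FitError("P1 peak is zero; cannot normalize recovery")
    if mode == "standard":
        y = p2 / p1
        return fit_exponential(np.column_stack([intervals, y]), mode=mode)
    diff = p1 - p2  # inward peaks are negative: p1 - p2 <= 0, magnitude decays
    ref = diff[np.argmin(intervals)]
    if abs(ref) < 1e-12:
        raise FitError("no inactivated fraction at the reference interval")
    y = 1.0 - diff / ref
    t_ref = float(intervals.min())
    return fit_exponential(np.column_stack([intervals, y]), t0=t_ref, mode=mode)
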