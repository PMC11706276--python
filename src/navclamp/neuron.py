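"""Virtual dynamic action potential clamp: a hybrid AIS neuron.

A single-compartment axon-initial-segment membrane receives three active
conductances: an in-silico delayed-rectifier K+ channel (n^4), an in-silico
Na_v_1.6 channel (m^3 h, activation left-shifted relative to Na_v_1.2 as at
the AIS), and the "external" Na_v_1.2 variant current produced by the same
single-gate channel model used in voltage clamp, scaled by ``na12_fraction``
of a wild-type-equivalent reference conductance.  This mirrors the dynamic
clamp configuration in which a patch-clamped cell's scaled Na_v_1.2 current
is injected into the model neuron whose membrane potential is fed back as
the command voltage.

The membrane equation  c_m dV/dt = −(I_leak + I_Kv + I_Nav1.6 + I_Nav1.2)
+ I_stim  is integrated with exponential-Euler updates for both the gates
and the voltage (the voltage relaxes toward the instantaneous weighted
reversal with time constant c_m/g_total each step).

The AIS parameters are a calibrated, frozen default set: only qualitative
firing phenotypes are claimed for this model (input-output shape, sustained
depolarization by non-inactivating variants, potentiation at low variant
fractions), not particular voltages or frequencies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import gating
from .params import VariantParams

__all__ = [
    "KvModel",
    "Nav16Model",
    "AISModel",
    "DAPCConfig",
    "SimResult",
    "FiringSummary",
    "DepolarizationSummary",
    "run_hybrid_sim",
    "detect_spikes",
    "input_output_curve",
    "detect_sustained_depolarization",
    "fraction_sweep",
    "pearson_r",
    "check_current_balance",
    "STIM_AMPLITUDES_PA",
]

#: step-current family: 1-s steps, 2-pA increments, -2..+24 pA
STIM_AMPLITUDES_PA = tuple(float(a) for a in range(-2, 25, 2))


def _sig(x: float) -> float:
    if x > 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


@dataclass(frozen=True)
class KvModel:
    """Delayed-rectifier K+ conductance, n^4 gating."""

    g_nS: float = 50.0
    e_K: float = -90.0
    v_half_n: float = -5.0
    k_n: float = 5.0
    tau_n_min: float = 4.0
    tau_n_amp: float = 55.0
    tau_n_vmid: float = -45.0
    tau_n_k: float = 10.0

    def n_inf(self, V: float) -> float:
        return _sig((V - self.v_half_n) / self.k_n)

    def tau_n(self, V: float) -> float:
        return self.tau_n_min + self.tau_n_amp * _sig(-(V - self.tau_n_vmid) / self.tau_n_k)


@dataclass(frozen=True)
class Nav16Model:
    """AIS Na_v_1.6 conductance, m^3 h gating.

    Activation sits hyperpolarized relative to Na_v_1.2 (the AIS property
    that makes it the spike initiator); inactivation is steep and recovers
    slowly in the subthreshold dwell range, which shapes the upper limit of
    the input-output relation (firing collapses into depolarization block at
    the largest stimulus steps, giving the bell-shaped relation seen in
    dynamic-clamp recordings).
    """

    g_nS: float = 100.0
    e_Na: float = 65.0
    v_half_m: float = -48.0
    k_m: float = 6.5
    v_half_h: float = -50.0
    k_h: float = 3.5
    tau_m_min: float = 0.01
    tau_m_amp: float = 0.04
    tau_h_min: float = 0.5
    tau_h_amp: float = 30.0
    tau_h_vmid: float = -63.0
    tau_h_delta: float = 13.0
    tau_h_k: float = 8.0

    def m_inf(self, V: float) -> float:
        return _sig((V - self.v_half_m) / self.k_m)

    def h_inf(self, V: float) -> float:
        return _sig(-(V - self.v_half_h) / self.k_h)

    def tau_m(self, V: float) -> float:
        return self.tau_m_min + self.tau_m_amp * _sig(-(V - self.v_half_m) / 15.0)

    def tau_h(self, V: float) -> float:
        norm = 2.0 * _sig(self.tau_h_delta / self.tau_h_k) - 1.0
        lo = _sig((V - (self.tau_h_vmid - self.tau_h_delta)) / self.tau_h_k)
        hi = _sig(-(V - (self.tau_h_vmid + self.tau_h_delta)) / self.tau_h_k)
        return self.tau_h_min + self.tau_h_amp * (lo + hi - 1.0) / norm


@dataclass(frozen=True)
class AISModel:
    """Single-compartment AIS membrane with its in-silico conductances.

    ``gKv_scale`` and ``gNav16_scale`` multiply the base conductances (the
    dynamic-clamp settings are 2 and 0.4); the native Na_v_1.2 conductance of
    the compartment is fixed at zero — variant current enters only through
    :class:`DAPCConfig`.  ``g_na12_ref`` is the wild-type-equivalent
    reference conductance scaled by the configured fraction; its default is
    calibrated so that a 0.2 fraction of the N1662D channel delivers a peak
    current of ~80 pA under an activation step.
    """

    c_m: float = 20.0
    g_leak: float = 0.4
    e_leak: float = -75.0
    kv: KvModel = field(default_factory=KvModel)
    nav16: Nav16Model = field(default_factory=Nav16Model)
    gKv_scale: float = 2.0
    gNav16_scale: float = 0.4
    g_na12_ref: float = 7.014

    def __post_init__(self) -> None:
        for attr in ("c_m", "g_leak"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        for attr in ("gKv_scale", "gNav16_scale", "g_na12_ref"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")

    def with_(self, **changes) -> "AISModel":
        return replace(self, **changes)


@dataclass
class DAPCConfig:
    """One dynamic-clamp experiment: a variant, its current fraction, and the
    step-stimulus family."""

    variant: VariantParams
    na12_fraction: float = 0.2
    stim_start_ms: float = 50.0
    stim_dur_ms: float = 1000.0
    post_ms: float = 50.0
    stim_amplitudes_pA: tuple[float, ...] = STIM_AMPLITUDES_PA
    dt_ms: float = 0.02
    record_components: bool = True

    def __post_init__(self) -> None:
        if self.na12_fraction < 0:
            raise ValueError("na12_fraction must be >= 0")
        if self.dt_ms <= 0 or self.dt_ms > 0.02 + 1e-12:
            raise ValueError("dt must be in (0, 0.02] ms")


@dataclass
class SimResult:
    """Recorded hybrid-neuron episode: V_m and component currents (pA)."""

    time_ms: np.ndarray
    vm_mV: np.ndarray
    i_kv: np.ndarray
    i_nav16: np.ndarray
    i_nav12: np.ndarray
    i_leak: np.ndarray
    i_stim: np.ndarray
    stim_start_ms: float
    stim_dur_ms: float
    c_m: float

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


@dataclass
class FiringSummary:
    """Input-output relation: spikes and mean frequency per stimulus step."""

    amplitudes_pA: np.ndarray
    spike_times_ms: list[np.ndarray]
    mean_freq_hz: np.ndarray


@dataclass
class DepolarizationSummary:
    sustained: bool
    plateau_vm: float
    onset_ms: float | None


def _na12_rates(params: VariantParams):
    """Scalar closed-over rate functions for the variant channel (fast path
    for the per-step neuron loop; same math as :mod:`navclamp.gating`)."""
    va, ka = params.v_half_act, params.k_act
    vi, ki = params.v_half_inact, params.k_inact
    pf = params.persistent_frac
    tau_a = params.tau_act_ms
    alpha, beta, g = gating._tau_h_coeffs(vi, params.tau_rec_ms, params.tau_inact_ms)
    delta, kb = gating._BELL_DELTA, gating._BELL_K
    norm = 2.0 * _sig(delta / kb) - 1.0
    tv, tk = gating._TREND_V, gating._TREND_K

    def rates(V: float):
        m_inf = _sig((V - va) / ka)
        h_inf = pf + (1.0 - pf) * _sig(-(V - vi) / ki)
        tau_m = 0.2 * tau_a + 0.8 * tau_a * _sig(-(V - va) / 15.0)
        bell = (_sig((V - (vi - delta)) / kb) + _sig(-(V - (vi + delta)) / kb) - 1.0) / norm
        tau_h = math.exp(alpha + beta * _sig((V - tv) / tk) + g * bell)
        return m_inf, tau_m, h_inf, tau_h

    return rates


def run_hybrid_sim(
    ais: AISModel, config: DAPCConfig, stim_amplitude: float
) -> SimResult:
    """Integrate one step-current episode of the hybrid neuron.

    Deterministic; raises on non-finite state.  Gates and voltage start at
    the resting fixed point found by a short unstimulated settling run from
    the leak reversal.
    """
    dt = config.dt_ms
    kv, nav16 = ais.kv, ais.nav16
    g_kv = ais.gKv_scale * kv.g_nS
    g_na16 = ais.gNav16_scale * nav16.g_nS
    g_na12 = config.na12_fraction * ais.g_na12_ref
    e_na12 = config.variant.e_na
    na12 = _na12_rates(config.variant)

    total = config.stim_start_ms + config.stim_dur_ms + config.post_ms
    n = int(round(total / dt)) + 1
    t_on, t_off = config.stim_start_ms, config.stim_start_ms + config.stim_dur_ms

    time = np.arange(n) * dt
    vm = np.empty(n)
    i_kv_arr = np.empty(n)
    i_na16_arr = np.empty(n)
    i_na12_arr = np.empty(n)
    i_leak_arr = np.empty(n)
    i_stim_arr = np.empty(n)

    # initial state: relax at rest (no stimulus, coarse steps are fine far
    # from threshold)
    V = ais.e_leak
    nK = kv.n_inf(V)
    m6, h6 = nav16.m_inf(V), nav16.h_inf(V)
    m2, tm2, h2i, th2 = na12(V)
    h2 = h2i
    for _ in range(2000):
        V, nK, m6, h6, m2, h2 = _step(
            ais, kv, nav16, na12, g_kv, g_na16, g_na12, e_na12,
            V, nK, m6, h6, m2, h2, 0.0, 0.5,
        )

    for i in range(n):
        t = time[i]
        stim = stim_amplitude if (t_on <= t < t_off) else 0.0
        ik = g_kv * nK**4 * (V - kv.e_K)
        ina16 = g_na16 * m6**3 * h6 * (V - nav16.e_Na)
        ina12 = g_na12 * m2 * h2 * (V - e_na12)
        ileak = ais.g_leak * (V - ais.e_leak)
        vm[i] = V
        i_kv_arr[i] = ik
        i_na16_arr[i] = ina16
        i_na12_arr[i] = ina12
        i_leak_arr[i] = ileak
        i_stim_arr[i] = stim
        V, nK, m6, h6, m2, h2 = _step(
            ais, kv, nav16, na12, g_kv, g_na16, g_na12, e_na12,
            V, nK, m6, h6, m2, h2, stim, dt,
        )
        if not math.isfinite(V):
            raise FloatingPointError(f"integration diverged at t={t:.3f} ms")

    return SimResult(
        time_ms=time,
        vm_mV=vm,
        i_kv=i_kv_arr,
        i_nav16=i_na16_arr,
        i_nav12=i_na12_arr,
        i_leak=i_leak_arr,
        i_stim=i_stim_arr,
        stim_start_ms=config.stim_start_ms,
        stim_dur_ms=config.stim_dur_ms,
        c_m=ais.c_m,
    )


def _step(ais, kv, nav16, na12, g_kv, g_na16, g_na12, e_na12,
          V, nK, m6, h6, m2, h2, stim, dt):
    """One exponential-Euler step of gates then voltage."""
    exp = math.exp
    # gates relax at the current V
    ninf = kv.n_inf(V)
    nK = ninf + (nK - ninf) * exp(-dt / kv.tau_n(V))
    minf6 = nav16.m_inf(V)
    m6 = minf6 + (m6 - minf6) * exp(-dt / nav16.tau_m(V))
    hinf6 = nav16.h_inf(V)
    h6 = hinf6 + (h6 - hinf6) * exp(-dt / nav16.tau_h(V))
    m2i, tm2, h2i, th2 = na12(V)
    m2 = m2i + (m2 - m2i) * exp(-dt / tm2)
    h2 = h2i + (h2 - h2i) * exp(-dt / th2)
    # voltage relaxes toward the instantaneous weighted reversal
    gk = g_kv * nK**4
    gn6 = g_na16 * m6**3 * h6
    gn2 = g_na12 * m2 * h2
    g_tot = ais.g_leak + gk + gn6 + gn2
    e_eff = (
        ais.g_leak * ais.e_leak + gk * kv.e_K + gn6 * nav16.e_Na
        + gn2 * e_na12 + stim
    ) / g_tot
    V = e_eff + (V - e_eff) * exp(-dt * g_tot / ais.c_m)
    return V, nK, m6, h6, m2, h2


def detect_spikes(
    time_ms: np.ndarray, vm_mV: np.ndarray, threshold: float = 0.0,
    refractory_ms: float = 2.0,
) -> np.ndarray:
    """Times of upward threshold crossings separated by the refractory gap."""
    above = vm_mV >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if len(crossings) == 0:
        return np.empty(0)
    times = time_ms[crossings]
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_ms:
            kept.append(t)
    return np.asarray(kept)


def input_output_curve(ais: AISModel, config: DAPCConfig) -> FiringSummary:
    """Mean firing frequency versus stimulus amplitude over the step family."""
    amps = np.asarray(config.stim_amplitudes_pA, dtype=float)
    spike_lists: list[np.ndarray] = []
    freqs = np.empty(len(amps))
    for i, amp in enumerate(amps):
        res = run_hybrid_sim(ais, config, amp)
        on, off = res.stim_start_ms, res.stim_start_ms + res.stim_dur_ms
        spikes = detect_spikes(res.time_ms, res.vm_mV)
        spikes = spikes[(spikes >= on) & (spikes < off)]
        spike_lists.append(spikes)
        freqs[i] = len(spikes) / (res.stim_dur_ms / 1000.0)
    return FiringSummary(
        amplitudes_pA=amps, spike_times_ms=spike_lists, mean_freq_hz=freqs
    )


def detect_sustained_depolarization(result: SimResult) -> DepolarizationSummary:
    """Plateau criterion: mean V_m over the final 200 ms of the stimulus
    above -30 mV with no spikes in the final 500 ms of the stimulus."""
    on, off = result.stim_start_ms, result.stim_start_ms + result.stim_dur_ms
    t = result.time_ms
    tail = (t >= off - 200.0) & (t < off)
    plateau = float(result.vm_mV[tail].mean())
    spikes = detect_spikes(t, result.vm_mV)
    late_spikes = spikes[(spikes >= off - 500.0) & (spikes < off)]
    sustained = plateau > -30.0 and len(late_spikes) == 0
    onset = None
    if sustained:
        depol = (t >= on) & (t < off) & (result.vm_mV > -30.0)
        onset = float(t[depol][0]) if depol.any() else None
    return DepolarizationSummary(sustained=sustained, plateau_vm=plateau, onset_ms=onset)


def fraction_sweep(
    ais: AISModel,
    variant: VariantParams,
    fractions,
    stim_amplitude: float,
    dt: float = 0.02,
) -> list[tuple[float, float]]:
    """Plateau V_m per Na_v_1.2 fraction; only sustained entries retained."""
    fractions = sorted(float(f) for f in fractions)
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be > 0")
    out = []
    for f in fractions:
        cfg = DAPCConfig(variant=variant, na12_fraction=f, dt_ms=dt)
        res = run_hybrid_sim(ais, cfg, stim_amplitude)
        summary = detect_sustained_depolarization(res)
        if summary.sustained:
            out.append((f, summary.plateau_vm))
    if not out:
        warnings.warn("no fraction produced sustained depolarization")
    return out


def pearson_r(xs, ys) -> float:
    """Product-moment correlation coefficient of paired samples."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) != len(ys) or len(xs) < 3:
        raise ValueError("need >= 3 paired samples")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(xs, ys).statistic)


def check_current_balance(result: SimResult) -> float:
    """Maximum residual of c_m dV/dt + sum(I_membrane) − I_stim (pA), using a
    central-difference derivative on interior samples.

    The residual is bounded by the second-order finite-difference truncation
    error, O(dt²·V''), not by machine precision; it shrinks as dt is reduced.
    """
    dvdt = np.gradient(result.vm_mV, result.time_ms)
    resid = (
        result.c_m * dvdt
        + result.i_kv + result.i_nav16 + result.i_nav12 + result.i_leak
        - result.i_stim
    )
    return float(np.abs(resid[2:-2]).max())
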