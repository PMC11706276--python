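"""Synthetic whole-cell recordings and parameter-recovery experiments.

Emulates the statistical structure the analysis pipeline faces in practice:
cell-to-cell variability of the gating parameters (drawn around the packaged
per-variant means with the population SD implied by the published SEM and n)
and additive band-limited recording noise (Gaussian, then low-pass filtered
at the 10 kHz acquisition cut-off).  Capacitive transients, seal leak and
series-resistance errors are deliberately not emulated.

Everything is seeded; there is no unseeded randomness anywhere in the
module.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import signal

from .calibrate import calibrate_gmax
from .clamp import TraceSet, run_voltage_clamp
from .fitting import (
    FitError,
    activation_analysis,
    default_recovery_mode,
    inactivation_analysis,
    measure_persistent,
    recovery_analysis,
)
from .params import VariantLibrary, VariantParams, default_library
from .protocols import RecordingConditions, standard_protocols

__all__ = [
    "CellPopulationSpec",
    "RecoveryReport",
    "sample_cells",
    "add_recording_noise",
    "recovery_experiment",
    "load_dispersion_table",
]

#: acquisition low-pass cut-off applied to the injected noise (Hz)
NOISE_CUTOFF_HZ = 10_000.0


@dataclass(frozen=True)
class CellPopulationSpec:
    """A virtual cell population for one variant.

    ``dispersion`` maps parameter name -> population SD; when omitted the
    published SEM·sqrt(n) (the implied population SD) is used for the
    parameters that have published errors, and zero for the rest.
    ``noise_sigma`` is the pre-filter SD of the additive recording noise in
    pA.  ``seed`` is mandatory.
    """

    variant: str
    n_cells: int
    seed: int
    noise_sigma: float = 0.0
    dispersion: dict[str, float] | None = None
    c_m: float = 10.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class RecoveryReport:
    """Aggregate of a parameter-recovery experiment.

    For each measured quantity: the generating truth, the mean and SD of the
    per-cell estimates, and the relative bias.  Failed fits are counted, not
    fatal.
    """

    variant: str
    n_cells: int
    n_success: int
    n_failed: int
    truth: dict[str, float]
    mean_estimate: dict[str, float] = field(default_factory=dict)
    sd_estimate: dict[str, float] = field(default_factory=dict)
    relative_bias: dict[str, float] = field(default_factory=dict)


def load_dispersion_table() -> dict[str, dict[str, tuple[float, int]]]:
    """Published per-variant (SEM, n) pairs for the five measured columns."""
    path = Path(resources.files("navclamp") / "data" / "table1_dispersion.csv")
    out: dict[str, dict[str, tuple[float, int]]] = {}
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            entry = {}
            for quantity in ("peak_density", "v_half_act", "v_half_inact",
                             "persistent_pct", "tau_rec"):
                sem = row[f"sem_{quantity}"]
                n = row[f"n_{quantity}"]
                if sem.strip():
                    entry[quantity] = (float(sem), int(n))
            out[row["name"]] = entry
    return out


def _implied_sd(variant: str) -> dict[str, float]:
    """Population SD implied by SEM·sqrt(n) for the published quantities."""
    table = load_dispersion_table().get(variant, {})
    mapping = {
        "peak_density": "peak_density",
        "v_half_act": "v_half_act",
        "v_half_inact": "v_half_inact",
        "tau_rec": "tau_rec_ms",
        "persistent_pct": "persistent_frac",
    }
    out = {}
    for quantity, attr in mapping.items():
        if quantity in table:
            sem, n = table[quantity]
            sd = sem * np.sqrt(n)
            if attr == "persistent_frac":
                sd /= 100.0  # percent -> fraction
            out[attr] = float(sd)
    return out


def sample_cells(
    spec: CellPopulationSpec, library: VariantLibrary | None = None
) -> list[VariantParams]:
    """Draw ``n_cells`` parameter sets around the variant's table values.

    Parameters are sampled independently from normal distributions;
    ``persistent_frac`` is clipped to [0, 1] and positive-only parameters
    are clipped away from zero.  Deterministic for a fixed seed.
    """
    library = default_library() if library is None else library
    base = library[spec.variant]
    sd = _implied_sd(spec.variant) if spec.dispersion is None else dict(spec.dispersion)
    rng = np.random.default_rng(spec.seed)
    cells = []
    for i in range(spec.n_cells):
        changes: dict[str, float] = {}
        for attr, sigma in sd.items():
            if sigma == 0:
                continue
            value = float(rng.normal(getattr(base, attr), sigma))
            if attr == "persistent_frac":
                value = float(np.clip(value, 0.0, 1.0))
            elif attr in ("peak_density", "tau_rec_ms", "k_act", "k_inact",
                          "tau_inact_ms", "tau_act_ms"):
                value = max(value, 1e-3)
            changes[attr] = value
        if changes.get("persistent_frac") is not None:
            changes["non_inactivating"] = changes["persistent_frac"] >= 0.5
        cells.append(base.with_(name=f"{base.name}#{i}", **changes))
    return cells


def add_recording_noise(traces: TraceSet, sigma: float, seed: int) -> TraceSet:
    """Additive band-limited Gaussian noise on every current sample.

    White Gaussian noise of SD ``sigma`` (pA) is low-pass filtered with a
    4-pole Butterworth at the 10-kHz acquisition cut-off (zero-phase), which
    is what a filtered patch-clamp record looks like.  ``sigma = 0`` returns
    the input unchanged (bitwise).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return traces
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=traces.current_pA.shape)
    fs = traces.protocol.sample_rate_hz
    wn = min(NOISE_CUTOFF_HZ / (fs / 2.0), 0.99)
    b, a = signal.butter(4, wn)
    noise = signal.filtfilt(b, a, noise, axis=1)
    return TraceSet(
        protocol=traces.protocol,
        time_ms=traces.time_ms,
        current_pA=traces.current_pA + noise,
        command_mV=traces.command_mV,
        windows=traces.windows,
        meta={**traces.meta, "noise_sigma_pA": sigma, "noise_seed": seed},
    )


def _measure_cell(cell: VariantParams, cond: RecordingConditions,
                  sigma: float, rng: np.random.Generator, dt: float) -> dict[str, float]:
    prot = standard_protocols()
    estimates: dict[str, float] = {}
    seeds = rng.integers(0, 2**31 - 1, size=4)
    act = add_recording_noise(
        run_voltage_clamp(cell, prot["activation"], cond, dt), sigma, int(seeds[0]))
    inact = add_recording_noise(
        run_voltage_clamp(cell, prot["inactivation"], cond, dt), sigma, int(seeds[1]))
    rec = add_recording_noise(
        run_voltage_clamp(cell, prot["recovery"], cond, dt), sigma, int(seeds[2]))
    pers = add_recording_noise(
        run_voltage_clamp(cell, prot["persistent"], cond, dt), sigma, int(seeds[3]))
    estimates["v_half_act"] = activation_analysis(act, cond).v_half
    estimates["v_half_inact"] = inactivation_analysis(inact).v_half
    estimates["tau_rec_ms"] = recovery_analysis(
        rec, mode=default_recovery_mode(cell)).tau
    persistent = measure_persistent(pers)
    if not persistent.nd:
        estimates["persistent_pct"] = persistent.percent_of_peak
    return estimates


def recovery_experiment(
    spec: CellPopulationSpec,
    library: VariantLibrary | None = None,
    dt: float = 0.02,
) -> RecoveryReport:
    """End-to-end validation loop: sample cells, simulate all standard
    protocols, add noise, run every analysis, and aggregate estimates
    against the generating truth."""
    library = default_library() if library is None else library
    base = library[spec.variant]
    cells = sample_cells(spec, library)
    rng = np.random.default_rng(spec.seed + 1)

    per_cell: list[dict[str, float]] = []
    n_failed = 0
    for cell in cells:
        cond = RecordingConditions(
            c_m=spec.c_m, v_rev=cell.e_na,
            g_max_total=calibrate_gmax(cell, RecordingConditions(
                c_m=spec.c_m, v_rev=cell.e_na, g_max_total=1.0), dt),
        )
        try:
            per_cell.append(_measure_cell(cell, cond, spec.noise_sigma, rng, dt))
        except (FitError, ValueError, FloatingPointError):
            n_failed += 1

    truth = {
        "v_half_act": base.v_half_act,
        "v_half_inact": base.v_half_inact,
        "tau_rec_ms": base.tau_rec_ms,
    }
    if not base.non_inactivating:
        truth["persistent_pct"] = 100.0 * base.persistent_frac

    report = RecoveryReport(
        variant=spec.variant,
        n_cells=spec.n_cells,
        n_success=len(per_cell),
        n_failed=n_failed,
        truth=truth,
    )
    for key, true_val in truth.items():
        vals = np.array([c[key] for c in per_cell if key in c])
        if len(vals) == 0:
            continue
        report.mean_estimate[key] = float(vals.mean())
        report.sd_estimate[key] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        denom = abs(true_val) if true_val != 0 else 1.0
        report.relative_bias[key] = float((vals.mean() - true_val) / denom)
    return report
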