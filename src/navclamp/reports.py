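"""Report generation: machine-readable JSON and a human-readable Markdown
table mirroring the layout of the published characterization (density,
activation and inactivation midpoints, persistent %, recovery tau)."""

from __future__ import annotations

import json
from pathlib import Path

from .calibrate import VariantCharacterization

__all__ = ["write_report", "characterization_to_dict"]

_COLUMNS = [
    ("peak_density_pA_per_pF", "I_Na density at -10 mV (pA/pF)"),
    ("v_half_act", "V_0.5,act (mV)"),
    ("v_half_inact", "V_0.5,inact (mV)"),
    ("persistent", "I_Na-P at -10 mV (% of peak)"),
    ("tau_rec_ms", "t recovery (ms)"),
]


def characterization_to_dict(c: VariantCharacterization) -> dict:
    return {
        "variant": c.name,
        "peak_density_pA_per_pF": c.peak_density_pA_per_pF,
        "v_half_act": c.v_half_act,
        "k_act": c.k_act,
        "v_half_inact": c.v_half_inact,
        "k_inact": c.k_inact,
        "persistent_pct": c.persistent_pct,
        "persistent_nd": c.persistent_nd,
        "tau_rec_ms": c.tau_rec_ms,
        "recovery_mode": c.recovery_mode,
    }


def _cell(c: VariantCharacterization, key: str) -> str:
    if key == "persistent":
        return "ND" if c.persistent_nd else f"{c.persistent_pct:.2f}"
    val = getattr(c, key)
    return f"{val:.2f}"


def write_report(results: list[VariantCharacterization], path: str | Path) -> None:
    """Write ``<path>.json`` and ``<path>.md`` for a list of simulated
    variant characterizations.  An empty list yields a valid empty report.
    ND-flagged persistent currents appear literally as "ND"."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [characterization_to_dict(c) for c in results]
    path.with_suffix(".json").write_text(json.dumps(payload, indent=2) + "\n")

    lines = [
        "| Variant | " + " | ".join(h for _, h in _COLUMNS) + " |",
        "|" + "---|" * (len(_COLUMNS) + 1),
    ]
    for c in results:
        lines.append(
            "| " + c.name + " | " + " | ".join(_cell(c, k) for k, _ in _COLUMNS) + " |"
        )
    path.with_suffix(".md").write_text("\n".join(lines) + "\n")
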