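"""Variant parameterization for Na_v_1.2 channel models.

Each channel variant is described by the quantities measured in whole-cell
voltage clamp: peak current density, activation and steady-state-inactivation
midpoints and slopes, the persistent (non-inactivating) current fraction, and
the time constant of recovery from fast inactivation.  The packaged parameter
file transcribes the characterization of wild-type plus eleven engineered and
pathogenic variants (N1662D, Q1494A/E/L/K, F1651C, M1501V/T, L1657P, P1658S,
A1659V).

Units are fixed package-wide: mV, ms, pA, nS, pF.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator

__all__ = [
    "VariantParams",
    "ChannelState",
    "VariantLibrary",
    "load_variant_table",
    "write_variant_table",
    "default_library",
    "VariantTableError",
]

#: column order of the variant parameter file (CSV)
TABLE_COLUMNS = (
    "name",
    "peak_density_pA_per_pF",
    "v_half_act_mV",
    "k_act_mV",
    "v_half_inact_mV",
    "k_inact_mV",
    "persistent_frac",
    "tau_rec_ms",
    "tau_inact_ms",
    "e_na_mV",
    "non_inactivating",
)


class VariantTableError(ValueError):
    """Raised when a variant parameter file violates the documented schema."""


@dataclass(frozen=True)
class VariantParams:
    """Gating parameterization of one Na_v_1.2 variant.

    Parameters
    ----------
    name : str
        Variant label, e.g. ``"WT"`` or ``"N1662D"``.
    peak_density : float
        Inward peak current density at -10 mV, pA/pF (positive magnitude;
        currents are negated to inward-negative at the trace level).
    v_half_act, k_act : float
        Midpoint and slope (mV) of the conductance-level activation sigmoid;
        ``k_act > 0`` and the sigmoid rises with voltage.
    v_half_inact, k_inact : float
        Midpoint and slope (mV) of the availability sigmoid; falls with
        voltage.
    persistent_frac : float
        Floor of the inactivation gate in [0, 1]: the fraction of conductance
        that never inactivates.
    tau_rec_ms : float
        Inactivation-gate time constant at the -120 mV recovery potential.
    tau_act_ms : float
        Scale of the activation-gate time constant (its hyperpolarized
        plateau value).
    tau_inact_ms : float
        Inactivation-gate time constant at -10 mV.
    non_inactivating : bool
        True for variants whose persistent current is >= 50% of the transient
        peak (the "ND" group).
    e_na : float
        Na+ reversal potential, mV.
    """

    name: str
    peak_density: float
    v_half_act: float
    k_act: float
    v_half_inact: float
    k_inact: float
    persistent_frac: float
    tau_rec_ms: float
    tau_act_ms: float = 0.05
    tau_inact_ms: float = 3.0
    non_inactivating: bool = False
    e_na: float = 65.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistent_frac <= 1.0:
            raise ValueError(
                f"{self.name}: persistent_frac must be in [0, 1], "
                f"got {self.persistent_frac}"
            )
        for attr in ("k_act", "k_inact", "tau_rec_ms", "tau_act_ms",
                     "tau_inact_ms", "peak_density"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.name}: {attr} must be > 0")
        if self.non_inactivating != (self.persistent_frac >= 0.5):
            raise ValueError(
                f"{self.name}: non_inactivating flag must equal "
                f"(persistent_frac >= 0.5); got flag={self.non_inactivating}, "
                f"persistent_frac={self.persistent_frac}"
            )

    def with_(self, **changes) -> "VariantParams":
        """Return a copy with fields replaced (validation re-runs)."""
        return replace(self, **changes)


@dataclass
class ChannelState:
    """Instantaneous gate occupancies: activation ``m`` and inactivation ``h``."""

    m: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.m <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError(f"gates must lie in [0, 1], got m={self.m}, h={self.h}")


@dataclass
class VariantLibrary:
    """Ordered, name-unique collection of :class:`VariantParams`."""

    variants: dict[str, VariantParams] = field(default_factory=dict)

    def __getitem__(self, name: str) -> VariantParams:
        try:
            return self.variants[name]
        except KeyError:
            raise KeyError(
                f"unknown variant {name!r}; available: {sorted(self.variants)}"
            ) from None

    def __iter__(self) -> Iterator[VariantParams]:
        return iter(self.variants.values())

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, name: str) -> bool:
        return name in self.variants

    @property
    def names(self) -> list[str]:
        return list(self.variants)

    def add(self, params: VariantParams) -> None:
        if params.name in self.variants:
            raise VariantTableError(f"duplicate variant name {params.name!r}")
        self.variants[params.name] = params


def _parse_bool(raw: str, where: str) -> bool:
    val = raw.strip().lower()
    if val in ("true", "1", "yes"):
        return True
    if val in ("false", "0", "no"):
        return False
    raise VariantTableError(f"{where}: expected a boolean, got {raw!r}")


def load_variant_table(path: str | Path) -> VariantLibrary:
    """Load and validate a variant parameter CSV.

    The file must carry exactly the documented header (see
    :data:`TABLE_COLUMNS`); unknown or missing columns, non-numeric cells,
    duplicate names and invariant violations raise
    :class:`VariantTableError` naming the offending row and column.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise VariantTableError(f"{path}: no variants (empty file)")
        extra = set(reader.fieldnames) - set(TABLE_COLUMNS)
        missing = set(TABLE_COLUMNS) - set(reader.fieldnames)
        if extra:
            raise VariantTableError(f"{path}: unknown column(s) {sorted(extra)}")
        if missing:
            raise VariantTableError(f"{path}: missing column(s) {sorted(missing)}")
        lib = VariantLibrary()
        for i, row in enumerate(reader, start=2):
            where = f"{path} row {i} ({row.get('name', '?')})"
            kwargs: dict = {"name": row["name"].strip()}
            if not kwargs["name"]:
                raise VariantTableError(f"{where}: empty variant name")
            numeric = {
                "peak_density": "peak_density_pA_per_pF",
                "v_half_act": "v_half_act_mV",
                "k_act": "k_act_mV",
                "v_half_inact": "v_half_inact_mV",
                "k_inact": "k_inact_mV",
                "persistent_frac": "persistent_frac",
                "tau_rec_ms": "tau_rec_ms",
                "tau_inact_ms": "tau_inact_ms",
                "e_na": "e_na_mV",
            }
            for attr, col in numeric.items():
                try:
                    kwargs[attr] = float(row[col])
                except (TypeError, ValueError):
                    raise VariantTableError(
                        f"{where}, column {col!r}: non-numeric cell {row[col]!r}"
                    ) from None
            kwargs["non_inactivating"] = _parse_bool(
                row["non_inactivating"], f"{where}, column 'non_inactivating'"
            )
            try:
                params = VariantParams(**kwargs)
            except ValueError as exc:
                raise VariantTableError(f"{where}: {exc}") from None
            lib.add(params)
    if len(lib) == 0:
        raise VariantTableError(f"{path}: no variants")
    return lib


def write_variant_table(lib: VariantLibrary, path: str | Path) -> None:
    """Write a library back to the documented CSV schema (round-trips)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TABLE_COLUMNS)
        for p in lib:
            writer.writerow(
                [
                    p.name,
                    p.peak_density,
                    p.v_half_act,
                    p.k_act,
                    p.v_half_inact,
                    p.k_inact,
                    p.persistent_frac,
                    p.tau_rec_ms,
                    p.tau_inact_ms,
                    p.e_na,
                    "true" if p.non_inactivating else "false",
                ]
            )


def packaged_table_path() -> Path:
    """Path of the parameter file shipped with the package."""
    return Path(resources.files("navclamp") / "data" / "variants.csv")


def default_library() -> VariantLibrary:
    """The packaged 12-variant library (WT first)."""
    return load_variant_table(packaged_table_path())
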