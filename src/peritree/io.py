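"""Readers and writers for outlet specs, surrogates and BC files.

CSV files are comma-separated, dot-decimal, UTF-8 with a mandatory header
row; provenance (package version, seed, config hash) travels in ``#``
comment lines at the top of boundary-condition files.  Stored quantities
are SI; millimetres, cm/s and mmHg are accepted/emitted only at the
documented I/O columns (1 mmHg = 133.322 Pa).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .coupling import (
    CoupledSolution,
    DomainSurrogate,
    OutletBC,
    OutletSpec,
    Segment,
    inlet_flow_from_velocity,
)
from .units import cms_to_ms, mm_to_m, pa_to_mmhg

__all__ = [
    "read_outlet_spec",
    "write_outlet_spec",
    "BCRecord",
    "bc_records_standalone",
    "bc_records_from_solution",
    "write_bc_file",
    "read_bc_file",
    "read_surrogate",
    "write_surrogate",
    "write_solution",
]


class OutletSpecError(ValueError):
    """A problem in an outlet-specification file, naming the offending field."""


def read_outlet_spec(path: str | Path) -> tuple[OutletSpec, ...]:
    """Read and validate an outlet set from CSV or JSON.

    Required columns/keys: ``name`` and one of ``diameter_mm`` /
    ``radius_mm``; optional: ``measured_velocity_cm_s``, ``is_ica``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, comment="#")

    if "name" not in df.columns:
        raise OutletSpecError(f"{path}: missing required column 'name'")
    if "radius_mm" not in df.columns and "diameter_mm" not in df.columns:
        raise OutletSpecError(
            f"{path}: need a 'radius_mm' or 'diameter_mm' column"
        )
    names = df["name"].astype(str).tolist()
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise OutletSpecError(f"{path}: duplicate outlet names {sorted(dupes)}")

    radius_col = "radius_mm" if "radius_mm" in df.columns else "diameter_mm"
    outlets = []
    for i, row in df.iterrows():
        raw = row[radius_col]
        try:
            val = float(raw)
        except (TypeError, ValueError):
            raise OutletSpecError(
                f"{path}: row {i} ({row['name']}): non-numeric {radius_col}={raw!r}"
            ) from None
        if not math.isfinite(val) or val <= 0:
            raise OutletSpecError(
                f"{path}: row {i} ({row['name']}): non-positive {radius_col}={val}"
            )
        radius_m = mm_to_m(val if radius_col == "radius_mm" else val / 2.0)
        v_meas = None
        if "measured_velocity_cm_s" in df.columns and pd.notna(
            row["measured_velocity_cm_s"]
        ):
            try:
                v_meas = cms_to_ms(float(row["measured_velocity_cm_s"]))
            except (TypeError, ValueError):
                raise OutletSpecError(
                    f"{path}: row {i} ({row['name']}): non-numeric "
                    f"measured_velocity_cm_s={row['measured_velocity_cm_s']!r}"
                ) from None
        is_ica = bool(row["is_ica"]) if "is_ica" in df.columns else False
        outlets.append(
            OutletSpec(
                name=str(row["name"]),
                radius=radius_m,
                is_ica=is_ica,
                measured_velocity=v_meas,
            )
        )
    return tuple(outlets)


def write_outlet_spec(outlets, path: str | Path) -> None:
    rows = []
    for o in outlets:
        rows.append(
            {
                "name": o.name,
                "radius_mm": o.radius * 1e3,
                "is_ica": int(o.is_ica),
                "measured_velocity_cm_s": (
                    o.measured_velocity * 1e2
                    if o.measured_velocity is not None
                    else ""
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class BCRecord:
    """One outlet's boundary condition as written to a BC file."""

    name: str
    variant: str
    resistance: float  # Pa·s/m³, equivalent lumped resistance
    terminal_resistance: float  # Pa·s/m³ per terminal vessel (nan if undefined)
    pressure_pa: float  # outlet pressure (nan when no flow is known)


def bc_records_standalone(bcs: dict[str, OutletBC]) -> list[BCRecord]:
    """BC records from outlet terminal models alone.

    When an outlet carries a measured velocity its flow is known
    (Q = v·π·r²) and the full present-model resistance and pressure are
    reported; otherwise the tree's base resistance is written and the
    flow-dependent entries are NaN.
    """
    records = []
    for name, bc in bcs.items():
        o = bc.outlet
        if bc.variant == "zero_pressure":
            records.append(BCRecord(name, bc.variant, 0.0, 0.0, 0.0))
            continue
        if o.measured_velocity is not None and o.measured_velocity > 0:
            q = inlet_flow_from_velocity(o.radius, o.measured_velocity)
            r = bc.lumped_resistance(q)
            n = bc.tree.n_generations
            r_term = (
                bc.terminal_pressure_pa / (q / 2**n)
                if bc.variant == "present_0d"
                else 0.0
            )
            records.append(BCRecord(name, bc.variant, r, r_term, r * q))
        elif bc.variant == "conventional_0d":
            records.append(
                BCRecord(name, bc.variant, bc.base_resistance, 0.0, float("nan"))
            )
        else:
            records.append(
                BCRecord(
                    name, bc.variant, bc.base_resistance, float("nan"), float("nan")
                )
            )
    return records


def bc_records_from_solution(
    solution: CoupledSolution, bcs: dict[str, OutletBC]
) -> list[BCRecord]:
    """BC records with flows/pressures taken from a converged coupled solution."""
    records = []
    for r in solution.outlets:
        bc = bcs[r.name]
        if bc.variant == "zero_pressure":
            records.append(BCRecord(r.name, bc.variant, 0.0, 0.0, 0.0))
            continue
        lumped = bc.lumped_resistance(r.flow)
        if bc.variant == "present_0d":
            n = bc.tree.n_generations
            r_term = bc.terminal_pressure_pa / (r.flow / 2**n)
        else:
            r_term = 0.0
        records.append(BCRecord(r.name, bc.variant, lumped, r_term, r.pressure_pa))
    return records


def _fmt(x: float) -> str:
    return repr(float(x))


def write_bc_file(
    records: list[BCRecord], path: str | Path, config: RunConfig
) -> None:
    """Write a boundary-condition CSV with a provenance comment header."""
    path = Path(path)
    lines = [
        f"# peritree_version: {__version__}",
        f"# seed: {config.seed}",
        f"# config_hash: {config.config_hash()}",
        "name,variant,resistance_pa_s_m3,terminal_resistance_pa_s_m3,"
        "pressure_pa,pressure_mmhg",
    ]
    for r in records:
        lines.append(
            ",".join(
                [
                    r.name,
                    r.variant,
                    _fmt(r.resistance),
                    _fmt(r.terminal_resistance),
                    _fmt(r.pressure_pa),
                    _fmt(pa_to_mmhg(r.pressure_pa)),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_bc_file(path: str | Path) -> tuple[list[BCRecord], dict[str, str]]:
    """Read a BC file back; returns (records, provenance metadata)."""
    path = Path(path)
    meta: dict[str, str] = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#") and ":" in line:
            k, v = line.lstrip("# ").split(":", 1)
            meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    records = [
        BCRecord(
            name=str(row["name"]),
            variant=str(row["variant"]),
            resistance=float(row["resistance_pa_s_m3"]),
            terminal_resistance=float(row["terminal_resistance_pa_s_m3"]),
            pressure_pa=float(row["pressure_pa"]),
        )
        for _, row in df.iterrows()
    ]
    return records, meta


def write_surrogate(surrogate: DomainSurrogate, path: str | Path) -> None:
    doc = {
        "inlet": {
            "name": surrogate.inlet_name,
            "radius_m": surrogate.inlet_radius,
            "velocity_m_s": surrogate.inlet_velocity,
        },
        "segments": [
            {"tail": s.tail, "head": s.head, "radius_m": s.radius, "length_m": s.length}
            for s in surrogate.segments
        ],
        "outlets": [
            {
                "name": o.name,
                "radius_m": o.radius,
                "is_ica": o.is_ica,
                "measured_velocity_m_s": o.measured_velocity,
            }
            for o in surrogate.outlets
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_surrogate(path: str | Path) -> DomainSurrogate:
    doc = json.loads(Path(path).read_text())
    return DomainSurrogate(
        inlet_name=doc["inlet"]["name"],
        inlet_radius=float(doc["inlet"]["radius_m"]),
        inlet_velocity=float(doc["inlet"]["velocity_m_s"]),
        segments=tuple(
            Segment(
                tail=s["tail"],
                head=s["head"],
                radius=float(s["radius_m"]),
                length=float(s["length_m"]),
            )
            for s in doc["segments"]
        ),
        outlets=tuple(
            OutletSpec(
                name=o["name"],
                radius=float(o["radius_m"]),
                is_ica=bool(o.get("is_ica", False)),
                measured_velocity=(
                    float(o["measured_velocity_m_s"])
                    if o.get("measured_velocity_m_s") is not None
                    else None
                ),
            )
            for o in doc["outlets"]
        ),
    )


def write_solution(solution: CoupledSolution, path: str | Path) -> None:
    df = solution.to_frame()
    df.insert(0, "variant", solution.variant)
    df.to_csv(path, index=False)
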