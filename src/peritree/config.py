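"""Run configuration: variants, tolerances, units and model switches."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .tree import TreeParams, VesselGroupTable
from .viscosity import BloodProperties

__all__ = ["RunConfig", "VARIANTS"]

VARIANTS = ("zero_pressure", "conventional_0d", "present_0d")

#: Constant length-to-radius ratio of the conventional 0D model.
CONVENTIONAL_LAMBDA = 30.0


@dataclass
class RunConfig:
    """All tunables of a boundary-condition run.

    ``coupling_tol`` is the convergence criterion of the coupled loop: the
    maximum relative change of any outlet flow between successive
    iterations must fall below it (default 1e-4, mirroring the convergence
    practice of steady flow solvers).  ``relaxation`` is an optional
    under-relaxation factor for the terminal-resistance update; when left
    ``None`` plain successive substitution is used and a factor of 0.5 is
    switched on automatically if the residual starts oscillating upward.
    """

    variant: str = "present_0d"
    coupling_tol: float = 1e-4
    max_iterations: int = 1000
    relaxation: float | None = None
    seed: int = 0
    pressure_unit: str = "mmHg"
    velocity_unit: str = "cm/s"
    calibration_mode: str = "calibrated"
    hct_ratio: str = "printed"
    log_base: str = "10"
    viscosity: str = "non_newtonian"
    blood: BloodProperties = field(default_factory=BloodProperties)
    tree_params: TreeParams = field(default_factory=TreeParams)
    group_table_path: str | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if self.coupling_tol <= 0:
            raise ValueError("coupling tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")

    def group_table(self) -> VesselGroupTable:
        if self.group_table_path is not None:
            return VesselGroupTable.from_csv(self.group_table_path)
        return VesselGroupTable.default()

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("blood"), dict):
            d["blood"] = BloodProperties(**d["blood"])
        if isinstance(d.get("tree_params"), dict):
            d["tree_params"] = TreeParams(**d["tree_params"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Short stable hash of the full configuration, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
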