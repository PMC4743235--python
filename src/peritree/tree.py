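"""Symmetric fractal tree of the peripheral vessel network.

Each outlet of the imaged carotid domain feeds a sub-resolution network of
small arteries, arterioles and capillaries.  That network is modelled as a
symmetric binary tree: generation 0 is the outlet vessel itself, every
vessel splits into two identical daughters whose diameters obey the
minimum-energy power law d_parent^ε = 2·d_daughter^ε, and the tree stops
at the first generation whose radius falls to the terminal capillary
radius (12 μm by default).  Each generation is classified into an
anatomical vessel group (large arteries, main artery branches, terminal
artery branches, arterioles, capillaries) and carries that group's
length-to-radius ratio λ = l/r and the apparent blood viscosity at its own
diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .units import m_to_mm, m_to_um, mmhg_to_pa, um_to_m
from .viscosity import (
    BloodProperties,
    apparent_viscosity,
    haematocrit_for_diameter,
)

__all__ = [
    "VesselGroup",
    "VesselGroupTable",
    "TreeParams",
    "GenerationLevel",
    "PeripheralTree",
    "daughter_diameter",
    "classify_vessel_group",
    "lambda_for_level",
    "build_tree",
]


@dataclass(frozen=True)
class VesselGroup:
    """One anatomical group of the peripheral network.

    ``avg_diameter_mm`` doubles as the lower diameter bound of the group's
    classification interval (see :meth:`VesselGroupTable.classify`);
    ``special`` marks the internal-carotid row, which is excluded from
    interval classification and whose λ is applied directly to the measured
    ICA radius.
    """

    name: str
    avg_diameter_mm: float
    min_diameter_mm: float
    length_mm: float
    lambda_ratio: float
    special: bool = False


class VesselGroupTable:
    """Ordered table of vessel groups with diameter intervals and λ values.

    Groups are ordered by strictly decreasing average diameter.  A vessel
    of diameter d (mm) belongs to the first group whose average diameter
    it reaches: group k covers [avg_k, avg_{k-1}), with diameters at or
    above the largest average mapping to the largest group and everything
    below the smallest interval falling to capillaries.  A diameter that
    lands exactly on a boundary therefore classifies into the larger-vessel
    group.  This interval construction keeps every group's own average
    diameter inside that group.
    """

    def __init__(self, groups: list[VesselGroup]):
        regular = [g for g in groups if not g.special]
        special = [g for g in groups if g.special]
        regular.sort(key=lambda g: -g.avg_diameter_mm)
        for a, b in zip(regular, regular[1:]):
            if not a.avg_diameter_mm > b.avg_diameter_mm:
                raise ValueError("group average diameters must be strictly decreasing")
        for g in regular:
            if g.lambda_ratio <= 0:
                raise ValueError(f"lambda must be positive in group {g.name}")
            lam = g.length_mm / (g.avg_diameter_mm / 2.0)
            if abs(lam - g.lambda_ratio) / g.lambda_ratio > 1e-3:
                raise ValueError(
                    f"group {g.name}: λ={g.lambda_ratio} inconsistent with "
                    f"length/radius={lam:.4f}"
                )
        self.groups = regular
        self.ica = special[0] if special else None

    @classmethod
    def default(cls) -> "VesselGroupTable":
        """The packaged carotid peripheral-network table."""
        with resources.as_file(
            resources.files("peritree.data").joinpath("vessel_groups.csv")
        ) as p:
            return cls.from_csv(p)

    @classmethod
    def from_csv(cls, path: str | Path) -> "VesselGroupTable":
        df = pd.read_csv(path)
        required = {"group", "avg_diameter_mm", "min_diameter_mm", "length_mm", "lambda"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"vessel group table missing columns: {sorted(missing)}")
        groups = [
            VesselGroup(
                name=row["group"],
                avg_diameter_mm=float(row["avg_diameter_mm"]),
                min_diameter_mm=float(row["min_diameter_mm"]),
                length_mm=float(row["length_mm"]),
                lambda_ratio=float(row["lambda"]),
                special=bool(row.get("special", 0)),
            )
            for row in df.to_dict("records")
        ]
        return cls(groups)

    def classify(self, diameter_mm: float) -> VesselGroup:
        """Group containing a vessel of the given diameter (mm)."""
        if not diameter_mm > 0:
            raise ValueError(f"diameter must be positive, got {diameter_mm} mm")
        for g in self.groups[:-1]:
            if diameter_mm >= g.avg_diameter_mm:
                return g
        return self.groups[-1]


@dataclass(frozen=True)
class TreeParams:
    """Construction parameters of the peripheral tree.

    epsilon:
        Bifurcation exponent of the daughter-diameter power law; 3.0 for
        laminar flow (minimum-energy result), 2.33 for turbulent flow.
    terminal_radius:
        Capillary stopping radius in μm (a branch ends at the first
        generation whose radius is at or below this value).
    terminal_pressure:
        Pressure imposed at the terminal generation, in mmHg.
    """

    epsilon: float = 3.0
    terminal_radius: float = 12.0
    terminal_pressure: float = 30.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.terminal_radius <= 1.1:
            raise ValueError("terminal radius must exceed 1.1 μm")
        if self.terminal_pressure <= 0:
            raise ValueError("terminal pressure must be positive")

    @property
    def terminal_radius_m(self) -> float:
        return um_to_m(self.terminal_radius)

    @property
    def terminal_pressure_pa(self) -> float:
        return mmhg_to_pa(self.terminal_pressure)


@dataclass(frozen=True)
class GenerationLevel:
    """One generation of the symmetric tree (all 2^index vessels identical)."""

    index: int
    radius: float  # m, per vessel
    n_vessels: int
    lambda_ratio: float
    group: str
    mu_app: float  # Pa·s at this generation's diameter


@dataclass(frozen=True)
class PeripheralTree:
    root_radius: float  # m
    params: TreeParams
    levels: tuple[GenerationLevel, ...]
    is_ica: bool = False

    @property
    def n_generations(self) -> int:
        """Index n of the deepest (terminal) generation; generations run 0..n."""
        return len(self.levels) - 1


def daughter_diameter(d_parent: float, epsilon: float) -> float:
    """Daughter diameter under the symmetric minimum-energy power law.

    d_daughter = d_parent · 0.5^(1/ε); each daughter carries half the
    parent's d^ε.
    """
    if d_parent <= 0 or epsilon <= 0:
        raise ValueError("parent diameter and epsilon must be positive")
    return d_parent * 0.5 ** (1.0 / epsilon)


def classify_vessel_group(diameter_mm: float, table: VesselGroupTable) -> str:
    """Name of the vessel group containing ``diameter_mm``."""
    return table.classify(diameter_mm).name


def lambda_for_level(radius_m: float, table: VesselGroupTable) -> float:
    """λ = l/r for a vessel of the given radius (m), by group lookup."""
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    return table.classify(m_to_mm(2.0 * radius_m)).lambda_ratio


def _level_viscosity(
    radius_m: float,
    props: BloodProperties,
    viscosity: str,
    calibration_mode: str,
    hct_ratio: str,
    log_base: str,
) -> float:
    if viscosity == "newtonian":
        return props.mu_newtonian
    d_um = m_to_um(2.0 * radius_m)
    hct = haematocrit_for_diameter(
        d_um, hct_systemic=props.hct_systemic, log_base=log_base
    )
    return apparent_viscosity(
        d_um, hct, props, mode=calibration_mode, hct_ratio=hct_ratio
    ).mu_app


def build_tree(
    root_radius: float,
    params: TreeParams | None = None,
    table: VesselGroupTable | None = None,
    props: BloodProperties | None = None,
    *,
    is_ica: bool = False,
    lambda_override: float | None = None,
    viscosity: str = "non_newtonian",
    calibration_mode: str = "calibrated",
    hct_ratio: str = "printed",
    log_base: str = "10",
) -> PeripheralTree:
    """Construct the symmetric peripheral tree below an outlet.

    Parameters
    ----------
    root_radius:
        Outlet radius in m (generation 0 of the tree).
    is_ica:
        Apply the internal-carotid λ to generation 0 instead of the group
        lookup; deeper generations are classified normally.  The ICA does
        not branch before entering the skull, so its own length-to-radius
        ratio comes from measured data rather than the group table.
    lambda_override:
        Use a single constant λ at every generation (the conventional-model
        setting is λ = 30), bypassing the group table.
    viscosity:
        ``"non_newtonian"`` (default): each generation uses the apparent
        viscosity at its own diameter; ``"newtonian"``: constant
        ``props.mu_newtonian`` everywhere.

    The tree runs from generation 0 (radius = root_radius) to the first
    generation whose radius is at or below the terminal radius; level k has
    radius root_radius·2^(−k/ε) and 2^k vessels.
    """
    params = params or TreeParams()
    table = table or VesselGroupTable.default()
    props = props or BloodProperties()
    r_term = params.terminal_radius_m
    if root_radius <= r_term:
        raise ValueError(
            f"outlet radius {m_to_um(root_radius):.2f} μm is not larger than the "
            f"terminal capillary radius {params.terminal_radius} μm"
        )

    levels: list[GenerationLevel] = []
    k = 0
    while True:
        r_k = root_radius * 2.0 ** (-k / params.epsilon)
        if lambda_override is not None:
            lam = lambda_override
            group = "override"
        elif is_ica and k == 0:
            if table.ica is None:
                raise ValueError("group table has no ICA row")
            lam = table.ica.lambda_ratio
            group = table.ica.name
        else:
            g = table.classify(m_to_mm(2.0 * r_k))
            lam, group = g.lambda_ratio, g.name
        mu = _level_viscosity(
            r_k, props, viscosity, calibration_mode, hct_ratio, log_base
        )
        levels.append(
            GenerationLevel(
                index=k,
                radius=r_k,
                n_vessels=2**k,
                lambda_ratio=lam,
                group=group,
                mu_app=mu,
            )
        )
        if r_k <= r_term:
            break
        k += 1

    return PeripheralTree(
        root_radius=root_radius,
        params=params,
        levels=tuple(levels),
        is_ica=is_ica,
    )
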