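"""Coupling of the imaged-domain surrogate to the 0D outlet models.

The imaged carotid domain (in the original workflow a 3D finite-volume
model) is represented here by a lumped surrogate: a tree of Poiseuille
segments from the common-carotid inlet to every outlet.  Each outlet is
closed by one of three boundary-condition variants:

``zero_pressure``
    Outlet pressure fixed at 0 (no peripheral model).
``conventional_0d``
    A peripheral tree with a constant length-to-radius ratio λ = 30 at
    every generation and zero terminal resistance.
``present_0d``
    A peripheral tree with the anatomical per-group λ schedule and a
    terminal resistance adjusted at every coupling iteration so that the
    terminal pressure equals the physiological 30 mmHg.

The coupling loop mirrors the 3D↔0D exchange: the domain solve supplies
outlet flows to the 0D models, which return outlet pressures (lumped
resistances); iteration continues until the largest relative change of
any outlet flow falls below the configured tolerance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CONVENTIONAL_LAMBDA, VARIANTS, RunConfig
from .resistance import compute_profile, terminal_resistance
from .tree import PeripheralTree, build_tree
from .units import pa_to_mmhg

log = logging.getLogger("peritree.coupling")

__all__ = [
    "OutletSpec",
    "Segment",
    "DomainSurrogate",
    "OutletBC",
    "OutletResult",
    "CoupledSolution",
    "VariantComparison",
    "inlet_flow_from_velocity",
    "velocity_from_flow",
    "attach_boundary_conditions",
    "solve_coupled",
    "compare_variants",
]


@dataclass(frozen=True)
class OutletSpec:
    """One outlet of the imaged domain."""

    name: str
    radius: float  # m
    is_ica: bool = False
    measured_velocity: float | None = None  # m/s, e.g. Doppler reference

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"outlet {self.name!r}: radius must be positive")


@dataclass(frozen=True)
class Segment:
    """A Poiseuille edge of the surrogate, oriented away from the inlet."""

    tail: str
    head: str
    radius: float  # m
    length: float  # m


@dataclass(frozen=True)
class DomainSurrogate:
    """Lumped resistive stand-in for the imaged 3D domain.

    A tree of cylindrical segments rooted at the inlet node, with one leaf
    node per outlet.  Segment lengths default (in the fixture generator)
    to 5 diameters, the same cut-off rule applied to the imaged branches.
    """

    inlet_name: str
    inlet_radius: float  # m
    inlet_velocity: float  # m/s, prescribed mean velocity
    segments: tuple[Segment, ...]
    outlets: tuple[OutletSpec, ...]

    def __post_init__(self) -> None:
        names = [o.name for o in self.outlets]
        if len(set(names)) != len(names):
            raise ValueError("outlet names must be unique")
        nodes = {self.inlet_name}
        for s in self.segments:
            nodes.add(s.tail)
            nodes.add(s.head)
        if len(self.segments) != len(nodes) - 1:
            raise ValueError("surrogate graph is not a tree (|E| != |V|-1)")
        # every outlet must be reachable from the inlet along segment heads
        reachable = {self.inlet_name}
        frontier = [self.inlet_name]
        children: dict[str, list[str]] = {}
        for s in self.segments:
            children.setdefault(s.tail, []).append(s.head)
        while frontier:
            u = frontier.pop()
            for v in children.get(u, ()):
                if v in reachable:
                    raise ValueError("surrogate graph contains a cycle")
                reachable.add(v)
                frontier.append(v)
        missing = [n for n in names if n not in reachable]
        if missing:
            raise ValueError(f"outlets not reachable from inlet: {missing}")

    @property
    def nodes(self) -> list[str]:
        ns = {self.inlet_name}
        for s in self.segments:
            ns.update((s.tail, s.head))
        return sorted(ns)


@dataclass(frozen=True)
class OutletBC:
    """The lumped terminal model attached to one outlet.

    For the 0D variants ``base_resistance`` is the tree's root resistance
    with zero terminal resistance; the present model adds the
    flow-dependent terminal contribution P_terminal/Q, which is the exact
    reduction of R_terminal/2^n through the symmetric tree.
    """

    outlet: OutletSpec
    variant: str
    tree: PeripheralTree | None
    base_resistance: float  # Pa·s/m³, tree reduced with zero terminal resistance
    terminal_pressure_pa: float

    def lumped_resistance(self, q: float | None = None) -> float:
        """Equivalent outlet resistance, given the current outlet flow."""
        if self.variant == "zero_pressure":
            return 0.0
        if self.variant == "conventional_0d":
            return self.base_resistance
        if q is None or q <= 0:
            raise ValueError(
                f"outlet {self.outlet.name!r}: present-model resistance needs a "
                "positive flow"
            )
        n = self.tree.n_generations
        r_term = terminal_resistance(self.terminal_pressure_pa, q / 2**n)
        return self.base_resistance + r_term / 2**n


def inlet_flow_from_velocity(radius: float, velocity: float) -> float:
    """Volumetric flow Q = v·π·r² of a uniform velocity profile."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if velocity < 0:
        raise ValueError("mean velocity must be non-negative")
    return velocity * math.pi * radius**2


def velocity_from_flow(flow: float, radius: float) -> float:
    """Mean velocity v = Q/(π·r²) over the vessel cross-section."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return flow / (math.pi * radius**2)


def attach_boundary_conditions(
    outlets: tuple[OutletSpec, ...] | list[OutletSpec],
    variant: str,
    config: RunConfig | None = None,
) -> dict[str, OutletBC]:
    """Build the per-outlet terminal model for one BC variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    config = config or RunConfig()
    params = config.tree_params
    table = config.group_table()
    props = config.blood

    bcs: dict[str, OutletBC] = {}
    for o in outlets:
        if variant == "zero_pressure":
            bcs[o.name] = OutletBC(
                outlet=o,
                variant=variant,
                tree=None,
                base_resistance=0.0,
                terminal_pressure_pa=0.0,
            )
            continue
        if variant == "conventional_0d":
            tree = build_tree(
                o.radius,
                params,
                table,
                props,
                lambda_override=CONVENTIONAL_LAMBDA,
                viscosity=config.viscosity,
                calibration_mode=config.calibration_mode,
                hct_ratio=config.hct_ratio,
                log_base=config.log_base,
            )
            p_term = 0.0
        else:  # present_0d
            tree = build_tree(
                o.radius,
                params,
                table,
                props,
                is_ica=o.is_ica,
                viscosity=config.viscosity,
                calibration_mode=config.calibration_mode,
                hct_ratio=config.hct_ratio,
                log_base=config.log_base,
            )
            p_term = params.terminal_pressure_pa
        base = compute_profile(tree, 0.0).root_resistance
        bcs[o.name] = OutletBC(
            outlet=o,
            variant=variant,
            tree=tree,
            base_resistance=base,
            terminal_pressure_pa=p_term,
        )
    return bcs


@dataclass(frozen=True)
class OutletResult:
    name: str
    radius: float
    is_ica: bool
    flow: float  # m³/s
    pressure_pa: float
    pressure_mmhg: float
    velocity: float  # m/s
    measured_velocity: float | None = None


@dataclass(frozen=True)
class CoupledSolution:
    """Converged per-outlet state of one BC variant on one surrogate."""

    variant: str
    outlets: tuple[OutletResult, ...]
    inlet_flow: float
    inlet_pressure_pa: float
    iterations: int
    converged: bool
    residual: float
    residual_history: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "outlet": [o.name for o in self.outlets],
                "radius_mm": [o.radius * 1e3 for o in self.outlets],
                "flow_m3_s": [o.flow for o in self.outlets],
                "pressure_pa": [o.pressure_pa for o in self.outlets],
                "pressure_mmhg": [o.pressure_mmhg for o in self.outlets],
                "velocity_m_s": [o.velocity for o in self.outlets],
            }
        )


class ConvergenceError(RuntimeError):
    """Coupled loop failed to converge; carries the residual history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = tuple(history)


def _solve_network(
    surrogate: DomainSurrogate,
    mu: float,
    outlet_r: dict[str, float],
    q_in: float,
) -> tuple[dict[str, float], dict[str, float]]:
    """One-shot nodal analysis of the surrogate with fixed outlet resistances.

    Returns (node pressures, outlet flows).  Outlets with zero lumped
    resistance are Dirichlet nodes at pressure 0; the others connect to the
    venous reference through their conductance 1/R.
    """
    nodes = surrogate.nodes
    dirichlet = {n for n, r in outlet_r.items() if r == 0.0}
    free = [n for n in nodes if n not in dirichlet]
    idx = {n: i for i, n in enumerate(free)}
    m = len(free)
    a = np.zeros((m, m))
    b = np.zeros(m)

    for s in surrogate.segments:
        g = math.pi * s.radius**4 / (8.0 * mu * s.length)
        for u, v in ((s.tail, s.head), (s.head, s.tail)):
            if u in idx:
                a[idx[u], idx[u]] += g
                if v in idx:
                    a[idx[u], idx[v]] -= g
    for name, r in outlet_r.items():
        if r > 0.0:
            a[idx[name], idx[name]] += 1.0 / r
    b[idx[surrogate.inlet_name]] = q_in

    p = np.linalg.solve(a, b)
    pressures = {n: (float(p[idx[n]]) if n in idx else 0.0) for n in nodes}

    leaf_seg = {s.head: s for s in surrogate.segments}
    flows: dict[str, float] = {}
    for o in surrogate.outlets:
        s = leaf_seg[o.name]
        g = math.pi * s.radius**4 / (8.0 * mu * s.length)
        flows[o.name] = g * (pressures[s.tail] - pressures[s.head])
    return pressures, flows


def solve_coupled(
    surrogate: DomainSurrogate,
    variant: str,
    config: RunConfig | None = None,
) -> CoupledSolution:
    """Iterative domain↔0D coupling for one BC variant.

    Alternates a linear solve of the resistive surrogate (with the current
    outlet lumped resistances) and, for the present model, an update of
    each terminal resistance from the freshly computed outlet flow, until
    the maximum relative flow change drops below ``config.coupling_tol``.
    """
    config = config or RunConfig()
    q_in = inlet_flow_from_velocity(surrogate.inlet_radius, surrogate.inlet_velocity)
    if q_in <= 0:
        raise ValueError("inlet flow must be positive")
    bcs = attach_boundary_conditions(surrogate.outlets, variant, config)
    mu = config.blood.mu_newtonian
    names = [o.name for o in surrogate.outlets]

    # initial solve: terminal updates off (present model starts from R_base)
    r0 = {n: (0.0 if variant == "zero_pressure" else bcs[n].base_resistance)
          for n in names}
    pressures, flows = _solve_network(surrogate, mu, r0, q_in)

    history: list[float] = []
    converged = variant != "present_0d"
    relax = config.relaxation
    iterations = 1
    if variant == "present_0d":
        q_est = dict(flows)
        for iterations in range(2, config.max_iterations + 2):
            r = {n: bcs[n].lumped_resistance(q_est[n]) for n in names}
            pressures, new_flows = _solve_network(surrogate, mu, r, q_in)
            resid = max(
                abs(new_flows[n] - flows[n]) / abs(new_flows[n]) for n in names
            )
            history.append(resid)
            log.debug("coupling iteration %d: residual %.3e", iterations, resid)
            if resid < config.coupling_tol:
                flows = new_flows
                q_est = dict(new_flows)
                converged = True
                break
            if relax is None and len(history) >= 2 and history[-1] > history[-2]:
                relax = 0.5  # damp an oscillating substitution
            w = 1.0 if relax is None else relax
            q_est = {
                n: w * new_flows[n] + (1.0 - w) * q_est[n] for n in names
            }
            flows = new_flows
        if not converged:
            raise ConvergenceError(
                f"coupled loop did not converge in {config.max_iterations} "
                f"iterations (last residual {history[-1]:.3e})",
                history,
            )

    by_name = {o.name: o for o in surrogate.outlets}
    results = tuple(
        OutletResult(
            name=n,
            radius=by_name[n].radius,
            is_ica=by_name[n].is_ica,
            flow=flows[n],
            pressure_pa=pressures[n],
            pressure_mmhg=pa_to_mmhg(pressures[n]),
            velocity=velocity_from_flow(flows[n], by_name[n].radius),
            measured_velocity=by_name[n].measured_velocity,
        )
        for n in names
    )
    return CoupledSolution(
        variant=variant,
        outlets=results,
        inlet_flow=q_in,
        inlet_pressure_pa=pressures[surrogate.inlet_name],
        iterations=iterations,
        converged=converged,
        residual=history[-1] if history else 0.0,
        residual_history=tuple(history),
    )


@dataclass(frozen=True)
class VariantComparison:
    """Side-by-side results of all three BC variants on one surrogate."""

    table: pd.DataFrame
    mean_errors: dict[str, tuple[float, float]]  # variant -> (mean %, SD %)
    solutions: dict[str, CoupledSolution]


def compare_variants(
    surrogate: DomainSurrogate, config: RunConfig | None = None
) -> VariantComparison:
    """Solve all three variants and tabulate velocities, pressures, errors.

    When outlets carry a reference (measured) velocity, the per-outlet
    relative error |v_sim − v_meas|/v_meas is reported per variant along
    with its mean ± sample SD across outlets, in percent.
    """
    config = config or RunConfig()
    solutions = {v: solve_coupled(surrogate, v, config) for v in VARIANTS}

    rows = []
    for o in surrogate.outlets:
        row: dict[str, object] = {"outlet": o.name, "radius_mm": o.radius * 1e3}
        if o.measured_velocity is not None:
            row["measured_velocity_cm_s"] = o.measured_velocity * 1e2
        for v in VARIANTS:
            res = next(r for r in solutions[v].outlets if r.name == o.name)
            row[f"{v}_velocity_cm_s"] = res.velocity * 1e2
            row[f"{v}_pressure_mmhg"] = res.pressure_mmhg
            if o.measured_velocity is not None and o.measured_velocity > 0:
                row[f"{v}_error_pct"] = (
                    abs(res.velocity - o.measured_velocity)
                    / o.measured_velocity
                    * 100.0
                )
        rows.append(row)
    table = pd.DataFrame(rows)

    mean_errors: dict[str, tuple[float, float]] = {}
    for v in VARIANTS:
        col = f"{v}_error_pct"
        if col in table.columns:
            errs = table[col].dropna().to_numpy()
            if errs.size:
                sd = float(np.std(errs, ddof=1)) if errs.size > 1 else 0.0
                mean_errors[v] = (float(np.mean(errs)), sd)
    return VariantComparison(table=table, mean_errors=mean_errors, solutions=solutions)
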