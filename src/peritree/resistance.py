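"""Recursive Poiseuille resistance of the peripheral tree.

The tree is reduced like an electrical ladder network.  A generation-i
vessel contributes the Poiseuille resistance of a segment of length
l = λ·r,

    R_seg = 8·μ·λ / (π·r³)  ≡  8·μ·l / (π·r⁴),

so the inlet resistance of a generation-i vessel is R_i(0) = R_seg,i +
R_i(L), and because the two daughters are identical the outlet resistance
of the parent is the parallel combination R_{i-1}(L) = R_i(0)/2.  The
recursion starts at the terminal generation with a lumped terminal
resistance, which in the present model is set from the per-leaf flow so
that the terminal pressure equals a physiological value (30 mmHg by
default); the conventional model instead closes the tree with zero
terminal resistance.

Pressures are gauge, referenced to 0 on the venous side of the terminal
resistor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tree import PeripheralTree

__all__ = [
    "ResistanceProfile",
    "PressureProfile",
    "segment_resistance",
    "terminal_resistance",
    "compute_profile",
    "explicit_network_oracle",
    "solve_terminal_fixed_point",
]


@dataclass(frozen=True)
class ResistanceProfile:
    """Per-generation resistances of one tree (per single vessel, Pa·s/m³).

    ``r_in[i]`` is the resistance seen looking into a generation-i vessel,
    ``r_out[i]`` the resistance beyond its outlet; ``root_resistance`` is
    the equivalent resistance of the whole tree seen from the outlet of the
    imaged domain (== r_in[0]).
    """

    r_in: np.ndarray
    r_out: np.ndarray
    terminal_resistance: float
    root_resistance: float


@dataclass(frozen=True)
class PressureProfile:
    """Gauge pressure at each generation inlet for a given root flow."""

    inlet_pressures: np.ndarray  # Pa, level 0..n
    terminal_pressure: float  # Pa, at the far side of the deepest segment
    q_root: float  # m³/s


def segment_resistance(radius: float, lambda_ratio: float, mu: float) -> float:
    """Poiseuille resistance 8·μ·λ/(π·r³) of a segment of length λ·r."""
    if radius <= 0 or lambda_ratio <= 0 or mu <= 0:
        raise ValueError("radius, lambda and viscosity must all be positive")
    return 8.0 * mu * lambda_ratio / (math.pi * radius**3)


def terminal_resistance(p_terminal: float, q_terminal: float) -> float:
    """Lumped terminal resistance R = p/q closing one terminal vessel."""
    if q_terminal <= 0:
        raise ValueError(
            f"terminal flow must be positive (got {q_terminal}); "
            "an unperfused outlet cannot define a terminal resistance"
        )
    return p_terminal / q_terminal


def _segment_resistances(tree: PeripheralTree) -> np.ndarray:
    return np.array(
        [segment_resistance(lv.radius, lv.lambda_ratio, lv.mu_app) for lv in tree.levels]
    )


def compute_profile(tree: PeripheralTree, terminal_r: float) -> ResistanceProfile:
    """Backward resistance recursion from the terminal generation to the root."""
    if len(tree.levels) == 0:
        raise ValueError("cannot compute the resistance profile of an empty tree")
    if terminal_r < 0:
        raise ValueError("terminal resistance must be non-negative")
    seg = _segment_resistances(tree)
    n = tree.n_generations
    r_in = np.empty(n + 1)
    r_out = np.empty(n + 1)
    r_out[n] = terminal_r
    for i in range(n, -1, -1):
        r_in[i] = seg[i] + r_out[i]
        if i > 0:
            r_out[i - 1] = 0.5 * r_in[i]  # two identical daughters in parallel
    return ResistanceProfile(
        r_in=r_in,
        r_out=r_out,
        terminal_resistance=terminal_r,
        root_resistance=float(r_in[0]),
    )


def explicit_network_oracle(
    tree: PeripheralTree, terminal_r: float, *, max_generations: int = 15
) -> float:
    """Root resistance by brute-force enumeration of every vessel.

    Materialises all 2^i vessels of each generation as explicit resistors
    and reduces the network from the leaves by elementary series/parallel
    steps.  Exponential in depth, hence capped; intended as an independent
    cross-check of :func:`compute_profile`, not for production trees.
    """
    n = tree.n_generations
    if n > max_generations:
        raise ValueError(
            f"tree has {n} generations; explicit enumeration capped at "
            f"{max_generations}"
        )
    seg = _segment_resistances(tree)
    # subtree resistance looking into each vessel of the deepest generation
    sub = [seg[n] + terminal_r] * (2**n)
    for i in range(n - 1, -1, -1):
        sub = [
            seg[i] + (sub[2 * j] * sub[2 * j + 1]) / (sub[2 * j] + sub[2 * j + 1])
            for j in range(2**i)
        ]
    (root,) = sub
    return float(root)


def solve_terminal_fixed_point(
    tree: PeripheralTree, q_root: float
) -> tuple[ResistanceProfile, PressureProfile]:
    """Resistance and pressure profiles with the terminal pressure pinned.

    With a known root flow the symmetric split fixes the per-leaf flow at
    q_root/2^n exactly, so the terminal resistance that realises the
    physiological terminal pressure is closed-form:
    R_term = P_terminal/(q_root/2^n).  The pressure profile marches the
    per-generation Poiseuille drops down from the root pressure
    root_resistance·q_root and lands on P_terminal identically.
    """
    if q_root <= 0:
        raise ValueError("root flow must be positive")
    n = tree.n_generations
    p_term = tree.params.terminal_pressure_pa
    q_leaf = q_root / 2**n
    r_term = terminal_resistance(p_term, q_leaf)
    profile = compute_profile(tree, r_term)

    seg = _segment_resistances(tree)
    inlet_p = np.empty(n + 1)
    p = profile.root_resistance * q_root
    for i in range(n + 1):
        inlet_p[i] = p
        p -= (q_root / 2**i) * seg[i]
    return profile, PressureProfile(
        inlet_pressures=inlet_p, terminal_pressure=float(p), q_root=q_root
    )
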