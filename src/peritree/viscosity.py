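"""Diameter-dependent haematocrit and apparent blood viscosity.

In vessels narrower than ~300 μm the tube haematocrit falls below the
systemic value (Fåhraeus effect) and the apparent viscosity drops with
decreasing diameter down to a minimum near 40 μm before rising steeply
in true capillaries (Fåhraeus–Lindqvist effect).  This module implements
the empirical in-vitro viscosity law of the Pries type: a tube-haematocrit
law, a diameter-dependent shape exponent ``Cd``, the relative viscosity
at haematocrit 0.45, and the full apparent-viscosity relation including
the ``(d/(d-1.1))²`` wall-layer factor.

Diameters are in μm throughout this module — the 1.1 μm offset and the
exponential coefficients of the empirical fits only make sense in μm.

Calibration modes
-----------------
The relative-viscosity law has a large-diameter asymptote.  In the default
``"calibrated"`` mode the law is evaluated in relative units with the
classical asymptotic constant 3.2 and then scaled so that the absolute
apparent viscosity of blood at haematocrit 0.45 in a large vessel equals
``BloodProperties.mu_newtonian_limit`` (4.06 mPa·s by default).  A
``"literal"`` mode substitutes the Pa·s constant directly into the
relative-viscosity formula; it is retained for traceability but is
dimensionally inconsistent and should not be used for physical runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BloodProperties",
    "ViscosityEvaluation",
    "haematocrit_for_diameter",
    "shape_exponent",
    "mu_045_relative",
    "apparent_viscosity",
    "CLASSICAL_C_INF",
]

#: Large-diameter asymptote of the classical relative in-vitro viscosity law.
CLASSICAL_C_INF = 3.2

#: Diameter (μm) below which the tube-haematocrit law would go negative.
HCT_ZERO_DIAMETER = 10.0 ** (0.117 / 0.196)


@dataclass(frozen=True)
class BloodProperties:
    """Physical constants of blood shared across the package.

    Parameters
    ----------
    density:
        Mass density in kg/m³.
    mu_newtonian:
        Constant Newtonian viscosity (Pa·s) used for the imaged-domain
        surrogate and for the purely Newtonian tree variant.
    mu_newtonian_limit:
        Large-vessel asymptote of the apparent-viscosity law (Pa·s); the
        calibration anchor of the non-Newtonian model.
    hct_systemic:
        Systemic (discharge) haematocrit, dimensionless.
    """

    density: float = 1050.0
    mu_newtonian: float = 0.0046
    mu_newtonian_limit: float = 4.06e-3
    hct_systemic: float = 0.45

    def __post_init__(self) -> None:
        if self.density <= 0 or self.mu_newtonian <= 0 or self.mu_newtonian_limit <= 0:
            raise ValueError("blood density and viscosities must be strictly positive")
        if not 0.0 < self.hct_systemic < 1.0:
            raise ValueError(f"hct_systemic must lie in (0, 1), got {self.hct_systemic}")


@dataclass(frozen=True)
class ViscosityEvaluation:
    """Full record of one apparent-viscosity evaluation.

    Attributes
    ----------
    diameter : float
        Vessel diameter in μm.
    hct : float
        Tube haematocrit used in the evaluation (dimensionless).
    cd : float
        Shape exponent of the haematocrit dependence.
    mu_045_rel : float
        Relative viscosity at haematocrit 0.45 (dimensionless in
        calibrated mode).
    mu_app : float
        Apparent viscosity in Pa·s.
    """

    diameter: float
    hct: float
    cd: float
    mu_045_rel: float
    mu_app: float


def _check_diameter(d: float) -> None:
    if not d > 0:
        raise ValueError(f"vessel diameter must be strictly positive, got {d} μm")


def haematocrit_for_diameter(
    d: float,
    *,
    hct_systemic: float = 0.45,
    log_base: str = "10",
) -> float:
    """Tube haematocrit as a function of vessel diameter ``d`` (μm).

    Equals the systemic haematocrit for d > 300 μm; below, it follows the
    empirical logarithmic reduction ``hct_systemic·(0.196·log10 d − 0.117)``,
    clamped at zero (the fit crosses zero near d ≈ 3.95 μm, below any
    physical capillary in this model).  The 300 μm boundary belongs to the
    reduced branch; the discontinuity of the piecewise fit is kept as is.

    ``log_base`` selects ``"10"`` (default) or ``"e"`` for the logarithm of
    the reduced branch.
    """
    _check_diameter(d)
    if d > 300.0:
        return hct_systemic
    log = math.log10 if log_base == "10" else math.log
    if log_base not in ("10", "e"):
        raise ValueError(f"log_base must be '10' or 'e', got {log_base!r}")
    return max(0.0, hct_systemic * (0.196 * log(d) - 0.117))


def shape_exponent(d: float) -> float:
    """Shape exponent Cd of the haematocrit dependence at diameter ``d`` (μm).

    Cd = (0.8 + exp(−0.075 d))·(−1 + 1/(1 + 10⁻¹¹ d¹²)) + 1/(1 + 10⁻¹¹ d¹²).

    Approaches 1 for capillary diameters and −0.8 for large vessels.
    """
    _check_diameter(d)
    # 10^-11 d^12 overflows double precision only for absurd d; evaluate the
    # sigmoid in log space to stay finite for any positive input.
    log_term = -11.0 * math.log(10.0) + 12.0 * math.log(d)
    if log_term > 700.0:
        t = 0.0
    else:
        t = 1.0 / (1.0 + math.exp(log_term))
    return (0.8 + math.exp(-0.075 * d)) * (-1.0 + t) + t


def mu_045_relative(
    d: float,
    *,
    mode: str = "calibrated",
    mu_newtonian_limit: float = 4.06e-3,
) -> float:
    """Viscosity of blood at haematocrit 0.45 as a function of diameter (μm).

    μ_0.45 = 6·exp(−0.085 d) + C∞ − 2.44·exp(−0.06 d^0.645)

    In ``"calibrated"`` mode (default) C∞ is the classical relative
    asymptote 3.2 and the result is a relative viscosity; in ``"literal"``
    mode C∞ is the absolute Pa·s constant ``mu_newtonian_limit``, exactly
    as the formula is sometimes printed, which mixes units and is flagged
    dimensionally inconsistent.
    """
    _check_diameter(d)
    if mode == "calibrated":
        c_inf = CLASSICAL_C_INF
    elif mode == "literal":
        c_inf = mu_newtonian_limit
    else:
        raise ValueError(f"unknown calibration mode {mode!r}")
    return 6.0 * math.exp(-0.085 * d) + c_inf - 2.44 * math.exp(-0.06 * d**0.645)


def apparent_viscosity(
    d: float,
    hct: float,
    props: BloodProperties | None = None,
    *,
    mode: str = "calibrated",
    hct_ratio: str = "printed",
) -> ViscosityEvaluation:
    """Apparent viscosity of blood in a tube of diameter ``d`` (μm).

    μ_app = [1 + (μ_0.45 − 1)·((1−Hct)^Cd / (1−0.45)^Cd)·(d/(d−1.1))²]
            ·(d/(d−1.1))²

    evaluated in relative units, then scaled to Pa·s so that the
    large-vessel value at haematocrit 0.45 equals
    ``props.mu_newtonian_limit`` (calibrated mode).

    Parameters
    ----------
    d:
        Diameter in μm; must exceed 1.1 μm (singularity of the wall-layer
        factor).
    hct:
        Tube haematocrit, in [0, 1).
    mode:
        ``"calibrated"`` (default) or ``"literal"``; see module docstring.
    hct_ratio:
        ``"printed"`` uses (1−Hct)^Cd/(1−0.45)^Cd; ``"classical"`` uses the
        in-vitro form ((1−Hct)^Cd − 1)/((1−0.45)^Cd − 1).  The two agree at
        Hct = 0.45 where both factors equal 1.
    """
    if not d > 1.1:
        raise ValueError(
            f"diameter must exceed 1.1 μm (wall-layer singularity), got {d}"
        )
    if not 0.0 <= hct < 1.0:
        raise ValueError(f"haematocrit must lie in [0, 1), got {hct}")
    if props is None:
        props = BloodProperties()

    cd = shape_exponent(d)
    mu45 = mu_045_relative(d, mode=mode, mu_newtonian_limit=props.mu_newtonian_limit)
    wall = (d / (d - 1.1)) ** 2

    if hct_ratio == "printed":
        ratio = (1.0 - hct) ** cd / (1.0 - 0.45) ** cd
    elif hct_ratio == "classical":
        ratio = ((1.0 - hct) ** cd - 1.0) / ((1.0 - 0.45) ** cd - 1.0)
    else:
        raise ValueError(f"unknown hct_ratio variant {hct_ratio!r}")

    mu_rel = (1.0 + (mu45 - 1.0) * ratio * wall) * wall
    if mode == "calibrated":
        mu_app = mu_rel * props.mu_newtonian_limit / CLASSICAL_C_INF
    else:  # literal: the printed formula already mixes Pa·s into the result
        mu_app = mu_rel
    return ViscosityEvaluation(
        diameter=d, hct=hct, cd=cd, mu_045_rel=mu45, mu_app=mu_app
    )
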