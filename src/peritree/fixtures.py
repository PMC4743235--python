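"""Seeded synthetic carotid outlet sets and domain surrogates.

No imaging or Doppler data ships with the package; every pipeline stage is
exercised on synthetic fixtures that emulate the anatomy of the carotid
bifurcation: an internal-carotid outlet near its anatomical mean diameter
plus 7–9 external-carotid branches (superior thyroid, lingual, facial,
occipital, maxillary, posterior auricular, superficial temporal, middle
meningeal, transverse facial arteries) with diameters in the main/terminal
artery-branch range.  The surrogate domain is a caterpillar tree: the
common carotid bifurcates into the ICA and an ECA trunk which sheds one
branch per junction, with trunk radii following the ε = 3 cube law of the
remaining downstream outlets and every segment cut at 5 diameters.

All sampling is driven by a single integer seed through one
``numpy.random.default_rng`` stream, so fixtures are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coupling import CoupledSolution, DomainSurrogate, OutletSpec, Segment

__all__ = [
    "FixtureConfig",
    "ECA_BRANCH_NAMES",
    "make_outlet_set",
    "make_surrogate",
    "make_pseudo_measurements",
]

#: Canonical external-carotid branch names, in anatomical (proximal→distal) order.
ECA_BRANCH_NAMES = ("SThA", "LA", "FA", "OA", "MA", "PAA", "STA", "MMA", "TFA")

#: Anatomical mean ICA diameter (mm) used as the sampling centre.
ICA_MEAN_DIAMETER_MM = 5.4834

#: ECA branch diameter sampling range (mm), spanning the terminal/main
#: artery-branch groups.
BRANCH_DIAMETER_RANGE_MM = (1.2, 3.2)


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic carotid fixture generator.

    n_branches:
        Number of ECA branch outlets (7 or 9 in the reference anatomy,
        depending on which small branches the imaging resolved).
    diameter_jitter:
        Relative spread applied to the ICA and inlet diameters.
    inlet_velocity:
        Prescribed mean common-carotid velocity in m/s (0.3 m/s default, a
        typical time-averaged CCA value).
    noise_sd:
        Relative SD of the Gaussian noise applied when generating
        pseudo-Doppler measured velocities.
    """

    seed: int = 0
    n_branches: int = 9
    diameter_jitter: float = 0.05
    inlet_velocity: float = 0.3
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_branches < 1:
            raise ValueError("need at least one ECA branch")
        if self.diameter_jitter < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise SD must be non-negative")


def make_outlet_set(config: FixtureConfig) -> tuple[OutletSpec, ...]:
    """One ICA outlet plus ``n_branches`` ECA-branch outlets, seeded."""
    rng = np.random.default_rng(config.seed)
    ica_d_mm = ICA_MEAN_DIAMETER_MM * (
        1.0 + config.diameter_jitter * rng.uniform(-1.0, 1.0)
    )
    outlets = [OutletSpec(name="ICA", radius=ica_d_mm * 1e-3 / 2.0, is_ica=True)]
    lo, hi = BRANCH_DIAMETER_RANGE_MM
    for i in range(config.n_branches):
        name = (
            ECA_BRANCH_NAMES[i]
            if i < len(ECA_BRANCH_NAMES)
            else f"ECA_B{i + 1}"
        )
        d_mm = rng.uniform(lo, hi)
        outlets.append(OutletSpec(name=name, radius=d_mm * 1e-3 / 2.0))
    return tuple(outlets)


def _cube_law_radius(radii: list[float]) -> float:
    """Parent radius feeding the given daughters under the ε = 3 power law."""
    return float(np.cbrt(np.sum(np.asarray(radii) ** 3)))


def make_surrogate(
    outlets: tuple[OutletSpec, ...] | list[OutletSpec],
    config: FixtureConfig,
) -> DomainSurrogate:
    """Caterpillar surrogate tree from a CCA inlet to every outlet.

    Node layout: ``CCA → BIF``; ``BIF → ICA`` and ``BIF → T1 → T2 → …``
    where trunk node ``Ti`` sheds outlet i+1 and the last trunk segment
    ends at the final outlet.  Trunk segment radii are the cube-law
    combination of all outlets still downstream; every segment's length is
    5 diameters, the same cut-off rule used for the imaged branches.
    """
    outlets = tuple(outlets)
    if not outlets:
        raise ValueError("need at least one outlet")

    def seg(tail: str, head: str, radius: float) -> Segment:
        return Segment(tail=tail, head=head, radius=radius, length=5.0 * 2.0 * radius)

    if len(outlets) == 1:
        o = outlets[0]
        inlet_r = o.radius
        return DomainSurrogate(
            inlet_name="CCA",
            inlet_radius=inlet_r,
            inlet_velocity=config.inlet_velocity,
            segments=(seg("CCA", o.name, o.radius),),
            outlets=outlets,
        )

    inlet_r = _cube_law_radius([o.radius for o in outlets])
    segments = [seg("CCA", "BIF", inlet_r)]
    # first outlet (ICA in the standard set) leaves at the bifurcation
    segments.append(seg("BIF", outlets[0].name, outlets[0].radius))
    trunk_tail = "BIF"
    remaining = list(outlets[1:])
    for i, o in enumerate(remaining):
        if i == len(remaining) - 1:
            segments.append(seg(trunk_tail, o.name, o.radius))
            break
        trunk_head = f"T{i + 1}"
        trunk_r = _cube_law_radius([x.radius for x in remaining[i:]])
        segments.append(seg(trunk_tail, trunk_head, trunk_r))
        segments.append(seg(trunk_head, o.name, o.radius))
        trunk_tail = trunk_head
    return DomainSurrogate(
        inlet_name="CCA",
        inlet_radius=inlet_r,
        inlet_velocity=config.inlet_velocity,
        segments=tuple(segments),
        outlets=outlets,
    )


def make_pseudo_measurements(
    solution: CoupledSolution, config: FixtureConfig
) -> tuple[OutletSpec, ...]:
    """Outlet specs with pseudo-Doppler velocities derived from a solution.

    measured = simulated × (1 + Normal(0, noise_sd)), with an independent
    seeded stream (offset from the fixture seed so measurements do not
    reuse the geometry draws).
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    specs = []
    for r in solution.outlets:
        noise = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
        specs.append(
            OutletSpec(
                name=r.name,
                radius=r.radius,
                is_ica=r.is_ica,
                measured_velocity=r.velocity * (1.0 + noise),
            )
        )
    return tuple(specs)
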