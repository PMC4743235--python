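# Methods

## Scope and model structure

`peritree` computes steady, resistive (0D) outflow boundary conditions for
a truncated carotid model.  It deliberately replaces the 3D finite-volume
domain of a full patient-specific workflow with a lumped Poiseuille-tree
surrogate: the package reproduces the *boundary-condition machinery* — the
peripheral trees, their resistances and pressures, and the coupling loop —
and the qualitative comparison between boundary-condition variants.  It
does **not** reproduce 3D velocity fields; no CFD, wall compliance,
pulsatility or transport is modelled, and reported per-outlet velocities
are cross-sectional means of the surrogate network.

## Peripheral tree

Each outlet of radius `r₀` (m) spawns a symmetric binary tree.  Flow
splits equally at every bifurcation and daughter diameters follow the
minimum-energy power law with exponent ε (default 3.0, appropriate for
laminar flow; 2.33 would describe turbulent branching and is accepted as a
parameter).  Generation k therefore has radius `r₀·2^(−k/ε)`, computed
directly from the closed form rather than by repeated multiplication so
the radius law holds to round-off at every depth.  The tree ends at the
first generation whose radius is ≤ the terminal radius (12 μm default);
generation indices are 0-based with the outlet itself as generation 0.

Total cross-sectional area grows by `2^(1−2/ε)` per generation (≈ 2^(1/3)
for ε = 3), reproducing the anatomical expansion of the vascular bed from
single artery toward the capillaries.

### Vessel groups and λ

Segment length is assigned through the dimensionless ratio λ = l/r, by
anatomical group:

| group | avg diameter (mm) | length (mm) | λ |
|---|---|---|---|
| large arteries | 6.5 | 200 | 61.5385 |
| main artery branches | 2.4 | 100 | 83.3333 |
| terminal artery branches | 1.2 | 10 | 16.6667 |
| arterioles | 0.1 | 12 | 240 |
| capillaries | 0.008 | 1 | 250 |
| ICA (special) | 5.4834 | 117.3925 | 50.0154 |

Classification intervals use each group's **average diameter as its lower
bound** (closed on that side): a diameter on a boundary classifies into
the larger-vessel group, and every group's own average sits inside the
group.  The source table also prints minimum diameters, but using those
as bounds would push a 2.4 mm vessel — the main-branch average itself —
into the large-artery group, so the average-based intervals were adopted.
The arterioles row's printed length is typographically unreliable; λ = 240
is taken as authoritative and the length back-computed as λ·r = 12 mm.
The ICA's printed λ (50.0154) is not exactly length/radius of its printed
dimensions (≈ 42.8); the printed λ is used as-is and the row is excluded
from the table's internal consistency check.  The ICA does not branch
before entering the skull, so when an outlet is flagged `is_ica` its λ
applies to generation 0 only; deeper generations classify normally.  The
aorta never occurs downstream of a carotid outlet and has no row;
diameters above the large-artery bound still classify as large arteries.

## Apparent viscosity

Tube haematocrit: `Hct = 0.45` for d > 300 μm, else
`0.45·(0.196·log₁₀ d − 0.117)`, clamped at 0 below d ≈ 3.95 μm
(unreachable at the 12 μm terminal radius, but defended).  log₁₀ is the
default because the underlying empirical fits are base-10; a natural-log
switch exists.  The 300 μm discontinuity is kept as printed, with the
boundary on the reduced branch.

Apparent viscosity (d in μm):

```
Cd     = (0.8 + e^(−0.075 d))·(−1 + 1/(1+10⁻¹¹d¹²)) + 1/(1+10⁻¹¹d¹²)
μ_0.45 = 6·e^(−0.085 d) + C∞ − 2.44·e^(−0.06 d^0.645)
μ_app  = [1 + (μ_0.45−1)·((1−Hct)^Cd/(0.55)^Cd)·(d/(d−1.1))²]·(d/(d−1.1))²
```

The formula as printed in the source mixes an absolute constant (Pa·s)
into a relative-viscosity law.  The default **calibrated** mode evaluates
everything in relative units with the classical asymptote C∞ = 3.2 and
scales the result by `4.06×10⁻³/3.2` Pa·s, so that
μ_app(d→∞, Hct 0.45) → 4.06 mPa·s exactly; a **literal** mode substitutes
the Pa·s constant directly for traceability, flagged dimensionally
inconsistent.  The haematocrit ratio is implemented exactly as printed,
`(1−Hct)^Cd/(0.55)^Cd`; the classical in-vitro form
`((1−Hct)^Cd−1)/((0.55)^Cd−1)` is available behind `hct_ratio="classical"`.
The two coincide at Hct = 0.45, and no worked number exists to
discriminate them, so the printed form is the default.  The sigmoid in Cd
is evaluated in log space so it cannot overflow.

## Resistance recursion and terminal fixed point

Per-vessel Poiseuille segment resistance `R_seg = 8μλ/(πr³)` (identically
`8μl/(πr⁴)` with l = λr).  Bookkeeping is per single vessel of each
generation; the parallelism of the 2^k identical vessels enters solely
through the factor ½ in the parent-outlet reduction
`R_{i−1}(L) = R_i(0)/2`.  Each generation uses μ_app at its own diameter;
a constant-μ (0.0046 Pa·s) mode reproduces a purely Newtonian tree.  The
conventional variant (λ = 30 everywhere, zero terminal resistance) keeps
the non-Newtonian per-generation viscosity by default — the viscosity
model is a property of blood, not of the λ schedule — and can be switched
to constant μ via `RunConfig.viscosity`.

In standalone use the terminal fixed point is closed-form: with root flow
known, per-leaf flow is exactly `Q_root/2^n`, so
`R_term = P_term/(Q_root/2^n)` and the marched pressure profile ends at
P_term identically (30 mmHg default; 1 mmHg = 133.322 Pa).  Pressures are
gauge, referenced to 0 on the venous side of the terminal resistor.  An
explicit-network oracle (`explicit_network_oracle`) materialises every
vessel up to 2¹⁵ leaves and reduces by elementary series/parallel steps;
it exists purely as an independent cross-check of the recursion.

No elasticity/compliance term is included anywhere: the model is
resistance-only by design (peripheral vessels are stiff), and no formula
for a reduced arteriolar elasticity was available to implement.

## Domain surrogate and coupling

The imaged domain is a tree of Poiseuille segments at the constant domain
viscosity 0.0046 Pa·s, each cut at 5 diameters (the same truncation rule
applied to imaged branches).  Flow↔velocity conversion uses a uniform
profile, `Q = v·πr²` (a parabolic factor-2 variant is noted but off).

`solve_coupled` alternates (a) one-shot nodal analysis of the surrogate
with the current outlet lumped resistances and (b) for the present
variant, an update of every terminal resistance from the freshly computed
outlet flow.  Convergence requires the largest relative change of any
outlet flow to fall below 1e-4 (configurable), echoing the convergence
practice of the steady solvers this feeds; plain successive substitution
is used, with a 0.5 under-relaxation factor switched on automatically if
the residual rises between iterations (max 1000 iterations, failure raises
with the residual history).  Because the present model adds the *same*
30 mmHg offset at every outlet, the flow split is nearly unchanged from
the resistance-only split and the loop typically converges in one or two
updates.  Mass conservation is inherited from the exact linear solve
(observed ~1e-13 relative).

For fixed outlet resistances the coupled solution equals one-shot dense
nodal analysis; for the present model the converged state satisfies
`Q_leaf·R_term = P_term` per outlet.  On every fixture tested the
per-outlet pressure ordering present ≥ conventional ≥ zero (≡ 0) holds.

## Synthetic fixtures

`make_outlet_set` emulates the carotid outlet anatomy: one ICA outlet
jittered ±5 % around the anatomical mean diameter 5.4834 mm, plus 7–9
ECA branches (9 default, matching the richer imaged models; 7 occurs when
small branches fall below imaging resolution) with diameters uniform in
1.2–3.2 mm — spanning the terminal/main artery-branch groups, a modelling
choice, not patient statistics.  `make_surrogate` arranges them as a
caterpillar: CCA → bifurcation → ICA and an ECA trunk shedding one branch
per junction, trunk radii from the ε = 3 cube law of the remaining
outlets (yielding CCA radii ≈ 3–4 mm).  Inlet velocity defaults to
0.3 m/s, a typical time-averaged common-carotid value.
`make_pseudo_measurements` produces Doppler-like references as
`v_sim·(1+N(0, σ))` with σ = 5 % by default, of the same order as
clinically reported velocity errors.  All draws come from seeded
`numpy.random.default_rng` streams (the measurement stream offset from the
geometry stream), so fixtures are bitwise reproducible.

What passing on these fixtures shows — and does not: the machinery is
exact against its oracles and behaves physiologically on carotid-like
geometry; it does not validate against real imaging or Doppler data, real
bifurcation angles, asymmetric trees, or pulsatile flow.

## Numerical choices

- Internal units SI throughout; mm/μm/mmHg/cm·s⁻¹ only at I/O.
- Diameter classification ties break toward the larger-vessel group.
- Radii from the closed-form power law (1e-12-relative accurate at depth).
- Nodal systems are dense `numpy.linalg.solve`; networks are ≤ ~25 nodes.
- The recursion↔oracle comparison runs at 1e-10 relative on trees of 1–15
  generations; the enumeration oracle is capped at 15 generations (2¹⁵
  leaves).
- Degenerate inputs fail loudly: outlet radius ≤ terminal radius,
  unperfused outlets (Q ≤ 0), non-tree surrogates, d ≤ 1.1 μm.

## Problem sizes

Default trees from millimetre outlets have 20–25 generations; acceptance
and test runs use fixtures of 8–10 outlets and Monte-Carlo loops of 200
seeded replicates, sizes at which the full suite completes in seconds.

## Known limitations

Resistance-only terminals (no Windkessel compliance or impedance), steady
flow, symmetric bifurcations, a surrogate domain instead of 3D CFD, and a
viscosity law without shear-rate dependence (no Carreau/Casson), plasma
skimming or temperature effects.  Reported mean-error statistics on
pseudo-measurements characterise the recovery experiment, not clinical
accuracy.
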