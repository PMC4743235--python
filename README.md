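# peritree

**0D peripheral-resistance outflow boundary conditions for carotid
blood-flow simulation.**

When a patient-specific 3D model of the carotid bifurcation is truncated a
few diameters past each branch, everything downstream — small arteries,
arterioles, capillaries — is lost, yet it is precisely that peripheral bed
that sets the flow split between the internal carotid and the
external-carotid branches feeding the face and oral cavity (the
tumour-feeding arteries targeted by intra-arterial chemotherapy).
`peritree` builds the missing periphery as a lumped (0D) resistance model
and turns it into outflow boundary conditions that close each outlet of
the imaged domain.

## The model

For each outlet of radius `r₀` a symmetric binary tree is grown: every
vessel splits into two identical daughters with

```
d_parent^ε = 2 · d_daughter^ε        (ε = 3, minimum-energy law)
```

so generation *k* has radius `r₀·2^(−k/ε)` and `2^k` vessels, stopping at
the first generation at or below the terminal capillary radius (12 μm).
Each generation is classified into an anatomical vessel group (large
arteries, main artery branches, terminal artery branches, arterioles,
capillaries), which assigns its length-to-radius ratio `λ = l/r`, and
carries the apparent blood viscosity at its own diameter from a
Fåhraeus–Lindqvist law `μ_app(d, Hct)` calibrated so that large vessels
recover the Newtonian value 4.06 mPa·s at haematocrit 0.45.

The tree reduces like an electrical ladder:

```
R_i(0) = 8·μ_i·λ_i/(π·r_i³) + R_i(L),      R_{i−1}(L) = R_i(0)/2
```

closed at the deepest generation by a terminal resistance
`R_term = P_term / Q_leaf` chosen so the terminal pressure is the
physiological 30 mmHg at the current per-leaf flow `Q_root/2^n`.

Three outflow boundary-condition variants are supported and compared on a
resistive surrogate of the imaged domain: **zero_pressure** (outlet
pressure ≡ 0), **conventional_0d** (constant λ = 30, zero terminal
resistance) and **present_0d** (anatomical λ schedule, 30 mmHg terminal
fixed point).

## Worked example

```python
from peritree import (FixtureConfig, compare_variants, make_outlet_set,
                      make_pseudo_measurements, make_surrogate, solve_coupled)

fc = FixtureConfig(seed=7, n_branches=9)           # ICA + 9 ECA branches
outlets = make_outlet_set(fc)
surrogate = make_surrogate(outlets, fc)
sol = solve_coupled(surrogate, "present_0d")       # coupled domain/0D solve
outlets = make_pseudo_measurements(sol, fc)        # pseudo-Doppler, 5 % noise
cmp_res = compare_variants(make_surrogate(outlets, fc))
for v, (mean, sd) in cmp_res.mean_errors.items():
    print(f"{v}: mean error {mean:.2f} +/- {sd:.2f} %")
```

prints

```
zero_pressure: mean error 62.76 +/- 30.32 %
conventional_0d: mean error 7.86 +/- 6.03 %
present_0d: mean error 4.37 +/- 2.81 %
```

The zero-pressure condition distributes flow by domain geometry alone and
misses the reference velocities badly; both 0D resistance models recover
them, and the anatomical λ schedule is the most precise.  The per-outlet
table (`cmp_res.table`) also shows the present-model outlet pressures
(~106–108 mmHg here), which land in the physiological arterial range,
whereas the conventional model's pressures are far below it.

The same pipeline is available from the shell:

```
peritree fixtures --seed 7 --n-branches 9
peritree build-bc --outlets outlets.csv --variant present_0d --out bc.csv
peritree solve    --surrogate surrogate.json --variant present_0d
peritree compare  --surrogate surrogate.json
```

`bc.csv` carries the per-outlet lumped resistance (Pa·s/m³), terminal
resistance and outlet pressure (Pa and mmHg) with a provenance header —
the file a flow solver's user-defined function would ingest.

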