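# fesff

Harmonic force-field parameterization for iron–sulfur and mononuclear
non-heme iron centers.

Rieske-type dioxygenases shuttle electrons through a [2Fe-2S] cluster —
ligated by four cysteines in ferredoxins ("4-Cys") or by two cysteines and
two histidines in the Rieske arrangement — into a mononuclear Fe(II) site
coordinated by two histidines, an aspartate (mono- or bidentate) and
water.  Simulating these proteins with Amber-style molecular mechanics
requires metal-site parameters that no general-purpose force field ships:
Fe–S and Fe–N stretch constants, angle terms around the iron, torsion
profiles for ligand rotation, and partial charges for the metal-binding
residues.  `fesff` is the toolchain that turns cluster-level
quantum-chemistry output into those parameters, for computational chemists
who have a geometry, a Cartesian Hessian and an ESP in hand and need a
`frcmod`/`prepin` pair out.

## What it computes

With mass matrix **M** and Hessian **H**, normal modes come from
M⁻¹ᐟ²·H·M⁻¹ᐟ² with ν̃ = (1/2πc)√λ, optionally after Eckart projection of
the rigid-body directions.  Modes are assigned to internal coordinates by
Wilson B-matrix projection, and each assigned coordinate gets a force
constant by two independent routes:

* **mode route** — k = μ_q ω², with μ_q = 1/(B_q·c)² the mode's reduced
  mass projected onto the coordinate (for a diatomic this is the textbook
  m₁m₂/(m₁+m₂));
* **finite-difference route** — a 5- or 7-point central stencil over
  energies at constrained displacements, where the target coordinate
  moves and every other internal of a non-redundant set is held at
  equilibrium.

The routes are cross-checked (default 20% tolerance) and the
finite-difference value is preferred when both exist.  Torsion profiles
V(φ) = Σ Vₙ(1+cos(nφ−γ)) are fitted to 30°-step rotation scans by linear
least squares.  ESP point charges are fitted with an exact net-charge
constraint (CHelpG-style, no restraints), averaged over declared
equivalence classes, renormalized, and compared against reference
(Amber94-style) residue tables.  Everything is emitted as fixed-column
`frcmod` and `prepin` files with byte-stable, round-trip-safe writers and
an explicit stretch-energy convention (`full`: K_file = k; `half`:
K_file = k/2).

Because electronic-structure runs are not reproducible at desk scale, the
package includes a first-class synthetic generator: ball-and-spring
models of the 4-Cys, Rieske and mononuclear-Fe centers with known
constants, analytic gradients and exact Hessians.  They drive the test
suite and let the whole pipeline run end-to-end with no external input.

## Worked example

```python
from fesff import (build_template, compute_modes, finite_difference_fc,
                   mode_force_constant)
from fesff.modes import assign_modes

model = build_template("rieske")                     # synthetic [2Fe-2S]
modes = compute_modes(model.to_bundle(), project_tr=True)
coords = model.internal_coordinates()
assignment = assign_modes(modes, coords, model.coords)

label = "K(Fe-Fe)"
idx, weight = assignment.assignments[label]
coord = next(c for c in coords if c.label == label)
k_mode = mode_force_constant(modes, idx, coord, model.coords)
hold = [c for c in coords if c.label != label]
k_fd = finite_difference_fc(model.energy, model.coords, coord, hold=hold)
print(f"{label}: mode {idx} at {modes.frequencies[idx]:.1f} cm^-1 "
      f"(overlap {weight:.2f})")
print(f"  mode route:              {k_mode.value:7.1f} kcal/mol/A^2")
print(f"  finite-difference route: {k_fd.value:7.1f} kcal/mol/A^2")
```

prints

```
K(Fe-Fe): mode 14 at 154.2 cm^-1 (overlap 0.19)
  mode route:                192.4 kcal/mol/A^2
  finite-difference route:    54.0 kcal/mol/A^2
```

Read: the best Fe–Fe-carrying mode of this template is heavily mixed
(overlap 0.19), so the per-mode estimate overshoots, while the
finite-difference route recovers the generating constant
(54 kcal·mol⁻¹·Å⁻² ≈ 0.38 mdyne/Å) exactly — precisely the situation the
two-route cross-check exists to expose.  On a pure diatomic the routes
agree to 1e-6.

The same pipeline from a shell:

```bash
fesff synth --template rieske --out rieske.json
fesff modes --bundle rieske.json --scale 1.03 --out rieske_modes.csv
fesff fc --template rieske --frcmod rieske.frcmod --convention full
fesff torsion --generate 1:2.0:0,3:1.0:180 --out torsion_fit.json
fesff benchmark
```

`rieske.frcmod` contains, among others, the line
`FE-FE   54.00   2.680` — the Fe–Fe stretch in kcal·mol⁻¹·Å⁻² with its
2.68 Å equilibrium.

## Layout

| module | contents |
|---|---|
| `fesff.units` | constants, exact unit conversions, diatomic closed form |
| `fesff.bundle` | the QM payload: JSON bundle, XYZ, fchk-subset reader |
| `fesff.internals` | internal coordinates and Wilson B-matrix rows |
| `fesff.synthetic` | harmonic cluster templates, torsion-scan generator |
| `fesff.modes` | normal modes, decomposition, assignment, scale factors |
| `fesff.forcefield` | force constants (both routes), torsion fitting, parameter sets |
| `fesff.charges` | ESP fitting, equivalence averaging, benchmarks, water chains |
| `fesff.amber` | frcmod/prepin writers and parsers |
| `fesff.benchmarks` | shipped reference tables and paired-unit checks |
| `fesff.cli` | the `fesff` command |

`docs/methods.md` documents the conventions (reduced masses, energy
conventions, constrained displacements) and the deliberate design
decisions in detail.
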