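# Methods

`fesff` turns cluster-level quantum-chemistry output — geometry, Cartesian
Hessian, atomic charges, ESP grids — into Amber-style molecular-mechanics
parameters for the metal centers of Rieske-type dioxygenases: the
[2Fe-2S] cluster in its 4-Cys (ferredoxin) and Rieske (2-Cys/2-His)
ligations and the mononuclear non-heme Fe(II) site ((His)₂ Fe Asp·H₂O,
with mono- or bidentate carboxylate).  This note records the model, the
conventions, and the design decisions that were genuinely open.

## Pipeline model

The harmonic approximation is assumed throughout.  Given a Hessian **H**
(kcal·mol⁻¹·Å⁻²) and masses **M**, normal modes are the eigenpairs of
M^(-1/2)·H·M^(-1/2); wavenumbers are ν̃ = sign(λ)·(1/2πc)·√|λ| with
imaginary modes encoded as negative numbers.  Rigid translations and
rotations can be removed before diagonalization by Eckart projection
(explicit construction of the six mass-weighted rigid vectors followed by
orthogonal-complement projection); this changes internal frequencies by
less than 1e-6 relative for structures at a stationary point and forces
the six rigid eigenvalues to zero exactly.

Modes are characterized by projection onto internal coordinates through
Wilson B-matrix rows (∂q/∂x): the weight of coordinate *q* in mode *d* is
|B_q·d| normalized over the coordinate set.  Mode→coordinate assignment is
globally greedy on these weights, each coordinate claiming its best
unclaimed mode, ties broken toward the lower frequency so reports are
reproducible.

### Reduced-mass conventions (they differ by a factor!)

Two conventions coexist and are both exposed:

* `NormalModeSet.reduced_masses` stores μ = (Σ c²)⁻¹ with c = M^(-1/2)·v
  and v the **unit** mass-weighted eigenvector — the convention of
  mainstream frequency-analysis printouts.  For a homonuclear diatomic
  this yields the *atomic* mass m.
* `projected_reduced_mass` gives μ_q = 1/(B_q·c)², the effective inertia
  of the mode along a named internal coordinate.  For a diatomic stretch
  it equals the textbook pair mass m₁m₂/(m₁+m₂), and it is the convention
  under which the per-mode force constant k = μ_q·ω² returns the spring
  constant of that bond exactly when the mode is pure.

Force-constant extraction (`mode_force_constant` with a coordinate) uses
the projected convention; without a coordinate the stored convention is
used and the value is gauge-dependent, which the docstrings flag.

### Force constants, two routes

*Mode route:* k = μ_q·ω² from the assigned mode.  Exact for a decoupled
coordinate; biased by mode mixing otherwise (on the synthetic Rieske
template individual stretch estimates deviate from the generating
constants at the tens-of-percent level, which is why the cross-check
below exists).

*Finite-difference route:* the energy is sampled on a symmetric stencil
along one internal coordinate and differentiated numerically; the
5-point stencil (−E₂+16E₁−30E₀+16E₋₁−E₋₂)/(12h²) is exact for quadratic
profiles, and a 7-point stencil is available.  Default steps: 0.01 Å
(stretches), 0.5° (bends/torsions).

Displaced geometries are constructed by **constrained solution**: the
target coordinate is set to q₀+δ while every other member of a
non-redundant internal-coordinate set is held at its equilibrium value
(Gauss–Newton on the B matrix with a first-order pseudo-inverse
predictor, sub-step continuation, and backtracking; residuals converge
below 1e-12).  This mirrors scan protocols in which all atoms not
defining the probed coordinate are relaxed.  A naive "rigid" displacement
(move only the two end atoms along the bond axis) is kept as an option
but cannot isolate a coordinate whose atoms appear in other terms:
moving an Fe atom necessarily bends every angle at that Fe, so the rigid
second derivative contains bend contributions of the same order as the
stretch constant itself.

`consistency_check` compares the two routes; the default 20% tolerance is
the historical level of agreement for [2Fe-2S] stretches.  When both are
available the finite-difference value is emitted (it probes the
coordinate directly) and the mode/FD ratio is recorded in the parameter's
note.

### Torsions

Dihedral profiles follow the Amber convention V(φ) = Σ Vₙ(1+cos(nφ−γ)).
Scans are fitted by linear least squares: with phases restricted to
{0°, 180°} the model is linear in the barriers plus an offset (a unique
solution, unlike freehand fitting); free phases remain linear through the
(V cos γ, V sin γ) parameterization and are reported as (Vₙ, γₙ).  The
scan grid must be uniform and span less than 360°; 30° steps (12 points)
are the reference protocol.

### Charges

ESP charges are unrestrained constrained least squares: point charges at
the atom positions minimizing Σₘ(Vₘ−Σᵢqᵢ/rₘᵢ)² subject to Σq = Q via one
Lagrange multiplier.  Grids are Connolly-style Fibonacci shells at
1.4–2.0× the van der Waals radii with interior points excluded; a seeded
random rotation de-aligns the shells between runs.  Hyperbolic (RESP)
restraints are deliberately **not** implemented: the equivalence behaviour
they provide is obtained by explicit averaging over user-declared
equivalence classes, which keeps fitting linear and conserves the total
charge exactly.  Classes are user-declared rather than auto-detected from
graph symmetry because chemically distinct but topologically equivalent
ligands (e.g. a His that hydrogen-bonds to a bridging Asp vs one that
does not) must not be merged.

Residue templates for free-water networks chain the water oxygens to an
anchor atom by greedy nearest-neighbour traversal (ties to the lower
index), one pseudo-bond per water; the links are emitted in the prepin
LOOP section.

### Unit conventions

Internal units are Å, amu, kcal·mol⁻¹, elementary charges.  The single
derived factor 1 mdyne/Å = 1e-18·N_A/4184 ≈ 143.93 kcal·mol⁻¹·Å⁻²
(thermochemical calorie, CODATA N_A) bridges to spectroscopic tables and
is never re-hard-coded.  Published paired-unit tables are verified at
*printed rounding*: |kcal − f·mdyne| ≤ half an ulp of the kcal column
plus half an ulp of the mdyne column propagated through f.

### File formats

frcmod and prepin are fixed-column dialects documented by the writers and
round-trip safe (`parse(write(x)) == x`, `write(parse(f))` byte-identical).
Because parameter files in the wild do not state their stretch energy
convention, both are supported and recorded on the title line: `full`
writes the physical second derivative k (E = ½kΔr²), `half` the
Amber-native K = k/2 (E = KΔr²).  DIHE barriers are written as Vₙ/2 with
negative periodicity marking continuation terms.  Prepin z-matrices are
built against three dummy atoms at fixed positions shared by writer and
parser, with dihedrals canonicalized to [0°, 360°) after rounding so the
round trip is stable at rounding boundaries.  The fchk reader handles the
`Atomic numbers`, `Current cartesian coordinates` and lower-triangular
`Cartesian Force Constants` blocks and converts bohr/hartree to the
internal units.

## The synthetic-cluster generator

`synthetic.build_template` builds ball-and-spring models whose ground
truth is known by construction, standing in for electronic-structure
output:

| template | sites | stretch/bend defaults |
|---|---|---|
| `fes_4cys` | 2 Fe, 2 S(b), 4 SMe pseudo-atoms | K(Fe-S(b)) 209, K(Fe-S(t)) 165, K(Fe-Fe) 33 kcal·mol⁻¹·Å⁻²; bends 70 kcal·mol⁻¹·rad⁻² |
| `rieske` | 2 Fe, 2 S(b), 2 SMe, 2 MeIm | K(Fe-S(b)) 158, K(Fe-S(t)) 163, K(Fe-N(t)) 63, K(Fe-Fe) 54; bends 139/127/63/36 |
| `roc_monodentate` | Fe, 2 MeIm, acetate-O, water-O | K(Fe-OH₂) 63.2, K(Fe-OAc) 37.7, K(Fe-N) 30.4/25.8; bends 29.9 |
| `roc_bidentate` | Fe, 2 MeIm, 2 acetate-O, water-O | K(Fe-OAc) 45.75 and K(Fe-N) 39.5 (means of the sym/antisym mode pairs), K(Fe-OH₂) 44.5; bends 29.9 |

Defaults are the mode-derived estimates for the **oxidized** clusters;
the reduced-state table is available through `template_constants`-style
overrides.  Equilibrium [2Fe-2S] geometry uses crystallographic lengths
(4-Cys: Fe–Fe 2.71, Fe–S(b) 2.22, Fe–S(t) 2.35 Å; Rieske: 2.68/2.20/
2.32/2.05 Å) with idealized tetrahedral splay; full coordinates for the
optimized clusters are not published, so the templates are idealized
motifs, not replicas.  ROC bond lengths are typical non-heme Fe(II)
values (Fe–N 2.15, Fe–O(Asp) 2.00 monodentate / 2.15 bidentate,
Fe–OH₂ 2.10 Å), chosen once.  Ligand groups are single pseudo-atoms with
the group's aggregate mass (SMe 47.10, methyl-imidazole 82.11, acetate
59.04 amu, split over the two oxygens when bidentate) at the donor-atom
position.

Two deliberate non-obvious choices:

* **Non-redundant term sets.**  Each template carries exactly 3N−6
  internal coordinates with a full-rank B matrix (verified at build
  time).  The [2Fe-2S] ring is spanned by its four Fe–S(b) stretches, the
  Fe–Fe stretch and one ring-pucker torsion (V₂ = 5 kcal·mol⁻¹, a package
  default — no out-of-plane constant is tabulated) instead of the
  redundant Fe-S(b)-Fe / S(b)-Fe-S(b) ring bends.  A redundant ring is
  geometrically frustrated — the Fe-S(b)-Fe triangle cannot change one
  coordinate while every other stays at equilibrium — which would make
  exact finite-difference recovery of the generating constants
  impossible.  The ring-bend constants still exist downstream: they are
  legitimate *assignment coordinates* and emitted parameters; they are
  just not independent generator springs.
* **Generic (C1) ROC geometries.**  Ideal trigonal bipyramids make some
  angle sets linearly dependent (near-trans ligand pairs degrade the
  constraint Jacobian), so the five-coordinate template is built with a
  mildly distorted, generic arrangement — which is also what the real
  sites look like.

The Hessian is assembled analytically as Σ V''(q₀)·B_qᵀB_q, exact at the
equilibrium because every term sits at its own extremum there: symmetric,
translationally invariant and positive semi-definite by construction.
Models not at a stationary point are rejected.

**What the generator does not emulate:** anharmonicity, mode coupling
beyond what shared atoms induce, electronic polarization, solvent, and
the redox-state geometry relaxation of real clusters.  Green tests
therefore certify the *machinery* — eigensolver, projections, stencils,
fitting, file formats — on exactly-known ground truth; they do not
certify that harmonic parameters describe a real metal site, which is a
property of the quantum chemistry feeding the pipeline, not of this
package.

## Numerical choices

* Hessian symmetry accepted to max|H−Hᵀ|/max|H| ≤ 1e-8, then
  symmetrized; charges must sum to the declared total within 1e-6 e.
* Wilson rows are analytic for stretches and bends; torsion rows use
  tight central differences (h = 1e-6) of the exact dihedral with
  branch-crossing correction — accurate to ~1e-11, ample for projections,
  outer products and Newton Jacobians.
* Constrained displacement: target tolerance 1e-12 on every internal,
  continuation sub-steps of ≤0.005 (Å or rad), backtracking line search.
* ESP design matrices with cond(AᵀA) > 1e10 are rejected (coincident
  atoms, degenerate grids).
* Near-zero eigenvalues map to ~1e-6 cm⁻¹ wavenumber noise through the
  square root; anything below 1e-3 cm⁻¹ is treated as rigid-body.
* Assignment tie-break: lower frequency wins.  Averaging of
  symmetry-equivalent coordinates: arithmetic mean (conserves the implied
  totals and matches how paired estimates are reported).

## Refit scale factors

`scripts/acceptance.py` refits least-squares-through-origin frequency
scale factors (f = Σ obs·calc / Σ calc²) from the shipped band tables
after un-scaling the printed calculated columns.  The refits land near
the published selections (≈1.07 vs 1.06 oxidized 4-Cys, ≈1.11 vs 1.1
reduced) but not exactly on them — the original factors were chosen by an
unstated fitting procedure, and a least-squares refit from the printed
(already rounded) bands is the reproducible formalization, not a
recovery of the original fit.

## Known limitations

* Templates are coarse-grained (pseudo-atom ligands); they reproduce the
  low-frequency metal-ligand block qualitatively, not the full ligand
  spectrum, and carry no symmetry labels (no point-group classification).
* The mode-route force constant is only as good as the mode purity;
  heavily mixed modes need the finite-difference route or a full
  internal-coordinate Hessian transformation (Seminario-style), which is
  out of scope.
* Torsion fitting assumes a uniform closed scan; relaxed scans with
  drifting constraints are not modelled.
* The prepin writer emits a single chain tree (all `M`); branched trees
  and improper records beyond the empty section are not generated.
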