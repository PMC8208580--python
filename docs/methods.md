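# Methods

## Model overview

The package poses the formation of the lateral structures of teleost
vertebral bodies as a compliance-minimization (stiffness-maximization)
problem. The body is discretized on a regular voxel grid (axis convention:
x cranial–caudal, y left–right, z dorsal–ventral, origin at the body
center). Three regions are fixed by development and never change density:

* **autocentrum** (ρ = 1): an amphicoelous hourglass shell — a central
  cylinder (radius `C_R`, length `C_X`) continued by two cones (half angle
  `θ`, slant length `L`), shelled radially to thickness `C_T`. Its outer
  conical radius is `R = C_T + C_R + L·sin θ`.
* **vertebral arches** (ρ = 1): four wedge sectors of angular width `ξ`,
  offset `η` from the dorsal and ventral midlines (gap width `2η`),
  spanning radially from the autocentrum surface to the bounding cylinder
  of radius `R` and axially over the whole body. On coarse grids a voxel
  is labeled arch when its subtended azimuth interval overlaps the wedge,
  which keeps the thin wedges connected.
* **arch gaps** (ρ = d): the sectors between the paired wedges.

Everything else inside the bounding cylinder is the **design domain**,
where density evolves in `[d, 1]`; the space inside the concave funnels
(notochord canal and intervertebral space) is outside the model. Geometry
is sampled analytically at voxel centers; named boundary facet sets
(concave surface, distal rims, arch surfaces, arch rim sectors) are
derived from label adjacency. The default element size, 0.02 cm, is the
coarsest grid that resolves the shell thickness `C_T`; all lengths are
converted to SI meters internally (the reference values are centimeters).

Defaults (reference configuration): `C_R = 0.04 cm`, `C_T = 0.02 cm`,
`C_X = 0.04 cm`, `L = 0.6 cm`, `θ = 45°`, `ξ = 5°`, `η = 15°`, `d = 0.01`;
material `E₀ = 20 GPa`, `ν = 0.3`, SIMP exponent `P = 3`; traction
magnitude `F = 10⁶ N/m²`. These are the study conditions; sweeps vary `η`,
`θ` (with `L(θ) = L·sin 45°/sin θ` so the dorsoventral height stays
fixed), the diagonal-bending ratio `w`, and the volume fraction `V_f`.

## Load cases and symmetry

Nine load cases model tissue-transmitted loads: normal/horizontal
compression of the concave surfaces, bending applied to the concave
surfaces or the distal rims (as two half-surface cases averaged into one
objective), diagonal bending (horizontal plus `w`-scaled vertical), shear
and torsion on the rims, and arch tension (left–right on the arch outer
surfaces; dorsal–ventral on the arch rim sectors). Tractions are constant
per boundary facet, evaluated at facet centroids; facets whose centroid
lies exactly on a sign plane (x/|x| etc.) carry zero traction. Point
constraints snap to the nearest active grid node; edge-circle constraints
take all nodes within half a voxel of the analytic circle.

Mirror symmetry is exploited two ways. Cases that are *symmetric* under a
reflection run on reduced grids with `u·n = 0` on the cut planes (eighth
model for compression and left–right arch tension, quarter for bending and
dorsal–ventral arch tension). Shear and torsion tractions are
*antisymmetric* under the remaining reflections — reflecting the load
yields its negation — so those cases reduce exactly to an eighth model
with the tangential displacement fixed on the cut planes. The package
supports both this reduction and the literal half/full construction; they
agree to solver tolerance (cross-checked in the test suite), and the
reduction is the default because the full-model torsion solve is ~20×
more expensive.

Paired cases are solved once per group: the reversed shear / opposite
torsion case is the exact negation of its partner, and the second bending
half is the mirror image of the first whenever the density is
mirror-symmetric (which the optimizer preserves; the solver verifies the
premise and falls back to an independent solve otherwise).

## FEM

Trilinear 8-node hexahedra with 2×2×2 Gauss quadrature (exact for this
element); `E(ρ) = ρ^P E₀`; out-of-domain voxels carry no stiffness and
their nodes leave the system; arch gaps stay at the floor `d` so the mesh
remains numerically connected. Compliance is the external work `f = tᵀu`;
element sensitivities are the standard self-adjoint SIMP expression
`∂f/∂ρₑ = −(1/N) Σᵢ P ρₑ^{P−1} uᵢₑᵀ k₀ uᵢₑ`. Systems below 20k free
degrees of freedom are solved by sparse LU; larger ones by
Jacobi-preconditioned conjugate gradients at relative residual 1e-8 with
warm starts across optimizer iterations (LU fill for 3D elasticity grows
steeply, and an incomplete-LU preconditioner proved unstable at the
`d³ = 10⁻⁶` stiffness contrast).

## Density evolution

One explicit pseudo-time step per FEM solve:

```
ρ ← clip( ρ + dt·[ K·(−s/⟨|s|⟩ − λ) + (τ/h²)·Δρ ],  ρ±move,  [d, 1] )
```

where `⟨|s|⟩` is the mean design-domain sensitivity magnitude (so the gain
`K` is a dimensionless step size), `Δ` the 6-neighbor Laplacian with
zero-flux conditions at the design-domain boundary, and `move` a
per-iteration change cap. The multiplier `λ` is 0 while the material
volume is under `V_f·|Ω|` (free accretion from the void floor, mirroring
load-driven deposition) and is found by bisection once the bound binds so
every later iterate is feasible; from a dense start (ρ₀ = 1) the update
saturates at maximal removal until the bound is reached. Where a load
group is equivariant under reflections the reduced model does not already
exploit, the summed sensitivity is symmetrized across those planes — exact
for the group objective and numerically pins the iterate to the symmetric
subspace. The run is deterministic: no random numbers anywhere.

Defaults and rationale: `K = 0.25` and `move = 0.2` give convergence in
40–150 iterations at desk scale; `dt = 1`; `τ = 0.12 h²/dt` places the
diffusion number at 0.12, inside the explicit stability limit 1/6 and
smoothing features below ~2 voxels (minimum strut width 2–3 voxels at the
default mesh); convergence is declared when the relative objective change
stays below 1e-4 over 10 iterations, capped at 300. A capped
(non-converged) run returns the best feasible iterate of the trailing
window, since early transients can undershoot the settled objective.
Infeasible bounds (`V_f` below the fixed-region volume ratio) are rejected
up front. The volume ratio is measured over the whole analysis domain,
fixed regions included.

This reaction–diffusion scheme is a documented surrogate for the
time-dependent evolution family it belongs to: it keeps
sensitivity-driven growth/removal, a diffusion-limited feature size, and
accretion-before-the-bound, and it is validated against an independently
implemented optimality-criteria optimizer (within 5% final compliance on a
16×10 cantilever fixture; the cantilever is one voxel thick with
plane-strain constraints). Alternative update strategies can be slotted in
at `optimizer.step`.

## Structure classification

Designs are analyzed on the full (mirrored) model at the ρ = 0.5 level.
The design-domain occupancy is unwrapped onto an (axial fraction s,
azimuth φ) map recording, per ray, the radial *protrusion height* above
the autocentrum outer surface and whether any solid material is present
("coated"). Azimuth sectors within `η + ξ` of the dorsal/ventral midlines
are masked so arches are never counted as lateral structures.

Stiffness maximization always deposits a thin reinforcement skin on the
loaded surfaces; the anatomical vocabulary refers to what *protrudes*
beyond that skin. A ray therefore only counts as structure when its
protrusion clears `max(2 voxels, 0.15 × local headroom)` (headroom = radial
room between shell and bounding cylinder), and a connected component is
only reported when it contains prominent cells rising above
`max(0.35 × headroom, background-coating median + 2 voxels)` with at least
5 map cells (speck suppression on the 46×72 map). Components are labeled
with 8-connectivity, periodic in φ, and attributed to the left/right
lateral side by their circular-mean azimuth.

Frozen classification rules, in order of precedence:

1. `SHELL` — angular extent > 120°, or a side with ≥ 80% coated rays and
   no discrete component (near-uniform thickening);
2. `DIAGONAL_RIDGE` (one per arm) — when splitting the component at the
   axial midline and its own azimuthal center yields ≥ 2 arms whose crest
   lines tilt ≥ 20° from the axial direction (crossing X/V ridges merge
   into one component but count per arm);
3. `PLATE_RIDGE` — axial span ≥ 0.8 of the reachable span, extent ≤ 60°,
   crest tilt < 20°;
4. `HUMP` — confined to the outer 25% of the axial span at a rim;
5. `DIAGONAL_RIDGE` — crest tilt ≥ 20°;
6. `PILLAR` — everything else.

The crest line is the per-slab azimuthal centroid in arc-length units; its
linear-fit slope against the axial coordinate defines the tilt, which is
robust to the width variations that defeat a plain principal-axis fit. All
thresholds are frozen in `ClassifierConfig` and exposed for sensitivity
probes; they operationalize qualitative anatomical descriptions, and the
test suite pins their values.

## Problem sizes and iteration caps

The end-to-end suites run the reference geometry at 0.02 cm voxels —
eighth models of ~7k elements (~26k dofs), quarter models of ~14k elements
(~51k dofs) — with iteration caps of 25–45 for the morphology runs (the
objective plateaus by ~25–30 iterations; classifications were verified
stable between 40 and 60 iterations for the structured cases) and 10–12
iterations for runs that only check constraint satisfaction and symmetry,
which hold at every iterate by construction. These sizes are the package's desk-scale defaults;
resolution and caps are plain configuration for larger studies.

## Known limitations

* **Local optima.** The evolution is a local scheme for a nonconvex
  problem. Runs from ρ₀ = d and ρ₀ = 1 can settle in different optima;
  for normal compression on the reference model their compliances differ
  by ~5–10% depending on the gain, with the dense start finding the
  stiffer design. This sensitivity is larger than for fine-mesh
  time-evolution runs of the same problem family.
* **Coarse-mesh morphology.** At the pinned resolution some morphological
  transitions shift: bending at `V_f = 0.4` produces a waist-centered
  band rather than a single longitudinal plate ridge, and the arch-tension
  cases grow full-length wings beneath the arch wedges rather than
  localized rim humps. The classifier reports these honestly; finer
  meshes (element size ≪ `C_T`) are expected to recover the discrete
  structures and can be configured directly.
* **Arch extent.** The wedges' axial and radial extents are an
  interpretation (full axial length, radially to the bounding cylinder);
  the arch-tension responses are sensitive to it.
* **Physics scope.** Static linear elasticity, isotropic material, no
  physiological load magnitudes or muscle lines of action, no
  trabecular-scale microstructure.
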