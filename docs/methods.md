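# Methods

This note documents the models, numerical choices and limitations behind
`hyperview`, module by module, in the spirit of a methods appendix.

## Structure input and bond perception

PDB files are read by fixed-column parsing (wwPDB v3.3 layout). The
element symbol comes from columns 77–78 and falls back to the atom name
with digits stripped, trusting a two-letter read (FE, CL, ZN, …) only when
the name starts in column 13. A `ParsePolicy` object fixes every
convention that affects atom counts: first MODEL only, first alternate
location per site, HETATM kept, hydrogens kept, waters kept. These are
deliberate defaults for viewer-style counting; all are switchable because
published per-entry atom counts depend on exactly these conventions.

Bonds use the classic distance rule
`min_dist < d ≤ r_cov(i) + r_cov(j) + tol` with `tol = min_dist = 0.4 Å`
— the common viewer heuristic — over Cordero (2008) covalent radii shipped
as `data/elements.tsv` (Bondi vdW radii and CPK-ish colors ride along; an
`X` row provides the default for unknown elements, which warn but never
fail). Two refinements prevent chemically absurd output at this tolerance:
a hydrogen keeps only its single nearest eligible heavy partner, and
waters never bond to non-water atoms (solvent is conventionally drawn
unbonded). Candidate pairs come from a uniform spatial hash with cell size
equal to the largest possible cutoff, so detection is O(n) with a small
constant rather than O(n²); a brute-force all-pairs oracle pins the result
set in the tests.

## Gaussian density surfaces

The density is `ρ(x) = Σᵢ exp(B·(dᵢ²/rᵢ² − 1))` with blobbiness `B = −2`,
iso level `τ = 1`, grid spacing `h = 0.5 Å`, padding 3 Å and per-atom
truncation at 3 rᵢ (all adjustable via `SurfaceParams`). The −1 in the
exponent normalizes each atom's contribution to exactly 1 at its own
radius, so the single-atom isosurface at τ = 1 is the sphere of radius rᵢ
— this gives every surface test an analytic oracle. More negative B
tightens the surface (less blobby); raising τ shrinks it. Accumulation is
cell-binned: each atom touches only the grid nodes inside its cutoff box,
keeping the build proportional to atoms × cutoff volume. A configurable
cell budget (default 4·10⁷) turns runaway grids into an explicit error
advising a larger spacing.

Marching cubes is the classic 256-case table walk. Rather than
transcribing the published tables, the case table is *constructed* at
import: per configuration, cut edges are paired on each cube face by
marching squares (the ambiguous 4-cut face uses a fixed rule isolating the
inside corners — i.e., no asymptotic-decider ambiguity resolution, the
classic behavior), chained into loops, fan-triangulated, and wound so
triangle normals descend the scalar field (outward for a blob). Edge
vertices interpolate at `t = (τ − v_a)/(v_b − v_a)` and are welded by
global grid edge; a vertex landing exactly on a grid node (t ≈ 0 or 1) is
welded by node instead, which removes the degenerate sliver triangles an
iso level passing exactly through node values would otherwise create.
Per-vertex normals are the normalized negative density gradient, falling
back to area-weighted face normals within half a cell of the boundary.
scikit-image's independent implementation serves as a vertex-count
cross-check in the tests, never as the implementation.

Trilinear sampling raises a distinct `OutOfDomainError` outside the grid
(a control signal, not a sentinel value); gradients are central
differences with step = half the local spacing per axis.

## Electrostatic field lines

Lines are streamlines of E = −∇φ integrated by RK4 with a **fixed
arclength step** (default ¼ of the minimum grid spacing) on the
unit-normalized direction field. Arclength parameterization keeps the
step geometric and avoids stiffness where |E| spans orders of magnitude.
Both directions are traced from each seed and concatenated. Stopping
rules: domain exit, |E| < 1e−6, 10⁴ steps, 500 Å of arclength, plus two
*resolution guards* that are the numerically load-bearing choices here:

- **turn guard** — stop when the direction turns more than 30° per grid
  cell traveled (a trilinear field cannot represent tighter bends);
- **growth guard** — stop when |E| grows by more than a factor 1.15 within
  one step. This is the guard that matters at point singularities
  approached head-on, where the direction never turns but the dipole/point
  field blows up inside the final cells. For a q/r potential it halts
  ~3–4 cells from the charge, which is where trilinear interpolation still
  tracks the analytic field to well under 1° of direction error; without
  it, lines orbit through the unresolved singular cell and come out
  anywhere.

Near the domain boundary the tracer degrades its gradient stencil to
one-sided differences so lines run out to within one step of the edge;
the public `gradient_at` keeps the strict half-cell domain contract.

Seeds are surface vertices ranked by |φ| descending, greedily thinned to a
minimum separation of 2× the mean grid spacing, truncated to `max_lines`.
The animated dash is `intensity(d,t) = ½(1+sin 2πφ)` gated by
`φ = frac(d/λ − f·t) < duty` (defaults λ = 5 Å, duty = 0.3, f = 1 cycle/s):
a lit segment of length duty·λ per wavelength advancing at f·λ Å/s,
exactly periodic in d and translation-covariant in t.

## HyperBalls geometry

Spheres and bond surfaces are homogeneous quadrics (p̃ᵀQp̃ = 0, inside
negative). The bond between spheres (rᵢ, rⱼ) at distance D is the
revolution surface ρ² = a² + c(x − x_w)² with waist a = (1−s)·min(rᵢ,rⱼ);
(c, x_w) are solved by a damped two-unknown Newton iteration (numerical
Jacobian, tolerance 1e−10) on the two tangency residuals, seeded from the
algebraic reduction u·x_w² = rᵢ²−a², u·(x_w−D)² = rⱼ²−a² (u = c/(1+c)).
The solve rejects, with explicit errors: containment (one sphere inside
the other — no external tangency exists) and deep overlap past the
parabolic transition u → 1, where this parameterization degenerates
(bonded atoms at chemically sensible radii sit safely on the hyperboloid
branch). The quadric is clipped to the slab between the tangency
abscissae; atom spheres cap their own ends. As s → 1 the waist pinches
toward the cone/two-sheet limit continuously — a property test sweeps
s = 0→0.95 and bounds the hit-point motion of a fixed ray. The shrink
semantics (waist linear in s) are this toolkit's own convention.

Ray casting substitutes p = o + t·d into the quadric, takes the smaller
positive root, falls through to the far root when the near one is clipped,
and orients the normal (spatial part of 2Qp̃) toward the ray origin. A
sampling + bisection brute-force oracle checks 100 random pairs to 1e−6.

## Renderer

Camera space is right-handed, view −z, y up; normals are stored in camera
space so lit-sphere shading is literally `texture[(n_x+1)/2, 1−(n_y+1)/2]`
(bilinear), blended `(1−blend)·texture + blend·base`. Quadrics are
ray-cast per pixel inside their projected AABB envelope (the software
equivalent of point-sprite impostors); meshes go through a z-buffer
rasterizer with barycentric normals. One sample per pixel, no
transparency or AA — that keeps the analytic oracles (disk coverage, cap
area) exact up to pixel quantization. Primitives are processed in chunks
of ≤16,000 (the classic per-particle-system cap); chunked and unchunked
renders are pixel-identical since painting is depth-tested and opaque.

Cut planes keep the half-space (p−p0)·n ≤ 0. A clipped near hit falls
through to the primitive's far intersection, painted flat in the cap color
with the plane normal — rays entering the open cross-section see the
"solid interior" fill. Mesh fragments above the plane are dropped and
back-facing fragments under an enabled cut get the cap treatment. Lambert
shading is a headlight model, 0.15 + 0.85·max(0, n_z).

## Networks and springs

XGMML import takes node id/label, graphics x/y (y negated — Cytoscape's y
grows downward), radius = w/2 (h/2, then 1.0 as fallbacks) and hex fill;
referential integrity is enforced loudly. The depth layout is the linear
min–max rule z = factor·(r − r_min)/(r_max − r_min) (all-equal radii ⇒ all
z = 0): scale-invariant, idempotent, monotone, with sign selecting
background vs foreground for the big nodes. Scene conversion reuses the
molecular primitives verbatim — node spheres, near-cylindrical low-shrink
bond hyperboloids for edges.

The spring network puts one Hookean spring on each bond with rest length
equal to the current distance (the loaded structure is the equilibrium)
and integrates with semi-implicit Euler — the standard game-physics
integrator, symplectic, so energy oscillates (amplitude ~dt·ω/2) without
secular drift. Stability needs dt < 0.2·√(m/k) (`stable_dt()`); a velocity
ceiling converts blow-ups into a clear "reduce dt" error. Dragging is
modeled headlessly as per-atom external forces and pinned sets. Per-atom
energy is each spring's ½k(l−l0)² split half per endpoint; colors ramp
white (0) to black (frame max, or a fixed reference for cross-frame
comparability).

## Synthetic data

The fixtures module generates everything the tests and the acceptance
script consume, deterministically in (parameters, seed): diatomics and
chains (1.5 Å C–C spacing — a typical bond length, inside the distance
rule's cutoff); analytic point-charge (φ = q/r, charge nudged 0.37 cells
off-node so no sample hits the singularity), dipole and uniform-gradient
potentials standing in for Poisson–Boltzmann solver output; seeded random
networks with degree-proportional radii mimicking Cytoscape's
connectivity sizing; and procedural matcap textures (vertical gradient,
polar checker, Lambert-lit hemisphere). These fixtures are idealized:
analytic potentials are smooth and noise-free, synthetic networks are
Erdős–Rényi rather than scale-free, and no fixture reproduces real PDB
pathologies (chain breaks, insertion codes in anger, disordered waters) —
so green tests demonstrate correctness of the algorithms on well-posed
input, not robustness to every archival PDB quirk. The two wwPDB entries
used as parse/bond calibration are therefore fetched live when a network
is available and skipped otherwise.

## Problem sizes

Default test and acceptance workloads are sized for a single CPU: 256²
frames, 64³ potential grids, ≤10⁴-step integrations, 100-ray oracles,
≤500-atom random clouds. Each was chosen as the smallest size at which
the measured quantity is stable against the next size up.

## Known limitations

- No solvent-excluded (MSMS-style) surfaces; the Gaussian surface is a
  different object and fuses atoms at low τ.
- Classic marching cubes without ambiguity resolution can, on adversarial
  grids, produce the standard non-manifold configurations; closedness is
  asserted (and holds) on smooth Gaussian blobs.
- The renderer is deliberately minimal: no transparency, anti-aliasing,
  shadows, or screen-space effects; perspective mesh depth interpolates
  affinely (exact for the small triangles it is used with).
- Field-line tracing is only as good as the grid; the resolution guards
  stop lines a few cells from singularities rather than pretending the
  interpolated field is meaningful there.
- Spring physics is a visualization aid, not molecular mechanics: no
  angles, torsions, non-bonded terms, or thermostats.
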