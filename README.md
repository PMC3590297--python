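# hyperview

Headless, scriptable molecular and biological-network visualization.
`hyperview` re-creates the rendering pipeline of game-engine-era molecular
viewers — sphere-impostor particles, ray-cast HyperBalls, Gaussian
molecular surfaces, animated electrostatic field lines, lit-sphere
("matcap") shading, cut planes, 3D network layouts and a toy spring-network
physics mode — as a pure-CPU Python library with a CLI, producing PNG
images and OBJ meshes with no GPU, window system or game engine required.

It is aimed at structural bioinformaticians and tool builders who want
publication-style molecular/network renderings from scripts or pipelines,
and at anyone who needs the underlying primitives (bond perception,
density isosurfaces, streamline tracing, ray-quadric tests) with a tested,
deterministic implementation.

## The models at the core

**Bond perception.** Atoms *i*, *j* are bonded iff
`min_dist < d(i,j) ≤ r_cov(i) + r_cov(j) + tolerance` (defaults 0.4 Å and
0.4 Å, Cordero covalent radii), with a spatial hash for linearity, a
nearest-partner rule for hydrogens and no solvent–solute bonds.

**Gaussian surface.** The density is a sum of atom-centered Gaussians

    ρ(x) = Σᵢ exp( B · ( |x − xᵢ|²/rᵢ² − 1 ) ),   B < 0 (default −2),

so an isolated atom contributes exactly 1 at distance rᵢ; marching cubes
at threshold τ (default 1) extracts the surface, so a lone atom yields a
sphere of radius rᵢ — the property the test suite leans on.

**HyperBalls.** An atom is the quadric sphere |p−c|²−r² = 0; a bond is the
surface of revolution ρ² = a² + c·(x−x_w)² with waist
a = (1−s)·min(rᵢ,rⱼ) controlled by the shrink factor s ∈ [0,1), and (c,
x_w) solved (2-unknown Newton, tol 1e-10) so the surface is tangent to
both atom spheres. Rendering is exact per-pixel ray casting of these
quadrics inside their projected envelopes.

**Field lines.** Streamlines of E = −∇φ through a potential grid (OpenDX,
e.g. APBS output), integrated by fixed-arclength RK4 on the unit direction
field, seeded on a surface where |φ| is largest, and animated as a
thresholded sinusoidal dash: intensity(d,t) = ½(1+sin 2π·phase) where
phase = frac(d/λ − f·t) < duty.

**Lit-sphere shading.** Covered pixels look up a 2D sphere texture at
(u,v) = ((n_x+1)/2, 1−(n_y+1)/2) from their camera-space normal, blending
with per-primitive base colors.

**Springs.** Each bond becomes a Hookean spring at its rest distance;
semi-implicit Euler integration, pinned atoms and external pulls stand in
for mouse dragging, and per-atom elastic energy maps to a white→black ramp.

## Worked example

```bash
hyperview fixtures diatomic -o di.pdb       # two carbons 1.5 A apart
hyperview info di.pdb
```

prints

```
atoms: 2
bonds: 1
chains: 1 (A)
bounding box: [0.000, 0.000, 0.000] .. [1.500, 0.000, 0.000] A
```

— two atoms, one bond found by the distance rule (2·0.76 + 0.4 = 1.92 Å
cutoff for C–C). Continue the pipeline:

```bash
hyperview surface di.pdb -o di.obj --radius-scheme uniform --uniform-radius 1.5
# -> "wrote 258 vertices, 512 faces to di.obj"   (fused two-sphere blob)
hyperview render di.pdb -o di.png --rep hyperballs --shading litsphere --size 512x512
hyperview fixtures point-charge-dx -o pc.dx --n 32
hyperview fieldlines pc.dx -o lines.json --max-lines 8 --frames 0.0,0.5
# -> traced lines (radial for a point charge) + two dash-animation frames
hyperview springs di.pdb -o traj.pdb --steps 500 --pull-atom 0
```

Library use mirrors the CLI: `mol_io.parse_pdb`, `topology.detect_bonds`,
`density_surface.compute_density_grid` / `marching_cubes`,
`hyperballs.bond_hyperboloid` / `intersect_ray`, `renderer.render_scene` /
`litsphere_shade`, `field_lines.trace_field_line`, `network3d.parse_xgmml`
/ `depth_layout`, `springs.build_spring_system` / `step`.

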