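# flipperfea

Finite-element structural analysis (FESA) of limb bones loaded by muscle
tension chords, with muscle-force estimation by compressive-stress
homogenization and an analog-model muscle length-change screen.

## The problem

Limb muscles of an extinct animal cannot be measured, but a loading
hypothesis can be tested mechanically: bone adapts toward a
bending-minimized state, so a *correct* set of muscle reconstructions and
lines of action (LOA), with appropriate force magnitudes, should load a
long bone in near-homogeneous compression with very little tension.  This
package implements that test environment for plesiosaur-style flippers —
the system it models is the humerus/femur of an underwater flier whose
girdle muscles drive a dorsoventral flipper beat with a ±19° axial twist —
but all components are generic for any muscle-loaded long bone.

The pipeline:

1. **Geometry** — tetrahedral meshes (4- or 10-node) with region tags
   (bone E = 12 000 MPa, articular cartilage E = 5 MPa, ν = 0.3 for both)
   and named surface sets; STL / Gmsh MSH / VTK VTU I/O; a deterministic
   synthetic-bone generator so no scan data is required.
2. **Muscle loads** — each muscle is a tension chord from an off-bone
   origin through via-points (wrapping) to an on-bone attachment.  Under
   tension *F* it applies a distributed attachment pull, a
   frictionless-post contact force *F*(û_prev + û_next) at each via-point
   (this is how wrapping muscles compress processes such as the dorsal
   tuberosity and the epicondyles), and its share of an equilibrating
   counterforce spread over the distal articular surface.
3. **Force estimation** — per-muscle forces are iterated (40 FE solves)
   until the first/third principal stresses at 12 monitor nodes on the
   outer bone surface satisfy σ₁ ≤ 0.5 MPa and σ₃ ∈ [−10, −0.1] MPa while
   the model displacement is minimized.
4. **Superposition** — downstroke and upstroke stress fields combine
   element-wise into a functional envelope (max σ₁, min σ₃), classified
   into compressive bands (0/−3.6/−7.2/−10.8 MPa) with a max-shear
   summary τ = (σ₁ − σ₃)/2 against the 62–72 MPa shear strength of bone.
5. **Length changes** — cord lengths at maximum ventral (−50°), neutral,
   and maximum dorsal (+50°) flipper excursion give, with neutral = 100 %,
   stretching = 100 + max lengthening %, contraction = 100 − max
   shortening %, and total = stretching − contraction; totals beyond
   ~40 % are outside the physiological envelope of striated muscle.
   The printed measurement table of the *Cryptoclidus eurymerus* mount
   IGPB R 324 ships as a fixture, together with an audit that recomputes
   every derived column from the printed lengths.

## Worked example

```python
from flipperfea import DEFAULT_MATERIALS, generate_case
from flipperfea.loads import FlipperPose, LoadCase
from flipperfea.optimize import OptimizationConfig, build_case_system, optimize

case = generate_case(seed=0)             # synthetic bone + 14 muscles
lc = LoadCase(pose=FlipperPose(0.0, -19.0, "downstroke"), muscles=case.muscles)
system = build_case_system(case.mesh, lc, DEFAULT_MATERIALS,
                           config=OptimizationConfig(seed=1))
sol = optimize(system, OptimizationConfig(seed=1))
print(sol.feasible, round(sol.objective, 4), sol.n_solves)
print(sol.monitor_report.head(3).to_string(index=False))
```

prints

```
True 0.2499 40
 node  sigma1_mpa  sigma3_mpa  violation_mpa  in_band
 1725    0.499999   -0.156690            0.0     True
  281   -0.069191   -0.391543            0.0     True
 2995    0.210801   -0.938335            0.0     True
```

`feasible=True` means all 12 monitor nodes sit in the compressive bands
after 40 exact FE evaluations: the synthetic loading hypothesis produces
the homogeneous compressive state the method requires, and `sol.forces`
holds one member of the (redundant) family of compliant activation
patterns.  The `examples/` directory walks through each capability:
synthetic geometry, closed-form FE validation, force estimation,
superposition reporting, and the length-change screen.

A thin CLI wraps the same functions:

```bash
flipperfea synth --out case --seed 0         # mesh + muscle table + fixtures
flipperfea fesa --out run --seed 1           # both load cases + envelope report
flipperfea lengths --out lc                  # length-change table + chart + audit
flipperfea audit                             # check the printed fixture table
```

## Layout

- `flipperfea.mesh` — TetMesh container, STL/MSH/VTU I/O, scaling, quality
- `flipperfea.fe` — linear-elastic tet4/tet10 solver, principal stresses
- `flipperfea.synthetic` — deterministic bone + muscle-set generator
- `flipperfea.loads` — LOA, attachment/wrapping/counterforce load sets
- `flipperfea.optimize` — monitor nodes, band objective, force iteration
- `flipperfea.superpose` — envelope, band classification, shear summary
- `flipperfea.length_change` — cord lengths → length-change screen + audit
- `flipperfea.fixtures` — packaged printed tables of the study case
- `flipperfea.cli` — `flipperfea` command-line pipeline

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
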