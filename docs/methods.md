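# Methods

This note documents the models behind `flipperfea`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical decisions a user should know before trusting a result.

## Mechanical model

The solver is small-displacement linear elasticity on tetrahedral meshes,
isotropic and homogeneous per region.  Two regions are distinguished:
bone (default E = 12 000 MPa — a deliberately low homogeneous estimate,
since cortical/trabecular inhomogeneity is not modelled; a stiffer
modulus would change strains but not the stress distribution) and the
proximal articular cartilage cap (E = 5 MPa), both with ν = 0.3.  The cap
shares nodes with the bone (bonded contact), and its free surface is the
fixed boundary: the model hangs from its joint socket.

Elements are 4-node (constant-strain) or 10-node tetrahedra.  The 10-node
element uses straight edges with midside nodes (the classic SOLID92
topology) and a four-point Gauss rule, which integrates the stiffness of
a straight-sided quadratic tet exactly.  Stress is recovered per element:
the constant value for tet4, the integration-point average for tet10.
The recovery scheme is a package choice; nodal values used by the
optimizer are volume-weighted averages of the adjacent element values.
Principal stresses are the eigenvalues of the per-element Cauchy tensor,
sorted σ₁ ≥ σ₂ ≥ σ₃, with maximum shear τ = (σ₁ − σ₃)/2.

Units are mm / N / MPa throughout: stresses come out in N/mm² = MPa with
no conversion.  The coordinate frame is +x proximal→distal, +y anterior,
+z dorsal; flipper elevation is a rotation about the anteroposterior
axis, axial twist about the long axis (downstroke: anterior edge down,
twist < 0).

The default sparse path assembles once, reduces for the Dirichlet set,
and factorizes with SuperLU (symmetric-mode, MMD ordering).  The contract
is accuracy, not implementation: on small meshes the solution must match
a dense direct solve to 1e-8 relative, and the test suite enforces this.

## Muscle loading

A muscle is a tension chord: origin (off the bone, on the girdle or the
distal limb), optional via-points where it wraps a bony process, and an
attachment node set on the bone (a geodesic disk, default radius 18 mm,
since attachment outlines are not otherwise known).  Under tension F:

* the attachment carries the distributed pull along the first segment of
  the line of action, split over optional weighted subsections;
* each via-point carries the frictionless-post contact force
  F·(û_prev + û_next), spread over a surface patch (16 mm linear taper) —
  a point contact would be a stress singularity, the very artifact the
  attachment subdivision exists to avoid.  A contact that points out of
  the surface (lift-off in that pose) is dropped with a warning;
* multi-headed muscles enter as their resultant; two-joint muscles apply
  no attachment load and act on the bone only through the counterforce.

The counterforce represents the rest of the flipper: −(vector sum of all
applied loads), spread equally over application points on the distal
articular surface (default 12; a single point is allowed but warned
against).  It enforces translational equilibrium only.  Rotational
equilibrium is deliberately *not* enforced — the procedure applies a
force resultant, not a moment — and the residual moment is reported per
load case so the user can judge it.

Two load cases are analyzed: downstroke and upstroke, each with the bone
horizontal and twisted ±19° about its long axis (the twist angle that
hydrodynamics identifies as optimal for lift generation at plausible
stroke speeds; here it is simply an input parameter).

## Force estimation by stress homogenization

The loading hypothesis is accepted when the bone is in near-homogeneous
compression.  Operationally: 12 monitor nodes are spread over the outer
bone surface by seeded farthest-point sampling (the cartilage cap and the
bone–cartilage interface ring are part of the joint and excluded), and
the nodal principal stresses must satisfy

* σ₁ ≤ 0.5 MPa — a tension cap.  The nominal band is [0, 0.5] MPa, but
  the lower edge is not penalized: at a surface point under contact
  pressure the element-averaged σ₁ is necessarily slightly negative, and
  penalizing that would punish better compression — the opposite of the
  method's goal;
* σ₃ ∈ [−10, −0.1] MPa — decisively compressed everywhere, but not
  excessively.

The objective is (max nodal displacement magnitude) + penalty × (summed
band violations in MPa), penalty default 10³ so either term can dominate.
A node counts as in-band when its violation is ≤ 0.01 MPa, the
discretization noise floor of volume-averaged nodal stress on these
meshes — an order of magnitude below the 0.1 MPa granularity at which the
bands are stated.

Displacement and stress are linear in the muscle-force vector, so the
system factorizes the stiffness once and solves one unit-force problem
per muscle; every objective evaluation then reconstructs the *exact* FE
solution for that force vector and is counted against the iteration
budget (default 40).  The search is a seeded stochastic iteration in the
spirit of subproblem approximation: evaluate the start point (uniform =
geometric mean of the force box, or role-scaled with a 2× head start for
depressors/retractors), ray-search the overall activation level, then
alternate exact-response-model subproblem minimizations with random
log-space perturbation restarts.  Accepted objectives are non-increasing
by construction, and identical seeds give identical solutions.  Force
bounds default to [1, 20 000] N; the lower bound is strictly positive
because the iteration can scale a muscle down but never switch it off.
If no in-band point is found within budget, the best-found forces are
returned flagged infeasible with their violation metrics — never
silently adjusted.

Muscle redundancy means infinitely many activation patterns satisfy the
bands; the package asserts compliance and objective quality, never
uniqueness.  The iteration runs on the linear-order (tet4) model by
default: band compliance is monitored on volume-averaged nodal stresses,
where element order is immaterial, and the linear model factorizes in
well under a second where the quadratic one costs more than a minute and
gigabytes of fill-in on the default mesh.  Quadratic order remains the
default for one-off stress analyses and is available to the pipeline via
`order="quadratic"`.

## Superposition and reporting

Bone responds to the whole load spectrum, so the long-term functional
load is the per-element envelope over cases: max σ₁ and min σ₃ ("highest
principal stresses summarized").  An algebraic per-element sum is
available behind a flag for comparison but is not the default reading.
The compressive axis is classified into low (0 to −3.6 MPa), moderate
(−3.6 to −7.2), and high (−7.2 to −10.8) bands — half-open intervals,
edge values belonging to the more compressive band — with everything
else `out_of_range`; volume fractions sum to 1.  Shear is summarized as
mean ± population SD, both unweighted and volume-weighted (the weighting
behind a whole-model shear statistic is not uniquely defined, so both
are emitted), with a safety ratio against the 62 MPa lower end of bone
shear strength.

## Length-change screen

Cord lengths at maximum ventral (−50°), neutral (0°), and maximum dorsal
(+50°) excursion; protraction/retraction are excluded as minor
contributors to the beat cycle.  With neutral = 100 %:

    stretching  = 100 + (largest positive Δ%)
    contraction = 100 − |most negative Δ%|
    total       = stretching − contraction

Percentage changes are rounded to two decimals *before* combination —
this reproduces the printed-table arithmetic exactly (e.g. 22.35 + 14.61
= 36.96).  Changes smaller than the measurement resolution (1.7 cm, the
width of the analog model's terminal strips) are recorded as zero.  A
total beyond 40 % is flagged non-physiological (boundary inclusive);
±25 % per direction is noted as the sarcomere working range but does not
flip the flag.  No resting length is inferred: the total change is
independent of where rest sits between the extremes.

`audit_table` recomputes every derived column of a printed table from its
cord lengths and lists rows that disagree beyond 0.02.  On the packaged
table it flags nine rows (including a dorsal change printed as −7.63 %
where the lengths give −27.94 %, and a contraction printed as 96.7 vs a
recomputed 91.06); discrepancies are reported, never corrected, and the
acceptance checks use only self-consistent rows.

## Synthetic data

The generator emulates the gross structure the analysis assumes: a long
bone with a rounded proximal head (head radius 42 mm on a 30 × 20 mm oval
shaft of 300 mm), a 10 mm bonded cartilage cap, a dorsal process 12 mm
high at 10 % of shaft length, and distal epicondyles expanded to a 52 mm
anterior half-span.  The mesh is a mapped structured grid: an O-grid
cross-section (square core plus transition rings — tensor-product
square-to-disk maps degenerate at the square corners) swept along
analytic axial profiles, hexes split into 12 tets via face triangles and
the hex centroid with a min-global-index diagonal rule (conforming by
construction).  The mesher balances angular, radial and axial cell sizes
against the requested edge length so the radius-ratio quality stays above
0.05; the requested resolution is therefore a target, not a promise.
Everything is deterministic in the parameters; the seed only drives the
muscle-set jitter and ground-truth force draws.

The muscle set places, per functional role (depressor, elevator,
protractor, retractor, rotator, extensor, flexor), chords that hug the
bone the way flipper muscles do: girdle muscles wrap the proximal head
rim (elevators over the dorsal-process apex) and dive steeply to origins
tucked behind the joint, so each chord's via contact squeezes the shaft
segment down to its staggered insertion; extensors and flexors attach on
the distal shaft, wrap an epicondyle, and pull distally toward off-bone
origins standing in for the rest of the flipper.  Overlapping chord spans
are what make a fully compressive, band-compliant state reachable — the
same reason the original analysis had to add wraps before the processes
carried compression.  Ground-truth forces are drawn log-uniformly in
[100, 10 000] N per antagonist pair (both members share the draw;
independent draws generically bend the bone out of the tension cap).

What the synthetic case does *not* emulate: real cortical/trabecular
architecture, realistic attachment footprints, asymmetric agonist
geometry, or hydrodynamic loading.  In particular the bone is nearly
dorsoventrally symmetric, so the downstroke/upstroke force asymmetry of a
real underwater flier (depressors/retractors stronger than
elevators/protractors) is *not* expected to reproduce — the pipeline
reports the ratio rather than asserting its direction.  Passing tests
demonstrate that the method's machinery is correct, not that the
synthetic bone is a plesiosaur.

## Problem sizes and defaults used in checks

The packaged validations run at desk scale by design: the default
synthetic bone meshes to ~30 000 linear tets (~17 000 dof); the
closed-form bar uses 240 quadratic tets; the cantilever check 37 500
quadratic tets (~110 000 dof, within 10 % of Euler–Bernoulli); the
solver oracle runs at 48 dof against a dense solve.  The published
per-muscle forces and shear means of the fossil study case are shipped
as fixtures only: they depend on the original micro-CT geometry and on
manual final adjustments that no automated pipeline can reproduce (the
package exposes per-muscle force pinning via the optimizer's `start`
argument instead).

## Known limitations

* No geometric or material nonlinearity, no frictional contact, no bone
  inhomogeneity, no remodelling simulation.
* Wrapping is quasi-static via fixed via-points; the path does not slide
  with pose beyond rigid rotation of the frames.
* The counterforce balances forces, not moments; check the reported
  residual moment before interpreting bending patterns.
* No muscle architecture (PCSA, pennation) enters the force bounds; the
  bands alone constrain magnitudes, so forces are hypothesis-test values,
  not physiological estimates.
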